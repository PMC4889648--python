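import numpy as np
import pandas as pd
import pytest

from splicescreen import simdata


@pytest.fixture(scope="session")
def tiny_target() -> simdata.TargetSpec:
    """Short, hand-checkable target: junctions are unambiguous by construction."""
    return simdata.TargetSpec(
        name="toy",
        exon5="ACGTACGTACGT",   # 12 nt
        intron="GGGAGGGAGGGA",  # 12 nt
        exon3="TTCATTCATTCA",   # 12 nt
        junction_flank_k=6,
    )


@pytest.fixture(scope="session")
def targets() -> list[simdata.TargetSpec]:
    return simdata.default_targets()


@pytest.fixture(scope="session")
def small_config(targets) -> simdata.SimulationConfig:
    return simdata.SimulationConfig(n_plates=1, n_replicates=2, targets=targets, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_screen(small_config):
    counts, truth = simdata.simulate_counts(small_config)
    return counts, truth


def make_counts(rows) -> pd.DataFrame:
    """Hand-written count tables for unit tests.

    rows: iterable of (strain_id, plate, well, replicate, target, spliced, unspliced).
    """
    df = pd.DataFrame(
        rows,
        columns=["strain_id", "plate", "well", "replicate", "target", "spliced", "unspliced"],
    )
    df["ambiguous"] = 0
    return df
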