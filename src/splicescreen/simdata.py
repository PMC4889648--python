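"""Synthetic splicing-screen generation.

Produces count tables with the statistical shape of a 384-well pooled
amplicon screen (log-normal read depths, beta-binomial counting noise,
optional plate effects, spiked true effects), plus read-level FASTQ output
with a plate-barcode / well-index structure, and full ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "TargetSpec",
    "BarcodeScheme",
    "SimulationConfig",
    "ScreenTruth",
    "default_targets",
    "generate_barcodes",
    "make_default_scheme",
    "make_layout",
    "physical_plate_id",
    "simulate_counts",
    "simulate_reads",
    "simulate_reads_to_files",
    "make_mixing_series",
    "well_names",
]

_BASES = np.array(list("ACGT"))

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24
WELLS_PER_PLATE = len(PLATE_ROWS) * PLATE_COLS  # 384


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


def well_names() -> list[str]:
    """All 384 well names of a plate in row-major order (A01..P24)."""
    return [f"{r}{c:02d}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]


def physical_plate_id(plate: str, replicate: int) -> str:
    """Label of the physical plate holding one replicate of a source plate."""
    return f"{plate}-r{replicate}"


@dataclass(frozen=True)
class TargetSpec:
    """One amplified splicing event: exon5 | intron | exon3.

    ``junction_flank_k`` bases are required on each side of a junction for a
    read to be classified as derived from one isoform.
    """

    name: str
    exon5: str
    intron: str
    exon3: str
    junction_flank_k: int = 6

    def __post_init__(self) -> None:
        for part in ("exon5", "intron", "exon3"):
            seq = getattr(self, part)
            if not seq or set(seq) - set("ACGT"):
                raise ConfigError(f"TargetSpec.{part}: nonempty A/C/G/T string required")
        k = self.junction_flank_k
        if k < 1:
            raise ConfigError("TargetSpec.junction_flank_k: must be >= 1")
        if min(len(self.exon5), len(self.intron), len(self.exon3)) < k:
            raise ConfigError(
                "TargetSpec: every segment must be at least junction_flank_k long"
            )

    @property
    def spliced_seq(self) -> str:
        return self.exon5 + self.exon3

    @property
    def unspliced_seq(self) -> str:
        return self.exon5 + self.intron + self.exon3

    @property
    def junction(self) -> int:
        """0-based position of the exon5 3' end in either isoform."""
        return len(self.exon5)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def default_targets(seed: int = 20160401) -> list[TargetSpec]:
    """Two fixture targets with typical short intron lengths (45 and 59 nt)."""
    rng = np.random.default_rng(seed)
    return [
        TargetSpec(
            name="fet5_intron1",
            exon5=_random_seq(rng, 60),
            intron=_random_seq(rng, 45),
            exon3=_random_seq(rng, 60),
        ),
        TargetSpec(
            name="pwi1_intron2",
            exon5=_random_seq(rng, 60),
            intron=_random_seq(rng, 59),
            exon3=_random_seq(rng, 60),
        ),
    ]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_barcodes(
    n: int, length: int, min_dist: int, rng: np.random.Generator, max_tries: int = 100_000
) -> list[str]:
    """Greedy random code of ``n`` barcodes with pairwise Hamming >= min_dist."""
    codes: list[str] = []
    tries = 0
    while len(codes) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not find {n} barcodes of length {length} at distance {min_dist}"
            )
        cand = _random_seq(rng, length)
        if all(_hamming(cand, c) >= min_dist for c in codes):
            codes.append(cand)
    return codes


@dataclass
class BarcodeScheme:
    """Plate barcodes (insert prefix) plus well-specific index pairs.

    Invariants checked at construction: fixed length within each set, pairwise
    distinct, and pairwise Hamming distance > 2x the mismatch tolerance of the
    set (so mismatch-tolerant assignment is unambiguous).
    """

    plate_barcodes: dict[str, str]
    well_indices: dict[str, tuple[str, str]]
    max_mismatch_plate: int = 0
    max_mismatch_index: int = 1

    def __post_init__(self) -> None:
        self._check_set(list(self.plate_barcodes.values()), self.max_mismatch_plate, "plate")
        i7 = sorted({p[0] for p in self.well_indices.values()})
        i5 = sorted({p[1] for p in self.well_indices.values()})
        self._check_set(i7, self.max_mismatch_index, "i7 index")
        self._check_set(i5, self.max_mismatch_index, "i5 index")
        self.plate_len = len(next(iter(self.plate_barcodes.values())))
        self._plate_lookup = {v: k for k, v in self.plate_barcodes.items()}
        self._pair_lookup = {v: k for k, v in self.well_indices.items()}
        self._i7_set = i7
        self._i5_set = i5

    @staticmethod
    def _check_set(codes: Sequence[str], max_mismatch: int, label: str) -> None:
        if not codes:
            raise ConfigError(f"BarcodeScheme: empty {label} barcode set")
        lengths = {len(c) for c in codes}
        if len(lengths) != 1:
            raise ConfigError(f"BarcodeScheme: {label} barcodes have mixed lengths")
        for i, a in enumerate(codes):
            for b in codes[i + 1 :]:
                d = _hamming(a, b)
                if d == 0:
                    raise ConfigError(f"BarcodeScheme: duplicate {label} barcode {a!r}")
                if d <= 2 * max_mismatch:
                    raise ConfigError(
                        f"BarcodeScheme: {label} barcodes {a!r}/{b!r} at Hamming "
                        f"distance {d} <= 2*max_mismatch ({2 * max_mismatch})"
                    )


def make_default_scheme(
    plate_ids: Sequence[str],
    seed: int = 7,
    plate_barcode_len: int = 6,
    index_len: int = 8,
    max_mismatch_plate: int = 0,
    max_mismatch_index: int = 1,
) -> BarcodeScheme:
    """Generate a collision-free scheme: one barcode per physical plate and a
    row-index x column-index pair per well (16 i5 x 24 i7)."""
    rng = np.random.default_rng(seed)
    plates = generate_barcodes(len(plate_ids), plate_barcode_len, 3, rng)
    i7 = generate_barcodes(PLATE_COLS, index_len, 3, rng)
    i5 = generate_barcodes(len(PLATE_ROWS), index_len, 3, rng)
    wells = {
        f"{row}{col:02d}": (i7[col - 1], i5[ri])
        for ri, row in enumerate(PLATE_ROWS)
        for col in range(1, PLATE_COLS + 1)
    }
    return BarcodeScheme(
        plate_barcodes=dict(zip(plate_ids, plates)),
        well_indices=wells,
        max_mismatch_plate=max_mismatch_plate,
        max_mismatch_index=max_mismatch_index,
    )


@dataclass
class SimulationConfig:
    """Parameters of a synthetic screen.

    Depths are log-normal per sample (``depth_log_mean``/``depth_log_sd`` on
    the natural-log scale). True splice indices are log-normal around
    ``baseline_si``; a ``spiked_fraction`` of strains get a true log2
    fold-change drawn uniformly from ``effect_log2_range``. Counting noise is
    beta-binomial with intra-class correlation ``overdispersion_rho``.
    """

    n_plates: int = 1
    n_replicates: int = 2
    targets: list[TargetSpec] = field(default_factory=default_targets)
    depth_log_mean: float = math.log(5000.0)
    depth_log_sd: float = 0.8
    baseline_si: float = 0.02
    si_log_sd: float = 0.3
    overdispersion_rho: float = 5e-4
    spiked_fraction: float = 0.0
    effect_log2_range: tuple[float, float] = (2.0, 4.0)
    effect_direction: str = "increase"  # "increase" | "decrease" | "both"
    plate_effect_log2_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plates < 1:
            raise ConfigError("SimulationConfig.n_plates: must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("SimulationConfig.n_replicates: must be >= 1")
        if not self.targets:
            raise ConfigError("SimulationConfig.targets: at least one target required")
        if not self.baseline_si > 0:
            raise ConfigError("SimulationConfig.baseline_si: must be > 0")
        if not 0 <= self.overdispersion_rho < 1:
            raise ConfigError("SimulationConfig.overdispersion_rho: must be in [0, 1)")
        if not 0 <= self.spiked_fraction <= 1:
            raise ConfigError("SimulationConfig.spiked_fraction: must be in [0, 1]")
        if self.effect_log2_range[0] > self.effect_log2_range[1]:
            raise ConfigError("SimulationConfig.effect_log2_range: min > max")
        if self.effect_direction not in ("increase", "decrease", "both"):
            raise ConfigError(
                "SimulationConfig.effect_direction: one of increase/decrease/both"
            )
        if self.depth_log_sd < 0 or self.si_log_sd < 0 or self.plate_effect_log2_sd < 0:
            raise ConfigError("SimulationConfig: scale parameters must be >= 0")

    @property
    def n_strains(self) -> int:
        return self.n_plates * WELLS_PER_PLATE

    @property
    def plate_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_plates)]


@dataclass
class ScreenTruth:
    """Simulator ground truth.

    ``strains``: one row per (strain_id, target) with true_si, is_spiked,
    effect_log2. ``depths``: one row per (strain_id, target, replicate) with
    total_depth. ``plate_effects``: additive log2 offset per
    (plate, replicate, target).
    """

    strains: pd.DataFrame
    depths: pd.DataFrame
    plate_effects: pd.DataFrame


def make_layout(config: SimulationConfig) -> pd.DataFrame:
    """Library layout: one row per (physical plate, well) position.

    Columns: plate_id (physical, barcode key), plate (source), well,
    strain_id, replicate.
    """
    wells = well_names()
    rows = []
    strain = 0
    for plate in config.plate_ids:
        for well in wells:
            strain += 1
            sid = f"strain_{strain:05d}"
            for rep in range(1, config.n_replicates + 1):
                rows.append((physical_plate_id(plate, rep), plate, well, sid, rep))
    return pd.DataFrame(
        rows, columns=["plate_id", "plate", "well", "strain_id", "replicate"]
    )


def _draw_unspliced(
    rng: np.random.Generator, depth: np.ndarray, pi: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial(n=depth, mean pi, ICC rho); plain binomial when rho=0."""
    if rho == 0:
        return rng.binomial(depth, pi)
    a = pi * (1 - rho) / rho
    b = (1 - pi) * (1 - rho) / rho
    p = rng.beta(a, b)
    return rng.binomial(depth, p)


def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate per-sample spliced/unspliced counts for a whole screen.

    Returns a count table (one row per strain x target x replicate, columns
    strain_id, plate, well, replicate, target, spliced, unspliced, ambiguous)
    and the generating ground truth. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    layout = make_layout(config)
    strains = layout[["plate", "well", "strain_id"]].drop_duplicates("strain_id")
    n = len(strains)

    spiked = rng.random(n) < config.spiked_fraction
    base_log2 = np.log2(config.baseline_si) + rng.normal(0, config.si_log_sd, size=n)

    truth_rows = []
    count_frames = []
    effect_rows = []
    for t in config.targets:
        effect = np.zeros(n)
        if spiked.any():
            mags = rng.uniform(*config.effect_log2_range, size=int(spiked.sum()))
            if config.effect_direction == "decrease":
                mags = -mags
            elif config.effect_direction == "both":
                mags *= rng.choice([-1.0, 1.0], size=mags.size)
            effect[spiked] = mags
        true_si = 2.0 ** (base_log2 + effect)
        truth_rows.append(
            pd.DataFrame(
                {
                    "strain_id": strains["strain_id"].to_numpy(),
                    "target": t.name,
                    "true_si": true_si,
                    "is_spiked": spiked,
                    "effect_log2": effect,
                }
            )
        )
        for rep in range(1, config.n_replicates + 1):
            pe = {
                p: rng.normal(0, config.plate_effect_log2_sd)
                if config.plate_effect_log2_sd > 0
                else 0.0
                for p in config.plate_ids
            }
            effect_rows.extend(
                (p, rep, t.name, off) for p, off in pe.items()
            )
            offsets = strains["plate"].map(pe).to_numpy()
            si_sample = true_si * 2.0**offsets
            pi = si_sample / (1.0 + si_sample)
            depth = np.maximum(
                1,
                np.rint(
                    rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=n)
                ).astype(np.int64),
            )
            unspliced = _draw_unspliced(rng, depth, pi, config.overdispersion_rho)
            count_frames.append(
                pd.DataFrame(
                    {
                        "strain_id": strains["strain_id"].to_numpy(),
                        "plate": strains["plate"].to_numpy(),
                        "well": strains["well"].to_numpy(),
                        "replicate": rep,
                        "target": t.name,
                        "spliced": depth - unspliced,
                        "unspliced": unspliced,
                        "ambiguous": 0,
                    }
                )
            )

    counts = pd.concat(count_frames, ignore_index=True)
    counts = counts.sort_values(
        ["target", "plate", "well", "replicate"], kind="stable"
    ).reset_index(drop=True)
    truth = ScreenTruth(
        strains=pd.concat(truth_rows, ignore_index=True),
        depths=counts[["strain_id", "target", "replicate"]].assign(
            total_depth=(counts["spliced"] + counts["unspliced"]).to_numpy()
        ),
        plate_effects=pd.DataFrame(
            effect_rows, columns=["plate", "replicate", "target", "log2_offset"]
        ),
    )
    return counts, truth


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        subs = rng.choice(_BASES, size=int(hit.sum()))
        for i, pos in enumerate(np.flatnonzero(hit)):
            cur = arr[pos].decode()
            new = subs[i]
            if new == cur:  # force a substitution
                new = "ACGT"[("ACGT".index(cur) + 1) % 4]
            arr[pos] = new.encode()
    return arr.tobytes().decode()


def simulate_reads(
    counts: pd.DataFrame,
    scheme: BarcodeScheme,
    targets: Sequence[TargetSpec],
    read_length: int,
    seed: int,
    error_rate: float = 0.0,
) -> Iterator[tuple[str, str, str, str, str, str, str]]:
    """Yield simulated reads for every count in ``counts``.

    Each yielded tuple is (read_id, sequence, index_pair_comment, plate_id,
    well, target, isoform). Sequences are plate barcode + an isoform fragment
    guaranteed to span the relevant junction with >= junction_flank_k bases on
    each side. Order is deterministic given the seed.
    """
    tmap = {t.name: t for t in targets}
    insert_len = read_length - scheme.plate_len
    for t in tmap.values():
        if insert_len < 2 * t.junction_flank_k:
            raise ConfigError(
                f"read_length too short for target {t.name}: need >= "
                f"{scheme.plate_len + 2 * t.junction_flank_k}"
            )
    rng = np.random.default_rng(seed)
    rid = 0
    for row in counts.itertuples(index=False):
        t = tmap[row.target]
        plate_id = physical_plate_id(row.plate, row.replicate)
        barcode = scheme.plate_barcodes[plate_id]
        i7, i5 = scheme.well_indices[row.well]
        comment = f"{i7}+{i5}"
        k = t.junction_flank_k
        for isoform, n_reads in (("spliced", row.spliced), ("unspliced", row.unspliced)):
            if n_reads <= 0:
                continue
            seq = t.spliced_seq if isoform == "spliced" else t.unspliced_seq
            if isoform == "spliced":
                junctions = np.full(n_reads, t.junction)
            else:
                # span either the 5' or the 3' exon-intron boundary
                junctions = rng.choice(
                    [t.junction, t.junction + len(t.intron)], size=n_reads
                )
            for j in junctions:
                lo = max(0, j + k - insert_len)
                hi = j - k
                start = int(rng.integers(lo, hi + 1))
                frag = seq[start : start + insert_len]
                read = _apply_errors(barcode + frag, rng, error_rate)
                rid += 1
                yield (f"sim:{rid}", read, comment, plate_id, row.well, row.target, isoform)


def simulate_reads_to_files(
    counts: pd.DataFrame,
    scheme: BarcodeScheme,
    targets: Sequence[TargetSpec],
    read_length: int,
    seed: int,
    fastq: TextIO,
    manifest: TextIO,
    error_rate: float = 0.0,
) -> int:
    """Stream simulated reads to a FASTQ handle and a TSV truth manifest.

    Returns the number of reads written. Qualities are constant 'I' (Phred 40).
    """
    manifest.write("read_id\tplate_id\twell\ttarget\tisoform\n")
    n = 0
    buf: list[str] = []
    for rid, seq, comment, plate_id, well, target, isoform in simulate_reads(
        counts, scheme, targets, read_length, seed, error_rate
    ):
        buf.append(f"@{rid} {comment}\n{seq}\n+\n{'I' * len(seq)}\n")
        manifest.write(f"{rid}\t{plate_id}\t{well}\t{target}\t{isoform}\n")
        n += 1
        if len(buf) >= 10_000:
            fastq.write("".join(buf))
            buf.clear()
    fastq.write("".join(buf))
    return n


def make_mixing_series(
    ratios: Iterable[float],
    depth: int,
    target: TargetSpec,
    seed: int,
    plate: str = "MIX",
) -> pd.DataFrame:
    """Counts for samples with known unspliced molecule fractions.

    Each ratio is the true unspliced fraction; counts are binomial at the
    given depth. Used to validate accuracy/linearity of the counting pipeline.
    """
    ratios = list(ratios)
    for r in ratios:
        if not 0 <= r <= 1:
            raise ConfigError(f"make_mixing_series: ratio {r} outside [0, 1]")
    if depth < 1:
        raise ConfigError("make_mixing_series: depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i, r in enumerate(ratios):
        unspliced = int(rng.binomial(depth, r))
        rows.append(
            (
                f"mix_{i:03d}",
                plate,
                f"A{i + 1:02d}",
                1,
                target.name,
                depth - unspliced,
                unspliced,
                0,
                r,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "plate",
            "well",
            "replicate",
            "target",
            "spliced",
            "unspliced",
            "ambiguous",
            "true_unspliced_fraction",
        ],
    )
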