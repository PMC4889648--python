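"""Cross-target statistics and end-to-end screen orchestration."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from splicescreen import nullmodel, sicore
from splicescreen.simdata import ScreenTruth, SimulationConfig, simulate_counts

__all__ = ["OverlapResult", "overlap_fisher", "hit_union", "run_screen_pipeline"]


@dataclass
class OverlapResult:
    """Fisher's exact test of overlap between two hit sets in one universe."""

    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float


def overlap_fisher(hits_a: set, hits_b: set, universe: set) -> OverlapResult:
    """Hypergeometric enrichment of the overlap of two strain sets.

    One-sided p is the upper tail P(X >= k) with k the observed overlap;
    two-sided p is the standard Fisher sum of tables at most as probable.
    """
    hits_a, hits_b, universe = set(hits_a), set(hits_b), set(universe)
    bad = (hits_a | hits_b) - universe
    if bad:
        raise ValueError(f"hits not in universe: {sorted(bad)[:10]}")
    n, n_a, n_b = len(universe), len(hits_a), len(hits_b)
    k = len(hits_a & hits_b)
    table = [[k, n_a - k], [n_b - k, n - n_a - n_b + k]]
    p_one = float(stats.hypergeom.sf(k - 1, n, n_a, n_b))
    p_two = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    denom = table[0][1] * table[1][0]
    odds = (table[0][0] * table[1][1] / denom) if denom else math.inf
    return OverlapResult(
        n_universe=n,
        n_a=n_a,
        n_b=n_b,
        n_overlap=k,
        odds_ratio=odds,
        p_one_sided=min(p_one, 1.0),
        p_two_sided=min(p_two, 1.0),
    )


def hit_union(calls_by_target: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of significant strains with per-target flags and direction.

    Direction is 'up' (higher relative SI than the null mean) or 'down'.
    """
    rows: dict[str, dict] = {}
    targets = list(calls_by_target)
    for target, calls in calls_by_target.items():
        sig = calls[calls["significant"]]
        for r in sig.itertuples(index=False):
            entry = rows.setdefault(r.strain_id, {"strain_id": r.strain_id})
            entry[f"significant_{target}"] = True
            entry[f"direction_{target}"] = "up" if r.z > 0 else "down"
            entry[f"q_{target}"] = r.q
    out = pd.DataFrame(rows.values())
    if out.empty:
        cols = ["strain_id"] + [f"significant_{t}" for t in targets]
        return pd.DataFrame(columns=cols)
    for t in targets:
        col = f"significant_{t}"
        if col not in out.columns:
            out[col] = False
        out[col] = out[col].eq(True)  # NaN (not significant for this target) -> False
    return out.sort_values("strain_id", kind="stable").reset_index(drop=True)


def run_screen_pipeline(
    config: SimulationConfig | None = None,
    counts: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    n_bins: int = nullmodel.DEFAULT_BINS,
    alpha: float = nullmodel.DEFAULT_ALPHA,
    universe: set | None = None,
) -> dict:
    """Run simulate/load -> SI -> QC -> null model -> calls -> overlap.

    Exactly one of ``config`` (simulate mode) or ``counts`` (analysis mode)
    must be given. Returns a result dict with all intermediate tables; when
    ``out_dir`` is set, writes them as TSV plus a JSON model dump and a text
    summary.
    """
    if (config is None) == (counts is None):
        raise ValueError("provide exactly one of config (simulate) or counts (analyze)")
    truth: ScreenTruth | None = None
    if config is not None:
        counts, truth = simulate_counts(config)

    normalized = sicore.plate_normalize(sicore.add_splice_index(counts))
    measurements = sicore.filter_replicates(normalized)
    summary_table = sicore.summarize_dataset(normalized, measurements)

    calls_by_target: dict[str, pd.DataFrame] = {}
    models: dict[str, nullmodel.NullModel] = {}
    for target in sorted(counts["target"].unique()):
        calls, model = nullmodel.fit_and_call(
            measurements, target, n_bins=n_bins, alpha=alpha
        )
        calls_by_target[target] = calls
        models[target] = model

    union = hit_union(calls_by_target)
    if universe is None:
        universe = set(counts["strain_id"].unique())
    overlap = None
    targets = sorted(calls_by_target)
    if len(targets) == 2:
        a = set(calls_by_target[targets[0]].query("significant")["strain_id"])
        b = set(calls_by_target[targets[1]].query("significant")["strain_id"])
        overlap = overlap_fisher(a, b, universe)

    summary = {
        "mode": "simulate" if config is not None else "analyze",
        "n_strains": int(counts["strain_id"].nunique()),
        "targets": targets,
        "alpha": alpha,
        "n_bins": n_bins,
        "qc_pass": {
            t: int(
                measurements.query("target == @t and passes_qc").shape[0]
            )
            for t in targets
        },
        "n_hits": {t: int(calls_by_target[t]["significant"].sum()) for t in targets},
        "n_union": int(len(union)),
        # strict-JSON safe: a non-finite odds ratio is serialized as None
        "overlap": (
            {
                k: (None if isinstance(v, float) and not math.isfinite(v) else v)
                for k, v in asdict(overlap).items()
            }
            if overlap
            else None
        ),
    }
    if config is not None:
        summary["seed"] = config.seed

    result = {
        "counts": counts,
        "normalized": normalized,
        "measurements": measurements,
        "summary_table": summary_table,
        "calls": calls_by_target,
        "models": models,
        "union": union,
        "overlap": overlap,
        "truth": truth,
        "summary": summary,
    }
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result["counts"].to_csv(out_dir / "counts.tsv", sep="\t", index=False)
    result["normalized"].to_csv(out_dir / "splice_index.tsv", sep="\t", index=False)
    result["measurements"].to_csv(out_dir / "measurements.tsv", sep="\t", index=False)
    result["summary_table"].to_csv(out_dir / "dataset_summary.tsv", sep="\t", index=False)
    calls = pd.concat(result["calls"].values(), ignore_index=True)
    calls.to_csv(out_dir / "calls.tsv", sep="\t", index=False)
    result["union"].to_csv(out_dir / "hit_union.tsv", sep="\t", index=False)
    model_dump = {
        t: {
            "knots": m.knots.to_dict(orient="list"),
            "sigma_floor": m.sigma_floor,
            "x_range": list(m.x_range),
        }
        for t, m in result["models"].items()
    }
    (out_dir / "null_model.json").write_text(json.dumps(model_dump, indent=2))
    (out_dir / "summary.json").write_text(
        json.dumps(result["summary"], indent=2, default=_jsonable)
    )
    # Fig-2-style scatter export: one point per strain, data not images
    scatter = calls.assign(log10_reads=np.log10(calls["combined_reads"]))[
        ["strain_id", "target", "log10_reads", "log2_si_rel", "significant"]
    ]
    scatter.to_csv(out_dir / "scatter.tsv", sep="\t", index=False)
    if result["truth"] is not None:
        result["truth"].strains.to_csv(out_dir / "truth_strains.tsv", sep="\t", index=False)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
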