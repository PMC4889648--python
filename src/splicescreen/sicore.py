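"""Splice-index computation, plate normalization, QC filtering, summaries.

The splice index (SI) of a sample is unspliced/spliced read count. SI is
normalized per physical plate by dividing by the plate-median SI (wild-type
proxy), then strains are filtered on replicate concordance (sample SD of
log2 relative SI < 1) and combined read depth (> 1000, strict).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "compute_si",
    "add_splice_index",
    "plate_normalize",
    "filter_replicates",
    "summarize_dataset",
    "MIN_DEFINED_PER_PLATE",
    "SD_CUTOFF",
    "READS_CUTOFF",
]

SD_CUTOFF = 1.0
READS_CUTOFF = 1000
MIN_DEFINED_PER_PLATE = 8


def compute_si(spliced: int, unspliced: int, pseudocount: float = 0.0) -> tuple[float, bool]:
    """(si, defined) for one sample; undefined when the denominator is zero.

    No pseudocount by default; with one, si = (u + pc) / (s + pc).
    """
    if spliced < 0 or unspliced < 0:
        raise ValueError(f"negative counts: spliced={spliced}, unspliced={unspliced}")
    denom = spliced + pseudocount
    if denom <= 0:
        return math.nan, False
    return (unspliced + pseudocount) / denom, True


def add_splice_index(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Vectorized per-sample SI: adds ``si`` and ``si_defined`` columns."""
    if (counts["spliced"] < 0).any() or (counts["unspliced"] < 0).any():
        raise ValueError("negative counts in input table")
    out = counts.copy()
    denom = out["spliced"].to_numpy(dtype=float) + pseudocount
    num = out["unspliced"].to_numpy(dtype=float) + pseudocount
    defined = denom > 0
    si = np.full(len(out), np.nan)
    si[defined] = num[defined] / denom[defined]
    out["si"] = si
    out["si_defined"] = defined
    return out


def plate_normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's SI by its plate median.

    Groups are (plate, replicate, target) — each physical plate normalized by
    its own median over defined SIs (even-n median = mean of central pair).
    Groups with median 0 or fewer than MIN_DEFINED_PER_PLATE defined records
    are flagged and their si_rel left undefined. Adds ``plate_median``,
    ``si_rel``, ``plate_flagged``.
    """
    if "si" not in records.columns:
        records = add_splice_index(records)
    out = records.copy()
    keys = ["plate", "replicate", "target"]

    def _median(g: pd.Series) -> float:
        vals = g.dropna()
        return float(vals.median()) if len(vals) else math.nan

    med = out.groupby(keys)["si"].transform(_median)
    n_def = out.groupby(keys)["si_defined"].transform("sum")
    flagged = (med == 0) | ~np.isfinite(med) | (n_def < MIN_DEFINED_PER_PLATE)
    out["plate_median"] = med
    out["plate_flagged"] = flagged
    si_rel = out["si"] / med
    si_rel[flagged] = np.nan
    out["si_rel"] = si_rel
    return out


def filter_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-replicate relative SIs into per-strain measurements.

    Per (strain_id, target): ``log2_si_rel`` is the mean over replicates of
    log2(si_rel); ``replicate_sd`` the sample SD (n-1 denominator; equals
    |a-b|/sqrt(2) for two replicates); ``combined_reads`` the spliced +
    unspliced total over replicates (ambiguous excluded). QC passes iff
    replicate_sd < 1, combined_reads > 1000 (both strict) and every
    replicate's si_rel is defined and > 0.
    """
    df = normalized.copy()
    df["reads"] = df["spliced"] + df["unspliced"]
    df["ok"] = df["si_rel"].notna() & (df["si_rel"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["log2_si_rel_rep"] = np.where(df["ok"], np.log2(df["si_rel"]), np.nan)

    g = df.groupby(["strain_id", "target"], sort=True)
    agg = g.agg(
        combined_reads=("reads", "sum"),
        n_replicates=("replicate", "size"),
        n_ok=("ok", "sum"),
        log2_si_rel=("log2_si_rel_rep", "mean"),
        replicate_sd=("log2_si_rel_rep", lambda v: v.std(ddof=1)),
    ).reset_index()

    all_ok = agg["n_ok"] == agg["n_replicates"]
    sd = agg["replicate_sd"].fillna(0.0)  # single replicate: concordance vacuous
    agg["replicate_sd"] = np.where(agg["n_replicates"] > 1, agg["replicate_sd"], 0.0)
    passes = (
        all_ok
        & (np.where(agg["n_replicates"] > 1, sd, 0.0) < SD_CUTOFF)
        & (agg["combined_reads"] > READS_CUTOFF)
    )
    reason = np.full(len(agg), "", dtype=object)
    reason[~all_ok] = "undefined_si_rel"
    reason[all_ok & ~(sd < SD_CUTOFF)] = "replicate_sd"
    reason[all_ok & (sd < SD_CUTOFF) & ~(agg["combined_reads"] > READS_CUTOFF)] = "low_reads"
    agg["passes_qc"] = passes
    agg["qc_reason"] = reason
    agg.loc[~all_ok, "log2_si_rel"] = np.nan
    return agg.drop(columns=["n_ok"])


def summarize_dataset(
    normalized: pd.DataFrame, measurements: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-target dataset summary.

    median_si / iqr_si over all defined per-sample SIs; replicate R^2 is the
    squared Pearson correlation of replicate-1 vs replicate-2 log2(si_rel)
    over QC-passing strains (NaN when fewer than two replicates).
    """
    if measurements is None:
        measurements = filter_replicates(normalized)
    rows = []
    for target, sub in normalized.groupby("target", sort=True):
        si = sub.loc[sub["si_defined"], "si"]
        q1, q3 = si.quantile([0.25, 0.75])
        passing = set(
            measurements.loc[
                (measurements["target"] == target) & measurements["passes_qc"],
                "strain_id",
            ]
        )
        r2 = math.nan
        reps = sorted(sub["replicate"].unique())
        if len(reps) >= 2 and passing:
            ok = sub[sub["strain_id"].isin(passing) & sub["si_rel"].gt(0)]
            wide = ok.pivot_table(
                index="strain_id", columns="replicate", values="si_rel", aggfunc="first"
            )
            wide = np.log2(wide[[reps[0], reps[1]]].dropna())
            if len(wide) >= 2:
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(wide[reps[0]], wide[reps[1]])[0, 1]
                r2 = float(r**2)
        rows.append(
            {
                "target": target,
                "n_samples": len(sub),
                "n_strains": sub["strain_id"].nunique(),
                "median_si": float(si.median()),
                "iqr_si": float(q3 - q1),
                "replicate_r2": r2,
                "n_pass_qc": len(passing),
            }
        )
    return pd.DataFrame(rows)
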