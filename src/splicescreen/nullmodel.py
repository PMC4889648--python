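"""Read-depth-aware empirical null and hit calling.

QC-passing strains are ranked by combined read depth and split into B
equal-size bins; the per-bin mean and SD of log2 relative SI become knots of
natural cubic interpolating splines mu(x) and sigma(x) over x = log10 reads.
Each strain is scored Z = (log2_si_rel - mu(x)) / sigma(x), given a
two-sided normal p-value, Benjamini-Hochberg corrected per target, and an
approximate 95% CI of log2_si_rel +/- 2*sigma(x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import norm

__all__ = [
    "DepthBin",
    "NullModel",
    "bin_by_depth",
    "fit_null_spline",
    "score_strains",
    "bh_correct",
    "call_hits",
    "fit_and_call",
    "DEFAULT_BINS",
    "DEFAULT_ALPHA",
    "DEFAULT_SIGMA_FLOOR",
]

DEFAULT_BINS = 20
DEFAULT_ALPHA = 0.05
DEFAULT_SIGMA_FLOOR = 1e-6


@dataclass
class DepthBin:
    """Summary of one rank-based read-depth bin of QC-passing strains."""

    bin_index: int
    strain_ids: list[str]
    x: float  # mean log10 combined reads
    mu: float  # mean log2_si_rel
    sigma: float  # sample SD of log2_si_rel
    n_members: int


@dataclass
class NullModel:
    """Spline-interpolated null mean/SD of log2_si_rel vs log10 read depth."""

    target: str
    knots: pd.DataFrame  # columns x, mu, sigma, n_members
    sigma_floor: float
    _mu_spline: CubicSpline
    _sigma_spline: CubicSpline

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.knots["x"].iloc[0]), float(self.knots["x"].iloc[-1])

    def mu(self, x: np.ndarray | float) -> np.ndarray:
        lo, hi = self.x_range
        return np.asarray(self._mu_spline(np.clip(x, lo, hi)))

    def sigma(self, x: np.ndarray | float) -> np.ndarray:
        lo, hi = self.x_range
        s = np.asarray(self._sigma_spline(np.clip(x, lo, hi)))
        return np.maximum(s, self.sigma_floor)


def bin_by_depth(measurements: pd.DataFrame, n_bins: int = DEFAULT_BINS) -> list[DepthBin]:
    """Split QC-passing strains into ``n_bins`` contiguous rank-based bins.

    Sorted by combined_reads (ties broken by strain_id); the remainder r of
    n / n_bins is spread over the first r bins, so sizes differ by at most 1.
    """
    df = measurements
    if "passes_qc" in df.columns:
        df = df[df["passes_qc"]]
    n = len(df)
    if n < 2 * n_bins:
        raise ValueError(
            f"{n} QC-passing strains is too few for {n_bins} bins; lower n_bins"
        )
    df = df.sort_values(["combined_reads", "strain_id"], kind="stable").reset_index(drop=True)
    base, rem = divmod(n, n_bins)
    bins: list[DepthBin] = []
    start = 0
    for i in range(n_bins):
        size = base + (1 if i < rem else 0)
        chunk = df.iloc[start : start + size]
        start += size
        log_reads = np.log10(chunk["combined_reads"].to_numpy(dtype=float))
        vals = chunk["log2_si_rel"].to_numpy(dtype=float)
        bins.append(
            DepthBin(
                bin_index=i,
                strain_ids=chunk["strain_id"].tolist(),
                x=float(log_reads.mean()),
                mu=float(vals.mean()),
                sigma=float(vals.std(ddof=1)),
                n_members=size,
            )
        )
    return bins


def fit_null_spline(
    bins: list[DepthBin],
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    target: str = "",
) -> NullModel:
    """Natural cubic interpolating splines through the bin (x, mu, sigma) knots.

    Duplicate knot abscissae are merged by averaging (with a warning).
    Evaluation outside the knot range clamps to the boundary knot values;
    sigma is floored at ``sigma_floor``.
    """
    knots = pd.DataFrame(
        {
            "x": [b.x for b in bins],
            "mu": [b.mu for b in bins],
            "sigma": [b.sigma for b in bins],
            "n_members": [b.n_members for b in bins],
        }
    ).sort_values("x", kind="stable")
    if knots["x"].duplicated().any():
        warnings.warn("duplicate bin abscissae; merging knots by averaging", stacklevel=2)
        knots = knots.groupby("x", as_index=False).agg(
            mu=("mu", "mean"), sigma=("sigma", "mean"), n_members=("n_members", "sum")
        )
    if len(knots) < 4:
        raise ValueError(f"need >= 4 distinct knots for a cubic spline, got {len(knots)}")
    knots = knots.reset_index(drop=True)
    x = knots["x"].to_numpy()
    return NullModel(
        target=target,
        knots=knots,
        sigma_floor=sigma_floor,
        _mu_spline=CubicSpline(x, knots["mu"].to_numpy(), bc_type="natural"),
        _sigma_spline=CubicSpline(x, knots["sigma"].to_numpy(), bc_type="natural"),
    )


def score_strains(measurements: pd.DataFrame, model: NullModel) -> pd.DataFrame:
    """Z-score and two-sided normal p-value per QC-passing strain.

    x = log10(combined_reads); p = 2 * (1 - Phi(|Z|)), floored into (0, 1];
    CI bounds are log2_si_rel +/- 2 * sigma(x).
    """
    df = measurements
    if "passes_qc" in df.columns:
        df = df[df["passes_qc"]]
    df = df.reset_index(drop=True)
    x = np.log10(df["combined_reads"].to_numpy(dtype=float))
    mu = model.mu(x)
    sigma = model.sigma(x)
    vals = df["log2_si_rel"].to_numpy(dtype=float)
    z = (vals - mu) / sigma
    p = np.minimum(2.0 * norm.sf(np.abs(z)), 1.0)
    p = np.maximum(p, np.finfo(float).tiny)
    out = pd.DataFrame(
        {
            "strain_id": df["strain_id"],
            "target": model.target if model.target else df.get("target", ""),
            "log2_si_rel": vals,
            "combined_reads": df["combined_reads"],
            "z": z,
            "p": p,
            "ci_low": vals - 2.0 * sigma,
            "ci_high": vals + 2.0 * sigma,
        }
    )
    return out


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_hits(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Add BH q-values and the significance flag (q < alpha, strict).

    Returned table is sorted by q then descending |z|.
    """
    out = results.copy()
    out["q"] = bh_correct(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out = out.assign(_absz=out["z"].abs()).sort_values(
        ["q", "_absz"], ascending=[True, False], kind="stable"
    )
    return out.drop(columns="_absz").reset_index(drop=True)


def fit_and_call(
    measurements: pd.DataFrame,
    target: str,
    n_bins: int = DEFAULT_BINS,
    alpha: float = DEFAULT_ALPHA,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> tuple[pd.DataFrame, NullModel]:
    """Full per-target pass: bin, fit, score, BH-correct, flag."""
    sub = measurements[measurements["target"] == target]
    bins = bin_by_depth(sub, n_bins)
    model = fit_null_spline(bins, sigma_floor=sigma_floor, target=target)
    calls = call_hits(score_strains(sub, model), alpha=alpha)
    return calls, model
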