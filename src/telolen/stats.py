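"""Replicate-variability and comparison statistics.

Companions to the estimator for evaluating its output: the coefficient of
variation across technical replicates (sequencing lanes), a two-sided
F-test comparing estimate variances between groups (e.g. low- versus
high-coverage runs), and a bootstrap test for the difference between two
correlation coefficients sharing a common variable (e.g. two length
measures against donor age).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["replicate_cv", "variance_f_test", "bootstrap_corr_diff", "cv_table"]


def replicate_cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over mean.

    Defined for >= 2 replicate values with a positive mean; invariant to
    rescaling all values by a positive constant.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 replicate values")
    mean = arr.mean()
    if not mean > 0:
        raise ValueError("CV requires a positive mean")
    return float(arr.std(ddof=1) / mean)


def variance_f_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """F-test of equal variances: F = var(a)/var(b), two-sided p.

    Sample variances use the n-1 denominator; p comes from the F
    distribution with (n_a - 1, n_b - 1) degrees of freedom, doubled and
    capped at 1 for two-sidedness.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("degenerate group with zero variance")
    f = float(va / vb)
    dist = sps.f(a.size - 1, b.size - 1)
    p = float(min(1.0, 2 * min(dist.cdf(f), dist.sf(f))))
    return f, p


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (B, n) matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom


def _rank_rows(m: np.ndarray) -> np.ndarray:
    return sps.rankdata(m, axis=1)


def bootstrap_corr_diff(
    x: Sequence[float],
    y1: Sequence[float],
    y2: Sequence[float],
    B: int = 1000,
    seed: int = 0,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float, float]:
    """Test whether corr(x, y1) differs from corr(x, y2).

    Paired case resampling: bootstrap replicates resample whole rows
    (x_i, y1_i, y2_i), preserving the dependence between the two
    correlations.  Returns (delta_rho, sd(delta_rho), two-sided p) where p
    refers delta_rho / sd to a standard normal.  Deterministic given seed.
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = x.size
    if not (y1.size == n and y2.size == n):
        raise ValueError("x, y1, y2 must have equal length")
    if n < 5:
        raise ValueError("need at least 5 observations")
    if B < 100:
        raise ValueError("B must be >= 100")
    for name, v in (("x", x), ("y1", y1), ("y2", y2)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")

    if method == "spearman":
        corr = lambda a, b: sps.spearmanr(a, b).statistic  # noqa: E731
    elif method == "pearson":
        corr = lambda a, b: sps.pearsonr(a, b).statistic  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    delta = float(corr(x, y1) - corr(x, y2))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    xb, y1b, y2b = x[idx], y1[idx], y2[idx]
    if method == "spearman":
        xb, y1b, y2b = _rank_rows(xb), _rank_rows(y1b), _rank_rows(y2b)
    diffs = _pearson_rows(xb, y1b) - _pearson_rows(xb, y2b)
    diffs = diffs[np.isfinite(diffs)]  # drop rare constant resamples
    if diffs.size < 2:
        raise ValueError("bootstrap produced too few valid replicates")
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2 * sps.norm.sf(abs(delta) / sd))
    return delta, sd, p


def cv_table(
    report: pd.DataFrame,
    sample_col: str = "sample",
    value_col: str = "length_kb",
) -> pd.DataFrame:
    """Per-sample lane variability from an estimator report.

    Groups rows (one per lane / read group) by sample and returns columns
    sample, n_lanes, mean_kb, sd_kb, cv.  Samples with fewer than 2
    defined estimates are dropped.
    """
    rows = []
    for sample, grp in report.groupby(sample_col):
        vals = grp[value_col].dropna().to_numpy(dtype=float)
        if vals.size < 2 or vals.mean() <= 0:
            continue
        rows.append(
            {
                "sample": sample,
                "n_lanes": vals.size,
                "mean_kb": vals.mean(),
                "sd_kb": vals.std(ddof=1),
                "cv": replicate_cv(vals),
            }
        )
    return pd.DataFrame(rows, columns=["sample", "n_lanes", "mean_kb", "sd_kb", "cv"])
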