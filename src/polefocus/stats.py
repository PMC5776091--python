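"""Correlation and ANOVA utilities, plus the reporter-vs-clustering analysis."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p_value: float
    n: int
    flagged: bool = False          # zero variance -> undefined coefficient

    def __post_init__(self):
        if not self.flagged and not (-1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12):
            raise ValueError("correlation coefficient outside [-1, 1]")


def correlation(x: Sequence[float], y: Sequence[float],
                method: str = "pearson",
                n_permutations: Optional[int] = None,
                seed: int = 0) -> CorrelationResult:
    """Pearson or Spearman correlation with a t-approximation p-value.

    Spearman uses average ranks for ties.  Zero variance in either series
    yields a flagged result with NaN coefficient.  For small samples an
    exact-style permutation p-value can be requested via ``n_permutations``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 observations for a p-value")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(method, math.nan, math.nan, len(x), flagged=True)
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    coef, p = float(res[0]), float(res[1])
    if n_permutations:
        rng = np.random.default_rng(seed)
        stat = abs(coef)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(y)
            if method == "pearson":
                c = sps.pearsonr(x, perm)[0]
            else:
                c = sps.spearmanr(x, perm)[0]
            if abs(c) >= stat:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    return CorrelationResult(method, coef, p, len(x))


def one_way_anova(groups: Sequence[Sequence[float]]):
    """Ordinary one-way ANOVA: between/within mean-square ratio on
    (k - 1, N - k) degrees of freedom.  Returns (F, p)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(a.std() == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if np.allclose(means, means[0]):
            return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def bootstrap_correlation_ci(x, y, method="pearson", n_boot: int = 2000,
                             alpha: float = 0.05, seed: int = 0):
    """Percentile bootstrap confidence interval for a correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(x)
    coefs = np.empty(n_boot)
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if x[idx].std() == 0 or y[idx].std() == 0:
            coefs[b] = np.nan
            continue
        coefs[b] = fn(x[idx], y[idx])[0]
    lo, hi = np.nanpercentile(coefs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def reporter_vs_clustering(cell_stats: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of per-cell reporter mean intensity against the
    fluorophore SDI, quantified on the same frame.

    ``cell_stats`` needs columns ``reporter_mi`` and ``sdi``.  The scatter
    table is attached as ``.scatter`` on the result.
    """
    if len(cell_stats) < 3:
        raise ValueError("need >= 3 cells")
    res = correlation(cell_stats["sdi"], cell_stats["reporter_mi"], "pearson")
    res.scatter = cell_stats[["sdi", "reporter_mi"]].copy()  # type: ignore[attr-defined]
    return res
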