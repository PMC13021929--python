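"""Statistical kernels: BH-FDR, Wilcoxon rank-sum, hypergeometric enrichment.

These are deliberately small, explicit implementations of the tests the
analysis depends on; independent library implementations serve as
cross-checks in the test suite, not as the computation path.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 12  # enumerate the rank-sum null exactly up to this total n


def bh_fdr(p: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration when ``len(x) + len(y) <= 12`` and there are no
    ties; otherwise the normal approximation with tie correction and a 0.5
    continuity correction. Degenerate (all-tied) samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < n

    ranks = sps.rankdata(pooled)
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0

    if n <= EXACT_LIMIT and not has_ties:
        dev = abs(w - mu)
        count = sum(
            1
            for combo in combinations(range(1, n + 1), nx)
            if abs(sum(combo) - mu) >= dev - 1e-9
        )
        return count / comb(n, nx)

    tie_sizes = np.unique(pooled, return_counts=True)[1]
    tie_term = float(np.sum(tie_sizes**3 - tie_sizes))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def motif_enrichment_hypergeom(
    fg_with: int, fg_total: int, bg_with: int, bg_total: int
) -> float:
    """Upper-tail (cumulative) hypergeometric enrichment p-value.

    Probability of seeing >= ``fg_with`` motif-bearing members in a foreground
    of ``fg_total`` drawn from a background universe of ``bg_total`` of which
    ``bg_with`` bear the motif.
    """
    if not (0 <= fg_with <= fg_total):
        raise ValueError("require 0 <= fg_with <= fg_total")
    if not (0 <= bg_with <= bg_total):
        raise ValueError("require 0 <= bg_with <= bg_total")
    if fg_total > bg_total or fg_with > bg_with:
        raise ValueError("foreground must be drawn from the background universe")
    return float(sps.hypergeom.sf(fg_with - 1, bg_total, bg_with, fg_total))


def spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations (mid-rank Pearson) between columns.

    Columns with zero rank variance produce NaN against every other column
    (undefined, never reported as 0); the diagonal stays 1 by definition.
    """
    values = np.asarray(values, dtype=float)
    n_col = values.shape[1]
    ranks = np.column_stack([sps.rankdata(values[:, j]) for j in range(n_col)])
    sd = ranks.std(axis=0)
    out = np.full((n_col, n_col), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n_col):
        for j in range(i + 1, n_col):
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = np.corrcoef(ranks[:, i], ranks[:, j])[0, 1]
            out[i, j] = out[j, i] = r
    return out
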