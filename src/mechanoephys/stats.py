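"""The statistical comparisons used by the pipeline.

Paired groups (stiffness during bursts vs IBIs, rates before vs during
compression, waveform features per epoch) use the Wilcoxon signed-rank
test; independent AFM groups use the two-tailed Mann-Whitney U; linear
association between stiffness and firing rate uses Pearson correlation;
responder proportions across stimulation conditions use a Pearson χ² test.

The signed-rank and U tests compute the exact null distribution at small
sample sizes (n ≤ 25 pairs; m + n ≤ 12) — by rank-sum enumeration over all
sign assignments / group assignments, implemented as a dynamic program over
doubled midranks so ties are exact too — and fall back to the normal
approximation with tie correction above.  p values are two-sided throughout;
values > 0.05 are conventionally read as non-significant, and no
multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "paired_wilcoxon",
    "mannwhitney_u",
    "pearson_corr",
    "chisq_proportions",
]


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined on the given data."""


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks of |values| scaled ×2 so tied ranks are exact integers."""
    ranks = sps.rankdata(values)          # midranks, multiples of 0.5
    doubled = np.round(ranks * 2).astype(np.int64)
    return doubled


def _signed_rank_null_cdf(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled rank-sum over all 2^n sign patterns.

    The generating polynomial ∏(1 + x^{r_i}) gives the number of sign
    assignments with positive-rank-sum r; equivalent to full enumeration.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] += counts[:-r].copy() if r > 0 else counts.copy()
    return counts


def paired_wilcoxon(x: Sequence[float], y: Sequence[float],
                    exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (drop-and-report convention); with n
    remaining pairs ≤ ``exact_max_n`` the p value comes from the exact null
    distribution of the positive-rank sum, otherwise from the normal
    approximation with tie correction.  Returns ``(W, p)`` with
    W = min(W+, W−).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)

    if n <= exact_max_n:
        doubled = _doubled_midranks(np.abs(d))
        counts = _signed_rank_null_cdf(doubled)
        total = counts.sum()        # 2**n
        w2 = int(round(w_plus * 2))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            raise DegenerateDataError("zero variance in signed ranks")
        z = (w_plus - mean) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return W, float(min(p, 1.0))


def mannwhitney_u(x: Sequence[float], y: Sequence[float],
                  exact_max_total: int = 12) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test on two independent samples.

    Exact p by enumeration of all C(m+n, m) group assignments of the pooled
    ranks when m + n ≤ ``exact_max_total``; normal approximation with tie
    correction otherwise.  Returns ``(U, p)`` with U counted for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = float(ranks[:m].sum())
    U = r_x - m * (m + 1) / 2.0

    if m + n <= exact_max_total:
        idx = range(m + n)
        u_values = []
        base = m * (m + 1) / 2.0
        for combo in itertools.combinations(idx, m):
            u_values.append(ranks[list(combo)].sum() - base)
        u_values = np.asarray(u_values)
        total = u_values.size
        p_le = np.count_nonzero(u_values <= U + 1e-9) / total
        p_ge = np.count_nonzero(u_values >= U - 1e-9) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = m * n / 2.0
        N = m + n
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
        var = m * n / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            raise DegenerateDataError("all pooled values identical")
        z = (U - mean) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return float(U), float(min(p, 1.0))


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a t-distribution p (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in one of the samples")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def chisq_proportions(counts) -> tuple[float, float]:
    """Pearson χ² on a 2×k responded/not table across conditions (df = k−1)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("counts must be a 2 x k table with k >= 2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateDataError("zero marginal in contingency table")
    expected = sps.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise DegenerateDataError("expected cell count of zero")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
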