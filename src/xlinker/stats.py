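"""Shared statistical primitives for the X-linkage pipeline.

Every stage of the pipeline reduces to a handful of tests: Benjamini–Hochberg
multiple-testing control, two-sided Wilcoxon rank-sum contrasts of X versus
autosomal genes, Fisher's exact test on 2x2 enrichment tables, an exact
multi-set intersection test for ortholog overlap between species, and a
weighted median used to summarize per-scaffold statistics while down-weighting
short, repeat-rich scaffolds.

The multi-set intersection test is computed exactly by iterated hypergeometric
convolution in log space, so astronomically small tail probabilities (the kind
produced when five species share >90% of their X-linked orthologs) survive
without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MultiSetOverlap",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
    "multiset_intersection_test",
    "weighted_median",
]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Parameters
    ----------
    p : sequence of float
        Raw p-values, each in [0, 1].

    Returns
    -------
    numpy.ndarray
        Adjusted values in the original order, capped at 1 and monotone in
        rank order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses exact enumeration when the combined sample size is at most 20 and the
    data contain no ties; otherwise the normal approximation with tie and
    continuity correction. Returns ``(U, p)`` where U is the Mann–Whitney
    statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 contingency table.

    Two-sided p-value follows the classical convention: the sum of
    probabilities of all tables at least as extreme (probability no larger
    than the observed table's) under the hypergeometric null.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    odds, p = sps.fisher_exact(t.astype(int), alternative=alternative)
    return float(odds), float(p)


@dataclass(frozen=True)
class MultiSetOverlap:
    """Result of the exact m-way set-intersection test."""

    universe_size: int
    set_sizes: tuple[int, ...]
    observed: int
    expected: float
    p_value: float
    log10_p: float
    fold_enrichment: float | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _intersection_log_pmf(n: int, set_sizes: Sequence[int]) -> np.ndarray:
    """Exact log-pmf of the m-way intersection size of random subsets.

    Subsets of fixed sizes are drawn independently and uniformly from a
    universe of ``n`` elements. Conditional on the current intersection having
    x elements, the intersection after adding a set of size s is
    hypergeometric(n, x, s); the full distribution is the iterated
    convolution, computed in log space.
    """
    sizes = list(set_sizes)
    logp = np.full(sizes[0] + 1, -np.inf)
    logp[sizes[0]] = 0.0
    for s in sizes[1:]:
        cur_max = len(logp) - 1
        new_max = min(cur_max, s)
        x = np.arange(cur_max + 1)
        j = np.arange(new_max + 1)
        with np.errstate(divide="ignore"):
            lp = sps.hypergeom.logpmf(j[None, :], n, x[:, None], s)
        lp = np.where(np.isnan(lp), -np.inf, lp)
        logp = logsumexp(lp + logp[:, None], axis=0)
    return logp


def multiset_intersection_test(n: int, set_sizes: Sequence[int],
                               observed: int) -> MultiSetOverlap:
    """Exact test for an unexpectedly large m-way set intersection.

    ``p_value`` is P(I >= observed) where I is the intersection size of m
    independent uniform subsets of the given sizes; ``expected`` is
    ``n * prod(s_i / n)`` and ``fold_enrichment = observed / expected``
    (None when the expectation is zero).
    """
    sizes = tuple(int(s) for s in set_sizes)
    n = int(n)
    if n <= 0:
        raise ValueError("universe size must be positive")
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    if any(s < 0 or s > n for s in sizes):
        raise ValueError("every set size must satisfy 0 <= s <= n")
    if observed < 0 or observed > min(sizes):
        raise ValueError("observed intersection must satisfy 0 <= obs <= min(s_i)")

    expected = n * float(np.prod([s / n for s in sizes]))
    logp = _intersection_log_pmf(n, sizes)
    if observed == 0:
        log_tail = 0.0
    else:
        log_tail = float(logsumexp(logp[observed:]))
        log_tail = min(log_tail, 0.0)
    p = float(np.exp(log_tail))
    fold: float | None
    if expected > 0:
        fold = observed / expected
    else:
        fold = None
    return MultiSetOverlap(universe_size=n, set_sizes=sizes, observed=int(observed),
                           expected=expected, p_value=p,
                           log10_p=log_tail / np.log(10.0), fold_enrichment=fold)


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half.

    When the cumulative weight hits exactly half the total at some value, the
    midpoint between that value and the next is returned (the symmetric
    convention, so equal weights reproduce the ordinary median).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or v.size != w.size:
        raise ValueError("values and weights must be nonempty and equal length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    order = np.argsort(v, kind="stable")
    v = v[order]
    w = w[order]
    cw = np.cumsum(w)
    half = total / 2.0
    idx = int(np.searchsorted(cw, half, side="left"))
    # exact split: average the bracketing values
    if np.isclose(cw[idx], half, rtol=1e-12, atol=0.0) and idx + 1 < v.size:
        return float((v[idx] + v[idx + 1]) / 2.0)
    return float(v[idx])
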