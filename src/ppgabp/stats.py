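"""Nonparametric group-separability tests and frequency-resolved profiling.

Pairwise comparisons (NT vs PHT, NT vs HT, PHT vs HT) use the two-sided
Wilcoxon rank-sum test at alpha = 0.1; the three-group comparison uses
Kruskal-Wallis.  The frequency profiler applies the pairwise test at every
grid frequency in the 1-10 Hz band and merges contiguous significant
frequencies into intervals.  No multiplicity correction is applied across
measures or frequencies; results are explicitly labelled unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "FrequencyProfileResult",
    "wilcoxon_ranksum",
    "kruskal_wallis",
    "frequency_profile",
]


@dataclass(frozen=True)
class GroupComparison:
    """One test outcome: statistic, p-value and its context labels."""

    measure: str
    direction: str
    comparison: str
    statistic: float
    p_value: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _has_cross_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def wilcoxon_ranksum(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.1,
    measure: str = "",
    direction: str = "",
    comparison: str = "",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when both groups have at most 10 subjects and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = max(a.size, b.size) <= 10 and not _has_cross_ties(a, b)
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return GroupComparison(
        measure=measure,
        direction=direction,
        comparison=comparison,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alpha=alpha,
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    measure: str = "",
    direction: str = "",
    comparison: str = "3-group",
) -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected, chi-square p with k-1 df)."""
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis requires at least three groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 1 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*arrays)
    return GroupComparison(
        measure=measure,
        direction=direction,
        comparison=comparison,
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
    )


@dataclass
class FrequencyProfileResult:
    """Per-frequency p-values and merged significant intervals (unadjusted)."""

    freqs: np.ndarray
    p_values: np.ndarray
    intervals: list[tuple[float, float]]
    alpha: float
    adjusted: bool = False  # no multiplicity correction by design


def frequency_profile(
    values_a: np.ndarray,
    values_b: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = (1.0, 10.0),
    alpha: float = 0.1,
) -> FrequencyProfileResult:
    """Frequency-resolved two-group separability.

    ``values_a`` and ``values_b`` are (n_subjects, n_freqs) arrays of a
    measure's per-frequency values on a shared grid.  At every grid point
    inside ``band`` the rank-sum test is applied; contiguous runs with
    p < alpha merge into intervals.
    """
    values_a = np.atleast_2d(np.asarray(values_a, dtype=float))
    values_b = np.atleast_2d(np.asarray(values_b, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if values_a.shape[1] != freqs.size or values_b.shape[1] != freqs.size:
        raise ValueError("frequency grid mismatch between values and freqs")
    mask = (freqs >= band[0]) & (freqs <= band[1])
    sel = np.flatnonzero(mask)
    if sel.size == 0:
        raise ValueError("band outside the frequency grid")
    pvals = np.empty(sel.size)
    for out_i, fi in enumerate(sel):
        pvals[out_i] = wilcoxon_ranksum(
            values_a[:, fi], values_b[:, fi], alpha=alpha
        ).p_value
    sig = pvals < alpha
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j + 1 < sig.size and sig[j + 1]:
                j += 1
            intervals.append((float(freqs[sel[i]]), float(freqs[sel[j]])))
            i = j + 1
        else:
            i += 1
    return FrequencyProfileResult(
        freqs=freqs[sel], p_values=pvals, intervals=intervals, alpha=alpha
    )
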