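"""Two-sample Mann–Whitney U test and significance-star annotation.

Intended for single-time-point contrasts between two small groups
(genotype or diet, typically 3–12 animals per group), where the exact null
distribution is both feasible and strictly safer than the normal
approximation.  Method dispatch:

* untied data with C(n1+n2, n1) <= 200,000 — exact enumeration of the
  U null distribution;
* tied data — seeded permutation test (10,000 resamples);
* above the enumeration cap — normal approximation with tie correction.

Two-sided p-values are tail-doubled: p = min(1, 2·min(tail probabilities)).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

__all__ = ["RankTestResult", "mann_whitney", "significance_stars"]

ENUMERATION_CAP = 200_000
PERMUTATION_RESAMPLES = 10_000


@dataclass(frozen=True)
class RankTestResult:
    """Mann–Whitney U outcome: U is for the first sample (x over y)."""

    U: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # exact_enumeration | permutation | normal_approx

    def __post_init__(self) -> None:
        assert 0 <= self.U <= self.n1 * self.n2
        assert 0 < self.p_two_sided <= 1 or self.p_two_sided == 0


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    seed: int = 0,
) -> RankTestResult:
    """Mann–Whitney U test of two independent samples.

    U is computed from midrank sums; the p-value is exact (full
    enumeration of group assignments) on untied data below the enumeration
    cap, a seeded 10,000-resample permutation p on tied data, and the
    tie-corrected normal approximation above the cap.  Identical constant
    samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        u = n1 * n2 / 2.0
        return RankTestResult(u, n1, n2, 1.0, "degenerate_constant")

    tied = _has_ties(pooled)
    small = comb(n1 + n2, n1) <= ENUMERATION_CAP
    if small and not tied:
        method_name = "exact_enumeration"
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
    elif small and tied:
        method_name = "permutation"
        res = stats.mannwhitneyu(
            x,
            y,
            alternative=alternative,
            method=stats.PermutationMethod(
                n_resamples=PERMUTATION_RESAMPLES, rng=np.random.default_rng(seed)
            ),
        )
    else:
        method_name = "normal_approx"
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankTestResult(
        U=float(res.statistic),
        n1=n1,
        n2=n2,
        p_two_sided=float(min(1.0, res.pvalue)),
        method=method_name,
    )


def significance_stars(p: float, marker: str = "*") -> str:
    """Figure-legend annotation for a p-value.

    ``****`` p < 0.0001, ``***`` p < 0.001, ``**`` p < 0.01, ``*`` p <
    0.05 (all strict), else ``ns``.  ``marker`` switches the symbol, e.g.
    ``"$"`` for a versus-indicated-group contrast.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    for threshold, count in ((0.0001, 4), (0.001, 3), (0.01, 2), (0.05, 1)):
        if p < threshold:
            return marker * count
    return "ns"
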