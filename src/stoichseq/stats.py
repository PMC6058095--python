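"""Habitat contrasts of nitrogen content: effect sizes and rank tests.

The effect size is the relative difference in mean nitrogen content,
100 * (mean_open - mean_coastal) / mean_coastal — negative when the
open-ocean group is nitrogen-poorer.  Significance uses the unpaired
Wilcoxon-Mann-Whitney rank-sum test; "approximative" means the
Monte-Carlo permutation variant (group labels permuted, rank-sum
statistic, add-one p-value), with the exact enumeration and the
tie/continuity-corrected normal approximation as alternatives.  The
test unit is the per-sequence nitrogen content.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "Alternative",
    "Method",
    "TestResult",
    "GroupComparison",
    "relative_difference",
    "wilcoxon_rank_sum",
    "sem",
    "compare_groups",
]


class Alternative(str, enum.Enum):
    LESS = "less"
    GREATER = "greater"
    TWO_SIDED = "two_sided"


class Method(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"
    MONTE_CARLO = "monte_carlo"


def relative_difference(mean_open: float, mean_coastal: float) -> float:
    """Percent difference of the open-ocean mean relative to coastal."""
    if mean_coastal == 0:
        raise ZeroDivisionError("coastal mean is zero; relative difference undefined")
    return 100.0 * (mean_open - mean_coastal) / mean_coastal


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean (sample sd, n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM needs at least 2 values")
    return float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass(frozen=True)
class TestResult:
    statistic: float     # rank sum of the first sample
    p_value: float
    method: Method
    alternative: Alternative


def _exact_enumeration_p(
    x: np.ndarray, y: np.ndarray, alternative: Alternative
) -> float:
    """Exact null distribution by full enumeration of the C(n, nx) group
    assignments of the (mid)ranks; ties are handled exactly because
    midranks are enumerated as observed."""
    from itertools import combinations

    ranks = sps.rankdata(np.concatenate([x, y]))
    nx, n = len(x), len(ranks)
    observed = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0
    sums = np.array([sum(ranks[i] for i in comb) for comb in combinations(range(n), nx)])
    eps = 1e-9
    if alternative is Alternative.LESS:
        extreme = np.sum(sums <= observed + eps)
    elif alternative is Alternative.GREATER:
        extreme = np.sum(sums >= observed - eps)
    else:
        extreme = np.sum(np.abs(sums - mu) >= abs(observed - mu) - eps)
    return float(extreme / len(sums))


def _rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    return float(ranks[: len(x)].sum())


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative | str = Alternative.TWO_SIDED,
    method: Method | str = Method.MONTE_CARLO,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Unpaired Wilcoxon-Mann-Whitney rank-sum test.

    ``exact`` enumerates the rank-assignment null distribution
    (restricted to combined n <= 20); ``normal_approx`` uses the standard normal
    approximation with tie and continuity corrections;
    ``monte_carlo`` permutes group labels and reports the add-one
    estimate p = (1 + #as-or-more-extreme) / (1 + n_permutations).
    """
    alternative = Alternative(alternative)
    method = Method(method)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    scipy_alt = {"less": "less", "greater": "greater", "two_sided": "two-sided"}[
        alternative.value
    ]
    w = _rank_sum(x, y)

    if method is Method.EXACT:
        n = x.size + y.size
        if n > 20:
            raise ValueError("exact method restricted to combined n <= 20")
        p = _exact_enumeration_p(x, y, alternative)
        return TestResult(w, p, method, alternative)

    if method is Method.NORMAL_APPROX:
        res = sps.mannwhitneyu(
            x, y, alternative=scipy_alt, method="asymptotic", use_continuity=True
        )
        return TestResult(w, float(res.pvalue), method, alternative)

    rng = np.random.default_rng(seed)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    nx = x.size
    observed = float(ranks[:nx].sum())
    perm = np.empty(n_permutations)
    for b in range(n_permutations):
        perm[b] = rng.permutation(ranks)[:nx].sum()
    mu = nx * (ranks.sum() / combined.size)  # null mean of the rank sum
    if alternative is Alternative.LESS:
        extreme = int(np.sum(perm <= observed))
    elif alternative is Alternative.GREATER:
        extreme = int(np.sum(perm >= observed))
    else:
        extreme = int(np.sum(np.abs(perm - mu) >= np.abs(observed - mu)))
    p = (1 + extreme) / (1 + n_permutations)
    return TestResult(observed, p, method, alternative)


@dataclass(frozen=True)
class GroupComparison:
    """One open-ocean vs coastal contrast within a stratum."""

    stratum: str
    mean_open: float
    mean_coastal: float
    sem_open: float
    sem_coastal: float
    relative_difference_percent: float
    p_value: float
    method: Method
    alternative: Alternative
    n_open: int
    n_coastal: int
    n_sites: int | None = None

    def summary(self) -> str:
        alt = {"less": "one-sided (open < coastal)",
               "greater": "one-sided (open > coastal)",
               "two_sided": "two-sided"}[self.alternative.value]
        lines = [
            f"Nitrogen-content contrast: {self.stratum}",
            "-" * 48,
            f"open ocean : mean Nc {self.mean_open:.5f} "
            f"(SEM {self.sem_open:.2g}, N={self.n_open})",
            f"coastal    : mean Nc {self.mean_coastal:.5f} "
            f"(SEM {self.sem_coastal:.2g}, N={self.n_coastal})",
            f"relative difference: {self.relative_difference_percent:+.3f}%",
            f"p-value: {self.p_value:.4g} "
            f"[Wilcoxon rank-sum, {self.method.value}, {alt}]",
        ]
        if self.n_sites is not None:
            lines.append(f"sites in stratum: {self.n_sites}")
        return "\n".join(lines)


def compare_groups(
    open_values: Sequence[float],
    coastal_values: Sequence[float],
    stratum: str = "overall",
    alternative: Alternative | str = Alternative.LESS,
    method: Method | str = Method.MONTE_CARLO,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    n_sites: int | None = None,
) -> GroupComparison:
    """Contrast per-sequence nitrogen contents between habitats.

    The default alternative is one-sided "open ocean < coastal" (the
    thrifty-nitrogen hypothesis); pathway-scan style contrasts use the
    two-sided variant.
    """
    xo = np.asarray(open_values, dtype=float)
    xc = np.asarray(coastal_values, dtype=float)
    if xo.size < 2 or xc.size < 2:
        raise ValueError("each group needs at least 2 sequences")
    test = wilcoxon_rank_sum(
        xo, xc, alternative=alternative, method=method,
        n_permutations=n_permutations, seed=seed,
    )
    return GroupComparison(
        stratum=stratum,
        mean_open=float(xo.mean()),
        mean_coastal=float(xc.mean()),
        sem_open=sem(xo),
        sem_coastal=sem(xc),
        relative_difference_percent=relative_difference(xo.mean(), xc.mean()),
        p_value=test.p_value,
        method=test.method,
        alternative=test.alternative,
        n_open=int(xo.size),
        n_coastal=int(xc.size),
        n_sites=n_sites,
    )
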