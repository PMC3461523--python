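"""Exhaustive group-exchange permutation inference with bias correction.

The null hypothesis throughout is that it makes no difference which
speaker a listener attended to.  It is realized by exchanging listeners
between the two attention groups while keeping the group sizes constant;
with 6-of-12 exchanges this gives C(12, 6) = 924 equally likely
assignments, the observed one included.  The same enumerated distribution
serves three purposes:

* exact p-values  (fraction of assignments with a statistic at least as
  large as the observed one, ties counted conservatively);
* family-wise corrected p-values via the max-statistic over a family of
  tests (lags, frequency bins, channels, ROI pairs);
* bias correction  (observed statistic minus the permutation mean), which
  turns the positively biased sample R^2 into an increase relative to the
  null, the reported effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PermutationDistribution", "enumerate_group_exchanges",
    "sample_group_exchanges", "build_distribution", "permutation_pvalue",
    "maxstat_correct", "bias_correct",
]

Assignment = tuple[int, ...]


@dataclass
class PermutationDistribution:
    """A statistic evaluated under every enumerated group assignment.

    ``values`` has one row per assignment; rows may be scalars (shape
    ``(N,)``) or family vectors (shape ``(N, m)`` over lags / bins /
    channels).  The observed (identity) assignment is row
    ``observed_index`` (0 by convention).
    """

    values: np.ndarray
    assignments: list[Assignment] = field(default_factory=list)
    observed_index: int = 0
    family: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2) or len(self.values) == 0:
            raise ValueError("values must be a non-empty (N,) or (N, m) array")
        if self.assignments and len(self.assignments) != len(self.values):
            raise ValueError("one value row per assignment required")
        if not 0 <= self.observed_index < len(self.values):
            raise ValueError("observed_index out of range")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def observed(self) -> np.ndarray | float:
        obs = self.values[self.observed_index]
        return float(obs) if np.ndim(obs) == 0 else obs


def enumerate_group_exchanges(n: int, k: int,
                              observed: Sequence[int] | None = None
                              ) -> list[Assignment]:
    """All distinct ways to choose the first attention group.

    Returns every size-``k`` subset of ``range(n)`` (the listeners assigned
    to the first group), the observed assignment first, the rest in
    lexicographic order.  ``observed`` defaults to ``(0, ..., k-1)``.
    """
    if not 0 < k < n:
        raise ValueError("group size k must satisfy 0 < k < n")
    obs = tuple(sorted(observed)) if observed is not None else tuple(range(k))
    if len(obs) != k or any(not 0 <= i < n for i in obs):
        raise ValueError("observed assignment must be k distinct indices in range")
    all_assignments = [c for c in combinations(range(n), k)]
    all_assignments.remove(obs)
    return [obs] + all_assignments


def sample_group_exchanges(n: int, k: int, n_samples: int, seed: int,
                           observed: Sequence[int] | None = None
                           ) -> list[Assignment]:
    """Monte-Carlo fallback for designs where C(n, k) is too large.

    The observed assignment is always first; the remaining ``n_samples - 1``
    assignments are drawn uniformly (with replacement) from all subsets.
    """
    if not 0 < k < n:
        raise ValueError("group size k must satisfy 0 < k < n")
    if n_samples < 2:
        raise ValueError("need at least 2 assignments")
    obs = tuple(sorted(observed)) if observed is not None else tuple(range(k))
    rng = np.random.default_rng(seed)
    out = [obs]
    for _ in range(n_samples - 1):
        out.append(tuple(sorted(rng.choice(n, size=k, replace=False).tolist())))
    return out


def build_distribution(stat_fn: Callable[[Assignment], float | np.ndarray],
                       assignments: Sequence[Assignment],
                       family: str | None = None) -> PermutationDistribution:
    """Evaluate a statistic under every assignment (identity must be first)."""
    values = np.asarray([np.asarray(stat_fn(a), dtype=float)
                         for a in assignments])
    return PermutationDistribution(values=values, assignments=list(assignments),
                                   observed_index=0, family=family)


def exhaustive_or_sampled(n: int, k: int, cap: int = 100_000,
                          seed: int = 0,
                          observed: Sequence[int] | None = None
                          ) -> list[Assignment]:
    """Enumerate exhaustively, or sample ``cap`` assignments when C(n,k) > cap."""
    if comb(n, k) <= cap:
        return enumerate_group_exchanges(n, k, observed)
    return sample_group_exchanges(n, k, cap, seed, observed)


def permutation_pvalue(dist: PermutationDistribution) -> float:
    """Exact permutation p-value: #(statistic >= observed) / N, identity counted.

    Ties count as exceedances (conservative), so p lies in [1/N, 1].
    """
    values = dist.values
    if values.ndim != 1:
        raise ValueError("scalar statistic required; use maxstat_correct for families")
    return float(np.count_nonzero(values >= values[dist.observed_index])
                 / len(values))


def maxstat_correct(dist: PermutationDistribution
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Family-wise corrected p-values via the max-statistic.

    For every assignment the maximum over the family is taken; element
    ``e``'s corrected p is the fraction of assignments whose family-max
    meets or exceeds the observed value at ``e``.  Returns
    ``(p_uncorrected, p_corrected)``, both of family length; corrected
    p-values dominate uncorrected ones.
    """
    values = dist.values
    if values.ndim != 2:
        raise ValueError("family distribution must be 2-D (assignments x family)")
    observed = values[dist.observed_index]
    p_unc = (values >= observed[None, :]).mean(axis=0)
    family_max = values.max(axis=1)
    p_cor = (family_max[:, None] >= observed[None, :]).mean(axis=0)
    return p_unc, p_cor


def bias_correct(dist: PermutationDistribution,
                 include_identity: bool = True) -> float | np.ndarray:
    """Bias-corrected effect: observed minus the permutation-distribution mean.

    The mean includes the identity assignment by default, matching the
    p-value convention of counting the observed assignment.
    """
    values = dist.values
    if include_identity:
        mean = values.mean(axis=0)
    else:
        mask = np.ones(len(values), dtype=bool)
        mask[dist.observed_index] = False
        mean = values[mask].mean(axis=0)
    delta = values[dist.observed_index] - mean
    return float(delta) if np.ndim(delta) == 0 else delta
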