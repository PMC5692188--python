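"""Rank templates and the exact null distribution of the Kendall statistic.

The rhythmicity test matches a series against cosine-derived rank templates.
Columns whose template values coincide (including all replicates of one
timepoint, and symmetric points of the cosine) form tie groups; only pairs
drawn from *distinct* groups contribute to the statistic

    S = sum over cross-group pairs (i, j) of
        sign(y_j - y_i) * sign(rank_j - rank_i).

Under the null hypothesis that all orderings of distinct data values are
equally likely, S has an exact distribution that depends only on the
multiset of tie-group sizes.  The number of cross-group discordances of a
uniform random ordering is distributed as the coefficient sequence of a
Gaussian (q-)multinomial, which factors into independent Mann-Whitney
blocks: merging a group of size m into the s columns already placed adds a
U(m, s)-distributed discordance count.  The full null therefore falls out
of a convolution of exact Mann-Whitney block distributions — no sampling,
no normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import CapacityError, ValidationError
from .grid import TimeGrid

#: columns beyond which the exact null is refused
MAX_COLUMNS = 256

_ROUND_DECIMALS = 9


@dataclass(frozen=True)
class ReferenceTemplate:
    """A cosine rank template on a fixed set of column times."""

    period_h: float
    phase_h: float
    template_values: np.ndarray
    group_ranks: np.ndarray  # per-column tie-group rank, ascending template value
    tie_signature: tuple[int, ...]  # sorted group sizes

    @property
    def n_columns(self) -> int:
        return self.template_values.size

    @property
    def tie_groups(self) -> list[np.ndarray]:
        """Column indices per tie group, in ascending template-value order."""
        return [
            np.flatnonzero(self.group_ranks == r)
            for r in range(self.group_ranks.max() + 1)
        ]


def reference_template(
    grid: TimeGrid | np.ndarray, period_h: float, phase_h: float
) -> ReferenceTemplate:
    """Template values and tie structure of ``cos(2*pi*(t - phase)/period)``.

    Accepts a :class:`TimeGrid` or a raw vector of per-column times.
    Replicate columns automatically share a tie group because they share a
    time; cosine symmetry may merge further columns.
    """
    if period_h <= 0:
        raise ValidationError(f"period_h={period_h} must be positive")
    if isinstance(grid, TimeGrid):
        col_times = grid.column_times_h
    else:
        col_times = np.asarray(grid, dtype=float)
    tv = np.cos(2.0 * np.pi * (col_times - phase_h) / period_h)
    keys = np.round(tv, _ROUND_DECIMALS) + 0.0  # normalize -0.0
    uniq, ranks = np.unique(keys, return_inverse=True)
    sizes = np.bincount(ranks)
    return ReferenceTemplate(
        period_h=float(period_h),
        phase_h=float(phase_h),
        template_values=tv,
        group_ranks=ranks.astype(np.int64),
        tie_signature=tuple(sorted(int(s) for s in sizes)),
    )


def pair_sign_matrix(template: ReferenceTemplate) -> np.ndarray:
    """Antisymmetric matrix W with W[i, j] = sign(rank_j - rank_i).

    Entries within a tie group are zero.  ``S = 0.5 * sum_ij D[i, j] W[i, j]``
    for the data-sign matrix D.
    """
    r = template.group_ranks
    return np.sign(r[None, :] - r[:, None]).astype(np.int64)


def kendall_s(values: np.ndarray, template: ReferenceTemplate) -> int:
    """Kendall-style concordance score of one series against a template.

    Pairs tied in the template are skipped; pairs tied in the data
    contribute zero.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size != template.n_columns:
        raise ValidationError(
            f"series has {v.size} values but template expects "
            f"{template.n_columns}"
        )
    d = np.sign(v[None, :] - v[:, None])
    w = pair_sign_matrix(template)
    return int(round((d * w).sum() / 2.0))


def kendall_s_matrix(values: np.ndarray, template: ReferenceTemplate) -> np.ndarray:
    """Vectorized :func:`kendall_s` over the rows of a matrix."""
    v = np.asarray(values, dtype=float)
    d = np.sign(v[:, None, :] - v[:, :, None]).astype(np.int8)
    w = pair_sign_matrix(template)
    s = np.tensordot(d, w, axes=([1, 2], [0, 1])) / 2
    return np.rint(s).astype(np.int64)


@lru_cache(maxsize=4096)
def _mwu_block_pmf(m: int, s: int) -> np.ndarray:
    """Exact PMF of the Mann-Whitney discordance count U(m, s).

    Classic two-sample recursion on the overall maximum:
    ``p(m, s, u) = m/(m+s) * p(m-1, s, u-s) + s/(m+s) * p(m, s-1, u)``,
    all terms non-negative so the convolution chain stays stable.
    """
    if m == 0 or s == 0:
        return np.ones(1)
    prev = [np.ones(1)] * (s + 1)  # j = 0 row: U identically 0
    for j in range(1, m + 1):
        cur: list[np.ndarray] = [np.ones(1)]
        for t in range(1, s + 1):
            arr = np.zeros(j * t + 1)
            a = prev[t]  # p_{j-1, t}
            b = cur[t - 1]  # p_{j, t-1}
            arr[t : t + a.size] += (j / (j + t)) * a
            arr[: b.size] += (t / (j + t)) * b
            cur.append(arr)
        prev = cur
    return prev[s]


@dataclass(frozen=True)
class NullDistribution:
    """Exact null distribution of S for one tie signature.

    ``support`` is ascending and symmetric about zero; ``probabilities``
    sum to one.
    """

    support: np.ndarray
    probabilities: np.ndarray
    tie_signature: tuple[int, ...]

    @property
    def max_s(self) -> int:
        return int(self.support[-1])

    def sf_abs(self, s_obs) -> np.ndarray | float:
        """Two-sided exact tail probability P(|S_null| >= |s_obs|)."""
        s = np.abs(np.asarray(s_obs))
        # upper-tail P(S >= x) from the right; symmetric support
        rev_cum = np.cumsum(self.probabilities[::-1])[::-1]
        idx = np.searchsorted(self.support, s, side="left")
        upper = np.where(idx < self.support.size, rev_cum[np.minimum(idx, self.support.size - 1)], 0.0)
        p = np.where(s > 0, np.minimum(2.0 * upper, 1.0), 1.0)
        if np.isscalar(s_obs):
            return float(p)
        return p


@lru_cache(maxsize=512)
def _exact_null_cached(signature: tuple[int, ...]) -> NullDistribution:
    n = sum(signature)
    inv_pmf = np.ones(1)
    placed = 0
    for m in signature:
        inv_pmf = np.convolve(inv_pmf, _mwu_block_pmf(m, placed))
        placed += m
    max_pairs = (n * n - sum(m * m for m in signature)) // 2
    assert inv_pmf.size == max_pairs + 1
    support = max_pairs - 2 * np.arange(max_pairs + 1)  # descending in inversions
    order = np.argsort(support)
    probs = inv_pmf[order]
    probs /= probs.sum()
    return NullDistribution(
        support=support[order], probabilities=probs, tie_signature=signature
    )


def exact_null(tie_group_sizes) -> NullDistribution:
    """Exact null of S for the given tie-group sizes (order-insensitive)."""
    sizes = tuple(sorted(int(m) for m in tie_group_sizes))
    if not sizes or any(m < 1 for m in sizes):
        raise ValidationError(f"tie-group sizes must be positive, got {sizes}")
    n = sum(sizes)
    if n > MAX_COLUMNS:
        raise CapacityError(
            f"exact null requested for {n} columns; the exact computation is "
            f"capped at {MAX_COLUMNS}"
        )
    return _exact_null_cached(sizes)
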