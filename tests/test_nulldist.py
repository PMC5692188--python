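"""Exact-null machinery checked against an independent permutation oracle."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circabench import (
    CapacityError,
    ValidationError,
    build_time_grid,
    exact_null,
    kendall_s,
    reference_template,
)


def oracle_null(sizes):
    """Brute-force null of S: enumerate every ordering of distinct values."""
    n = sum(sizes)
    ranks = np.repeat(np.arange(len(sizes)), sizes)
    pmf = Counter()
    for perm in itertools.permutations(range(n)):
        s = 0
        for i in range(n):
            for j in range(i + 1, n):
                if ranks[i] != ranks[j]:
                    s += np.sign(perm[j] - perm[i]) * np.sign(ranks[j] - ranks[i])
        pmf[int(s)] += 1
    total = sum(pmf.values())
    return {s: c / total for s, c in pmf.items()}


def all_signatures(n):
    """Integer partitions of n (tie-group size multisets)."""
    if n == 0:
        yield ()
        return
    for first in range(n, 0, -1):
        for rest in all_signatures(n - first):
            if not rest or rest[0] <= first:
                yield (first, *rest)


@pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
def test_exact_null_matches_permutation_oracle_for_all_signatures(n):
    for sig in all_signatures(n):
        if len(sig) < 2:
            continue  # single tie group: statistic degenerate at 0
        nd = exact_null(sig)
        expected = oracle_null(sig)
        computed = dict(zip(nd.support.tolist(), nd.probabilities.tolist()))
        assert set(expected) <= set(computed), sig
        for s, p in computed.items():
            assert abs(p - expected.get(s, 0.0)) < 1e-12, (sig, s)


def test_two_group_null_is_plus_minus_one():
    nd = exact_null((1, 1))
    assert nd.support.tolist() == [-1, 1]
    np.testing.assert_allclose(nd.probabilities, [0.5, 0.5])


@given(
    st.lists(st.integers(min_value=1, max_value=5), min_size=2, max_size=8)
)
def test_null_is_normalized_and_symmetric(sizes):
    nd = exact_null(sizes)
    assert abs(nd.probabilities.sum() - 1.0) < 1e-12
    np.testing.assert_allclose(nd.probabilities, nd.probabilities[::-1], atol=1e-12)
    assert np.array_equal(nd.support, -nd.support[::-1])


def test_tail_probability_is_valid_and_monotone():
    nd = exact_null((2, 4, 4, 2))
    s = np.arange(0, nd.max_s + 2)
    p = nd.sf_abs(s)
    assert p[0] == 1.0
    assert np.all(np.diff(p) <= 1e-15)
    assert p[-1] == 0.0  # beyond the attainable maximum


def test_capacity_cap_raises_explicit_error():
    with pytest.raises(CapacityError, match="capped"):
        exact_null([1] * 300)
    with pytest.raises(ValidationError):
        exact_null([0, 3])


class TestReferenceTemplate:
    def test_phase_zero_peak_alone_at_top_of_24h_cycle(self):
        grid = build_time_grid(24, 2, 1)
        t = reference_template(grid, 24.0, 0.0)
        top_group = t.tie_groups[-1]
        assert top_group.tolist() == [0]  # cosine maximum at t = 0

    def test_full_period_phase_shift_gives_identical_template(self):
        grid = build_time_grid(24, 2, 1)
        a = reference_template(grid, 24.0, 0.0)
        b = reference_template(grid, 24.0, 24.0)
        np.testing.assert_allclose(a.template_values, b.template_values, atol=1e-12)
        assert np.array_equal(a.group_ranks, b.group_ranks)

    def test_two_cycles_tie_every_template_value(self):
        grid = build_time_grid(48, 2, 1)
        t = reference_template(grid, 24.0, 0.0)
        assert all(len(g) >= 2 for g in t.tie_groups)
        assert sum(len(g) for g in t.tie_groups) == grid.n_columns

    def test_replicate_columns_share_a_tie_group(self):
        grid = build_time_grid(24, 4, 3)
        t = reference_template(grid, 24.0, 1.0)
        ranks = t.group_ranks.reshape(grid.n_timepoints, 3)
        assert np.all(ranks == ranks[:, :1])


class TestKendallS:
    def test_concordant_series_reaches_pair_count(self):
        t = reference_template(np.array([0.0, 1, 2, 3, 4]), 1000.0, 500.0)
        assert t.tie_signature == (1, 1, 1, 1, 1)
        values = t.template_values + 0.0
        assert kendall_s(values, t) == 10  # n(n-1)/2 concordant pairs
        assert kendall_s(-values, t) == -10

    def test_template_tied_pair_is_skipped(self):
        # template groups ({0,1}, {2}); data (1, 3, 2):
        # (0,2) concordant, (1,2) discordant, (0,1) skipped -> S = 0
        t = reference_template(np.array([0.0, 0.0, 6.0]), 24.0, 0.0)
        assert t.tie_signature == (1, 2)
        assert kendall_s(np.array([1.0, 3.0, 2.0]), t) == 0

    def test_length_mismatch_rejected(self):
        t = reference_template(np.array([0.0, 1, 2]), 24.0, 0.0)
        with pytest.raises(ValidationError):
            kendall_s(np.array([1.0, 2.0]), t)

    @given(
        st.lists(
            # measurement-like resolution so differences survive the
            # affine map instead of underflowing into spurious ties
            st.floats(min_value=-50, max_value=50, allow_nan=False).map(
                lambda x: round(x, 3)
            ),
            min_size=6, max_size=6,
        ),
        st.floats(min_value=0.05, max_value=20),
        st.floats(min_value=-30, max_value=30),
    )
    def test_rank_statistic_invariant_under_positive_affine_maps(self, vals, scale, shift):
        t = reference_template(np.arange(0.0, 24.0, 4.0), 24.0, 0.0)
        v = np.asarray(vals)
        assert kendall_s(v, t) == kendall_s(scale * v + shift, t)
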