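import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circabench import (
    JTKDetector,
    ValidationError,
    bh_adjust,
    build_time_grid,
    jtk_test,
)


@pytest.fixture(scope="module")
def grid_48_2():
    return build_time_grid(48, 2, 1)


class TestJTK:
    def test_noiseless_cosine_recovered_with_tiny_p(self, grid_48_2):
        t = grid_48_2.column_times_h
        phase_true = 6.0
        series = 10 + 3 * np.cos(2 * np.pi * (t - phase_true) / 24.0)
        res = jtk_test(series, grid_48_2, period_set=(24.0,))
        row = res.iloc[0]
        assert row.p_adj < 0.05
        assert row.best_period_h == 24.0
        assert abs(row.best_phase_h - phase_true) <= 2.0  # within one phase step
        # maximal S attains the smallest exact p of the searched family
        det = JTKDetector(period_set=(24.0,)).fit(series[None, :], grid_48_2)
        assert det.S_.max() == det.S_[0, det.S_.argmax()]

    def test_phase_reversal_reports_half_period_shift(self, grid_48_2):
        t = grid_48_2.column_times_h
        series = 10 - 3 * np.cos(2 * np.pi * t / 24.0)  # trough at t=0
        row = jtk_test(series, grid_48_2).iloc[0]
        assert abs(row.best_phase_h - 12.0) <= 2.0

    def test_constant_series_has_p_one_and_no_phase(self, grid_48_2):
        res = jtk_test(np.full(grid_48_2.n_columns, 5.0), grid_48_2)
        assert res.iloc[0].p_adj == 1.0
        assert np.isnan(res.iloc[0].best_phase_h)

    def test_p_raw_le_p_adj_and_bonferroni_factor(self, noise_dataset):
        det = JTKDetector().fit_dataset(noise_dataset)
        assert det.n_alternatives_ == 12  # full 24 h cycle at 2 h steps
        assert np.all(det.p_raw_ > 0)
        assert np.all(det.p_raw_ <= det.p_adj_)
        assert np.all(det.p_adj_ <= 1.0)
        expected = np.minimum(1.0, det.p_raw_ * 12)
        np.testing.assert_allclose(det.p_adj_, expected)

    def test_best_period_member_of_searched_set(self, rhythmic_dataset):
        det = JTKDetector(period_set=(20.0, 24.0)).fit_dataset(rhythmic_dataset)
        assert set(np.unique(det.best_period_h_)) <= {20.0, 24.0}

    def test_pure_noise_hit_rate_consistent_with_two_percent_bound(self, noise_dataset):
        # single-run check within binomial error; the strict bound is
        # asserted on pooled replicates in the acceptance suite
        det = JTKDetector().fit_dataset(noise_dataset)
        rate = (det.results_["p_adj"] < 0.05).mean()
        assert rate < 0.02 + 3 * np.sqrt(0.02 * 0.98 / 1000), rate

    @given(
        st.floats(min_value=0.1, max_value=9.0),
        st.floats(min_value=-20.0, max_value=20.0),
    )
    def test_p_values_invariant_under_positive_affine_transform(self, scale, shift):
        grid = build_time_grid(24, 4, 1)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, grid.n_columns))
        a = JTKDetector().fit(x, grid)
        b = JTKDetector().fit(scale * x + shift, grid)
        assert np.array_equal(a.S_, b.S_)
        np.testing.assert_allclose(a.p_raw_, b.p_raw_)
        np.testing.assert_allclose(a.p_adj_, b.p_adj_)

    def test_power_monotone_in_amplitude_to_noise_ratio(self):
        from circabench import SimulationConfig, synthesize_dataset

        rates = []
        for snr in (0.5, 1.0, 2.0, 4.0):
            cfg = SimulationConfig(
                duration_h=48, interval_h=2, n_series=1000, frac_rhythmic=1.0,
                amp_min=snr, amp_max=snr, noise_sd=1.0, seed=101,
            )
            ds = synthesize_dataset(cfg)
            det = JTKDetector().fit_dataset(ds)
            rates.append((det.results_["p_adj"] < 0.05).mean())
        slack = 3 * np.sqrt(0.25 / 1000)  # binomial error allowance
        assert all(b >= a - slack for a, b in zip(rates, rates[1:])), rates

    def test_phase_step_must_divide_period(self, grid_48_2):
        with pytest.raises(ValidationError, match="divide"):
            JTKDetector(period_set=(24.0,), phase_step_h=5.0).fit(
                np.zeros((1, grid_48_2.n_columns)), grid_48_2
            )

    def test_empty_period_set_rejected(self, grid_48_2):
        with pytest.raises(ValidationError):
            JTKDetector(period_set=()).fit(
                np.zeros((1, grid_48_2.n_columns)), grid_48_2
            )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1, max_size=30,
        )
    )
    def test_matches_direct_step_up_formula_and_dominates_input(self, p_list):
        p = np.asarray(p_list)
        q = bh_adjust(p)
        # independent oracle: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1
        m = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        expected_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
        expected = np.empty_like(p)
        expected[order] = expected_sorted
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1], [np.nan]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_adjust(bad)
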