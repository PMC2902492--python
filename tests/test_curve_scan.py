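import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orcurve import (AnalyticSample, CutoffRule, build_table, explicit_grid,
                     make_full_grid, make_window_grid, odds_ratio, scan,
                     stability_profile)
from orcurve.simulate import NullOutcome, LognormalExposure, SimulationConfig, \
    simulate_sample

from ._oracles import loop_count_table


def _sample(lo, hi, n=6):
    x = np.linspace(lo, hi, n)
    return AnalyticSample(x, np.arange(n) % 2)


class TestGrids:
    def test_full_grid_four_point_construction(self):
        s = AnalyticSample(np.array([10.00, 10.02, 10.05]), np.array([0, 1, 1]))
        grid = make_full_grid(s, 0.01)
        assert np.allclose(grid.cutoffs, [10.01, 10.02, 10.03, 10.04])

    def test_full_grid_endpoints_one_increment_inside_range(self):
        s = _sample(13.36, 130.21)
        grid = make_full_grid(s, 0.01)
        assert grid.cutoffs[0] == pytest.approx(13.37)
        assert grid.cutoffs[-1] == pytest.approx(130.20)
        assert len(grid) == 11684  # (13021 - 1336 - 1) integer steps

    @given(
        lo=st.floats(5, 50),
        span=st.floats(1, 80),
        inc=st.sampled_from([0.01, 0.02, 0.05, 0.1, 0.25]),
    )
    def test_full_grid_strictly_increasing_constant_step(self, lo, span, inc):
        s = _sample(lo, lo + span)
        grid = make_full_grid(s, inc)
        diffs = np.diff(grid.cutoffs)
        assert np.all(diffs > 0)
        assert np.allclose(diffs, inc, rtol=0, atol=1e-9)

    def test_degenerate_sample_rejected(self):
        s = AnalyticSample(np.array([25.0, 25.0]), np.array([0, 1]))
        with pytest.raises(ValueError):
            make_full_grid(s)

    def test_window_bounds_match_percentile_conventions(self):
        # 100 distinct exposures 1..100: bounds computed by the stated
        # convention, brute-checked: type-7 interpolation gives
        # P25 = 25.75, P75 = 75.25; the (n+1)q convention gives 25.25, 75.75
        s = AnalyticSample(np.arange(1.0, 101.0), np.arange(100) % 2)
        linear = make_window_grid(s, 25, 75, 0.01)
        assert linear.cutoffs[0] == pytest.approx(25.75)
        assert linear.cutoffs[-1] == pytest.approx(75.25)
        weibull = make_window_grid(s, 25, 75, 0.01, percentile_method="weibull")
        assert weibull.cutoffs[0] == pytest.approx(25.25)
        assert weibull.cutoffs[-1] == pytest.approx(75.75)

    def test_full_percentile_window_equals_full_range_span(self):
        s = _sample(20.0, 40.0, n=11)
        full = make_full_grid(s, 0.01)
        window = make_window_grid(s, 0, 100, 0.01)
        # same span up to the endpoint convention (window includes the
        # extremes; the full grid stops one increment inside)
        assert window.cutoffs[0] == pytest.approx(full.cutoffs[0] - 0.01)
        assert window.cutoffs[-1] == pytest.approx(full.cutoffs[-1] + 0.01)

    def test_window_grid_inside_observed_range(self, fixture_sample):
        grid = make_window_grid(fixture_sample, 25, 75)
        assert grid.cutoffs[0] >= fixture_sample.exposure.min()
        assert grid.cutoffs[-1] <= fixture_sample.exposure.max()

    def test_collapsed_window_rejected(self):
        s = AnalyticSample(np.full(50, 25.0), np.arange(50) % 2)
        with pytest.raises(ValueError):
            make_window_grid(s, 40, 60, 0.01)


class TestScan:
    def test_matches_per_cutoff_oracle_on_toy(self, toy_sample):
        grid = explicit_grid([21.0, 24.0, 25.5, 27.0, 31.0])
        curve = scan(toy_sample, grid)
        for i, cutoff in enumerate(grid.cutoffs):
            cells = loop_count_table(
                toy_sample.exposure, toy_sample.case, cutoff)
            assert curve.table_at(i).cells() == cells
            est = odds_ratio(build_table(
                toy_sample, CutoffRule.scalar(cutoff)))
            got = curve.estimate_at(i)
            if est.estimable:
                assert got.or_value == est.or_value  # identical fp formula
                assert got.se_log_or == est.se_log_or
            else:
                assert not got.estimable

    def test_singleton_grid_equals_single_odds_ratio(self, toy_sample):
        med = float(np.median(toy_sample.exposure))
        curve = scan(toy_sample, explicit_grid([med]))
        direct = odds_ratio(build_table(toy_sample, CutoffRule.scalar(med)))
        assert curve.estimate_at(0).or_value == direct.or_value

    def test_conservation_and_constant_margins(self, small_fixture_sample):
        s = small_fixture_sample
        curve = scan(s, make_full_grid(s, 0.05))
        assert np.all(curve.a + curve.b + curve.c + curve.d == s.n)
        assert np.all(curve.a + curve.c == s.n_cases)
        assert np.all(curve.b + curve.d == s.n - s.n_cases)

    def test_exposed_count_non_increasing(self, small_fixture_sample):
        curve = scan(small_fixture_sample,
                     make_full_grid(small_fixture_sample, 0.05))
        assert np.all(np.diff(curve.a + curve.b) <= 0)

    def test_equal_tables_iff_no_observation_between_cutoffs(self):
        s = AnalyticSample(np.array([1.0, 2.0, 2.0, 5.0]),
                           np.array([0, 1, 0, 1]))
        curve = scan(s, explicit_grid([1.5, 3.0, 3.5, 4.0]))
        # no exposure in (3.0, 3.5] or (3.5, 4.0] -> identical tables
        assert curve.table_at(1) == curve.table_at(2) == curve.table_at(3)
        assert curve.table_at(0) != curve.table_at(1)

    def test_haldane_policy_marks_corrected_points(self, toy_sample):
        lo = toy_sample.exposure.min()
        grid = explicit_grid([lo - 0.5, 25.5])  # first cutoff exposes all
        flagged = scan(toy_sample, grid, correction="flag")
        assert not flagged.estimable[0] and flagged.estimable[1]
        corrected = scan(toy_sample, grid, correction="haldane")
        assert corrected.estimable.all()
        assert corrected.correction_applied.tolist() == [True, False]

    def test_null_sample_ci_rarely_excludes_one(self):
        cfg = SimulationConfig(
            n=5000,
            exposure=LognormalExposure(np.log(14.0), 0.37, shift=13.0),
            outcome=NullOutcome(0.5),
            seed=2024,
        )
        s = simulate_sample(cfg)
        curve = scan(s, make_window_grid(s, 25, 75, 0.05))
        est = curve.estimable
        excludes = (curve.ci_low[est] > 1.0) | (curve.ci_high[est] < 1.0)
        # pointwise 5% level; curve points are highly correlated, so the
        # fraction fluctuates more than an independent binomial would
        assert excludes.mean() < 0.25


class TestStability:
    def test_constant_or_has_zero_jumps(self):
        s = AnalyticSample(np.array([1.0, 1.0, 2.0, 2.0, 5.0, 5.0]),
                           np.array([0, 1, 0, 1, 0, 1]))
        curve = scan(s, explicit_grid([3.0, 3.5, 4.0]))
        frame, summary = stability_profile(curve)
        assert np.allclose(frame["delta_log_or"].iloc[1:], 0.0)
        assert summary.max_jump == 0.0

    def test_tail_se_exceeds_central_se(self, fixture_sample):
        curve = scan(fixture_sample, make_full_grid(fixture_sample, 0.01))
        frame, summary = stability_profile(curve)
        cuts = frame["cutoff"].to_numpy()
        p1, p50 = np.percentile(fixture_sample.exposure, [1, 50])
        se_tail = frame["se_log_or"][np.argmin(np.abs(cuts - p1))]
        se_mid = frame["se_log_or"][np.argmin(np.abs(cuts - p50))]
        assert se_tail > se_mid
        # and the minimum-SE cutoff sits in the middle of the distribution
        p10, p90 = np.percentile(fixture_sample.exposure, [10, 90])
        assert p10 < summary.min_se_cutoff < p90

    def test_non_estimable_run_reported_with_interval(self, toy_sample):
        lo = toy_sample.exposure.min()
        curve = scan(toy_sample, explicit_grid([lo - 1.0, lo - 0.5, 25.5, 27.0]))
        _, summary = stability_profile(curve)
        assert summary.non_estimable_runs == ((lo - 1.0, lo - 0.5),)

    def test_all_flagged_curve_rejected(self, toy_sample):
        lo = toy_sample.exposure.min()
        curve = scan(toy_sample, explicit_grid([lo - 1.0, lo - 0.5]))
        with pytest.raises(ValueError):
            stability_profile(curve)
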