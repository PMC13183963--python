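"""Closed-form analytics: error metrics, regression, doubling time, 4PL
dose-response, sampling plans, normalisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microcyte as mc


class TestErrorMetrics:
    def test_zero_error(self):
        e = mc.error_metrics([1.0, 2.0], [1.0, 2.0])
        assert (e.mae, e.mse, e.rmse) == (0, 0, 0)

    def test_hand_computed_values(self):
        e = mc.error_metrics([0.0, 4.0], [0.0, 0.0])
        assert e.mae == pytest.approx(2.0)
        assert e.mse == pytest.approx(8.0)
        assert e.rmse == pytest.approx(math.sqrt(8.0))

    def test_single_pair(self):
        e = mc.error_metrics([3.0], [1.0])
        assert e.mae == e.rmse == pytest.approx(2.0)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.normal(size=10)
            t = rng.normal(size=10)
            e = mc.error_metrics(p, t)
            assert e.rmse >= e.mae - 1e-12
            assert e.rmse == pytest.approx(math.sqrt(e.mse), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mc.error_metrics([1.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
           st.data())
    def test_rmse_mae_ordering_property(self, pred, data):
        truth = data.draw(st.lists(st.floats(-1e6, 1e6),
                                   min_size=len(pred), max_size=len(pred)))
        e = mc.error_metrics(pred, truth)
        assert e.rmse >= e.mae - 1e-9 * max(1.0, e.rmse)
        errs = np.abs(np.subtract(pred, truth))
        if np.all(errs == errs[0]):  # equality iff all |errors| identical
            assert e.rmse == pytest.approx(e.mae, rel=1e-9, abs=1e-12)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3, 4])
        fit = mc.linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_y(self):
        fit = mc.linear_fit([0.0, 1, 2, 3], [5.0, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5)
        y = 1.7 * x - 0.4 + rng.normal(0, 0.3, 5)
        fit = mc.linear_fit(x, y)
        A = np.vstack([x, np.ones(5)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            mc.linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDoublingTime:
    def test_doubling_in_unit_time(self):
        s = mc.GrowthSeries(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        r = mc.doubling_time(s)
        assert r.gr == pytest.approx(math.log(2), abs=1e-12)
        assert r.td == pytest.approx(1.0, abs=1e-12)

    def test_eightfold_in_three_units(self):
        s = mc.GrowthSeries(np.array([0.0, 3.0]), np.array([1.0, 8.0]))
        assert mc.doubling_time(s).td == pytest.approx(1.0, abs=1e-12)

    def test_two_point_equals_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n0, nt = rng.uniform(10, 100), rng.uniform(10, 1000)
            t = rng.uniform(0.5, 5)
            s = mc.GrowthSeries(np.array([0.0, t]), np.array([n0, nt]))
            assert mc.doubling_time(s).gr == pytest.approx(
                math.log(nt / n0) / t, rel=1e-10)

    def test_flat_series_flagged_infinite(self):
        s = mc.GrowthSeries(np.array([0.0, 1.0, 2.0]), np.array([5.0, 5.0, 5.0]))
        r = mc.doubling_time(s)
        assert math.isinf(r.td)
        assert r.nonpositive_growth


FIG_DOSES = np.array([0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 20.0])  # nM


class TestFit4PL:
    def test_noise_free_round_trip(self):
        tab = mc.simulate_dose_response(100, 0, 1.0, 1.0, FIG_DOSES, sd=0)
        fit = mc.fit_4pl(tab)
        assert fit.ic50 == pytest.approx(1.0, rel=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-4)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-4)

    def test_midpoint_identity(self):
        tab = mc.simulate_dose_response(80, 20, 2.0, 1.5, FIG_DOSES, sd=0)
        fit = mc.fit_4pl(tab)
        from microcyte.imagesim import logistic4
        mid = logistic4(fit.ic50, fit.top, fit.bottom, fit.log_ic50,
                        fit.hill_slope)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2, rel=1e-6)

    def test_dose_unit_invariance(self):
        tab = mc.simulate_dose_response(100, 0, 1.0, 1.2, FIG_DOSES, sd=2.0,
                                        replicates=3, seed=4)
        fit_nm = mc.fit_4pl(tab)
        tab_m = mc.DoseResponseTable(tab.doses * 1e-9, tab.responses,
                                     tab.replicate)
        fit_m = mc.fit_4pl(tab_m)
        assert fit_m.ic50 == pytest.approx(fit_nm.ic50 * 1e-9, rel=1e-4)
        assert fit_m.hill_slope == pytest.approx(fit_nm.hill_slope, rel=1e-4)
        assert fit_m.top == pytest.approx(fit_nm.top, rel=1e-4)

    def test_zero_dose_handled_on_log_axis(self):
        doses = np.array([0.0, 0.1, 0.5, 1.0, 5.0, 20.0])
        tab = mc.simulate_dose_response(100, 0, 1.0, 1.0, doses, sd=0)
        # the log-offset placement of d=0 shifts the fit slightly
        fit = mc.fit_4pl(tab)
        assert fit.ic50 == pytest.approx(1.0, rel=0.05)


class TestSamplePlan:
    def test_identical_fields_need_one(self):
        p = mc.sample_plan([40.0] * 12, vessel_area=100.0, field_area=1.0)
        assert p.n_fields == 1
        assert p.achieved_sd == 0.0

    def test_agrees_with_sd_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(40.0, 7.0, size=200)
        p = mc.sample_plan(vals, vessel_area=100.0, field_area=1.0,
                           target_sd=5.0, seed=1)
        sd = vals.std(ddof=0)
        closed_form = math.ceil((sd / 5.0) ** 2)
        assert abs(p.n_fields - closed_form) <= 1
        assert p.fraction_of_area == pytest.approx(p.n_fields / 100.0)

    def test_unattainable_target_flagged(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(40.0, 7.0, size=20)
        p = mc.sample_plan(vals, vessel_area=100.0, field_area=1.0,
                           target_sd=1e-4, seed=0)
        assert not p.attainable

    def test_too_few_fields_rejected(self):
        with pytest.raises(ValueError):
            mc.sample_plan([1.0] * 5, 10.0, 1.0)


class TestNormalizeToMax:
    def test_basic(self):
        out = mc.normalize_to_max([1.0, 2.0, 4.0])
        assert list(out) == [25.0, 50.0, 100.0]

    def test_single_value(self):
        assert list(mc.normalize_to_max([7.0])) == [100.0]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mc.normalize_to_max([1.0, -0.5])
        with pytest.raises(ValueError):
            mc.normalize_to_max([0.0, 0.0])
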