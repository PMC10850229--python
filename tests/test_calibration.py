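import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from qnta import fit_calibration, loo_cv, qc_summary, run_calibration_approach
from qnta.calibration import (
    CalibrationModel,
    DegenerateDesignError,
    UnboundedIntervalError,
)
from qnta.data import InsufficientDataError


def _fit_from_log2(x, y, **kw):
    return fit_calibration(2.0 ** np.asarray(x), 2.0 ** np.asarray(y), **kw)


class TestFit:
    def test_exact_line_recovered(self):
        x = np.arange(9, dtype=float)
        fit = _fit_from_log2(x, x + 3.0)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(3.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_three_point_normal_equations(self):
        # hand-worked normal equations for (0,0),(1,2),(2,3)
        fit = _fit_from_log2([0, 1, 2], [0, 2, 3])
        assert fit.slope == pytest.approx(1.5, abs=1e-12)
        assert fit.intercept == pytest.approx(1 / 6, abs=1e-12)
        assert fit.r_squared == pytest.approx(27 / 28, abs=1e-12)
        # residual SD uses the n-2 denominator
        sse = sum((y - (1 / 6 + 1.5 * x)) ** 2 for x, y in [(0, 0), (1, 2), (2, 3)])
        assert fit.residual_sd == pytest.approx(np.sqrt(sse / 1), rel=1e-12)

    def test_constant_response_r2_zero_by_convention(self):
        fit = _fit_from_log2([0, 1, 2, 3], [5, 5, 5, 5])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_degenerate_and_insufficient(self):
        with pytest.raises(DegenerateDesignError):
            fit_calibration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            fit_calibration([1.0, 2.0], [1.0, 2.0])


class TestInverseEstimate:
    def test_zero_noise_degenerate_interval(self):
        x = np.arange(5, dtype=float)
        fit = _fit_from_log2(x, x + 3.0)
        est = fit.inverse_estimate(2.0**5)
        assert est.conc_hat == pytest.approx(4.0, rel=1e-12)
        assert est.conc_lcl == pytest.approx(4.0, rel=1e-12)
        assert est.conc_ucl == pytest.approx(4.0, rel=1e-12)

    @pytest.mark.parametrize("offset", [0.0, -2.5, 3.0])
    def test_limits_match_bisection_oracle(self, offset):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 8, 9)
        fit = _fit_from_log2(x, 1.0 + x + rng.normal(0, 0.3, 9))
        y0 = float(fit.predict(fit.x_mean + offset))
        est = fit.inverse_estimate(2.0**y0)
        x_hat = (y0 - fit.intercept) / fit.slope

        def band(x, sign):
            return fit.predict(x) + sign * fit.band_halfwidth(x) - y0

        # independent oracle: bisect each band-crossing equation
        lcl = optimize.bisect(lambda x: band(x, +1), x_hat - 60, x_hat, xtol=1e-12)
        ucl = optimize.bisect(lambda x: band(x, -1), x_hat, x_hat + 60, xtol=1e-12)
        assert est.conc_lcl == pytest.approx(2.0**lcl, rel=1e-9)
        assert est.conc_ucl == pytest.approx(2.0**ucl, rel=1e-9)

    def test_three_point_fit_interval_unbounded_at_95(self):
        # with a single residual df, t ~ 12.7 makes t*s/sqrt(Sxx) exceed
        # the slope: the prediction band never crosses the observed y
        fit = _fit_from_log2([0, 1, 2], [0, 2, 3])
        with pytest.raises(UnboundedIntervalError):
            fit.inverse_estimate(2.0 ** float(fit.predict(fit.x_mean)))
        # at a lower confidence level the same fit inverts cleanly
        est = fit.inverse_estimate(2.0 ** float(fit.predict(1.0)), 0.60)
        assert est.conc_lcl < est.conc_hat < est.conc_ucl

    @given(
        slope=st.floats(0.5, 2.0),
        intercept=st.floats(-5, 5),
        noise=st.floats(0.01, 0.5),
        xq=st.floats(0.0, 8.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_inversion_identity_property(self, slope, intercept, noise, xq, seed):
        # inverse_estimate of the fitted value at x returns 2^x exactly
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 8, 9)
        y = intercept + slope * x + rng.normal(0, noise, x.size)
        fit = _fit_from_log2(x, y)
        est = fit.inverse_estimate(2.0 ** float(fit.predict(xq)))
        assert est.conc_hat == pytest.approx(2.0**xq, rel=1e-9)
        if fit.residual_sd > 0:
            assert est.conc_lcl < est.conc_hat < est.conc_ucl

    def test_interval_width_grows_away_from_center(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 8, 9)
        y = 1.0 + x + rng.normal(0, 0.2, 9)
        fit = _fit_from_log2(x, y)
        widths = []
        for xq in (fit.x_mean, fit.x_mean + 2, fit.x_mean + 5, fit.x_mean + 9):
            est = fit.inverse_estimate(2.0 ** float(fit.predict(xq)))
            widths.append(np.log2(est.conc_ucl) - np.log2(est.conc_lcl))
        assert np.all(np.diff(widths) > 0)

    def test_unbounded_interval_raises(self):
        # nearly flat slope drowned in noise: band never crosses
        rng = np.random.default_rng(1)
        x = np.linspace(0, 8, 12)
        y = 0.01 * x + rng.normal(0, 2.0, 12)
        fit = _fit_from_log2(x, y)
        with pytest.raises(UnboundedIntervalError):
            fit.inverse_estimate(2.0 ** float(fit.predict(4.0)))


class TestLooCv:
    def test_exact_line_recovers_truth_everywhere(self):
        conc = np.repeat([1.0, 2.0, 4.0, 8.0], 2)
        abun = 8.0 * conc
        out = loo_cv(conc, abun)
        assert len(out) == conc.size
        np.testing.assert_allclose(out["conc_hat"], out["conc_true"], rtol=1e-9)

    def test_fold_equals_manual_three_point_fit(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0])
        abun = np.array([10.0, 21.0, 40.0, 95.0])  # one perturbed point
        out = loo_cv(conc, abun).set_index("obs_index")
        fit = fit_calibration(conc[:3], abun[:3])
        direct = fit.inverse_estimate(abun[3])
        row = out.loc[3]
        assert row["conc_hat"] == pytest.approx(direct.conc_hat, rel=1e-12)
        assert row["conc_lcl"] == pytest.approx(direct.conc_lcl, rel=1e-9)
        assert row["conc_ucl"] == pytest.approx(direct.conc_ucl, rel=1e-9)

    def test_cardinality_and_min_points(self):
        conc = np.repeat([1.0, 2, 4, 8, 16], 3)
        rng = np.random.default_rng(0)
        abun = 100 * conc * np.exp(rng.normal(0, 0.1, conc.size))
        assert len(loo_cv(conc, abun)) == conc.size
        with pytest.raises(InsufficientDataError):
            loo_cv([1.0, 2, 4], [1.0, 2, 4])

    def test_coverage_near_nominal_on_lognormal_noise(self, default_config):
        # log-normal injection noise is exactly normal on the log2 axis,
        # so held-out 95% prediction intervals should cover ~95%
        from qnta import generate_dataset, add_metrics, reliability

        inside = total = 0
        for seed in (11, 12, 13):
            ds = generate_dataset(default_config, seed=seed)
            _, est = run_calibration_approach(ds, "A2")
            rel = reliability(est)
            inside += rel.orp * rel.n / 100
            total += rel.n
        assert total >= 2000
        assert 100 * inside / total == pytest.approx(95.0, abs=3.0)


class TestQcSummary:
    def test_symmetric_slopes_give_t_zero(self):
        fits = [self._fit_with_slope(s) for s in (0.9, 1.0, 1.1)]
        qc = qc_summary(fits)
        assert qc["mean_slope"] == pytest.approx(1.0)
        assert qc["t_statistic"] == pytest.approx(0.0, abs=1e-9)
        assert qc["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_shifted_slopes_match_textbook_t(self):
        qc = qc_summary([self._fit_with_slope(s) for s in (1.1, 1.2, 1.3)])
        t_expected = 0.2 / (0.1 / np.sqrt(3))
        assert qc["t_statistic"] == pytest.approx(t_expected, rel=1e-9)
        assert qc["p_value"] == pytest.approx(2 * stats.t.sf(t_expected, 2), rel=1e-9)

    def test_single_fit_insufficient(self):
        with pytest.raises(InsufficientDataError):
            qc_summary([self._fit_with_slope(1.0)])

    @staticmethod
    def _fit_with_slope(s):
        x = np.linspace(0, 8, 9)
        return _fit_from_log2(x, s * x + 1.0)


def test_run_approach_a1_requires_internal_standard(synthetic_dataset):
    fits1, est1 = run_calibration_approach(synthetic_dataset, "A1")
    fits2, est2 = run_calibration_approach(synthetic_dataset, "A2")
    assert set(fits1.columns) == set(fits2.columns)
    assert len(est2) == len(synthetic_dataset.observations)
    # IS normalization strips the shared run-level error: tighter residuals
    assert fits1["residual_sd"].median() < fits2["residual_sd"].median()
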