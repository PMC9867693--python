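"""Power-function effort model: exact recovery, a grid-search oracle,
inference identities, uncertainty bands and the parity-crossing solver."""

import numpy as np
import pytest
from scipy import stats

from checklist_bias.effort import (
    PowerFitResult,
    completeness_percent,
    crossing_duration,
    fit_power,
    mc_confidence_band,
    predict_bias,
    taylor_confidence_band,
)

# published-scale parameter pairs used as generator truth in exact-fit tests
PARAM_SETS = [(0.1729, 0.2853), (0.3879, 0.1414), (0.1473, 0.2837), (0.3301, 0.1402)]


def rss(coef, exp, x, y):
    return float(np.sum((coef * x**exp - 1.0 - y) ** 2))


def grid_search_oracle(x, y, coef_range=(0.01, 2.0), exp_range=(-0.5, 1.0)):
    """Dense 2-D grid minimisation with iterative zoom to ~1e-5 per axis."""
    lo_c, hi_c = coef_range
    lo_e, hi_e = exp_range
    best = None
    for _ in range(8):
        cs = np.linspace(lo_c, hi_c, 41)
        es = np.linspace(lo_e, hi_e, 41)
        vals = np.array([[rss(c, e, x, y) for e in es] for c in cs])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = (cs[i], es[j])
        dc, de = cs[1] - cs[0], es[1] - es[0]
        lo_c, hi_c = best[0] - 2 * dc, best[0] + 2 * dc
        lo_e, hi_e = best[1] - 2 * de, best[1] + 2 * de
    return best


class TestFitPower:
    @pytest.mark.parametrize("coef,exp", PARAM_SETS)
    def test_noiseless_recovery_to_1e6(self, coef, exp):
        x = np.arange(6.0, 201.0)
        y = coef * x**exp - 1.0
        fit = fit_power(x, y)
        assert fit.converged
        assert fit.coef == pytest.approx(coef, abs=1e-6)
        assert fit.exp == pytest.approx(exp, abs=1e-6)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-8)

    def test_constant_bias_degenerate_case(self):
        """y = -0.5 everywhere: flat curve with coef*x**exp ~ 0.5, exp ~ 0."""
        x = np.linspace(6, 200, 30)
        y = np.full_like(x, -0.5)
        fit = fit_power(x, y)
        preds = predict_bias(fit, x)
        assert np.allclose(preds, -0.5, atol=1e-6)
        assert abs(fit.exp) < 0.01

    def test_grid_search_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        x = np.linspace(6, 200, 18)
        y = 0.2 * x**0.3 - 1.0 + rng.normal(0, 0.05, x.size)
        fit = fit_power(x, y)
        oc, oe = grid_search_oracle(x, y)
        assert fit.coef == pytest.approx(oc, abs=1e-4)
        assert fit.exp == pytest.approx(oe, abs=1e-4)

    def test_first_order_optimality(self):
        rng = np.random.default_rng(3)
        x = np.linspace(6, 200, 50)
        y = 0.17 * x**0.29 - 1.0 + rng.normal(0, 0.2, x.size)
        fit = fit_power(x, y)
        # gradient of RSS: -2 * J' r
        r = y - (fit.coef * x**fit.exp - 1.0)
        xe = x**fit.exp
        grad = -2 * np.array([np.sum(xe * r), np.sum(fit.coef * xe * np.log(x) * r)])
        assert np.linalg.norm(grad) < 1e-5 * max(1.0, np.sum(r**2))

    def test_inference_identities(self):
        rng = np.random.default_rng(5)
        x = np.linspace(6, 200, 80)
        y = 0.17 * x**0.29 - 1.0 + rng.normal(0, 0.25, x.size)
        fit = fit_power(x, y)
        assert fit.dof == 78
        assert fit.t_coef == pytest.approx(fit.coef / fit.se_coef)
        assert fit.t_exp == pytest.approx(fit.exp / fit.se_exp)
        assert fit.p_exp == pytest.approx(2 * stats.t.sf(abs(fit.t_exp), 78))
        assert np.allclose(fit.covariance, fit.covariance.T)
        rse_direct = np.sqrt(np.sum((y - predict_bias(fit, x)) ** 2) / 78)
        assert fit.residual_se == pytest.approx(rse_direct)

    def test_monotone_fitted_curve_for_positive_params(self):
        x = np.arange(6.0, 201.0)
        fit = fit_power(x, 0.2 * x**0.3 - 1.0)
        preds = predict_bias(fit, x)
        assert np.all(np.diff(preds) >= 0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_power([1, 2], [0, 0])
        with pytest.raises(ValueError):
            fit_power([0, 1, 2], [0, 0, 0])


class TestPredictionAndCompleteness:
    @pytest.mark.parametrize(
        "coef,exp,bias60,pct60",
        [
            (0.1729, 0.2853, -0.44, 56),
            (0.3879, 0.1414, -0.31, 69),
            (0.1473, 0.2837, -0.53, 47),
            (0.3301, 0.1402, -0.41, 59),
        ],
    )
    def test_sixty_minute_evaluation(self, coef, exp, bias60, pct60):
        fit = PowerFitResult.from_params(coef, exp)
        assert round(predict_bias(fit, 60.0), 2) == bias60
        assert round(completeness_percent(fit, 60.0)) == pct60

    def test_zero_bias_means_full_completeness(self):
        fit = PowerFitResult.from_params(1.0 / 60**0.3, 0.3)
        assert predict_bias(fit, 60.0) == pytest.approx(0.0)
        assert completeness_percent(fit, 60.0) == pytest.approx(100.0)

    def test_short_duration_limit_is_minus_one(self):
        fit = PowerFitResult.from_params(0.2, 0.3)
        assert predict_bias(fit, 1e-9) == pytest.approx(-1.0, abs=1e-3)

    def test_rejects_non_positive_duration(self):
        fit = PowerFitResult.from_params(0.2, 0.3)
        with pytest.raises(ValueError):
            predict_bias(fit, 0.0)


class TestCrossingDuration:
    def test_parity_unreachable_within_200_minutes(self):
        fit = PowerFitResult.from_params(0.1729, 0.2853)
        assert crossing_duration(fit, 0.0, x_max=200.0) is None
        # bisection oracle for the unrestricted crossing
        lo, hi = 200.0, 2000.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if predict_bias(fit, mid) < 0:
                lo = mid
            else:
                hi = mid
        x = crossing_duration(fit, 0.0, x_max=2000.0)
        assert x == pytest.approx((lo + hi) / 2, rel=1e-6)

    def test_analytic_solution(self):
        fit = PowerFitResult.from_params(0.5, 0.5)
        assert crossing_duration(fit, 0.0, x_max=200.0) == pytest.approx(4.0)

    def test_flat_or_decreasing_curve_never_crosses(self):
        assert crossing_duration(PowerFitResult.from_params(0.8, 0.0)) is None
        assert crossing_duration(PowerFitResult.from_params(0.8, -0.2)) is None


class TestConfidenceBands:
    def _noisy_fit(self, seed=9):
        rng = np.random.default_rng(seed)
        x = np.linspace(6, 200, 100)
        y = 0.2 * x**0.3 - 1.0 + rng.normal(0, 0.2, x.size)
        return fit_power(x, y)

    def test_zero_covariance_collapses_band(self):
        fit = self._noisy_fit()
        flat = PowerFitResult(
            **{
                **{f: getattr(fit, f) for f in (
                    "coef", "exp", "se_coef", "se_exp", "t_coef", "t_exp",
                    "p_coef", "p_exp", "residual_se", "dof", "converged", "n_points",
                )},
                "covariance": np.zeros((2, 2)),
            }
        )
        band = mc_confidence_band(flat, np.linspace(6, 200, 20), n_sims=500, seed=1)
        assert np.allclose(band.lower95, band.fitted)
        assert np.allclose(band.upper95, band.fitted)

    def test_band_contains_fit_and_is_seed_deterministic(self):
        fit = self._noisy_fit()
        grid = np.linspace(6, 200, 25)
        b1 = mc_confidence_band(fit, grid, n_sims=4000, seed=7)
        b2 = mc_confidence_band(fit, grid, n_sims=4000, seed=7)
        assert np.array_equal(b1.lower95, b2.lower95)
        assert np.all(b1.lower95 <= b1.fitted + 1e-9)
        assert np.all(b1.fitted <= b1.upper95 + 1e-9)

    def test_wider_covariance_widens_band(self):
        fit = self._noisy_fit()
        grid = np.linspace(6, 200, 15)
        widths = []
        for scale in (1.0, 4.0):
            scaled = PowerFitResult(
                **{
                    **{f: getattr(fit, f) for f in (
                        "coef", "exp", "se_coef", "se_exp", "t_coef", "t_exp",
                        "p_coef", "p_exp", "residual_se", "dof", "converged", "n_points",
                    )},
                    "covariance": fit.covariance * scale,
                }
            )
            band = mc_confidence_band(scaled, grid, n_sims=6000, seed=3)
            widths.append(band.upper95 - band.lower95)
        assert np.all(widths[1] > widths[0])

    @pytest.mark.parametrize("order", [1, 2])
    def test_taylor_band_brackets_curve(self, order):
        fit = self._noisy_fit()
        grid = np.linspace(6, 200, 15)
        band = taylor_confidence_band(fit, grid, order=order)
        fitted = predict_bias(fit, grid)
        assert np.all(band.lower95 <= fitted)
        assert np.all(band.upper95 >= fitted)
        assert band.method == f"taylor_order{order}"

    def test_mc_and_first_order_taylor_same_scale(self):
        """The simulation band and the delta-method band agree in scale;
        the simulation band may be wider where the curve is most nonlinear
        in the exponent."""
        fit = self._noisy_fit()
        grid = np.linspace(20, 180, 9)
        mc = mc_confidence_band(fit, grid, n_sims=20000, seed=11)
        ta = taylor_confidence_band(fit, grid, order=1)
        ratio = (mc.upper95 - mc.lower95) / (ta.upper95 - ta.lower95)
        assert np.all(ratio > 0.5) and np.all(ratio < 2.5)
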