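import numpy as np
import pytest
from scipy.optimize import curve_fit

from synertri.models import Endpoint
from synertri.normalization import ConcentrationResponseSeries
from synertri.dose_response import (
    FourParamLogistic,
    InsufficientDataError,
    confidence_interval,
    fit_enhancement,
    fit_inhibition,
)


def four_pl(x, bottom, top, hill, ic50):
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def _pct_series(conc, resp, endpoint=Endpoint.IL6):
    return ConcentrationResponseSeries(
        endpoint=endpoint,
        treatment_label="t",
        concentrations=np.asarray(conc, float),
        responses=np.asarray(resp, float),
        s_mean=1000.0,
        ref_mean=100.0,
        scale="percent_of_stimulated",
    )


def _teer_series(conc, resp):
    return ConcentrationResponseSeries(
        endpoint=Endpoint.TEER,
        treatment_label="t",
        concentrations=np.asarray(conc, float),
        responses=np.asarray(resp, float),
        s_mean=-150.0,
        ref_mean=50.0,
        scale="normalized_teer",
    )


class TestNoiseFreeRecovery:
    @pytest.mark.parametrize("ic50,hill,bottom", [(14.0, 1.0, 0.0), (3.0, 1.7, 20.0)])
    def test_inhibition_recovers_analytic_midpoint(self, ic50, hill, bottom):
        """On exact 4PL data the fitted midpoint equals the analytic inverse
        of the curve at its own half-height."""
        x = np.repeat(np.geomspace(0.1, 100, 8), 3)
        y = four_pl(x, bottom, 100.0, hill, ic50)
        fit = fit_inhibition(_pct_series(x, y))
        assert fit.half_max == pytest.approx(ic50, rel=1e-6)
        assert fit.hill == pytest.approx(hill, rel=1e-6)
        assert fit.bottom == pytest.approx(bottom, abs=1e-5)
        # independent check: half-height concentration from the fitted curve
        est = FourParamLogistic(weighting="none").fit(x, y)
        half_height = (est.top_ + est.bottom_) / 2.0
        grid = np.geomspace(0.01, 1000, 200001)
        inv = grid[np.argmin(np.abs(est.predict(grid) - half_height))]
        assert inv == pytest.approx(fit.half_max, rel=1e-3)

    def test_enhancement_recovers_ec50(self):
        x = np.repeat(np.geomspace(1, 500, 8), 3)
        y = 100.0 * x / (x + 48.0)
        fit = fit_enhancement(_teer_series(x, y))
        assert fit.half_max == pytest.approx(48.0, rel=1e-6)

    def test_zero_noise_interval_width_collapses(self):
        x = np.repeat(np.geomspace(0.1, 100, 8), 3)
        y = four_pl(x, 0.0, 100.0, 1.0, 14.0)
        fit = fit_inhibition(_pct_series(x, y))
        lo, hi = fit.ci95
        assert hi / lo == pytest.approx(1.0, abs=1e-4)


class TestFlatAndErrors:
    def test_constant_series_is_flat_verdict(self):
        x = np.repeat(np.geomspace(0.1, 100, 6), 2)
        fit = fit_inhibition(_pct_series(x, np.full(x.size, 100.0)))
        assert fit.flat
        assert fit.half_max is None and fit.ci95 is None

    def test_flat_teer_at_zero_percent(self):
        x = np.repeat(np.geomspace(1, 100, 6), 2)
        fit = fit_enhancement(_teer_series(x, np.zeros(x.size)))
        assert fit.flat

    def test_too_few_concentrations(self):
        with pytest.raises(InsufficientDataError):
            fit_inhibition(_pct_series([1, 2, 4], [90, 60, 30]))

    def test_wrong_scale_rejected(self):
        s = ConcentrationResponseSeries(
            endpoint=Endpoint.IL6, treatment_label="t",
            concentrations=np.array([1.0, 2, 4, 8]),
            responses=np.array([900.0, 700, 400, 200]),
            s_mean=1000.0, ref_mean=100.0, scale="raw",
        )
        with pytest.raises(Exception):
            fit_inhibition(s)


class TestInvariants:
    @pytest.mark.parametrize("c", [0.1, 3.0, 1000.0])
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(5)
        x = np.repeat(np.geomspace(0.1, 100, 8), 3)
        y = four_pl(x, 10.0, 100.0, 1.2, 9.0) * rng.lognormal(0, 0.1, x.size)
        base = fit_inhibition(_pct_series(x, y))
        scaled = fit_inhibition(_pct_series(c * x, y))
        assert scaled.half_max == pytest.approx(c * base.half_max, rel=1e-6)
        assert scaled.hill == pytest.approx(base.hill, rel=1e-6)
        np.testing.assert_allclose(scaled.ci95, np.multiply(base.ci95, c), rtol=1e-6)

    def test_fitted_curve_strictly_monotone(self):
        x = np.repeat(np.geomspace(0.1, 100, 8), 3)
        y = four_pl(x, 5.0, 100.0, 0.8, 20.0)
        est = FourParamLogistic(weighting="none").fit(x, y)
        grid = np.geomspace(0.01, 1000, 500)
        assert np.all(np.diff(est.predict(grid)) < 0)

    def test_interval_contains_estimate(self):
        rng = np.random.default_rng(2)
        x = np.repeat(np.geomspace(0.1, 100, 8), 3)
        y = four_pl(x, 0.0, 100.0, 1.0, 14.0) * rng.lognormal(0, 0.15, x.size)
        fit = fit_inhibition(_pct_series(x, y))
        lo, hi = fit.ci95
        assert lo <= fit.half_max <= hi
        assert confidence_interval(fit, 0.95) == pytest.approx((lo, hi))
        lo90, hi90 = confidence_interval(fit, 0.90)
        assert lo < lo90 < hi90 < hi


def test_matches_unconstrained_curve_fit_oracle():
    """On interior-optimum data the multistart estimator agrees with a direct
    curve_fit started at the truth (independent optimisation route)."""
    rng = np.random.default_rng(42)
    x = np.repeat(np.geomspace(0.1, 100, 8), 3)
    y = four_pl(x, 20.0, 100.0, 1.0, 9.0) + rng.normal(0, 2.0, x.size)

    def model(xv, bottom, hill, m):
        return bottom + (100.0 - bottom) / (1.0 + 10 ** (hill * (np.log10(xv) - m)))

    popt, _ = curve_fit(model, x, y, p0=[20.0, 1.0, np.log10(9.0)], maxfev=10000)
    est = FourParamLogistic(weighting="none").fit(x, y)
    assert est.half_max_ == pytest.approx(10 ** popt[2], rel=1e-5)
    assert est.hill_ == pytest.approx(popt[1], rel=1e-4)


def test_sklearn_param_interface():
    est = FourParamLogistic(direction="enhancement", n_starts=3)
    params = est.get_params()
    assert params["direction"] == "enhancement"
    est.set_params(n_starts=7)
    assert est.get_params()["n_starts"] == 7
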