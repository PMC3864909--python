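"""Fitting, AICc, model selection and confidence-band behavior."""

import math

import numpy as np
import pytest

from paleogrowth import growth_models as gm
from paleogrowth.datasets import WholeBoneDataset
from paleogrowth.fitting_selection import (FitResult, aicc, confidence_band,
                                           fit, r_squared, select_models)

LOGISTIC_PARAMS = {"a": 100.0, "b": 12.0, "c": 0.4}


class TestAicc:
    def test_hand_computed_value(self):
        # n ln(rss/n) + 2k + 2k(k+1)/(n-k-1) with rss=10, n=10, k=2:
        # 10*ln(1) + 4 + 12/7
        assert aicc(10.0, 10, 2) == pytest.approx(4.0 + 12.0 / 7.0)

    def test_infinite_when_overfit(self):
        assert aicc(1.0, 5, 4) == math.inf       # n - k - 1 == 0
        assert aicc(1.0, 4, 4) == math.inf
        assert math.isfinite(aicc(1.0, 6, 4))

    def test_perfect_fit_flagged_minus_infinite(self):
        assert aicc(0.0, 10, 2) == -math.inf

    def test_extra_parameter_at_equal_rss_strictly_worse(self):
        for k in range(1, 6):
            assert aicc(5.0, 12, k + 1) > aicc(5.0, 12, k)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            aicc(-1.0, 10, 2)


class TestFit:
    @pytest.mark.parametrize("orientation", ["reverse", "direct"])
    def test_exact_line_recovered(self, linear_exact, orientation):
        f = fit(linear_exact, "Linear 2", orientation=orientation, seed=0)
        assert f.converged
        assert f.rss == 0.0
        assert f.params["b"] == pytest.approx(2.0, abs=1e-8)
        assert f.params["c"] == pytest.approx(3.0, abs=1e-9)

    @pytest.mark.parametrize("orientation", ["reverse", "direct"])
    def test_noiseless_logistic_recovery_vs_independent_oracle(
            self, logistic_full_span, orientation):
        f = fit(logistic_full_span, "Logistic 3", orientation=orientation,
                seed=1)
        for k, v in LOGISTIC_PARAMS.items():
            assert f.params[k] == pytest.approx(v, rel=1e-4)

        # independent oracle: coarse grid search + Nelder-Mead polish on the
        # direct objective (no shared code with the multi-start fitter)
        t, y = logistic_full_span.ages, logistic_full_span.dimensions

        def sse(p):
            a, b, c = p
            return float(np.sum((y - a / (1 + np.exp(-c * (t - b)))) ** 2))

        grid = [(a, b, c)
                for a in np.linspace(90, 140, 6)
                for b in np.linspace(5, 20, 7)
                for c in np.linspace(0.1, 1.0, 7)]
        x0 = min(grid, key=sse)
        from scipy.optimize import minimize
        polished = minimize(sse, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14,
                                     "maxiter": 5000}).x
        for fitted, oracle in zip((f.params["a"], f.params["b"],
                                   f.params["c"]), polished):
            assert fitted == pytest.approx(oracle, rel=1e-3)

    def test_deterministic_given_seed(self, logistic_full_span):
        f1 = fit(logistic_full_span, "Gompertz 3", seed=7)
        f2 = fit(logistic_full_span, "Gompertz 3", seed=7)
        assert f1.params == f2.params and f1.rss == f2.rss

    @pytest.mark.parametrize("name", [
        "Logistic 3", "Gompertz 3", "von Bertalanffy 3", "Monomolecular 2",
        "Michaelis Menten 2", "Extreme Value 3a", "Power 2", "Exponential 3",
        "Linear 2", "Rational 2z"])
    def test_self_recovery_ten_models(self, name):
        """Reverse-fitting data generated from the model itself (noiseless,
        full span) recovers its parameters to 1e-3 relative."""
        model = gm.get_model(name)
        rng = np.random.default_rng(99)
        p = gm.sample_params(model, rng)
        a = model._asymptote(p)
        if math.isfinite(a):
            lo = max(gm.lower_limit(model, p), 0.0)
            levels = lo + (a - lo) * np.linspace(0.05, 0.95, 20)
            ages = np.asarray(gm.inverse_age(model, p, levels))
        else:
            t0 = gm.age_floor(model, p)
            ages = np.linspace(t0 + 0.5, t0 + 25.0, 20)
        keep = ages >= 0
        ages = ages[keep]
        dims = np.asarray(gm.evaluate(model, p, ages))
        ds = WholeBoneDataset(ages=ages, dimensions=dims)
        f = fit(ds, model, orientation="reverse", seed=5)
        truth = dict(zip(model.param_names, p))
        for k, v in truth.items():
            assert f.params[k] == pytest.approx(v, rel=1e-3), (name, k)


class TestSelection:
    def test_linear_data_linear2_wins_by_tie_rule(self, linear_exact):
        # Power 3 (d + b t^c with c = 1) also achieves rss 0 but has k = 3;
        # the tie among perfect fits breaks to the fewest parameters
        rep = select_models(linear_exact,
                            models=["Linear 2", "Power 3", "Quadratic 3",
                                    "Logistic 3", "Monomolecular 2"],
                            seed=2)
        assert rep.best.model_name == "Linear 2"
        assert rep.best.support_class == "best"
        power3 = next(f for f in rep.fits if f.model_name == "Power 3")
        assert power3.rss == pytest.approx(0.0, abs=1e-12)

    def test_full_span_logistic_asymptotic_wins(self, logistic_full_span):
        rep = select_models(logistic_full_span,
                            models=["Logistic 3", "Gompertz 3", "Linear 2",
                                    "Quadratic 2", "Power 2", "Cubic 2",
                                    "Exponential 2", "Michaelis Menten 2"],
                            seed=3)
        assert rep.best.model.family_class in ("sigmoidal", "attenuating")
        assert rep.best.model_name == "Logistic 3"

    def test_never_selects_overfit_model(self):
        ds = WholeBoneDataset(ages=[1.0, 2.0, 3.0], dimensions=[2.0, 4.0, 6.5])
        rep = select_models(ds, models=["Linear 2", "Logistic 3",
                                        "Gompertz 3"], seed=1)
        # n = 3: any k >= 2 has n-k-1 <= 0 only for k >= 2 -> k=2 gives 0
        assert all(f.k < f.n - 1 or f.aicc == math.inf for f in rep.fits)
        assert rep.status == "insufficient data" or rep.best.k < rep.best.n - 1

    def test_insufficient_data_status(self):
        ds = WholeBoneDataset(ages=[1.0, 2.0], dimensions=[2.0, 4.0])
        rep = select_models(ds, models=["Linear 2", "Logistic 3"], seed=1)
        assert rep.status == "insufficient data"
        assert rep.best is None

    def test_delta_and_relative_likelihood_bookkeeping(self, logistic_full_span):
        # noisy data so no fit is perfect and deltas are finite
        rng = np.random.default_rng(4)
        ds = WholeBoneDataset(
            ages=logistic_full_span.ages + rng.normal(0, 0.5, logistic_full_span.n),
            dimensions=logistic_full_span.dimensions)
        rep = select_models(ds, models=["Logistic 3", "Gompertz 3",
                                        "Linear 2"], seed=4)
        deltas = [f.delta_aicc for f in rep.fits if f.converged]
        assert min(deltas) == 0.0
        for f in rep.fits:
            if f.converged and math.isfinite(f.delta_aicc):
                assert f.rel_likelihood == pytest.approx(
                    math.exp(-f.delta_aicc / 2.0))
                assert 0.0 < f.rel_likelihood <= 1.0


class TestRSquaredAndBands:
    def test_perfect_fit_r2_one(self, linear_exact):
        f = fit(linear_exact, "Linear 2", seed=0)
        assert r_squared(f) == pytest.approx(1.0)

    def test_constant_prediction_r2_zero(self):
        # a fit whose rss equals the total sum of squares explains nothing
        y = np.array([1.0, 2.0, 3.0, 4.0])
        tss = float(np.sum((y - y.mean()) ** 2))
        f = FitResult("Linear 2", {"b": 0.0, "c": 1.0}, "direct", tss,
                      4, 2, aicc(tss, 4, 2), True, "", np.arange(4.0), y)
        assert r_squared(f) == pytest.approx(0.0)

    def test_zero_variance_flagged_nan(self):
        y = np.array([5.0, 5.0, 5.0])
        f = FitResult("Linear 2", {"b": 5.0, "c": 0.0}, "direct", 0.0,
                      3, 2, -math.inf, True, "", np.arange(3.0), y)
        assert math.isnan(r_squared(f))

    def test_band_brackets_curve_and_grows_with_extrapolation(self):
        rng = np.random.default_rng(11)
        t = np.linspace(2, 18, 25)
        y = np.asarray(gm.evaluate("Logistic 3", LOGISTIC_PARAMS, t))
        y = y + rng.normal(0, 1.0, len(t))
        ds = WholeBoneDataset(ages=t, dimensions=np.maximum(y, 0.5))
        f = fit(ds, "Logistic 3", orientation="direct", seed=2)
        grid = np.array([10.0, 36.0])     # centroid vs 2x the max observed age
        center, lo, hi = confidence_band(f, grid)
        assert np.all(lo <= center) and np.all(center <= hi)
        assert (hi[1] - lo[1]) > (hi[0] - lo[0])

    def test_band_requires_converged_fit(self):
        bad = FitResult("Linear 2", {}, "direct", math.inf, 5, 2, math.inf,
                        False, "", np.arange(5.0), np.arange(5.0) + 1)
        with pytest.raises(ValueError):
            confidence_band(bad, np.array([1.0]))
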