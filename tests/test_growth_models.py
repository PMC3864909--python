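"""Catalog invariants: census, monotonicity, inverses, derivatives, classes."""

import math

import numpy as np
import pytest

from paleogrowth import growth_models as gm

ALL_MODELS = gm.model_names()


def _grid(model, params, n=40, span=30.0, margin=0.1):
    """Well-conditioned test ages: inside the domain, away from saturation."""
    t0 = gm.age_floor(model, params) + margin
    ts = np.linspace(t0, t0 + span, n)
    y = np.asarray(gm.evaluate(model, params, ts), float)
    a = gm.asymptote(model, params)
    lo = gm.lower_limit(model, params)
    mask = np.isfinite(y)
    scale = max(abs(a), 1.0) if math.isfinite(a) else max(np.max(np.abs(y)), 1.0)
    if math.isfinite(a):
        mask &= (a - y) > 1e-6 * scale
    if math.isfinite(lo):
        mask &= (y - lo) > 1e-9 * scale
    return ts[mask], y[mask], scale


def test_census_counts():
    c = gm.census()
    assert c == {"increasing": 15, "sigmoidal": 48, "attenuating": 14}
    assert sum(c.values()) == 77


def test_manifest_matches_registry():
    import importlib.resources as res
    import pandas as pd

    with res.as_file(res.files("paleogrowth") / "data" /
                     "catalog_manifest.tsv") as p:
        man = pd.read_csv(p, sep="\t")
    assert len(man) == 77
    assert set(man["name"]) == set(ALL_MODELS)
    for _, row in man.iterrows():
        m = gm.get_model(row["name"])
        assert m.family_class == row["family_class"]
        assert m.k == row["k"]
        assert m.reconstructed == bool(row["reconstructed"])


def test_named_core_models_present():
    for name in ["Logistic 3", "Gompertz 3", "von Bertalanffy 3",
                 "Monomolecular 2", "Extreme Value 2", "Extreme Value 3a",
                 "Extreme Value 3b", "Rational 2z", "Michaelis Menten 2",
                 "Persistence 3a", "Power 2", "Power 3", "Exponential 2",
                 "Exponential 3", "Linear 2", "Quadratic 2", "Quadratic 2b",
                 "Cubic 2", "Cubic 2b", "Morgan Mercer Flodin 4b"]:
        gm.get_model(name)


def test_naming_convention_trailing_parameter_count():
    import re

    for name in ALL_MODELS:
        mdl = gm.get_model(name)
        m = re.search(r"(\d)[a-z]?$", name)
        assert m, f"{name} lacks a parameter-count suffix"
        assert int(m.group(1)) == mdl.k, name


@pytest.mark.parametrize("name", ALL_MODELS)
def test_monotone_and_inverse_roundtrip(name):
    """Strict monotonicity plus t -> y -> t round trips to 1e-8 relative."""
    model = gm.get_model(name)
    rng = np.random.default_rng(101)
    for _ in range(50):
        p = gm.sample_params(model, rng)
        ts, y, scale = _grid(model, p)
        if len(ts) < 5:
            continue
        assert np.all(np.diff(y) > 0), f"{name}: not strictly increasing"
        tt = np.asarray(gm.inverse_age(model, p, y), float)
        assert np.allclose(tt, ts, rtol=1e-8, atol=1e-8 * max(1.0, np.max(np.abs(ts)))), \
            f"{name}: inverse round-trip error {np.max(np.abs(tt - ts)):.2e}"


@pytest.mark.parametrize("name", ALL_MODELS)
def test_growth_rate_matches_finite_difference(name):
    """Analytic dy/dt agrees with a central difference to 1e-6 relative
    (on points where the rate is numerically well conditioned)."""
    model = gm.get_model(name)
    rng = np.random.default_rng(202)
    checked = 0
    for _ in range(50):
        p = gm.sample_params(model, rng)
        ts, y, scale = _grid(model, p)
        if len(ts) < 5:
            continue
        t0 = gm.age_floor(model, p)
        ts = ts[1:-1]
        r = np.asarray(gm.growth_rate(model, p, ts), float)
        assert np.all(np.isfinite(r)) and np.all(r >= 0)
        h = 1e-3 * np.maximum(np.abs(ts), 1.0)
        h = np.minimum(h, (ts - t0) / 3 if math.isfinite(t0) else h)
        ok = (r > 1e-4 * scale) & (h > 0)
        if not ok.any():
            continue
        th, hh = ts[ok], h[ok]

        def f(x):
            return np.asarray(gm.evaluate(model, p, x), float)

        # fourth-order central stencil: truncation negligible at this h
        fd = (-f(th + 2 * hh) + 8 * f(th + hh)
              - 8 * f(th - hh) + f(th - 2 * hh)) / (12 * hh)
        rel = np.abs(fd - r[ok]) / r[ok]
        assert np.max(rel) < 1e-6, f"{name}: derivative mismatch {np.max(rel):.2e}"
        checked += 1
    assert checked >= 25


@pytest.mark.parametrize("name", gm.model_names("sigmoidal"))
def test_sigmoidal_inflection_is_global_rate_maximum(name):
    model = gm.get_model(name)
    rng = np.random.default_rng(303)
    for _ in range(10):
        p = gm.sample_params(model, rng)
        t_i, y_i, r_max = gm.inflection(model, p)
        assert math.isfinite(t_i) and r_max > 0
        assert np.isclose(gm.evaluate(model, p, t_i), y_i)
        assert np.isclose(gm.growth_rate(model, p, t_i), r_max)
        t0 = max(gm.age_floor(model, p), t_i - 25.0)
        grid = np.linspace(t0 + 1e-6, t_i + 25.0, 400)
        rr = np.asarray(gm.growth_rate(model, p, grid))
        assert np.max(rr) <= r_max * (1 + 1e-9)


@pytest.mark.parametrize("name", gm.model_names("attenuating"))
def test_attenuating_rate_maximal_at_domain_edge(name):
    model = gm.get_model(name)
    rng = np.random.default_rng(404)
    for _ in range(10):
        p = gm.sample_params(model, rng)
        assert gm.inflection(model, p) is gm.NOT_MEANINGFUL
        t0 = gm.age_floor(model, p) + 1e-6
        grid = np.linspace(t0, t0 + 30.0, 400)
        rr = np.asarray(gm.growth_rate(model, p, grid))
        assert int(np.argmax(rr)) == 0, f"{name}: rate max not at left edge"


@pytest.mark.parametrize("name", ALL_MODELS)
def test_asymptote_class_consistency(name):
    model = gm.get_model(name)
    rng = np.random.default_rng(505)
    p = gm.sample_params(model, rng)
    a = gm.asymptote(model, p)
    if model.family_class == "increasing":
        assert math.isinf(a)
    else:
        assert math.isfinite(a) and a > 0
        t0 = gm.age_floor(model, p)
        ts = t0 + np.array([1.0, 5.0, 20.0, 100.0])
        y = np.asarray(gm.evaluate(model, p, ts))
        # strictly below the asymptote wherever float resolution permits
        assert np.all(y <= a)
        assert y[0] < a


class TestClosedFormExamples:
    def test_logistic_at_inflection_is_half_asymptote(self):
        p = {"a": 120.0, "b": 9.0, "c": 0.3}
        assert gm.evaluate("Logistic 3", p, 9.0) == pytest.approx(60.0)
        t_i, y_i, r_max = gm.inflection("Logistic 3", p)
        assert (t_i, y_i) == pytest.approx((9.0, 60.0))
        assert r_max == pytest.approx(120.0 * 0.3 / 4.0)

    def test_gompertz_inflection_at_a_over_e(self):
        p = {"a": 90.0, "b": 7.0, "c": 0.5}
        t_i, y_i, r_max = gm.inflection("Gompertz 3", p)
        assert t_i == pytest.approx(7.0)
        assert y_i == pytest.approx(90.0 / math.e)
        # grid oracle for the maximum rate
        grid = np.linspace(0.01, 40, 20001)
        rr = np.asarray(gm.growth_rate("Gompertz 3", p, grid))
        assert r_max == pytest.approx(np.max(rr), rel=1e-6)

    def test_linear_intercept_slope_and_no_inflection(self):
        p = {"b": 4.0, "c": 2.5}
        assert gm.evaluate("Linear 2", p, 0.0) == pytest.approx(4.0)
        assert gm.growth_rate("Linear 2", p, 3.0) == pytest.approx(2.5)
        assert gm.growth_rate("Linear 2", p, 30.0) == pytest.approx(2.5)
        assert gm.inflection("Linear 2", p) is gm.NOT_MEANINGFUL

    def test_monomolecular_closed_form_inverse(self):
        # y = a(1 - e^{-ct}); at y = a(1 - 1/e) the age is exactly 1/c
        a, c = 80.0, 0.25
        y = a * (1.0 - 1.0 / math.e)
        assert gm.inverse_age("Monomolecular 2", {"a": a, "c": c}, y) == \
            pytest.approx(1.0 / c, rel=1e-12)

    def test_michaelis_menten_approaches_asymptote(self):
        p = {"a": 55.0, "b": 4.0}
        y = gm.evaluate("Michaelis Menten 2", p, 1e6)
        assert abs(y - 55.0) / 55.0 < 0.01

    def test_cubic_asymptote_infinite(self):
        assert math.isinf(gm.asymptote("Cubic 2", {"b": 1.0, "c": 0.1}))


class TestErrors:
    def test_constraint_violation_raises(self):
        with pytest.raises(gm.ParameterError):
            gm.evaluate("Logistic 3", {"a": -5.0, "b": 1.0, "c": 0.2}, 1.0)
        with pytest.raises(gm.ParameterError):
            gm.evaluate("Linear 2", {"b": 0.0, "c": -1.0}, 1.0)

    def test_age_outside_domain_raises(self):
        with pytest.raises(gm.DomainError):
            gm.evaluate("Frechet 2", {"a": 50.0, "b": 5.0}, -1.0)

    def test_size_at_or_above_asymptote_raises(self):
        with pytest.raises(gm.RangeError):
            gm.inverse_age("Logistic 3", {"a": 100.0, "b": 10.0, "c": 0.3},
                           100.0)
        with pytest.raises(gm.RangeError):
            gm.inverse_age("Power 2", {"b": 2.0, "c": 1.5}, -1.0)

    def test_unknown_model_name(self):
        with pytest.raises(KeyError):
            gm.get_model("Loggistic 3")
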