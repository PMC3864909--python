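"""Catalog of growth functions y(t) for skeletochronological curve fitting.

The catalog holds 77 named growth models in three classes:

* ``increasing`` (15): unbounded curves (linear, polynomial, power, exponential,
  persistence) with :math:`\\lim_{t\\to\\infty} y(t) = \\infty`.
* ``sigmoidal`` (48): asymptotic S-shaped curves with a free interior inflection
  point (logistic, Gompertz, von Bertalanffy, Richards, extreme-value, ...).
* ``attenuating`` (14): asymptotic curves whose growth rate is maximal at the
  left edge of the admissible age domain — like a sigmoid that starts at its
  inflection point (monomolecular, Michaelis–Menten, ...).

Every model is strictly monotone increasing in age over its admissible domain,
so the inverse function t(y) exists; it is used for reverse-orientation
regression in which bone size is the independent variable and age the
dependent one.  All but one model (Persistence 3b) carry closed-form inverses;
a bisection fallback covers the rest.

Parameters follow the field's conventional symbols: ``a`` finite asymptote,
``b`` location/scale, ``c`` rate per year, ``d`` lower offset (starting value),
``g`` dimensionless shape.  Sizes are in the data set's length unit (cm or mm);
ages in years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import special, optimize

__all__ = [
    "GrowthModel",
    "ParameterError",
    "DomainError",
    "RangeError",
    "NOT_MEANINGFUL",
    "CATALOG",
    "get_model",
    "model_names",
    "census",
    "evaluate",
    "inverse_age",
    "growth_rate",
    "inflection",
    "asymptote",
    "lower_limit",
    "age_floor",
    "sample_params",
    "manifest_frame",
]


class ParameterError(ValueError):
    """Parameter values violate the model's admissibility constraints."""


class DomainError(ValueError):
    """Age lies outside the model's admissible domain."""


class RangeError(ValueError):
    """Size lies outside the model's attainable range (e.g. above the asymptote)."""


class _NotMeaningful:
    """Sentinel for quantities (inflection point) undefined for a model class."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_MEANINGFUL"

    def __bool__(self) -> bool:
        return False


NOT_MEANINGFUL = _NotMeaningful()

_INF = float("inf")


# ---------------------------------------------------------------------------
# Fitting metadata: per-parameter box bounds and a central start, as functions
# of the observed (ages, sizes) arrays.  Multi-start jitter is applied on top
# by the fitting module.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    name: str
    lo: Callable  # (t, y) -> float
    hi: Callable
    init: Callable
    kind: str = ""  # 'asym' marks the asymptote parameter (reverse-fit lower bound)


def _span(t):
    s = float(np.max(t) - np.min(t))
    return s if s > 0 else 1.0


def _const(v):
    return lambda t, y: v


def p_asym(name="a", factor=1.3):
    return ParamSpec(name,
                     lambda t, y: float(np.max(y)) * (1.0 + 1e-9),
                     _const(1e60),
                     lambda t, y: float(np.max(y)) * factor,
                     kind="asym")


def p_loc(name="b"):
    return ParamSpec(name, _const(-1e4), _const(1e5),
                     lambda t, y: float(np.median(t)))


def p_rate(name="c", mult=3.0):
    return ParamSpec(name, _const(1e-18), _const(1e4),
                     lambda t, y: mult / _span(t), kind="rate")


def p_floor(name="d", positive=False):
    lo = _const(1e-12) if positive else _const(-1e12)
    return ParamSpec(name, lo,
                     lambda t, y: float(np.min(y)) * (1.0 - 1e-9),
                     lambda t, y: float(np.min(y)) * 0.5,
                     kind="floor")


def p_shape(name="g", lo=1.0 + 1e-6, hi=30.0, init=2.0):
    return ParamSpec(name, _const(lo), _const(hi), _const(init))


def p_tscale(name="b", power=1):
    return ParamSpec(name, _const(1e-9), _const(1e12),
                     lambda t, y: float(max(np.median(t), 0.5)) ** power)


def p_icept(name="b"):
    return ParamSpec(name, _const(-1e9), _const(1e9),
                     lambda t, y: float(np.min(y)))


def p_slope(name="c"):
    return ParamSpec(name, _const(1e-12), _const(1e9),
                     lambda t, y: (float(np.max(y)) - float(np.min(y))) / _span(t))


def p_coef(name="b"):
    return ParamSpec(name, _const(1e-12), _const(1e9),
                     lambda t, y: max(float(np.min(y)), 1e-3))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthModel:
    """A named parametric growth function family.

    The private callables all take ``(arg, params_tuple)`` with ``params``
    ordered as ``param_names``; use the module-level operations
    (:func:`evaluate`, :func:`inverse_age`, ...) for validated access.
    """

    name: str
    family_class: str                  # 'sigmoidal' | 'attenuating' | 'increasing'
    param_names: tuple
    formula: str
    constraints: str
    reconstructed: bool
    _eval: Callable
    _deriv: Callable
    _asymptote: Callable               # params -> finite value or +inf
    _inverse: Optional[Callable] = None
    _inflection_t: Optional[Callable] = None   # params -> t_i (sigmoidal only)
    _lower: Callable = None            # params -> inf of y over math domain
    _tmin: Callable = None             # params -> left edge of math domain
    _check: Callable = None            # params -> bool
    _sample: Callable = None           # rng -> params tuple
    fit_spec: tuple = ()               # tuple[ParamSpec]

    @property
    def k(self) -> int:
        return len(self.param_names)

    def params_tuple(self, params) -> tuple:
        if isinstance(params, dict):
            try:
                return tuple(float(params[p]) for p in self.param_names)
            except KeyError as e:  # pragma: no cover - defensive
                raise ParameterError(f"{self.name}: missing parameter {e}") from e
        p = tuple(float(v) for v in params)
        if len(p) != self.k:
            raise ParameterError(
                f"{self.name}: expected {self.k} parameters {self.param_names}, got {len(p)}")
        return p

    def check(self, params) -> bool:
        p = self.params_tuple(params)
        if not all(math.isfinite(v) for v in p):
            return False
        return bool(self._check(p)) if self._check is not None else True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GrowthModel({self.name!r}, {self.family_class}, k={self.k})"


# ---------------------------------------------------------------------------
# Shape primitives: unit CDF-like kernels F(x) with derivative, inverse and
# the x at which F' is maximal (None when F' is monotone, i.e. no inflection).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Kernel:
    label: str
    f: Callable
    df: Callable
    finv: Callable
    xstar: Optional[float]      # argmax of f'; None if f' monotone decreasing
    lo: float                   # inf of f over its x-domain
    xmin: float                 # left edge of x-domain (-inf if all reals)


def _expit(x):
    return special.expit(x)


K_LOGISTIC = _Kernel("logistic", _expit,
                     lambda x: _expit(x) * (1.0 - _expit(x)),
                     lambda u: np.log(u / (1.0 - u)), 0.0, 0.0, -_INF)

K_GUMBEL_MAX = _Kernel("gumbel-max", lambda x: np.exp(-np.exp(-x)),
                       lambda x: np.exp(-x - np.exp(-x)),
                       lambda u: -np.log(-np.log(u)), 0.0, 0.0, -_INF)

K_GUMBEL_MIN = _Kernel("gumbel-min", lambda x: -np.expm1(-np.exp(x)),
                       lambda x: np.exp(x - np.exp(x)),
                       lambda u: np.log(-np.log1p(-u)), 0.0, 0.0, -_INF)

K_ERF = _Kernel("erf", lambda x: 0.5 * (1.0 + special.erf(x)),
                lambda x: np.exp(-x * x) / math.sqrt(math.pi),
                lambda u: special.erfinv(2.0 * u - 1.0), 0.0, 0.0, -_INF)

K_ATAN = _Kernel("arctan", lambda x: 0.5 + np.arctan(x) / math.pi,
                 lambda x: 1.0 / (math.pi * (1.0 + x * x)),
                 lambda u: np.tan(math.pi * (u - 0.5)), 0.0, 0.0, -_INF)

K_TANH = _Kernel("tanh", lambda x: 0.5 * (1.0 + np.tanh(x)),
                 lambda x: 0.5 / np.cosh(x) ** 2,
                 lambda u: np.arctanh(2.0 * u - 1.0), 0.0, 0.0, -_INF)

K_ALGEBRAIC = _Kernel("algebraic", lambda x: 0.5 * (1.0 + x / np.sqrt(1.0 + x * x)),
                      lambda x: 0.5 * (1.0 + x * x) ** -1.5,
                      lambda u: (2.0 * u - 1.0) / np.sqrt(1.0 - (2.0 * u - 1.0) ** 2),
                      0.0, 0.0, -_INF)

K_GUDERMANN = _Kernel("gudermannian", lambda x: 0.5 + np.arctan(np.sinh(x)) / math.pi,
                      lambda x: 1.0 / (math.pi * np.cosh(x)),
                      lambda u: np.arcsinh(np.tan(math.pi * (u - 0.5))), 0.0, 0.0, -_INF)

# saturating exponential: range (-inf, 1) over all reals; rate monotone.
K_EXPSAT = _Kernel("expsat", lambda x: -np.expm1(-x),
                   lambda x: np.exp(-x),
                   lambda u: -np.log1p(-u), None, -_INF, -_INF)


# ---------------------------------------------------------------------------
# Builders.  Each returns a GrowthModel.  ``samplers`` are per-parameter
# callables rng -> value, applied in order with later samplers receiving the
# values drawn so far (enables relational constraints such as d < a).
# ---------------------------------------------------------------------------

_REGISTRY: dict = {}


def _register(m: GrowthModel) -> GrowthModel:
    if m.name in _REGISTRY:  # pragma: no cover - build-time guard
        raise ValueError(f"duplicate model name {m.name}")
    _REGISTRY[m.name] = m
    return m


def _mk_sample(samplers):
    def sample(rng):
        out = []
        for s in samplers:
            out.append(float(s(rng, out)))
        return tuple(out)
    return sample


def _u(lo, hi):
    return lambda rng, prev: rng.uniform(lo, hi)


def _logu(lo, hi):
    return lambda rng, prev: math.exp(rng.uniform(math.log(lo), math.log(hi)))


_S_A = _u(20.0, 150.0)            # asymptote, size units
_S_RATE = _logu(0.08, 0.6)        # per-year rate
_S_LOC = _u(2.0, 15.0)            # inflection location, years


def _cdf_model(name, kernel, *, loc=True, floor=False, family_class=None,
               reconstructed=True, formula=None, constraints=None,
               loc_sampler=_S_LOC, loc_spec=None, extra_check=None):
    """y = d + (a-d) * F(c*(t-b)); omit b (loc=False) and/or d (floor=False)."""
    names = ["a"]
    spec = [p_asym()]
    samplers = [_S_A]
    if loc:
        names.append("b")
        spec.append(loc_spec if loc_spec is not None else p_loc())
        samplers.append(loc_sampler)
    names.append("c")
    spec.append(p_rate())
    samplers.append(_S_RATE)
    if floor:
        names.append("d")
        spec.append(p_floor(positive=False))
        samplers.append(lambda rng, prev: rng.uniform(0.02, 0.25) * prev[0])
    names = tuple(names)

    def unpack(p):
        if loc and floor:
            a, b, c, d = p
        elif loc:
            (a, b, c), d = p, 0.0
        elif floor:
            (a, c, d), b = p, 0.0
        else:
            (a, c), b, d = p, 0.0, 0.0
        return a, b, c, d

    def ev(t, p):
        a, b, c, d = unpack(p)
        return d + (a - d) * kernel.f(c * (np.asarray(t, float) - b))

    def dv(t, p):
        a, b, c, d = unpack(p)
        return (a - d) * c * kernel.df(c * (np.asarray(t, float) - b))

    def inv(y, p):
        a, b, c, d = unpack(p)
        return b + kernel.finv((np.asarray(y, float) - d) / (a - d)) / c

    infl = None
    if kernel.xstar is not None:
        def infl(p):
            a, b, c, d = unpack(p)
            return b + kernel.xstar / c

    def asym(p):
        return unpack(p)[0]

    def lower(p):
        a, b, c, d = unpack(p)
        return d + (a - d) * kernel.lo if math.isfinite(kernel.lo) else -_INF

    def tmin(p):
        a, b, c, d = unpack(p)
        return b + kernel.xmin / c if math.isfinite(kernel.xmin) else -_INF

    def chk(p):
        a, b, c, d = unpack(p)
        ok = a > 0 and c > 0 and d < a
        if ok and extra_check is not None:
            ok = extra_check(p)
        return ok

    if family_class is None:
        family_class = "sigmoidal" if (loc and kernel.xstar is not None) else "attenuating"
    if formula is None:
        core = f"{kernel.label}(c*(t-b))" if loc else f"{kernel.label}(c*t)"
        formula = (f"y = d + (a-d)*{core}" if floor else
                   (f"y = a*{core}"))
    if constraints is None:
        constraints = "a > 0, c > 0" + (", d < a" if floor else "")
    return _register(GrowthModel(
        name=name, family_class=family_class, param_names=names,
        formula=formula, constraints=constraints, reconstructed=reconstructed,
        _eval=ev, _deriv=dv, _inverse=inv, _inflection_t=infl,
        _asymptote=asym, _lower=lower, _tmin=tmin, _check=chk,
        _sample=_mk_sample(samplers), fit_spec=tuple(spec)))


def _half_cdf_model(name, kernel, formula_label):
    """Attenuating 2-parameter y = a*(2*F(c*t)-1) restricted to t >= 0."""
    def ev(t, p):
        a, c = p
        return a * (2.0 * kernel.f(c * np.asarray(t, float)) - 1.0)

    def dv(t, p):
        a, c = p
        return 2.0 * a * c * kernel.df(c * np.asarray(t, float))

    def inv(y, p):
        a, c = p
        return kernel.finv((np.asarray(y, float) / a + 1.0) / 2.0) / c

    return _register(GrowthModel(
        name=name, family_class="attenuating", param_names=("a", "c"),
        formula=f"y = a*{formula_label}", constraints="a > 0, c > 0",
        reconstructed=True,
        _eval=ev, _deriv=dv, _inverse=inv, _inflection_t=None,
        _asymptote=lambda p: p[0], _lower=lambda p: 0.0,
        _tmin=lambda p: 0.0,
        _check=lambda p: p[0] > 0 and p[1] > 0,
        _sample=_mk_sample([_S_A, _S_RATE]),
        fit_spec=(p_asym(), p_rate())))


def _ratio_model(name, power, *, floor=False, shift=False, family_class=None,
                 shape_free=False, reconstructed=True):
    """t-ratio saturation: y = d + (a-d)*u/(1+u) with u = ((t-b0)/b)^p.

    power: fixed exponent p, or None with shape_free=True for a free exponent g.
    shift: use (t-b) with a raw denominator scale c (units yr^p).
    """
    if shift:
        # y = a*(t-b)^p / (c + (t-b)^p), domain t >= b
        names = ("a", "b", "c")
        b_spec = ParamSpec("b", _const(-1e4),
                           lambda t, y: float(np.min(t)) - 1e-9,
                           lambda t, y: float(np.min(t)) - 1.0)

        def ev(t, p_):
            a, b, c = p_
            v = np.asarray(t, float) - b
            return a * v ** power / (c + v ** power)

        def dv(t, p_):
            a, b, c = p_
            v = np.asarray(t, float) - b
            return a * power * c * v ** (power - 1) / (c + v ** power) ** 2

        def inv(y, p_):
            a, b, c = p_
            y = np.asarray(y, float)
            return b + (c * y / (a - y)) ** (1.0 / power)

        def infl(p_):
            a, b, c = p_
            return b + (c * (power - 1.0) / (power + 1.0)) ** (1.0 / power)

        return _register(GrowthModel(
            name=name, family_class="sigmoidal", param_names=names,
            formula=f"y = a*(t-b)^{power}/(c+(t-b)^{power})",
            constraints="a > 0, c > 0; domain t >= b",
            reconstructed=reconstructed,
            _eval=ev, _deriv=dv, _inverse=inv, _inflection_t=infl,
            _asymptote=lambda p_: p_[0], _lower=lambda p_: 0.0,
            _tmin=lambda p_: p_[1],
            _check=lambda p_: p_[0] > 0 and p_[2] > 0,
            _sample=_mk_sample([_S_A, _u(0.0, 5.0),
                                lambda rng, prev: rng.uniform(2.0, 12.0) ** power]),
            fit_spec=(p_asym(), b_spec, p_tscale("c", power))))

    names = ["a", "b"]
    spec = [p_asym(), p_tscale("b")]
    samplers = [_S_A, _u(2.0, 15.0)]
    if shape_free:
        names.append("g")
        spec.append(p_shape("g", lo=1.0 + 1e-6, hi=20.0, init=2.0))
        samplers.append(_u(1.3, 4.0))
    if floor:
        names.append("d")
        spec.append(p_floor(positive=True))
        samplers.append(lambda rng, prev: rng.uniform(0.02, 0.25) * prev[0])
    names = tuple(names)

    def unpack(p_):
        a, b = p_[0], p_[1]
        i = 2
        if shape_free:
            g = p_[i]; i += 1
        else:
            g = float(power)
        d = p_[i] if floor else 0.0
        return a, b, g, d

    def ev(t, p_):
        a, b, g, d = unpack(p_)
        u = (np.asarray(t, float) / b) ** g
        return d + (a - d) * u / (1.0 + u)

    def dv(t, p_):
        a, b, g, d = unpack(p_)
        t = np.asarray(t, float)
        u = (t / b) ** g
        return (a - d) * g * t ** (g - 1.0) / b ** g / (1.0 + u) ** 2

    def inv(y, p_):
        a, b, g, d = unpack(p_)
        u = (np.asarray(y, float) - d) / (a - np.asarray(y, float))
        return b * u ** (1.0 / g)

    p = power

    def infl(p_):
        a, b, g, d = unpack(p_)
        return b * ((g - 1.0) / (g + 1.0)) ** (1.0 / g)

    # Michaelis-Menten (p == 1): no interior inflection; domain extends to t > -b.
    if power == 1 and not shape_free:
        def ev1(t, p_):
            a, b, g, d = unpack(p_)
            t = np.asarray(t, float)
            return d + (a - d) * t / (b + t)

        def dv1(t, p_):
            a, b, g, d = unpack(p_)
            t = np.asarray(t, float)
            return (a - d) * b / (b + t) ** 2

        def inv1(y, p_):
            a, b, g, d = unpack(p_)
            y = np.asarray(y, float)
            return b * (y - d) / (a - y)

        return _register(GrowthModel(
            name=name, family_class="attenuating", param_names=names,
            formula=("y = d + (a-d)*t/(b+t)" if floor else "y = a*t/(b+t)"),
            constraints="a > 0, b > 0" + (", 0 < d < a" if floor else ""),
            reconstructed=reconstructed,
            _eval=ev1, _deriv=dv1, _inverse=inv1, _inflection_t=None,
            _asymptote=lambda p_: p_[0], _lower=lambda p_: -_INF,
            _tmin=lambda p_: -p_[1],
            _check=lambda p_: p_[0] > 0 and p_[1] > 0 and (not floor or p_[-1] < p_[0]),
            _sample=_mk_sample(samplers), fit_spec=tuple(spec)))

    fclass = "sigmoidal"
    gtxt = "g" if shape_free else str(power)
    return _register(GrowthModel(
        name=name, family_class=fclass, param_names=names,
        formula=(f"y = d + (a-d)*(t/b)^{gtxt}/(1+(t/b)^{gtxt})" if floor
                 else f"y = a*(t/b)^{gtxt}/(1+(t/b)^{gtxt})"),
        constraints="a > 0, b > 0" + (", g > 1" if shape_free else "")
                    + (", 0 < d < a" if floor else "") + "; domain t >= 0",
        reconstructed=reconstructed,
        _eval=ev, _deriv=dv, _inverse=inv, _inflection_t=infl,
        _asymptote=lambda p_: p_[0], _lower=lambda p_: unpack(p_)[3],
        _tmin=lambda p_: 0.0,
        _check=lambda p_: (p_[0] > 0 and p_[1] > 0
                           and (not shape_free or p_[2] > 1.0)
                           and (not floor or 0 <= p_[-1] < p_[0])),
        _sample=_mk_sample(samplers), fit_spec=tuple(spec)))


def _vb_model(name, m, *, loc=False, floor=False, w_from_floor=False,
              shape_free=False, reconstructed=True):
    """Generalized von Bertalanffy / Chapman-Richards:
    y = d + (a-d)*(1 - w*exp(-c*(t-b)))^m, w = 1 by default."""
    names = ["a"]
    spec = [p_asym()]
    samplers = [_S_A]
    if loc:
        names.append("b")
        # the domain is 1 - w*exp(-c*(t-b)) >= 0, i.e. t >= b for w = 1
        spec.append(ParamSpec("b", _const(-1e4),
                              lambda t, y: float(np.min(t)) - 1e-9,
                              lambda t, y: float(np.min(t)) - 1.0))
        samplers.append(_u(-2.0, 8.0))
    names.append("c"); spec.append(p_rate()); samplers.append(_S_RATE)
    if shape_free:
        names.append("g"); spec.append(p_shape("g", lo=1.0 + 1e-6, hi=15.0, init=3.0))
        samplers.append(_u(1.3, 4.0))
    if floor:
        names.append("d"); spec.append(p_floor(positive=True))
        if w_from_floor:
            # z-variant: d = y(0); keep d < a/4 so the inflection stays interior
            samplers.append(lambda rng, prev: rng.uniform(0.02, 0.2) * prev[0])
        else:
            samplers.append(lambda rng, prev: rng.uniform(0.02, 0.25) * prev[0])

    def unpack(p_):
        i = 0
        a = p_[i]; i += 1
        b = p_[i] if loc else 0.0
        if loc:
            i += 1
        c = p_[i]; i += 1
        mm = p_[i] if shape_free else float(m)
        if shape_free:
            i += 1
        d = p_[i] if floor else 0.0
        if w_from_floor:
            w = 1.0 - (d / a) ** (1.0 / mm)
            d = 0.0
        else:
            w = 1.0
        return a, b, c, mm, d, w

    def core(t, p_):
        a, b, c, mm, d, w = unpack(p_)
        return 1.0 - w * np.exp(-c * (np.asarray(t, float) - b))

    def ev(t, p_):
        a, b, c, mm, d, w = unpack(p_)
        u = core(t, p_)
        if mm == 3.0:
            return d + (a - d) * u ** 3
        return d + (a - d) * np.where(u > 0, u, 0.0) ** mm

    def dv(t, p_):
        a, b, c, mm, d, w = unpack(p_)
        t = np.asarray(t, float)
        u = 1.0 - w * np.exp(-c * (t - b))
        base = np.where(u > 0, u, 0.0) if mm != 3.0 else u
        return (a - d) * mm * base ** (mm - 1.0) * w * c * np.exp(-c * (t - b))

    def inv(y, p_):
        a, b, c, mm, d, w = unpack(p_)
        frac = (np.asarray(y, float) - d) / (a - d)
        root = np.cbrt(frac) if mm == 3.0 else frac ** (1.0 / mm)
        return b - np.log((1.0 - root) / w) / c

    def infl(p_):
        a, b, c, mm, d, w = unpack(p_)
        return b + math.log(w * mm) / c

    def lower(p_):
        a, b, c, mm, d, w = unpack(p_)
        return d

    def tmin(p_):
        # admissible branch: u = 1 - w*exp(-c*(t-b)) >= 0 (rate is unbounded on
        # the negative branch of the cubed form, so it is excluded)
        a, b, c, mm, d, w = unpack(p_)
        return b + math.log(w) / c if w != 1.0 else b

    def chk(p_):
        a, b, c, mm, d, w = unpack(p_)
        return a > 0 and c > 0 and mm > 1 and 0 < w * mm and w * mm > 1 and d < a

    fclass = "sigmoidal"
    wtxt = "(1-(d/a)^(1/%g))" % m if w_from_floor else ""
    btxt = "(t-b)" if loc else "t"
    mtxt = "g" if shape_free else str(m)
    inner = f"1-{wtxt or '1'}*exp(-c*{btxt})".replace("1-1*", "1-")
    ftxt = (f"y = d + (a-d)*({inner})^{mtxt}" if (floor and not w_from_floor)
            else f"y = a*({inner})^{mtxt}")
    return _register(GrowthModel(
        name=name, family_class=fclass, param_names=tuple(names),
        formula=ftxt,
        constraints="a > 0, c > 0" + (", g > 1" if shape_free else "")
                    + (", 0 < d < a/4 (interior inflection)" if w_from_floor
                       else (", 0 < d < a" if floor else "")),
        reconstructed=reconstructed,
        _eval=ev, _deriv=dv, _inverse=inv, _inflection_t=infl,
        _asymptote=lambda p_: p_[0], _lower=lower, _tmin=tmin, _check=chk,
        _sample=_mk_sample(samplers), fit_spec=tuple(spec)))


def _weibull_model(name, *, g_fixed=None, g_lo=1.0, g_hi=30.0, loc=False,
                   floor=False, att=False, reconstructed=True):
    """y = d + (a-d)*(1 - exp(-(c*(t-b))^g)); attenuating when g <= 1."""
    names = ["a"]
    spec = [p_asym()]
    samplers = [_S_A]
    if loc:
        names.append("b")
        spec.append(ParamSpec("b", _const(-1e3),
                              lambda t, y: float(np.min(t)) - 1e-9,
                              lambda t, y: float(np.min(t)) - 0.5))
        samplers.append(_u(0.0, 5.0))
    names.append("c"); spec.append(p_rate()); samplers.append(_S_RATE)
    if g_fixed is None:
        names.append("g")
        spec.append(p_shape("g", lo=(0.05 if att else 1.0 + 1e-6),
                            hi=(1.0 if att else 20.0), init=(0.6 if att else 2.0)))
        samplers.append(_u(0.3, 0.95) if att else _u(1.3, 4.0))
    if floor:
        names.append("d"); spec.append(p_floor(positive=True))
        samplers.append(lambda rng, prev: rng.uniform(0.02, 0.25) * prev[0])

    def unpack(p_):
        i = 0
        a = p_[i]; i += 1
        b = p_[i] if loc else 0.0
        if loc:
            i += 1
        c = p_[i]; i += 1
        g = p_[i] if g_fixed is None else float(g_fixed)
        if g_fixed is None:
            i += 1
        d = p_[i] if floor else 0.0
        return a, b, c, g, d

    def ev(t, p_):
        a, b, c, g, d = unpack(p_)
        x = (c * (np.asarray(t, float) - b)) ** g
        return d - (a - d) * np.expm1(-x)

    def dv(t, p_):
        a, b, c, g, d = unpack(p_)
        v = c * (np.asarray(t, float) - b)
        return (a - d) * g * c * v ** (g - 1.0) * np.exp(-v ** g)

    def inv(y, p_):
        a, b, c, g, d = unpack(p_)
        x = -np.log1p(-(np.asarray(y, float) - d) / (a - d))
        return b + x ** (1.0 / g) / c

    def infl(p_):
        a, b, c, g, d = unpack(p_)
        return b + ((g - 1.0) / g) ** (1.0 / g) / c

    fclass = "attenuating" if att else "sigmoidal"
    gtxt = str(g_fixed) if g_fixed is not None else "g"
    btxt = "(t-b)" if loc else "t"
    return _register(GrowthModel(
        name=name, family_class=fclass, param_names=tuple(names),
        formula=(f"y = d + (a-d)*(1-exp(-(c*{btxt})^{gtxt}))" if floor
                 else f"y = a*(1-exp(-(c*{btxt})^{gtxt}))"),
        constraints="a > 0, c > 0, "
                    + ("0 < g <= 1" if att else f"g > 1" if g_fixed is None else "")
                    + (", 0 < d < a" if floor else "")
                    + f"; domain t >= {'b' if loc else '0'}",
        reconstructed=reconstructed,
        _eval=ev, _deriv=dv, _inverse=inv,
        _inflection_t=None if att else infl,
        _asymptote=lambda p_: p_[0],
        _lower=lambda p_: unpack(p_)[4],
        _tmin=lambda p_: unpack(p_)[1],
        _check=lambda p_: (lambda a, b, c, g, d: a > 0 and c > 0 and
                           (g <= 1.0 if att else g > 1.0 or g_fixed is not None)
                           and g > 0 and 0 <= d < a)(*unpack(p_)),
        _sample=_mk_sample(samplers), fit_spec=tuple(spec)))


def _simple(name, fclass, names, formula, constraints, ev, dv, inv, asym,
            lower, tmin, chk, samplers, spec, infl=None, reconstructed=True):
    return _register(GrowthModel(
        name=name, family_class=fclass, param_names=tuple(names),
        formula=formula, constraints=constraints, reconstructed=reconstructed,
        _eval=ev, _deriv=dv, _inverse=inv, _inflection_t=infl,
        _asymptote=asym, _lower=lower, _tmin=tmin, _check=chk,
        _sample=_mk_sample(samplers), fit_spec=tuple(spec)))


# ===========================================================================
# Increasing models (15)
# ===========================================================================

_simple("Linear 2", "increasing", ("b", "c"), "y = b + c*t", "c > 0",
        lambda t, p: p[0] + p[1] * np.asarray(t, float),
        lambda t, p: p[1] + 0.0 * np.asarray(t, float),
        lambda y, p: (np.asarray(y, float) - p[0]) / p[1],
        lambda p: _INF, lambda p: -_INF, lambda p: -_INF,
        lambda p: p[1] > 0,
        [_u(0.0, 20.0), _u(0.3, 8.0)], [p_icept(), p_slope()],
        reconstructed=False)

_simple("Quadratic 2", "increasing", ("b", "c"), "y = b*t + c*t^2",
        "b >= 0, c > 0; domain t >= 0",
        lambda t, p: p[0] * np.asarray(t, float) + p[1] * np.asarray(t, float) ** 2,
        lambda t, p: p[0] + 2.0 * p[1] * np.asarray(t, float),
        lambda y, p: (-p[0] + np.sqrt(p[0] ** 2 + 4.0 * p[1] * np.asarray(y, float)))
                     / (2.0 * p[1]),
        lambda p: _INF, lambda p: 0.0, lambda p: 0.0,
        lambda p: p[0] >= 0 and p[1] > 0,
        [_u(0.0, 5.0), _u(0.05, 1.0)],
        [p_slope("b"), ParamSpec("c", _const(1e-12), _const(1e6),
                                 lambda t, y: float(np.max(y)) / _span(t) ** 2)])

_simple("Quadratic 2b", "increasing", ("b", "c"), "y = b*(t+c)^2",
        "b > 0, c >= 0; domain t >= -c",
        lambda t, p: p[0] * (np.asarray(t, float) + p[1]) ** 2,
        lambda t, p: 2.0 * p[0] * (np.asarray(t, float) + p[1]),
        lambda y, p: np.sqrt(np.asarray(y, float) / p[0]) - p[1],
        lambda p: _INF, lambda p: 0.0, lambda p: -p[1],
        lambda p: p[0] > 0 and p[1] >= 0,
        [_u(0.05, 2.0), _u(0.0, 5.0)],
        [ParamSpec("b", _const(1e-12), _const(1e6),
                   lambda t, y: float(np.max(y)) / (float(np.max(t)) + 1.0) ** 2),
         ParamSpec("c", _const(0.0), _const(1e4), _const(1.0))])

_simple("Quadratic 3", "increasing", ("d", "b", "c"), "y = d + b*t + c*t^2",
        "b >= 0, c > 0; domain t >= 0",
        lambda t, p: p[0] + p[1] * np.asarray(t, float) + p[2] * np.asarray(t, float) ** 2,
        lambda t, p: p[1] + 2.0 * p[2] * np.asarray(t, float),
        lambda y, p: (-p[1] + np.sqrt(p[1] ** 2 + 4.0 * p[2] * (np.asarray(y, float) - p[0])))
                     / (2.0 * p[2]),
        lambda p: _INF, lambda p: p[0], lambda p: 0.0,
        lambda p: p[1] >= 0 and p[2] > 0,
        [_u(0.0, 10.0), _u(0.0, 5.0), _u(0.05, 1.0)],
        [p_icept("d"), p_slope("b"),
         ParamSpec("c", _const(1e-12), _const(1e6),
                   lambda t, y: float(np.max(y)) / _span(t) ** 2)])

_simple("Cubic 2", "increasing", ("b", "c"), "y = b + c*t^3", "c > 0",
        lambda t, p: p[0] + p[1] * np.asarray(t, float) ** 3,
        lambda t, p: 3.0 * p[1] * np.asarray(t, float) ** 2,
        lambda y, p: np.cbrt((np.asarray(y, float) - p[0]) / p[1]),
        lambda p: _INF, lambda p: -_INF, lambda p: -_INF,
        lambda p: p[1] > 0,
        [_u(0.0, 20.0), _u(0.005, 0.5)],
        [p_icept(), ParamSpec("c", _const(1e-12), _const(1e6),
                              lambda t, y: float(np.max(y)) / _span(t) ** 3)])

_simple("Cubic 2b", "increasing", ("b", "c"), "y = b*(t+c)^3",
        "b > 0",
        lambda t, p: p[0] * (np.asarray(t, float) + p[1]) ** 3,
        lambda t, p: 3.0 * p[0] * (np.asarray(t, float) + p[1]) ** 2,
        lambda y, p: np.cbrt(np.asarray(y, float) / p[0]) - p[1],
        lambda p: _INF, lambda p: -_INF, lambda p: -_INF,
        lambda p: p[0] > 0,
        [_u(0.005, 0.5), _u(0.0, 5.0)],
        [ParamSpec("b", _const(1e-12), _const(1e6),
                   lambda t, y: float(np.max(y)) / (float(np.max(t)) + 1.0) ** 3),
         ParamSpec("c", _const(-1e3), _const(1e4), _const(1.0))])

_simple("Cubic 3", "increasing", ("d", "b", "c"), "y = d + b*(t+c)^3",
        "b > 0",
        lambda t, p: p[0] + p[1] * (np.asarray(t, float) + p[2]) ** 3,
        lambda t, p: 3.0 * p[1] * (np.asarray(t, float) + p[2]) ** 2,
        lambda y, p: np.cbrt((np.asarray(y, float) - p[0]) / p[1]) - p[2],
        lambda p: _INF, lambda p: -_INF, lambda p: -_INF,
        lambda p: p[1] > 0,
        [_u(0.0, 10.0), _u(0.005, 0.5), _u(0.0, 5.0)],
        [p_icept("d"),
         ParamSpec("b", _const(1e-12), _const(1e6),
                   lambda t, y: float(np.max(y)) / (float(np.max(t)) + 1.0) ** 3),
         ParamSpec("c", _const(-1e3), _const(1e4), _const(1.0))])

_simple("Power 2", "increasing", ("b", "c"), "y = b*t^c",
        "b > 0, c > 0; domain t >= 0",
        lambda t, p: p[0] * np.asarray(t, float) ** p[1],
        lambda t, p: p[0] * p[1] * np.asarray(t, float) ** (p[1] - 1.0),
        lambda y, p: (np.asarray(y, float) / p[0]) ** (1.0 / p[1]),
        lambda p: _INF, lambda p: 0.0, lambda p: 0.0,
        lambda p: p[0] > 0 and p[1] > 0,
        [_u(0.3, 8.0), _u(0.5, 2.5)],
        [p_coef("b"), ParamSpec("c", _const(1e-6), _const(20.0), _const(1.0))])

_simple("Power 3", "increasing", ("d", "b", "c"), "y = d + b*t^c",
        "b > 0, c > 0; domain t >= 0",
        lambda t, p: p[0] + p[1] * np.asarray(t, float) ** p[2],
        lambda t, p: p[1] * p[2] * np.asarray(t, float) ** (p[2] - 1.0),
        lambda y, p: ((np.asarray(y, float) - p[0]) / p[1]) ** (1.0 / p[2]),
        lambda p: _INF, lambda p: p[0], lambda p: 0.0,
        lambda p: p[1] > 0 and p[2] > 0,
        [_u(0.0, 10.0), _u(0.3, 8.0), _u(0.5, 2.5)],
        [p_icept("d"), p_coef("b"),
         ParamSpec("c", _const(1e-6), _const(20.0), _const(1.0))])

_simple("Exponential 2", "increasing", ("b", "c"), "y = b*exp(c*t)",
        "b > 0, c > 0",
        lambda t, p: p[0] * np.exp(p[1] * np.asarray(t, float)),
        lambda t, p: p[0] * p[1] * np.exp(p[1] * np.asarray(t, float)),
        lambda y, p: np.log(np.asarray(y, float) / p[0]) / p[1],
        lambda p: _INF, lambda p: 0.0, lambda p: -_INF,
        lambda p: p[0] > 0 and p[1] > 0,
        [_u(0.5, 15.0), _u(0.03, 0.3)],
        [p_coef("b"), p_rate("c", mult=1.5)])

_simple("Exponential 3", "increasing", ("d", "b", "c"), "y = d + b*exp(c*t)",
        "b > 0, c > 0",
        lambda t, p: p[0] + p[1] * np.exp(p[2] * np.asarray(t, float)),
        lambda t, p: p[1] * p[2] * np.exp(p[2] * np.asarray(t, float)),
        lambda y, p: np.log((np.asarray(y, float) - p[0]) / p[1]) / p[2],
        lambda p: _INF, lambda p: p[0], lambda p: -_INF,
        lambda p: p[1] > 0 and p[2] > 0,
        [_u(0.0, 10.0), _u(0.5, 15.0), _u(0.03, 0.3)],
        [p_icept("d"), p_coef("b"), p_rate("c", mult=1.5)])


def _pers3a_inv(y, p):
    d, b, c = p
    x = c * (np.asarray(y, float) - d) / b
    return np.real(special.lambertw(x)) / c


_simple("Persistence 3a", "increasing", ("d", "b", "c"), "y = d + b*t*exp(c*t)",
        "b > 0, c > 0; domain t >= 0",
        lambda t, p: p[0] + p[1] * np.asarray(t, float) * np.exp(p[2] * np.asarray(t, float)),
        lambda t, p: p[1] * np.exp(p[2] * np.asarray(t, float))
                     * (1.0 + p[2] * np.asarray(t, float)),
        _pers3a_inv,
        lambda p: _INF, lambda p: p[0], lambda p: 0.0,
        lambda p: p[1] > 0 and p[2] > 0,
        [_u(0.0, 10.0), _u(0.3, 5.0), _u(0.02, 0.2)],
        [p_icept("d"), p_coef("b"), p_rate("c", mult=1.0)])

_simple("Persistence 3b", "increasing", ("b", "g", "c"), "y = b*t^g*exp(c*t)",
        "b > 0, g > 0, c > 0; domain t >= 0",
        lambda t, p: p[0] * np.asarray(t, float) ** p[1]
                     * np.exp(p[2] * np.asarray(t, float)),
        lambda t, p: p[0] * np.asarray(t, float) ** (p[1] - 1.0)
                     * np.exp(p[2] * np.asarray(t, float))
                     * (p[1] + p[2] * np.asarray(t, float)),
        None,  # no closed-form inverse; bisection fallback
        lambda p: _INF, lambda p: 0.0, lambda p: 0.0,
        lambda p: p[0] > 0 and p[1] > 0 and p[2] > 0,
        [_u(0.3, 5.0), _u(0.5, 2.0), _u(0.02, 0.2)],
        [p_coef("b"), ParamSpec("g", _const(1e-6), _const(10.0), _const(1.0)),
         p_rate("c", mult=1.0)])

_simple("Logarithmic 2", "increasing", ("b", "c"), "y = b*log(1+c*t)",
        "b > 0, c > 0; domain t > -1/c",
        lambda t, p: p[0] * np.log1p(p[1] * np.asarray(t, float)),
        lambda t, p: p[0] * p[1] / (1.0 + p[1] * np.asarray(t, float)),
        lambda y, p: np.expm1(np.asarray(y, float) / p[0]) / p[1],
        lambda p: _INF, lambda p: -_INF, lambda p: -1.0 / p[1],
        lambda p: p[0] > 0 and p[1] > 0,
        [_u(2.0, 40.0), _u(0.1, 2.0)],
        [ParamSpec("b", _const(1e-12), _const(1e9),
                   lambda t, y: float(np.max(y)) / max(math.log1p(float(np.max(t))), 0.5)),
         p_rate("c", mult=2.0)])

_simple("Hyperbolic Sine 2", "increasing", ("b", "c"), "y = b*sinh(c*t)",
        "b > 0, c > 0",
        lambda t, p: p[0] * np.sinh(p[1] * np.asarray(t, float)),
        lambda t, p: p[0] * p[1] * np.cosh(p[1] * np.asarray(t, float)),
        lambda y, p: np.arcsinh(np.asarray(y, float) / p[0]) / p[1],
        lambda p: _INF, lambda p: -_INF, lambda p: -_INF,
        lambda p: p[0] > 0 and p[1] > 0,
        [_u(0.5, 15.0), _u(0.03, 0.3)],
        [p_coef("b"), p_rate("c", mult=1.5)])


# ===========================================================================
# Attenuating models (14)
# ===========================================================================

_cdf_model("Monomolecular 2", K_EXPSAT, loc=False, floor=False,
           family_class="attenuating", reconstructed=False,
           formula="y = a*(1-exp(-c*t))")
_cdf_model("Monomolecular 3", K_EXPSAT, loc=False, floor=True,
           family_class="attenuating",
           formula="y = a - (a-d)*exp(-c*t)")

_ratio_model("Michaelis Menten 2", 1)
_ratio_model("Michaelis Menten 3", 1, floor=True)

_simple("Rational 2z", "attenuating", ("a", "b"), "y = a*t/(1+b*t)",
        "a > 0, b > 0; asymptote a/b; domain t > -1/b",
        lambda t, p: p[0] * np.asarray(t, float) / (1.0 + p[1] * np.asarray(t, float)),
        lambda t, p: p[0] / (1.0 + p[1] * np.asarray(t, float)) ** 2,
        lambda y, p: np.asarray(y, float) / (p[0] - p[1] * np.asarray(y, float)),
        lambda p: p[0] / p[1], lambda p: -_INF, lambda p: -1.0 / p[1],
        lambda p: p[0] > 0 and p[1] > 0,
        [_u(2.0, 40.0), _u(0.05, 0.5)],
        [ParamSpec("a", _const(1e-12), _const(1e9),
                   lambda t, y: float(np.max(y)) / max(float(np.median(t)), 0.5)),
         ParamSpec("b", lambda t, y: 1.0 / (float(np.max(y)) * (1 + 1e-9) * 1e6),
                   _const(1e9), lambda t, y: 0.5 / float(np.max(y)))])

_cdf_model("Extreme Value 2", K_GUMBEL_MIN, loc=False, floor=False,
           family_class="attenuating",
           formula="y = a*(1-exp(-exp(c*t)))")

_half_cdf_model("Hyperbolic Tangent 2", K_TANH, "tanh(c*t)")
_half_cdf_model("Arctangent 2", K_ATAN, "(2/pi)*arctan(c*t)")
_half_cdf_model("Algebraic 2", K_ALGEBRAIC, "c*t/sqrt(1+(c*t)^2)")
_half_cdf_model("Error Function 2", K_ERF, "erf(c*t)")

_simple("Power Decay 3", "attenuating", ("a", "c", "g"),
        "y = a*(1-(1+c*t)^-g)", "a > 0, c > 0, g > 0; domain t > -1/c",
        lambda t, p: p[0] * -np.expm1(-p[2] * np.log1p(p[1] * np.asarray(t, float))),
        lambda t, p: p[0] * p[1] * p[2]
                     * (1.0 + p[1] * np.asarray(t, float)) ** (-p[2] - 1.0),
        lambda y, p: np.expm1(-np.log1p(-np.asarray(y, float) / p[0]) / p[2]) / p[1],
        lambda p: p[0], lambda p: -_INF, lambda p: -1.0 / p[1],
        lambda p: p[0] > 0 and p[1] > 0 and p[2] > 0,
        [_S_A, _u(0.05, 0.5), _u(0.5, 3.0)],
        [p_asym(), p_rate("c", mult=2.0),
         ParamSpec("g", _const(1e-6), _const(50.0), _const(1.0))])

_weibull_model("Weibull 3a", att=True)

_cdf_model("Confined Exponential 3", K_GUMBEL_MAX, loc=True, floor=False,
           family_class="attenuating",
           loc_sampler=_u(-10.0, 0.0),
           loc_spec=ParamSpec("b", _const(-1e4), _const(0.0), _const(-1.0)),
           extra_check=lambda p: p[1] <= 0,
           formula="y = a*exp(-exp(-c*(t-b))), b <= 0",
           constraints="a > 0, c > 0, b <= 0 (inflection pinned left of t=0)")

_simple("Reciprocal 2", "attenuating", ("a", "b"), "y = a - b/t",
        "a > 0, b > 0; domain t > 0",
        lambda t, p: p[0] - p[1] / np.asarray(t, float),
        lambda t, p: p[1] / np.asarray(t, float) ** 2,
        lambda y, p: p[1] / (p[0] - np.asarray(y, float)),
        lambda p: p[0], lambda p: -_INF, lambda p: 0.0,
        lambda p: p[0] > 0 and p[1] > 0,
        [_S_A, _u(5.0, 100.0)],
        [p_asym(), ParamSpec("b", _const(1e-9), _const(1e9),
                             lambda t, y: float(np.max(y)))])


# ===========================================================================
# Sigmoidal models (48)
# ===========================================================================

# --- logistic family -------------------------------------------------------
_cdf_model("Logistic 3", K_LOGISTIC, loc=True, reconstructed=False,
           formula="y = a/(1+exp(-c*(t-b)))")
_cdf_model("Logistic 4", K_LOGISTIC, loc=True, floor=True,
           formula="y = d + (a-d)/(1+exp(-c*(t-b)))")

_simple("Logistic 3b", "sigmoidal", ("a", "b", "c"), "y = a/(1+b*exp(-c*t))",
        "a > 0, b > 1, c > 0",
        lambda t, p: p[0] / (1.0 + p[1] * np.exp(-p[2] * np.asarray(t, float))),
        lambda t, p: (lambda s: p[2] * s * (p[0] - s) / p[0])(
            p[0] / (1.0 + p[1] * np.exp(-p[2] * np.asarray(t, float)))),
        lambda y, p: -np.log((p[0] / np.asarray(y, float) - 1.0) / p[1]) / p[2],
        lambda p: p[0], lambda p: 0.0, lambda p: -_INF,
        lambda p: p[0] > 0 and p[1] > 1 and p[2] > 0,
        [_S_A, _u(3.0, 40.0), _S_RATE],
        [p_asym(), ParamSpec("b", _const(1.0 + 1e-9), _const(1e12), _const(10.0)),
         p_rate()],
        infl=lambda p: math.log(p[1]) / p[2])

_simple("Logistic 3z", "sigmoidal", ("a", "c", "d"),
        "y = a/(1+(a/d-1)*exp(-c*t))",
        "a > 0, c > 0, 0 < d < a/2 (d = y(0); interior inflection)",
        lambda t, p: p[0] / (1.0 + (p[0] / p[2] - 1.0)
                             * np.exp(-p[1] * np.asarray(t, float))),
        lambda t, p: (lambda s: p[1] * s * (p[0] - s) / p[0])(
            p[0] / (1.0 + (p[0] / p[2] - 1.0) * np.exp(-p[1] * np.asarray(t, float)))),
        lambda y, p: -np.log((p[0] / np.asarray(y, float) - 1.0)
                             / (p[0] / p[2] - 1.0)) / p[1],
        lambda p: p[0], lambda p: 0.0, lambda p: -_INF,
        lambda p: p[0] > 0 and p[1] > 0 and 0 < p[2] < p[0] / 2,
        [_S_A, _S_RATE, lambda rng, prev: rng.uniform(0.03, 0.3) * prev[0]],
        [p_asym(), p_rate(), p_floor("d", positive=True)],
        infl=lambda p: math.log(p[0] / p[2] - 1.0) / p[1])

_simple("Generalized Logistic 3", "sigmoidal", ("a", "c", "g"),
        "y = a/(1+exp(-c*t))^g", "a > 0, c > 0, g > 1",
        lambda t, p: p[0] * _expit(p[1] * np.asarray(t, float)) ** p[2],
        lambda t, p: (lambda s: p[0] * p[2] * p[1] * s ** p[2] * (1.0 - s))(
            _expit(p[1] * np.asarray(t, float))),
        lambda y, p: K_LOGISTIC.finv((np.asarray(y, float) / p[0]) ** (1.0 / p[2]))
                     / p[1],
        lambda p: p[0], lambda p: 0.0, lambda p: -_INF,
        lambda p: p[0] > 0 and p[1] > 0 and p[2] > 1,
        [_S_A, _S_RATE, _u(1.3, 4.0)],
        [p_asym(), p_rate(), p_shape("g")],
        infl=lambda p: math.log(p[2]) / p[1])

_simple("Generalized Logistic 4", "sigmoidal", ("a", "b", "c", "g"),
        "y = a/(1+exp(-c*(t-b)))^g", "a > 0, c > 0, g > 0",
        lambda t, p: p[0] * _expit(p[2] * (np.asarray(t, float) - p[1])) ** p[3],
        lambda t, p: (lambda s: p[0] * p[3] * p[2] * s ** p[3] * (1.0 - s))(
            _expit(p[2] * (np.asarray(t, float) - p[1]))),
        lambda y, p: p[1] + K_LOGISTIC.finv((np.asarray(y, float) / p[0])
                                            ** (1.0 / p[3])) / p[2],
        lambda p: p[0], lambda p: 0.0, lambda p: -_INF,
        lambda p: p[0] > 0 and p[2] > 0 and p[3] > 0,
        [_S_A, _S_LOC, _S_RATE, _u(0.5, 4.0)],
        [p_asym(), p_loc(), p_rate(), p_shape("g", lo=1e-3, hi=30.0, init=1.0)],
        infl=lambda p: p[1] + math.log(p[3]) / p[2])

# --- Gompertz family -------------------------------------------------------
_cdf_model("Gompertz 3", K_GUMBEL_MAX, loc=True, reconstructed=False,
           formula="y = a*exp(-exp(-c*(t-b)))")
_cdf_model("Gompertz 4", K_GUMBEL_MAX, loc=True, floor=True,
           formula="y = d + (a-d)*exp(-exp(-c*(t-b)))")

_simple("Gompertz 3b", "sigmoidal", ("a", "b", "c"), "y = a*exp(-b*exp(-c*t))",
        "a > 0, b > 1, c > 0",
        lambda t, p: p[0] * np.exp(-p[1] * np.exp(-p[2] * np.asarray(t, float))),
        lambda t, p: (lambda y_: y_ * p[2] * -np.log(y_ / p[0]))(
            p[0] * np.exp(-p[1] * np.exp(-p[2] * np.asarray(t, float)))),
        lambda y, p: -np.log(-np.log(np.asarray(y, float) / p[0]) / p[1]) / p[2],
        lambda p: p[0], lambda p: 0.0, lambda p: -_INF,
        lambda p: p[0] > 0 and p[1] > 1 and p[2] > 0,
        [_S_A, _u(3.0, 40.0), _S_RATE],
        [p_asym(), ParamSpec("b", _const(1.0 + 1e-9), _const(1e12), _const(5.0)),
         p_rate()],
        infl=lambda p: math.log(p[1]) / p[2])

_simple("Gompertz 3z", "sigmoidal", ("a", "c", "d"),
        "y = a*exp(log(d/a)*exp(-c*t))",
        "a > 0, c > 0, 0 < d < a/e (d = y(0); interior inflection)",
        lambda t, p: p[0] * np.exp(np.log(p[2] / p[0])
                                   * np.exp(-p[1] * np.asarray(t, float))),
        lambda t, p: (lambda y_: y_ * p[1] * -np.log(y_ / p[0]))(
            p[0] * np.exp(np.log(p[2] / p[0]) * np.exp(-p[1] * np.asarray(t, float)))),
        lambda y, p: -np.log(np.log(np.asarray(y, float) / p[0])
                             / np.log(p[2] / p[0])) / p[1],
        lambda p: p[0], lambda p: 0.0, lambda p: -_INF,
        lambda p: p[0] > 0 and p[1] > 0 and 0 < p[2] < p[0] / math.e,
        [_S_A, _S_RATE, lambda rng, prev: rng.uniform(0.02, 0.3) * prev[0]],
        [p_asym(), p_rate(), p_floor("d", positive=True)],
        infl=lambda p: math.log(math.log(p[0] / p[2])) / p[1])

# --- von Bertalanffy / Chapman-Richards family -----------------------------
_vb_model("von Bertalanffy 2", 3)
_vb_model("von Bertalanffy 2b", 2)
_vb_model("von Bertalanffy 3", 3, loc=True, reconstructed=False)
_vb_model("von Bertalanffy 3z", 3, floor=True, w_from_floor=True)
_vb_model("von Bertalanffy 4", 3, loc=True, floor=True)
_vb_model("Chapman Richards 3", None, shape_free=True)
_vb_model("Chapman Richards 4", None, loc=True, shape_free=True)

# --- Richards --------------------------------------------------------------
_simple("Richards 4", "sigmoidal", ("a", "b", "c", "g"),
        "y = a*(1+g*exp(-c*(t-b)))^(-1/g)", "a > 0, c > 0, g > 0",
        lambda t, p: p[0] * (1.0 + p[3] * np.exp(-p[2] * (np.asarray(t, float) - p[1])))
                     ** (-1.0 / p[3]),
        lambda t, p: (lambda z: p[0] * z * (1.0 + p[3] * z) ** (-1.0 / p[3] - 1.0)
                      * p[2])(np.exp(-p[2] * (np.asarray(t, float) - p[1]))),
        lambda y, p: p[1] - np.log(((np.asarray(y, float) / p[0]) ** -p[3] - 1.0)
                                   / p[3]) / p[2],
        lambda p: p[0], lambda p: 0.0, lambda p: -_INF,
        lambda p: p[0] > 0 and p[2] > 0 and p[3] > 0,
        [_S_A, _S_LOC, _S_RATE, _u(0.3, 4.0)],
        [p_asym(), p_loc(), p_rate(), p_shape("g", lo=1e-3, hi=30.0, init=1.0)],
        infl=lambda p: p[1])

# --- extreme value family --------------------------------------------------
_cdf_model("Extreme Value 3a", K_GUMBEL_MIN, loc=True,
           formula="y = a*(1-exp(-exp(c*(t-b))))")
_cdf_model("Extreme Value 3b", K_GUMBEL_MAX, loc=True,
           formula="y = a*exp(-exp(-c*(t-b)))")
_cdf_model("Extreme Value 4", K_GUMBEL_MIN, loc=True, floor=True,
           formula="y = d + (a-d)*(1-exp(-exp(c*(t-b))))")

# --- Morgan-Mercer-Flodin / log-logistic -----------------------------------
_ratio_model("Morgan Mercer Flodin 3", None, shape_free=True)
_ratio_model("Morgan Mercer Flodin 4a", None, shape_free=True, floor=True)


def _mmf4b():
    # y = a - (a-d)/(1+(t/b)^g): algebraically the MMF 4a curve in the
    # subtractive parameterisation (catalog keeps both, as Table 4 does for
    # Michaelis-Menten 2 / Rational 2z).
    def ev(t, p):
        a, b, g, d = p
        return a - (a - d) / (1.0 + (np.asarray(t, float) / b) ** g)

    def dv(t, p):
        a, b, g, d = p
        t = np.asarray(t, float)
        u = (t / b) ** g
        return (a - d) * g * t ** (g - 1.0) / b ** g / (1.0 + u) ** 2

    def inv(y, p):
        a, b, g, d = p
        u = (np.asarray(y, float) - d) / (a - np.asarray(y, float))
        return b * u ** (1.0 / g)

    return _simple(
        "Morgan Mercer Flodin 4b", "sigmoidal", ("a", "b", "g", "d"),
        "y = a - (a-d)/(1+(t/b)^g)",
        "a > 0, b > 0, g > 1, 0 < d < a; domain t >= 0",
        ev, dv, inv,
        lambda p: p[0], lambda p: p[3], lambda p: 0.0,
        lambda p: p[0] > 0 and p[1] > 0 and p[2] > 1 and 0 <= p[3] < p[0],
        [_S_A, _u(2.0, 15.0), _u(1.3, 4.0),
         lambda rng, prev: rng.uniform(0.02, 0.25) * prev[0]],
        [p_asym(), p_tscale("b"), p_shape("g"), p_floor("d", positive=True)],
        infl=lambda p: p[1] * ((p[2] - 1.0) / (p[2] + 1.0)) ** (1.0 / p[2]))


_mmf4b()

# --- Weibull / Janoschek ---------------------------------------------------
_weibull_model("Weibull 2", g_fixed=2)
_weibull_model("Weibull 3b")
_weibull_model("Weibull 4", loc=True)
_weibull_model("Janoschek 4", floor=True)

# --- symmetric-kernel sigmoids --------------------------------------------
_cdf_model("Error Function 3", K_ERF, loc=True,
           formula="y = a*(1+erf(c*(t-b)))/2")
_cdf_model("Error Function 4", K_ERF, loc=True, floor=True)
_cdf_model("Arctangent 3", K_ATAN, loc=True,
           formula="y = a*(1/2+arctan(c*(t-b))/pi)")
_cdf_model("Arctangent 4", K_ATAN, loc=True, floor=True)
_cdf_model("Algebraic 3", K_ALGEBRAIC, loc=True,
           formula="y = a*(1+u/sqrt(1+u^2))/2, u = c*(t-b)")
_cdf_model("Algebraic 4", K_ALGEBRAIC, loc=True, floor=True)
_cdf_model("Hyperbolic Tangent 3", K_TANH, loc=True,
           formula="y = a*(1+tanh(c*(t-b)))/2")
_cdf_model("Hyperbolic Tangent 4", K_TANH, loc=True, floor=True)
_cdf_model("Gudermannian 3", K_GUDERMANN, loc=True,
           formula="y = a*(1/2+arctan(sinh(c*(t-b)))/pi)")

# --- rational sigmoids -----------------------------------------------------
_ratio_model("Rational 2", 2)
_ratio_model("Rational 3", 2, floor=True)
_ratio_model("Rational 3b", 2, shift=True)
_ratio_model("Cubic Rational 2", 3)
_ratio_model("Cubic Rational 3", 3, floor=True)
_ratio_model("Cubic Rational 3b", 3, shift=True)

# --- Frechet family --------------------------------------------------------

def _frechet(name, *, g_free=False, floor=False):
    names = ["a", "b"]
    spec = [p_asym(), p_tscale("b")]
    samplers = [_S_A, _u(2.0, 15.0)]
    if g_free:
        names.append("g"); spec.append(p_shape("g", lo=0.05, hi=20.0, init=1.5))
        samplers.append(_u(0.7, 3.0))
    if floor:
        names.append("d"); spec.append(p_floor(positive=True))
        samplers.append(lambda rng, prev: rng.uniform(0.02, 0.25) * prev[0])

    def unpack(p_):
        a, b = p_[0], p_[1]
        g = p_[2] if g_free else 1.0
        d = p_[-1] if floor else 0.0
        return a, b, g, d

    def ev(t, p_):
        a, b, g, d = unpack(p_)
        return d + (a - d) * np.exp(-(b / np.asarray(t, float)) ** g)

    def dv(t, p_):
        a, b, g, d = unpack(p_)
        t = np.asarray(t, float)
        x = (b / t) ** g
        return (a - d) * np.exp(-x) * g * x / t

    def inv(y, p_):
        a, b, g, d = unpack(p_)
        return b * (-np.log((np.asarray(y, float) - d) / (a - d))) ** (-1.0 / g)

    def infl(p_):
        a, b, g, d = unpack(p_)
        return b * (g / (g + 1.0)) ** (1.0 / g)

    gtxt = "g" if g_free else "1"
    return _simple(
        name, "sigmoidal", names,
        (f"y = d + (a-d)*exp(-(b/t)^{gtxt})" if floor else f"y = a*exp(-(b/t)^{gtxt})"),
        "a > 0, b > 0" + (", g > 0" if g_free else "")
        + (", 0 < d < a" if floor else "") + "; domain t > 0",
        ev, dv, inv,
        lambda p_: p_[0], lambda p_: unpack(p_)[3], lambda p_: 0.0,
        lambda p_: p_[0] > 0 and p_[1] > 0 and (not g_free or p_[2] > 0)
                   and (not floor or 0 <= p_[-1] < p_[0]),
        samplers, spec, infl=infl)


_frechet("Frechet 2")
_frechet("Frechet 3", g_free=True)
_frechet("Frechet 4", g_free=True, floor=True)

# --- log-normal ------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)


def _lognorm(name, *, floor=False):
    names = ["a", "b", "g"] + (["d"] if floor else [])
    spec = [p_asym(), p_tscale("b"), p_shape("g", lo=1e-3, hi=30.0, init=1.5)]
    samplers = [_S_A, _u(2.0, 15.0), _u(0.7, 3.0)]
    if floor:
        spec.append(p_floor(positive=True))
        samplers.append(lambda rng, prev: rng.uniform(0.02, 0.25) * prev[0])

    def unpack(p_):
        a, b, g = p_[0], p_[1], p_[2]
        d = p_[3] if floor else 0.0
        return a, b, g, d

    def ev(t, p_):
        a, b, g, d = unpack(p_)
        z = g * np.log(np.asarray(t, float) / b)
        return d + (a - d) * 0.5 * (1.0 + special.erf(z / _SQRT2))

    def dv(t, p_):
        a, b, g, d = unpack(p_)
        t = np.asarray(t, float)
        z = g * np.log(t / b)
        return (a - d) * np.exp(-z * z / 2.0) / math.sqrt(2.0 * math.pi) * g / t

    def inv(y, p_):
        a, b, g, d = unpack(p_)
        z = _SQRT2 * special.erfinv(2.0 * (np.asarray(y, float) - d) / (a - d) - 1.0)
        return b * np.exp(z / g)

    def infl(p_):
        a, b, g, d = unpack(p_)
        return b * math.exp(-1.0 / (g * g))

    return _simple(
        name, "sigmoidal", names,
        ("y = d + (a-d)*Phi(g*log(t/b))" if floor else "y = a*Phi(g*log(t/b))"),
        "a > 0, b > 0, g > 0" + (", 0 < d < a" if floor else "") + "; domain t > 0",
        ev, dv, inv,
        lambda p_: p_[0], lambda p_: unpack(p_)[3], lambda p_: 0.0,
        lambda p_: p_[0] > 0 and p_[1] > 0 and p_[2] > 0
                   and (not floor or 0 <= p_[-1] < p_[0]),
        samplers, spec, infl=infl)


_lognorm("Log Normal 3")
_lognorm("Log Normal 4", floor=True)


# ===========================================================================
# Public catalog API
# ===========================================================================

CATALOG: dict = dict(_REGISTRY)

_EXPECTED = {"increasing": 15, "sigmoidal": 48, "attenuating": 14}


def census() -> dict:
    """Class counts of the catalog, e.g. ``{'increasing': 15, ...}``."""
    out = {"increasing": 0, "sigmoidal": 0, "attenuating": 0}
    for m in CATALOG.values():
        out[m.family_class] += 1
    return out


def model_names(family_class: Optional[str] = None) -> list:
    return sorted(n for n, m in CATALOG.items()
                  if family_class is None or m.family_class == family_class)


def get_model(name: str) -> GrowthModel:
    try:
        return CATALOG[name]
    except KeyError:
        raise KeyError(f"unknown growth model {name!r}; see model_names()") from None


def sample_params(model, rng) -> tuple:
    """Draw an admissible parameter tuple for property testing."""
    if isinstance(model, str):
        model = get_model(model)
    p = model._sample(rng)
    assert model.check(p), f"{model.name}: sampler produced inadmissible {p}"
    return p


def _validated(model, params):
    if isinstance(model, str):
        model = get_model(model)
    p = model.params_tuple(params)
    if not model.check(p):
        raise ParameterError(f"{model.name}: parameters {p} violate constraints "
                             f"({model.constraints})")
    return model, p


def evaluate(model, params, age):
    """Size y(t) at age t (years).  Raises on inadmissible parameters/domain."""
    model, p = _validated(model, params)
    t = np.asarray(age, float)
    tmin = model._tmin(p)
    if np.any(t < tmin):
        raise DomainError(f"{model.name}: age below domain edge t >= {tmin:g}")
    y = model._eval(t, p)
    return float(y) if np.isscalar(age) or np.ndim(age) == 0 else y


def growth_rate(model, params, age):
    """dy/dt at age t; nonnegative over the admissible domain."""
    model, p = _validated(model, params)
    t = np.asarray(age, float)
    tmin = model._tmin(p)
    if np.any(t < tmin):
        raise DomainError(f"{model.name}: age below domain edge t >= {tmin:g}")
    r = model._deriv(t, p)
    return float(r) if np.isscalar(age) or np.ndim(age) == 0 else r


def asymptote(model, params):
    """Finite asymptote for sigmoidal/attenuating models, +inf for increasing."""
    model, p = _validated(model, params)
    return float(model._asymptote(p))


def lower_limit(model, params):
    """Infimum of y over the model's mathematical domain (may be -inf)."""
    model, p = _validated(model, params)
    return float(model._lower(p))


def age_floor(model, params):
    """Left edge of the admissible age domain, floored at 0 for age data."""
    model, p = _validated(model, params)
    return max(0.0, float(model._tmin(p)))


def _bisect_inverse(model, p, y):
    """Monotone bisection fallback for models without a closed-form inverse."""
    tmin = model._tmin(p)
    lo = tmin + 1e-9 if math.isfinite(tmin) else -1e3
    y = np.atleast_1d(np.asarray(y, float))
    out = np.empty_like(y)
    for i, yi in enumerate(y):
        hi = max(lo + 1.0, 1.0)
        for _ in range(200):
            if model._eval(hi, p) >= yi:
                break
            hi = lo + 2.0 * (hi - lo)
        out[i] = optimize.brentq(lambda t: float(model._eval(t, p)) - yi, lo, hi,
                                 xtol=1e-12, rtol=1e-14)
    return out


def inverse_age(model, params, size):
    """Age t(y) such that evaluate(t) == y; RangeError outside attainable sizes."""
    model, p = _validated(model, params)
    y = np.asarray(size, float)
    hi = model._asymptote(p)
    lo = model._lower(p)
    if np.any(y >= hi) or np.any(y <= lo):
        raise RangeError(f"{model.name}: size outside attainable range ({lo:g}, {hi:g})")
    if model._inverse is None:
        t = _bisect_inverse(model, p, y)
    else:
        t = model._inverse(y, p)
    return float(t) if np.isscalar(size) or np.ndim(size) == 0 else t


def inflection(model, params):
    """(t_i, y_i, r_max) for sigmoidal models; NOT_MEANINGFUL otherwise."""
    model, p = _validated(model, params)
    if model.family_class != "sigmoidal" or model._inflection_t is None:
        return NOT_MEANINGFUL
    t_i = float(model._inflection_t(p))
    y_i = float(model._eval(t_i, p))
    r_max = float(model._deriv(t_i, p))
    return (t_i, y_i, r_max)


def manifest_frame():
    """The catalog manifest as a pandas DataFrame (name, class, k, ...)."""
    import pandas as pd

    rows = [{"name": m.name, "family_class": m.family_class, "k": m.k,
             "param_names": ",".join(m.param_names),
             "constraints": m.constraints,
             "reconstructed": m.reconstructed,
             "formula": m.formula}
            for m in sorted(CATALOG.values(), key=lambda m: (m.family_class, m.name))]
    return pd.DataFrame(rows)


def _selfcheck():  # pragma: no cover - exercised via tests
    c = census()
    if c != _EXPECTED:
        raise RuntimeError(f"catalog census {c} != expected {_EXPECTED}")


_selfcheck()
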