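"""Nonlinear least-squares fitting, AICc model selection and confidence bands.

Two regression orientations are supported:

* ``reverse`` (the preferred orientation): bone dimension is the independent
  variable and estimated age the dependent one, because dimensions are
  measured to the millimetre while LAG-count ages carry the bulk of the error.
  The fit minimises :math:`\\sum_i (t_i - t(y_i; \\theta))^2` using the
  catalog's closed-form inverse functions.
* ``direct``: the conventional age-independent orientation, minimising
  :math:`\\sum_i (y_i - y(t_i; \\theta))^2`.  Used for replicating earlier
  analyses and in the Monte Carlo orientation experiments.

Model comparison uses the small-sample corrected Akaike information criterion

.. math:: AIC_c = n \\ln(RSS/n) + 2k + \\frac{2k(k+1)}{n-k-1},

which is :math:`+\\infty` whenever :math:`n - k - 1 \\le 0`, so overfit
models can never be selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import growth_models as gm
from .datasets import WholeBoneDataset

__all__ = [
    "FitResult",
    "SelectionReport",
    "aicc",
    "fit",
    "select_models",
    "confidence_band",
    "r_squared",
    "DEFAULT_SELECTION_SUBSET",
]

_PENALTY = 1e4

# The models (asymptotic and increasing) that achieve a best fit for at
# least one reanalysed data set; bootstrap/Monte Carlo winner-class tallies
# refit this subset rather than all 77 models.
DEFAULT_SELECTION_SUBSET = (
    "Extreme Value 2", "Rational 2z", "Michaelis Menten 2",
    "Extreme Value 3a", "Extreme Value 3b",
    "Linear 2", "Quadratic 2", "Quadratic 2b", "Cubic 2", "Cubic 2b",
    "Power 2", "Power 3", "Exponential 2", "Exponential 3", "Persistence 3a",
)


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected AIC in its least-squares form.

    Returns ``+inf`` when ``n - k - 1 <= 0`` (overfit guard) and ``-inf``
    for a numerically perfect fit (rss == 0), which callers rank separately.
    """
    if rss < 0 or n < 1 or k < 1:
        raise ValueError("aicc requires rss >= 0, n >= 1, k >= 1")
    if n - k - 1 <= 0:
        return float("inf")
    if rss == 0.0:
        return float("-inf")
    return n * math.log(rss / n) + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class FitResult:
    """One model fit to one data set."""

    model_name: str
    params: dict
    orientation: str            # 'reverse' | 'direct'
    rss: float                  # in dependent-variable units squared
    n: int
    k: int
    aicc: float
    converged: bool
    message: str = ""
    ages: np.ndarray = None     # the fitted data (kept for bands/maturity)
    dimensions: np.ndarray = None
    delta_aicc: float = float("nan")
    rel_likelihood: float = float("nan")
    support_class: str = ""     # 'best' | 'strong' | 'other'

    @property
    def model(self) -> gm.GrowthModel:
        return gm.get_model(self.model_name)

    @property
    def param_values(self) -> tuple:
        return tuple(self.params[p] for p in self.model.param_names)

    def predict_size(self, ages):
        return gm.evaluate(self.model, self.params, ages)

    def predict_age(self, sizes):
        return gm.inverse_age(self.model, self.params, sizes)


def _residual_fn(model: gm.GrowthModel, t, y, orientation: str):
    n = len(t)
    t_scale = max(float(np.std(t)), 1e-3)
    y_scale = max(float(np.std(y)), 1e-3)

    if orientation == "reverse":
        def resid(x):
            p = tuple(x)
            with np.errstate(all="ignore"):
                a = model._asymptote(p)
                lo = model._lower(p)
                res = np.full(n, _PENALTY)
                good = np.isfinite(y)
                if math.isfinite(a):
                    good &= y < a * (1.0 - 1e-12) if a > 0 else y < a
                if math.isfinite(lo):
                    good &= y > lo
                if good.any():
                    if model._inverse is None:
                        tp = gm._bisect_inverse(model, p, y[good])
                    else:
                        tp = model._inverse(y[good], p)
                    r = (t[good] - tp) / 1.0
                    r = np.where(np.isfinite(r), np.clip(r, -_PENALTY, _PENALTY),
                                 _PENALTY)
                    res[good] = r
                # gentle gradient for points above the asymptote
                if math.isfinite(a):
                    over = ~good & np.isfinite(y)
                    res[over] = _PENALTY * (1.0 + (y[over] - a) / y_scale)
                return res
        return resid

    def resid(x):
        p = tuple(x)
        with np.errstate(all="ignore"):
            tmin = model._tmin(p)
            ok = t >= tmin
            yp = np.where(ok, model._eval(np.where(ok, t, tmin), p), np.nan)
            r = (y - yp) / 1.0
            r = np.where(np.isfinite(r), np.clip(r, -_PENALTY * y_scale,
                                                 _PENALTY * y_scale),
                         _PENALTY * y_scale)
            return r
    return resid


def _make_starts(model, t, y, orientation, n_starts, rng):
    spec = model.fit_spec
    lb = np.array([s.lo(t, y) for s in spec])
    ub = np.array([s.hi(t, y) for s in spec])
    if orientation == "direct":
        # direct fits do not require the asymptote to clear every data point
        for i, s in enumerate(spec):
            if s.kind == "asym":
                lb[i] = 1e-12
    center = np.array([s.init(t, y) for s in spec], float)
    center = np.clip(center, lb, ub)
    starts = [center]
    # deterministic ladder over the two dominant scales (asymptote and rate),
    # then random multiplicative/additive jitter for the remaining starts
    i_asym = next((i for i, s in enumerate(spec) if s.kind == "asym"), None)
    i_rate = next((i for i, s in enumerate(spec) if s.kind == "rate"), None)
    ladder = []
    for fa in (1.05, 1.7, 4.0):
        for fr in (0.3, 1.0, 3.5):
            x = center.copy()
            if i_asym is not None:
                x[i_asym] = float(np.max(y)) * fa
            if i_rate is not None:
                x[i_rate] = center[i_rate] * fr
            ladder.append(np.clip(x, lb, ub))
    if i_asym is not None:
        # far-asymptote starts with slope-matched rate: saturating models
        # degenerate to a straight line as a -> inf with a*c fixed, which is
        # the relevant regime when the data carry no asymptote at all
        i_floor = next((i for i, s in enumerate(spec) if s.kind == "floor"),
                       None)
        t_span = max(float(np.max(t)) - float(np.min(t)), 1e-3)
        slope = (float(np.max(y)) - float(np.min(y))) / t_span
        icept = float(np.min(y)) - slope * float(np.min(t))
        for fa in (1e6, 1e13):
            x = center.copy()
            x[i_asym] = float(np.max(y)) * fa
            if i_rate is not None:
                x[i_rate] = max(slope / x[i_asym], lb[i_rate])
            if i_floor is not None:
                x[i_floor] = icept
            ladder.append(np.clip(x, lb, ub))
    seen = {tuple(center)}
    for x in ladder:
        if tuple(x) not in seen and len(starts) < n_starts:
            seen.add(tuple(x))
            starts.append(x)
    while len(starts) < n_starts:
        x = center.copy()
        for i in range(len(x)):
            if lb[i] >= 0 and x[i] > 0:
                x[i] = x[i] * math.exp(rng.normal(0.0, 0.9))
            else:
                scale = max(abs(x[i]), float(np.ptp(t)), 1.0)
                x[i] = x[i] + rng.normal(0.0, 0.5 * scale)
        starts.append(np.clip(x, lb, ub))
    return starts, lb, ub


def fit(data: WholeBoneDataset, model, orientation: str = "reverse",
        n_starts: int = 12, seed: int = 0, max_nfev: int = 400,
        tol: float = 1e-13) -> FitResult:
    """Multi-start nonlinear least squares of one model to one data set.

    Deterministic for a given ``seed``.  A fit that never converges is
    returned as a non-converged :class:`FitResult` (aicc = +inf), not raised.
    """
    if isinstance(model, str):
        model = gm.get_model(model)
    if orientation not in ("reverse", "direct"):
        raise ValueError("orientation must be 'reverse' or 'direct'")
    t = np.asarray(data.ages, float)
    y = np.asarray(data.dimensions, float)
    n = len(t)
    rng = np.random.default_rng(seed)
    resid = _residual_fn(model, t, y, orientation)
    starts, lb, ub = _make_starts(model, t, y, orientation, n_starts, rng)

    best_x, best_cost, best_msg = None, float("inf"), "no start converged"
    for x0 in starts:
        try:
            # dogbox: the trf interior transform degenerates under the very
            # wide asymptote bounds the artifact experiments require
            sol = optimize.least_squares(resid, x0, bounds=(lb, ub),
                                         method="dogbox", x_scale="jac",
                                         max_nfev=max_nfev,
                                         ftol=tol, xtol=tol, gtol=tol)
        except Exception as e:  # pragma: no cover - optimizer edge cases
            best_msg = str(e)
            continue
        if sol.cost < best_cost and np.all(np.isfinite(sol.x)):
            r = resid(sol.x)
            if np.all(np.abs(r) < _PENALTY):  # no penalized points at optimum
                best_x, best_cost, best_msg = sol.x, sol.cost, sol.message

    if best_x is None:
        return FitResult(model.name, {}, orientation, float("inf"), n, model.k,
                         float("inf"), False, best_msg, t, y)
    r = resid(best_x)
    rss = float(np.sum(r * r))
    if rss < 1e-20:
        rss = 0.0
    params = dict(zip(model.param_names, (float(v) for v in best_x)))
    return FitResult(model.name, params, orientation, rss, n, model.k,
                     aicc(rss, n, model.k), True, best_msg, t, y)


@dataclass
class SelectionReport:
    """Outcome of fitting a catalog subset and ranking by AICc."""

    fits: list
    status: str = "ok"          # 'ok' | 'insufficient data'
    best: Optional[FitResult] = None

    @property
    def frame(self) -> pd.DataFrame:
        rows = [{"model": f.model_name, "class": f.model.family_class,
                 "k": f.k, "n": f.n, "orientation": f.orientation,
                 "rss": f.rss, "aicc": f.aicc, "delta_aicc": f.delta_aicc,
                 "rel_likelihood": f.rel_likelihood,
                 "support": f.support_class, "converged": f.converged,
                 **{f"p_{k}": v for k, v in f.params.items()}}
                for f in self.fits]
        return pd.DataFrame(rows)

    def best_of_class(self, family_class: str) -> Optional[FitResult]:
        cands = [f for f in self.fits
                 if f.model.family_class == family_class and f.converged]
        if not cands:
            return None
        return min(cands, key=_rank_key)


def _rank_key(f: FitResult):
    # -inf aicc (perfect fits) first, then aicc, ties by fewer params then name
    return (0 if f.aicc == float("-inf") else 1, f.aicc, f.k, f.model_name)


def select_models(data: WholeBoneDataset, models: Optional[Iterable] = None,
                  orientation: str = "reverse", n_starts: int = 8,
                  seed: int = 0, delta_strong: float = 2.0,
                  max_nfev: int = 400, tol: float = 1e-13) -> SelectionReport:
    """Fit a set of models and rank them by AICc.

    Ties in AICc are broken by fewer parameters, then by model name.  If every
    candidate overfits (all AICc infinite) the report's status is
    ``'insufficient data'``.
    """
    if models is None:
        models = gm.model_names()
    fits = []
    rng = np.random.default_rng(seed)
    for name in models:
        m = gm.get_model(name) if isinstance(name, str) else name
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fits.append(fit(data, m, orientation=orientation, n_starts=n_starts,
                        seed=sub_seed, max_nfev=max_nfev, tol=tol))

    usable = [f for f in fits if f.converged and f.aicc < float("inf")]
    if not usable:
        return SelectionReport(fits, status="insufficient data")

    perfect = [f for f in usable if f.aicc == float("-inf")]
    if perfect:
        # rank zero-rss fits among themselves by parameter count, then name
        best = min(perfect, key=lambda f: (f.k, f.model_name))
        for f in fits:
            if f.aicc == float("-inf"):
                f.delta_aicc, f.rel_likelihood = 0.0, 1.0
                f.support_class = "best"
            else:
                f.delta_aicc, f.rel_likelihood = float("inf"), 0.0
                f.support_class = "other"
    else:
        amin = min(f.aicc for f in usable)
        for f in fits:
            f.delta_aicc = f.aicc - amin
            f.rel_likelihood = math.exp(-f.delta_aicc / 2.0) if \
                math.isfinite(f.delta_aicc) else 0.0
            if f.delta_aicc == 0.0:
                f.support_class = "best"
            elif f.delta_aicc <= delta_strong:
                f.support_class = "strong"
            else:
                f.support_class = "other"
        best = min([f for f in usable if f.delta_aicc == 0.0],
                   key=lambda f: (f.k, f.model_name))
    report = SelectionReport(sorted(fits, key=_rank_key), best=best)
    return report


def r_squared(fit_result: FitResult) -> float:
    """Coefficient of determination of the fit's dependent variable.

    Reported for comparison with earlier studies only; never used for model
    selection (a high R^2 does not validate an asymptotic extrapolation).
    Returns nan when the dependent variable has zero variance.
    """
    if not fit_result.converged:
        raise ValueError("r_squared requires a converged fit")
    dep = fit_result.ages if fit_result.orientation == "reverse" \
        else fit_result.dimensions
    tss = float(np.sum((dep - np.mean(dep)) ** 2))
    if tss == 0.0:
        return float("nan")
    return 1.0 - fit_result.rss / tss


def _prediction_and_grad(fit_result: FitResult, x_new):
    """Prediction at new independent-variable points plus parameter gradient."""
    model = fit_result.model
    p = np.array(fit_result.param_values, float)

    if fit_result.orientation == "reverse":
        def predict(pv):
            return np.asarray(model._inverse(x_new, tuple(pv))
                              if model._inverse is not None
                              else gm._bisect_inverse(model, tuple(pv), x_new),
                              float)
    else:
        def predict(pv):
            return np.asarray(model._eval(x_new, tuple(pv)), float)

    f0 = predict(p)
    grads = []
    for i in range(len(p)):
        h = 1e-6 * max(abs(p[i]), 1e-6)
        pp, pm = p.copy(), p.copy()
        pp[i] += h
        pm[i] -= h
        grads.append((predict(pp) - predict(pm)) / (2.0 * h))
    return f0, np.column_stack(grads)


def confidence_band(fit_result: FitResult, grid, level: float = 0.95):
    """Pointwise delta-method confidence band for the fitted curve.

    Assumes homoscedastic, normally distributed errors in the dependent
    variable.  ``grid`` is in the fit's independent variable: sizes for a
    reverse fit, ages for a direct fit.  Returns (center, lower, upper).
    """
    if not fit_result.converged:
        raise ValueError("confidence band requires a converged fit")
    n, k = fit_result.n, fit_result.k
    if n - k <= 0:
        raise ValueError("confidence band requires n > k")
    grid = np.asarray(grid, float)
    x_data = fit_result.dimensions if fit_result.orientation == "reverse" \
        else fit_result.ages
    _, J = _prediction_and_grad(fit_result, x_data)
    f0, G = _prediction_and_grad(fit_result, grid)
    sigma2 = fit_result.rss / (n - k)
    JtJ = J.T @ J
    cov = sigma2 * np.linalg.pinv(JtJ)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, cov, G), 0.0))
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - k)
    return f0, f0 - tcrit * se, f0 + tcrit * se
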