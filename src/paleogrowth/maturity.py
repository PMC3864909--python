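"""Skeletal-maturity assessment by rescaling sizes to percent-of-asymptote.

For an asymptotic fit with asymptote :math:`a` and minimum value :math:`y_0`,
each observed dimension :math:`y_i` is rescaled to

.. math:: s_i = 100\\,\\frac{y_i - y_0}{a - y_0}\\;[\\%],

so the data span a sub-interval of [0%, 100%].  The largest rescaled size
``s_max`` measures how far the oldest specimen progressed toward the
model's predicted maximum; a data set whose largest specimen reaches at
least 90% is considered skeletally mature.  Growth rates are reported only
at observed data points — never extrapolated to an inflection point the
data do not constrain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import growth_models as gm
from .datasets import WholeBoneDataset
from .fitting_selection import FitResult

__all__ = [
    "MaturityReport",
    "RateAtData",
    "MATURITY_THRESHOLD_PCT",
    "rescale_sizes",
    "maturity_summary",
    "rescaled_inflection",
    "rate_at_data",
]

MATURITY_THRESHOLD_PCT = 90.0


def _y0(fit: FitResult) -> float:
    """Minimum value of the fitted growth function.

    The function's infimum over its domain when finite; otherwise (curves
    unbounded below, e.g. monomolecular) the fitted value at the smallest
    observed age, which keeps rescaled data inside [0, 100].
    """
    model = fit.model
    lo = gm.lower_limit(model, fit.params)
    if math.isfinite(lo):
        return lo
    return float(fit.predict_size(float(np.min(fit.ages))))


def _require_asymptotic(fit: FitResult):
    model = fit.model
    if model.family_class == "increasing":
        raise ValueError(f"{model.name} is an increasing model: no asymptote, "
                         "maturity rescaling undefined")
    if not fit.converged:
        raise ValueError("maturity assessment requires a converged fit")


def rescale_sizes(data: WholeBoneDataset, fit: FitResult) -> np.ndarray:
    """Observed dimensions as percent of the fitted asymptote span."""
    _require_asymptotic(fit)
    a = gm.asymptote(fit.model, fit.params)
    y0 = _y0(fit)
    return 100.0 * (np.asarray(data.dimensions, float) - y0) / (a - y0)


@dataclass
class MaturityReport:
    model_name: str
    s: np.ndarray                # rescaled sizes, percent
    s_min: float
    s_max: float
    inflection_pct: Optional[float]   # sigmoidal fits only
    mature: bool
    threshold_pct: float = MATURITY_THRESHOLD_PCT


def maturity_summary(data: WholeBoneDataset, fit: FitResult,
                     threshold_pct: float = MATURITY_THRESHOLD_PCT) -> MaturityReport:
    """Rescaled size span and the maturity verdict for one asymptotic fit."""
    s = rescale_sizes(data, fit)
    infl_pct = rescaled_inflection(fit)
    if infl_pct is gm.NOT_MEANINGFUL:
        infl_pct = None
    return MaturityReport(model_name=fit.model_name, s=s,
                          s_min=float(np.min(s)), s_max=float(np.max(s)),
                          inflection_pct=infl_pct,
                          mature=bool(np.max(s) >= threshold_pct),
                          threshold_pct=threshold_pct)


def rescaled_inflection(fit: FitResult):
    """Inflection size as percent of the asymptote span; NOT_MEANINGFUL for
    non-sigmoidal fits (attenuating curves carry no inflection marker)."""
    _require_asymptotic(fit)
    infl = gm.inflection(fit.model, fit.params)
    if infl is gm.NOT_MEANINGFUL:
        return gm.NOT_MEANINGFUL
    _, y_i, _ = infl
    a = gm.asymptote(fit.model, fit.params)
    y0 = _y0(fit)
    return 100.0 * (y_i - y0) / (a - y0)


@dataclass
class RateAtData:
    t_m: float                  # age of the maximizing data point, years
    y_m: float                  # observed dimension there
    rate: float                 # fitted growth rate there, size units / yr
    percent_rate: float         # 100 * rate / y_m, % / yr
    rates: np.ndarray           # fitted rate at every data point


def rate_at_data(data: WholeBoneDataset, fit: FitResult) -> RateAtData:
    """Fitted growth rate evaluated at the observed data points only.

    Returns the data point at which the fitted rate is largest; this bounds
    the model's lifetime maximum rate from below without extrapolating
    beyond the observed ages.
    """
    if not fit.converged:
        raise ValueError("rate_at_data requires a converged fit")
    model = fit.model
    t = np.asarray(data.ages, float)
    floor = gm.age_floor(model, fit.params)
    t_eval = np.maximum(t, floor + 1e-9)
    rates = np.asarray(gm.growth_rate(model, fit.params, t_eval), float)
    i = int(np.argmax(rates))
    y_m = float(data.dimensions[i])
    return RateAtData(t_m=float(t[i]), y_m=y_m, rate=float(rates[i]),
                      percent_rate=100.0 * float(rates[i]) / y_m,
                      rates=rates)
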