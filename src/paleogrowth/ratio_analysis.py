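"""Relative growth between bones via ratios of fitted models.

If two bones of one taxon grow isometrically, the ratio of their fitted
growth curves is constant over age; systematic trends reveal allometry,
and ratios that diverge to implausible values flag incompatible data sets
(e.g. specimens combined from biologically distinct groups).  For two
asymptotic fits the ratio tends to the ratio of their asymptotes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fitting_selection import FitResult

__all__ = ["RatioSeries", "model_ratio", "ratio_plateau", "isometry_verdict",
           "PlateauResult"]


@dataclass
class RatioSeries:
    ages: np.ndarray
    ratio: np.ndarray
    numerator: str
    denominator: str


def model_ratio(fit_a: FitResult, fit_b: FitResult, ages) -> RatioSeries:
    """Pointwise ratio of two fitted growth curves over a shared age grid.

    Both fits must live in a common age frame (e.g. composites aligned with
    compatible global shifts).  Raises if the denominator curve is not
    strictly positive on the grid.
    """
    ages = np.asarray(ages, float)
    ya = np.asarray(fit_a.predict_size(ages), float)
    yb = np.asarray(fit_b.predict_size(ages), float)
    if np.any(yb <= 0):
        raise ValueError("denominator model non-positive on the age grid")
    return RatioSeries(ages=ages, ratio=ya / yb,
                       numerator=fit_a.model_name,
                       denominator=fit_b.model_name)


@dataclass
class PlateauResult:
    plateau: Optional[float]       # None when the series diverges
    is_monotone_approach: bool
    divergent: bool
    final_rel_slope: float         # per year, relative to the final value


def ratio_plateau(series: RatioSeries, rel_slope_tol: float = 1e-3,
                  transient_frac: float = 0.1) -> PlateauResult:
    """Detect whether a ratio series settles to a plateau.

    The plateau is the final grid value when the mean relative slope over
    the last decile falls below ``rel_slope_tol`` per year; monotonicity is
    judged after discarding the initial ``transient_frac`` of the grid.
    A series still drifting at the end of the grid is flagged divergent —
    the signature of incompatible data sets whose ratio climbs without
    limit.
    """
    t, r = series.ages, series.ratio
    n = len(t)
    if n < 5:
        raise ValueError("ratio series too short")
    i0 = int(math.floor(0.9 * n))
    tail_slope = np.polyfit(t[i0:], r[i0:], 1)[0]
    rel = abs(tail_slope) / max(abs(r[-1]), 1e-12)
    divergent = rel >= rel_slope_tol
    j0 = int(math.floor(transient_frac * n))
    d = np.diff(r[j0:])
    monotone = bool(np.all(d >= -1e-12) or np.all(d <= 1e-12))
    return PlateauResult(plateau=None if divergent else float(r[-1]),
                         is_monotone_approach=monotone,
                         divergent=divergent,
                         final_rel_slope=float(rel))


def isometry_verdict(series: RatioSeries, tolerance: float = 0.05) -> bool:
    """True when the ratio stays within ``tolerance`` of its mean.

    Isometric growth between two bones means their size ratio is constant;
    the default 5% band separates measurement scatter from real allometry.
    """
    r = series.ratio
    mean = float(np.mean(r))
    return bool(np.max(np.abs(r - mean)) / abs(mean) < tolerance)
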