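"""Allometric body-mass estimation from limb-bone dimensions.

Two families of estimators are provided:

* the limb-circumference regressions of Anderson et al. (1985), with the
  scaling exponent 2.73 calibrated on extant quadrupedal mammals:

  .. math:: M = k_b \\, C_f^{2.73} \\quad\\text{(bipeds)},\\qquad
            M = k_q \\,(C_h + C_f)^{2.73} \\quad\\text{(quadrupeds)},

  circumferences in mm, mass in grams;

* developmental mass extrapolation (DME) — in effect isometric
  interpolation — which scales the mass of a reference specimen by the cube
  of the femur-length ratio: :math:`M = M_{max} (L/L_{max})^3`.

Under isometric bone proportions the DME estimate for a sub-adult is
smaller than a direct Anderson estimate on the same bone by the factor
:math:`(L/L_{max})^{3-2.73}`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "MassEstimate",
    "ANDERSON_EXPONENT",
    "CAMPIONE_EXPONENT",
    "ANDERSON_BIPED_COEF",
    "ANDERSON_QUADRUPED_COEF",
    "DME_EXPONENT",
    "anderson_biped",
    "anderson_quadruped",
    "dme_mass",
    "allometric_ratio",
    "dme_vs_anderson_ratio",
    "fit_scaling_exponent",
    "ScalingFit",
    "ExtrapolationWarning",
]

ANDERSON_EXPONENT = 2.73
#: Campione & Evans' recalibration on 200 mammals + 47 reptiles; config option.
CAMPIONE_EXPONENT = 2.749
#: Anderson et al. (1985) coefficients: grams from circumferences in mm.
ANDERSON_BIPED_COEF = 0.16
ANDERSON_QUADRUPED_COEF = 0.078
DME_EXPONENT = 3.0


class ExtrapolationWarning(UserWarning):
    """DME applied above the reference femur length (extrapolation)."""


@dataclass(frozen=True)
class MassEstimate:
    mass: float                 # grams
    method: str                 # anderson_biped | anderson_quadruped | dme
    inputs: dict

    def __post_init__(self):
        if not self.mass > 0:
            raise ValueError("mass must be positive")

    @property
    def mass_kg(self) -> float:
        return self.mass / 1000.0


def anderson_biped(femur_circumference_mm: float,
                   coefficient: float = ANDERSON_BIPED_COEF,
                   exponent: float = ANDERSON_EXPONENT) -> MassEstimate:
    """Bipedal limb-circumference mass estimate, grams from mm."""
    c = float(femur_circumference_mm)
    if not c > 0:
        raise ValueError("femur circumference must be positive")
    return MassEstimate(coefficient * c ** exponent, "anderson_biped",
                        {"femur_circumference_mm": c, "exponent": exponent})


def anderson_quadruped(humerus_circumference_mm: float,
                       femur_circumference_mm: float,
                       coefficient: float = ANDERSON_QUADRUPED_COEF,
                       exponent: float = ANDERSON_EXPONENT) -> MassEstimate:
    """Quadrupedal estimate from the summed humerus + femur circumferences."""
    ch, cf = float(humerus_circumference_mm), float(femur_circumference_mm)
    if not (ch > 0 and cf > 0):
        raise ValueError("circumferences must be positive")
    return MassEstimate(coefficient * (ch + cf) ** exponent,
                        "anderson_quadruped",
                        {"humerus_circumference_mm": ch,
                         "femur_circumference_mm": cf, "exponent": exponent})


def dme_mass(femur_length: float, l_max: float, m_max_grams: float,
             exponent: float = DME_EXPONENT) -> MassEstimate:
    """Developmental mass extrapolation (isometric interpolation).

    ``m_max_grams`` is the estimated mass of the reference specimen whose
    femur length is ``l_max``; lengths may be in any shared unit since only
    their ratio enters.  Lengths above ``l_max`` are computed but flagged
    with :class:`ExtrapolationWarning`.
    """
    L, Lm = float(femur_length), float(l_max)
    if not (L > 0 and Lm > 0 and m_max_grams > 0):
        raise ValueError("lengths and reference mass must be positive")
    if L > Lm:
        warnings.warn("femur length exceeds the reference; DME is "
                      "interpolation and this is an extrapolation",
                      ExtrapolationWarning, stacklevel=2)
    return MassEstimate(m_max_grams * (L / Lm) ** exponent, "dme",
                        {"femur_length": L, "l_max": Lm,
                         "m_max_grams": m_max_grams, "exponent": exponent})


def allometric_ratio(dimension_ratio: float,
                     exponent: float = ANDERSON_EXPONENT) -> float:
    """Mass ratio implied by a linear-dimension ratio under a power law."""
    r = float(dimension_ratio)
    if not r > 0:
        raise ValueError("dimension ratio must be positive")
    return r ** exponent


def dme_vs_anderson_ratio(femur_length: float, l_max: float,
                          anderson_exponent: float = ANDERSON_EXPONENT,
                          dme_exponent: float = DME_EXPONENT) -> float:
    """DME mass over the direct circumference mass for the same specimen.

    Assuming isometric proportions (specimen circumference scales with
    ``femur_length / l_max``), the reference circumference cancels and the
    ratio reduces to ``(L/L_max)^(3 - 2.73)``, equal to 1 at ``L = L_max``
    and below 1 for sub-adults.
    """
    L, Lm = float(femur_length), float(l_max)
    if not (L > 0 and Lm > 0):
        raise ValueError("lengths must be positive")
    return (L / Lm) ** (dme_exponent - anderson_exponent)


@dataclass(frozen=True)
class ScalingFit:
    """Log-log scaling of mass against a bone dimension."""

    exponent: float
    exponent_stderr: float
    intercept: float            # log-space intercept of the two-parameter fit
    fixed_exponent: float       # the one-parameter (DME-like) comparison fit
    fixed_intercept: float
    n: int
    rss_free: float             # residual sums of squares in log space
    rss_fixed: float


def fit_scaling_exponent(dimensions: Sequence[float], masses: Sequence[float],
                         fixed_exponent: float = DME_EXPONENT) -> ScalingFit:
    """OLS of log(mass) on log(dimension), plus a fixed-exponent fit.

    The free two-parameter power law estimates the allometric exponent with
    its standard error; the one-parameter fit holds the exponent at
    ``fixed_exponent`` (cubic, DME-like) for comparison.
    """
    d = np.asarray(dimensions, float)
    m = np.asarray(masses, float)
    if d.shape != m.shape or d.ndim != 1 or len(d) < 2:
        raise ValueError("need >= 2 paired positive observations")
    if np.any(d <= 0) or np.any(m <= 0):
        raise ValueError("dimensions and masses must be positive")
    x, y = np.log(d), np.log(m)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    inter, slope = res.params
    se = res.bse[1] if len(d) > 2 else float("nan")
    resid_free = y - (inter + slope * x)
    c_fixed = float(np.mean(y - fixed_exponent * x))
    resid_fixed = y - (c_fixed + fixed_exponent * x)
    return ScalingFit(exponent=float(slope), exponent_stderr=float(se),
                      intercept=float(inter), fixed_exponent=fixed_exponent,
                      fixed_intercept=c_fixed, n=len(d),
                      rss_free=float(resid_free @ resid_free),
                      rss_fixed=float(resid_fixed @ resid_fixed))
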