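"""Monte Carlo and bootstrap experiments quantifying estimation error.

Four experiments probe the statistical failure modes of growth-curve
studies on small fossil samples:

* ``mc_iv_choice`` — orientation of the regression.  Age estimates carry
  the error, so regressing age on size (reverse) is correctly specified
  while the conventional size-on-age (direct) regression has errors in its
  independent variable.  The experiment measures how much wider the spread
  of asymptote estimates becomes under the wrong orientation.
* ``linear_cubic_artifact`` — asymptotic curves fit to data drawn from
  unbounded (linear/cubic) curves achieve near-perfect R² while their
  fitted "asymptotes" scatter over tens of orders of magnitude: the
  asymptote of a wrong-class model is a mathematical artifact.
* ``mc_finite_sample`` / ``mc_age_error`` — finite, juvenile-biased samples
  of a genuinely sigmoidal curve (or age-perturbed real data sets) are
  frequently best-fit by increasing curves, and increasingly so at higher
  age-error magnitudes.
* ``bootstrap_selection`` — resampling a data set with replacement shows
  how fragile the asymptotic-versus-increasing verdict is to which few
  specimens happen to be sampled.

All experiments take an explicit seed and are bit-reproducible; monotone
stress-response comparisons reuse common random numbers across magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import growth_models as gm
from .config import Config, DEFAULT_CONFIG
from .datasets import WholeBoneDataset
from .fitting_selection import (DEFAULT_SELECTION_SUBSET, fit, r_squared,
                                select_models)
from .synthetic_data import AgeSampler, ErrorModel, gen_whole_bone, normal_ages, regular_ages

__all__ = [
    "IVChoiceResult",
    "ClassFractionResult",
    "ArtifactTable",
    "mc_iv_choice",
    "linear_cubic_artifact",
    "mc_finite_sample",
    "mc_age_error",
    "bootstrap_selection",
]


def _mc_curve(cfg: Config):
    params = {"a": cfg.mc_logistic_a, "c": cfg.mc_logistic_c,
              "d": cfg.mc_logistic_d}
    return "Logistic 3z", params


@dataclass
class IVChoiceResult:
    """Spread of asymptote estimates: direct versus reverse orientation."""

    sd_direct: float
    sd_reverse: float
    n_converged: int
    n_dropped: int
    reps: int
    seed: int
    error: ErrorModel
    a_direct: np.ndarray = field(repr=False, default=None)
    a_reverse: np.ndarray = field(repr=False, default=None)

    @property
    def ratio_percent(self) -> float:
        """SD(direct) / SD(reverse) as a percentage."""
        return 100.0 * self.sd_direct / self.sd_reverse

    def _boot_ratios(self, n_boot: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        n = len(self.a_direct)
        idx = rng.integers(0, n, size=(n_boot, n))
        sd_d = np.std(self.a_direct[idx], axis=1, ddof=1)
        sd_r = np.std(self.a_reverse[idx], axis=1, ddof=1)
        return 100.0 * sd_d / sd_r

    def ratio_se_percent(self, n_boot: int = 2000, seed: int = 0) -> float:
        """Bootstrap standard error of the percentage ratio.  The asymptote
        spread can be heavy-tailed, so prefer :meth:`ratio_lower_percent`
        for one-sided statements."""
        return float(np.std(self._boot_ratios(n_boot, seed), ddof=1))

    def ratio_lower_percent(self, alpha: float = 0.001, n_boot: int = 4000,
                            seed: int = 0) -> float:
        """One-sided lower bootstrap bound on the percentage ratio."""
        return float(np.quantile(self._boot_ratios(n_boot, seed), alpha))


def mc_iv_choice(error: ErrorModel, reps: Optional[int] = None,
                 n_points: Optional[int] = None, seed: int = 0,
                 curve=None, params=None,
                 config: Config = DEFAULT_CONFIG) -> IVChoiceResult:
    """Monte Carlo comparison of regression orientations.

    Each replicate samples ``n_points`` regularly spaced ages from the
    generating logistic, evaluates exact sizes, perturbs the recorded ages
    per ``error``, and fits the generating model in both orientations.  The
    result summarises the spread of the asymptote estimates; ratios above
    100% mean the direct (size-on-age) orientation is noisier.
    """
    cfg = config
    reps = cfg.reps if reps is None else reps
    n_points = cfg.mc_n_points if n_points is None else n_points
    if curve is None:
        curve, params = _mc_curve(cfg)
    sampler = regular_ages(cfg.mc_age_lo, cfg.mc_age_hi)
    rng = np.random.default_rng(seed)
    a_dir, a_rev, dropped = [], [], 0
    for _ in range(reps):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        ds = gen_whole_bone(curve, params, n_points, sampler, error=error,
                            seed=sub)
        fd = fit(ds, curve, orientation="direct", n_starts=cfg.n_starts_mc,
                 seed=sub, tol=1e-10, max_nfev=250)
        fr = fit(ds, curve, orientation="reverse", n_starts=cfg.n_starts_mc,
                 seed=sub, tol=1e-10, max_nfev=250)
        if fd.converged and fr.converged:
            a_dir.append(fd.params["a"])
            a_rev.append(fr.params["a"])
        else:
            dropped += 1
    a_dir = np.asarray(a_dir)
    a_rev = np.asarray(a_rev)
    return IVChoiceResult(sd_direct=float(np.std(a_dir, ddof=1)),
                          sd_reverse=float(np.std(a_rev, ddof=1)),
                          n_converged=len(a_dir), n_dropped=dropped,
                          reps=reps, seed=seed, error=error,
                          a_direct=a_dir, a_reverse=a_rev)


@dataclass
class ArtifactTable:
    """Asymptote artifacts from fitting asymptotic models to unbounded data."""

    frame: pd.DataFrame
    base_kind: str

    @property
    def asymptote_min(self) -> float:
        return float(self.frame["asymptote"].min())

    @property
    def asymptote_max(self) -> float:
        return float(self.frame["asymptote"].max())

    @property
    def orders_of_magnitude(self) -> float:
        return math.log10(self.asymptote_max / self.asymptote_min)


def linear_cubic_artifact(base_data: WholeBoneDataset,
                          models: Optional[Iterable[str]] = None,
                          orientation: str = "direct", seed: int = 0,
                          n_starts: int = 14) -> ArtifactTable:
    """Fit every asymptotic catalog model to linear or cubic data.

    Returns per-model fitted asymptote and R²; the asymptote spread (orders
    of magnitude for equally good fits) demonstrates that the parameter is
    an artifact of model choice when the data carry no asymptote.
    """
    if models is None:
        models = gm.model_names("sigmoidal") + gm.model_names("attenuating")
    rng = np.random.default_rng(seed)
    rows = []
    for name in models:
        f = fit(base_data, name, orientation=orientation, n_starts=n_starts,
                seed=int(rng.integers(0, 2 ** 31 - 1)))
        row = {"model": name, "class": gm.get_model(name).family_class,
               "converged": f.converged}
        if f.converged:
            row["asymptote"] = gm.asymptote(f.model, f.params)
            row["r_squared"] = r_squared(f)
            row["rss"] = f.rss
        rows.append(row)
    return ArtifactTable(pd.DataFrame(rows), base_kind=base_data.name)


@dataclass
class ClassFractionResult:
    """Winner-class tallies across simulation replicates."""

    fraction_increasing: float
    tallies: dict               # class -> count (plus 'insufficient data')
    reps: int
    seed: int
    per_replicate: list = field(repr=False, default=None)

    def se(self) -> float:
        """Binomial Monte Carlo standard error of the increasing fraction."""
        p, n = self.fraction_increasing, self.reps
        return math.sqrt(max(p * (1.0 - p), 1.0 / n ** 2) / n)


def _winner_tally(datasets: Iterable[WholeBoneDataset], models, n_starts,
                  seed: int) -> ClassFractionResult:
    rng = np.random.default_rng(seed)
    tallies = {"increasing": 0, "sigmoidal": 0, "attenuating": 0,
               "insufficient data": 0}
    per_rep = []
    n = 0
    for ds in datasets:
        n += 1
        # loose polish tolerance: winner-class tallies need the right basin,
        # not the last digits of the optimum
        rep = select_models(ds, models=models, n_starts=n_starts,
                            seed=int(rng.integers(0, 2 ** 31 - 1)),
                            max_nfev=150, tol=1e-8)
        if rep.status != "ok" or rep.best is None:
            tallies["insufficient data"] += 1
            per_rep.append("insufficient data")
        else:
            cls = rep.best.model.family_class
            tallies[cls] += 1
            per_rep.append(cls)
    frac = tallies["increasing"] / n if n else float("nan")
    return ClassFractionResult(fraction_increasing=frac, tallies=tallies,
                               reps=n, seed=seed, per_replicate=per_rep)


def mc_finite_sample(n_points: int, reps: Optional[int] = None,
                     error: Optional[ErrorModel] = None, seed: int = 0,
                     curve=None, params=None,
                     models: Sequence[str] = DEFAULT_SELECTION_SUBSET,
                     config: Config = DEFAULT_CONFIG) -> ClassFractionResult:
    """Fraction of finite samples of a sigmoidal curve won by increasing models.

    Ages are drawn from the juvenile-biased truncated normal (config mean
    11.5 yr, SD 2.875 yr); sizes are exact unless an age ``error`` is given.
    """
    cfg = config
    reps = cfg.reps if reps is None else reps
    if n_points < 4:
        raise ValueError("need n_points >= 4")
    if curve is None:
        curve, params = _mc_curve(cfg)
    sampler = normal_ages(cfg.age_mean, cfg.age_sd)
    rng = np.random.default_rng(seed)

    def datasets():
        for _ in range(reps):
            yield gen_whole_bone(curve, params, n_points, sampler,
                                 error=error,
                                 seed=int(rng.integers(0, 2 ** 31 - 1)))

    return _winner_tally(datasets(), list(models), cfg.n_starts_mc, seed)


def mc_age_error(data: WholeBoneDataset, error: ErrorModel,
                 reps: Optional[int] = None, seed: int = 0,
                 models: Sequence[str] = DEFAULT_SELECTION_SUBSET,
                 config: Config = DEFAULT_CONFIG) -> ClassFractionResult:
    """Winner-class stability of one data set under age perturbation.

    Each replicate adds a fresh age-error draw to the recorded ages, reruns
    model selection, and tallies the winning class.
    """
    cfg = config
    reps = cfg.reps if reps is None else reps
    rng = np.random.default_rng(seed)

    def datasets():
        for _ in range(reps):
            ages = np.maximum(error.perturb(data.ages, rng), 0.0)
            yield WholeBoneDataset(ages=ages, dimensions=data.dimensions,
                                   specimen_ids=list(data.specimen_ids),
                                   dimension_type=data.dimension_type,
                                   bone=data.bone, units=data.units,
                                   name=data.name)

    return _winner_tally(datasets(), list(models), cfg.n_starts_mc, seed)


def bootstrap_selection(data: WholeBoneDataset, reps: Optional[int] = None,
                        seed: int = 0,
                        models: Sequence[str] = DEFAULT_SELECTION_SUBSET,
                        min_distinct: int = 3,
                        config: Config = DEFAULT_CONFIG) -> ClassFractionResult:
    """Winner-class tallies over bootstrap resamples of one data set.

    Resamples ``n`` points with replacement; resamples with fewer than
    ``min_distinct`` distinct ages are redrawn (and counted) since no
    two-parameter model is identifiable on them.  Data sets too small for
    any candidate model (the AICc infinity rule) tally as 'insufficient
    data' rather than raising.
    """
    cfg = config
    reps = cfg.reps if reps is None else reps
    if data.n < 2:
        raise ValueError("bootstrap needs n >= 2")
    min_distinct = min(min_distinct, len(np.unique(data.ages)))
    rng = np.random.default_rng(seed)
    redrawn = 0

    def datasets():
        nonlocal redrawn
        for _ in range(reps):
            while True:
                idx = rng.integers(0, data.n, size=data.n)
                if len(np.unique(data.ages[idx])) >= min_distinct:
                    break
                redrawn += 1
            yield data.subset(idx)

    res = _winner_tally(datasets(), list(models), cfg.n_starts_mc, seed)
    res.tallies["redrawn"] = redrawn
    return res
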