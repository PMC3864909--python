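# paleogrowth

Growth-curve estimation and error analysis for skeletochronological data.

Paleohistologists estimate the ages of extinct vertebrates by counting
annual growth marks (lines of arrested growth, LAGs) in fossil bone, pair
those ages with bone dimensions, and fit growth curves to infer growth
rates, maximum sizes and maturity.  Published analyses of this kind have
often rested on fragile statistical choices: regressing size on a noisy
age estimate, fitting a single hand-picked sigmoid, reading an asymptote
off data that never approach one.  `paleogrowth` implements the
methodology that addresses these failure modes, for researchers analysing
LAG-derived growth data or probing how robust such analyses can be.

## What it does

* **Growth-function catalog** — 77 parametric models `y(t)` in three
  classes (15 increasing, 48 sigmoidal, 14 attenuating), each with
  closed-form inverse `t(y)`, derivative, inflection and asymptote; the
  machine-readable manifest ships in
  `src/paleogrowth/data/catalog_manifest.tsv`.
* **Reverse regression + AICc selection** — bone dimension as the
  independent variable (ages carry the error), multi-start bounded least
  squares, ranking by the small-sample corrected Akaike criterion
  `AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` (infinite when
  `n − k − 1 ≤ 0`, so overfitting is structurally impossible), with
  delta-method confidence bands.
* **Longitudinal alignment** — least-squares continuous (non-integer) time
  offsets merging per-specimen LAG series into composite growth
  histories, plus two-group split clustering for data sets that mix
  biologically distinct populations.
* **Maturity assessment** — sizes rescaled to percent of the fitted
  asymptote, `s_i = 100 (y_i − y0)/(a − y0)`; a taxon's largest specimen
  at `s_max ≥ 90 %` marks skeletal maturity; growth rates evaluated only
  at observed data points.
* **Allometric mass estimation** — limb-circumference power laws
  (`M = 0.16 C_f^2.73` for bipeds, `0.078 (C_h + C_f)^2.73` for
  quadrupeds; mm → grams), developmental mass extrapolation
  (`M = M_max (L/L_max)³`), their ratio, and log–log scaling-exponent
  fits.
* **Error analysis** — Monte Carlo experiments for regression
  orientation, wrong-model asymptote artifacts, finite juvenile-biased
  sampling and age-estimation error, plus bootstrap model-selection
  stability; all seeded and bit-reproducible.
* **Synthetic data** — generators for every input shape the pipeline
  consumes, so each stage is testable without any fossil data.

## Worked example

```python
import numpy as np
from paleogrowth import growth_models as gm, WholeBoneDataset, select_models
from paleogrowth.maturity import maturity_summary, rate_at_data
from paleogrowth.mass_estimation import allometric_ratio, anderson_biped

# a 20-point sample spanning 5-96% of a logistic growth trajectory
levels = 100.0 * np.linspace(0.05, 0.96, 20)
ages = np.asarray(gm.inverse_age("Logistic 3",
                                 {"a": 100, "b": 12, "c": 0.4}, levels))
ds = WholeBoneDataset(ages=ages, dimensions=levels, name="demo")

rep = select_models(ds, models=["Logistic 3", "Gompertz 3", "Linear 2",
                                "Power 2", "Michaelis Menten 2"], seed=0)
best = rep.best
mat = maturity_summary(ds, best)
r = rate_at_data(ds, best)
print("best model:", best.model_name, "| class:", best.model.family_class)
print("asymptote: %.2f cm" % gm.asymptote(best.model, best.params))
print("rescaled span: %.1f%% - %.1f%% -> mature: %s"
      % (mat.s_min, mat.s_max, mat.mature))
print("max data-point rate: %.2f cm/yr at age %.1f yr (%.1f%%/yr)"
      % (r.rate, r.t_m, r.percent_rate))
print("mass factor for a 338/190 mm femur pair: x%.1f"
      % allometric_ratio(338 / 190, 2.73))
print("338 mm femur circumference -> %.0f kg" % anderson_biped(338).mass_kg)
```

prints

```
best model: Logistic 3 | class: sigmoidal
asymptote: 100.00 cm
rescaled span: 5.0% - 96.0% -> mature: True
max data-point rate: 9.99 cm/yr at age 11.8 yr (20.8%/yr)
mass factor for a 338/190 mm femur pair: x4.8
338 mm femur circumference -> 1283 kg
```

The selection correctly identifies the generating sigmoid over the
increasing alternatives; the data span reaches 96 % of the fitted
asymptote, so the sample counts as skeletally mature; the fastest growth
seen *at a data point* is 9.99 cm/yr near the inflection age; and a femur
pair whose circumferences differ 338 mm vs 190 mm implies a 4.8-fold body
mass difference under the circumference exponent 2.73.

A `paleogrowth` console script exposes the same functionality
(`fit`, `align`, `simulate`, `bootstrap`, `mass`, `ratio`, `generate`,
`report`); see `paleogrowth --help`.

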