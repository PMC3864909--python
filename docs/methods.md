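# Methods

`paleogrowth` estimates skeletal growth trajectories from
skeletochronological data — per-specimen ages counted from annual growth
marks (LAGs) in fossil bone, paired with bone dimensions — and quantifies
how fragile those estimates are.  This note records the statistical model,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## The estimation problem

A growth curve is a strictly increasing function `y(t)` mapping age in
years to a bone dimension (length or circumference; masses only enter via
allometric conversion).  Three curve classes are distinguished:

* **sigmoidal** — finite asymptote `a`, interior inflection at `(t_i, y_i)`
  where the growth rate peaks at `r_max`;
* **attenuating** — finite asymptote but growth rate maximal at the left
  edge of the admissible age domain (no interior inflection);
* **increasing** — no asymptote (`y → ∞`).

The catalog holds 77 parametric models (15 increasing, 48 sigmoidal, 14
attenuating), each with closed-form evaluation, derivative, asymptote and
(for all but one model) closed-form inverse `t(y)`.  Class membership is
operationalised through parameter constraints: a model is attenuating iff
its constraints pin any inflection at or left of the domain edge for every
admissible parameter set.  Several catalog entries are reparameterisations
of the same curve (e.g. `Michaelis Menten 2` and `Rational 2z`); this is
deliberate — published model suites carry such duplicates, and the
selection tie-break (below) handles them.  Entries whose exact published
algebraic form was not available were reconstructed as standard 2–4
parameter variants of their families and are flagged `reconstructed` in
`data/catalog_manifest.tsv`, with the formula used recorded there.

## Regression orientation

Bone dimensions are measured to the millimetre; LAG-count ages are
estimates with substantial error.  Ordinary least squares assumes the
error lives in the dependent variable, so the package's preferred
("reverse") orientation regresses **age on size**, minimising
`Σ (t_i − t(y_i; θ))²` through the catalog's inverse functions.  The
conventional ("direct") orientation `Σ (y_i − y(t_i; θ))²` is retained for
replicating earlier analyses and for the orientation Monte Carlo, which
measures the price of the wrong choice.

## Fitting and model selection

Fits use bounded trust-region least squares (`scipy.optimize.least_squares`,
dogbox; the trf interior transform degenerates under the very wide
asymptote bounds the artifact experiment needs).  Initialisation is a
deterministic multi-start ladder: a data-driven center (asymptote ≈
1.3 × max size, location ≈ median age, rate ≈ 3/age-span), a 3 × 3 grid
over asymptote and rate multipliers, two *far-asymptote* starts
(asymptote = 10⁶ and 10¹³ × max size with slope-matched rate — the regime
where saturating models degenerate to a straight line, essential when the
data carry no asymptote), and random multiplicative jitter up to
`n_starts` (default 12; 3 inside Monte Carlo loops, where only the winning
basin matters and polish tolerances are relaxed from 1e-13 to 1e-8).
Non-convergence is a reported result, never an exception.

Model comparison uses the small-sample corrected AIC,
`AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`, infinite when `n − k − 1 ≤ 0`
so overfit models cannot be selected.  A numerically perfect fit
(RSS = 0, possible on noiseless synthetic data) maps to `−∞` and perfect
fits are ranked among themselves by parameter count, then name — the same
tie-break applied to equal AICc generally.  "Best" is ΔAICc = 0 (up to
ties); "strong support" is Δ ≤ 2, i.e. relative likelihood
`exp(−Δ/2) ≥ 0.368`, the standard information-theoretic convention.  R² is
reported for comparison with older studies but never used for selection:
the artifact experiment shows why.

Confidence bands are pointwise delta-method bands
(`ŷ ± t_{α/2,n−k} σ̂ √(gᵀ(JᵀJ)⁻¹g)`) under homoscedastic normal errors in
the fit's dependent variable.

## Longitudinal alignment

Each specimen's LAG series is indexed from its first preserved mark;
alignment recovers continuous per-specimen time offsets by minimising the
summed squared difference between every ordered pair of series over their
overlapping age interval, interpolating piecewise-linearly (the minimal
assumption; pairwise costs are unweighted by overlap length, and reports
carry the overlap counts).  Optimisation is coordinate descent with a
bounded golden-section-style scalar search (±2 yr per sweep) from
integer-offset warm starts, iterated until the cost changes by < 1e-10.
Two safeguards matter: the reference specimen (most samples) is pinned at
offset 0 to fix the gauge, and a move that would strand a specimen with no
overlap at all is rejected — a disconnected placement has vacuously zero
cost, not a good one.  Absolute ages remain undetermined up to a global
shift unless the youngest specimen is known to be a neonate; `composite`
defaults to placing the smallest aligned age at zero.

`split_align` searches two-group partitions (exhaustively for ≤ 10
specimens, seeded local swap search beyond) minimising the summed
within-group alignment cost, for data sets suspected of mixing
biologically distinct populations.  Identifiability caveat: in the early
exponential phase a size-scaled sigmoid is indistinguishable from a
time-shifted one, so series that never reach the curve's bend cannot be
attributed to a population by alignment cost alone.

## Maturity and growth rates

For an asymptotic fit, sizes rescale to `s_i = 100 (y_i − y0)/(a − y0)` %
where `y0` is the fitted curve's minimum — its infimum when finite,
otherwise its value at the smallest observed age, which keeps data inside
[0, 100] %.  A data set is skeletally mature when `s_max ≥ 90 %`.  The
inflection size is rescaled identically for sigmoidal fits only;
attenuating fits carry no inflection marker.  Growth rates are evaluated
**only at observed data points** (the maximum over data points bounds the
lifetime maximum from below without extrapolation); the percent rate
divides by the observed size at the maximising point.  Replication fits,
by contrast, report the lifetime peak of the fitted derivative, because
that is what the replicated studies published.

## Mass estimation

Limb-circumference estimates use the classic extant-calibration power laws
`M = 0.16 C_f^2.73` (bipeds) and `M = 0.078 (C_h + C_f)^2.73` (quadrupeds),
circumferences in mm, mass in grams; the exponent and both coefficients
are config values (a 2.749 exponent recalibration is available as an
option).  Developmental mass extrapolation (DME) is isometric
interpolation `M = M_max (L/L_max)³`; applied above `L_max` it computes
but warns.  Under isometric proportions the DME/direct-circumference ratio
reduces to `(L/L_max)^0.27`, independent of the reference circumference.
All identity checks are coefficient-free ratios, pinned by the exponents.
`fit_scaling_exponent` is OLS of log-mass on log-dimension (statsmodels),
plus a one-parameter cubic-exponent fit for comparison.

## Synthetic data: what it emulates

Generators own explicit seeds (`numpy.random.Generator`; no global state).

* **Whole-bone samples**: exact sizes at true ages; recorded ages carry
  the error — homoscedastic (SD in years) or heteroscedastic (SD
  proportional to age), matching how LAG-count error behaves.
* **Age sampling**: uniform/regular spans, or a normal distribution
  truncated at zero by redraw (default mean 11.5 yr, SD 2.875 yr),
  emulating the scarcity of very young and very old fossil specimens.
* **Longitudinal series**: annual samples from hidden non-integer offsets,
  truncated per specimen, with multiplicative lognormal size noise forced
  monotone (bone does not shrink).
* **Polynomial data** (linear/cubic) for the wrong-model artifact; and
  **two-population mixtures** with ground-truth labels.

The Monte Carlo generating curve defaults to a tyrannosaur-shaped
`Logistic 3z` (asymptote 5649, rate 0.55/yr, starting size 5 — the shape
of the best-known published dinosaur age–mass logistic), sampled at 20
regular points over 2–28 yr; error magnitudes default to 10 % of age
(heteroscedastic) and 1 yr (homoscedastic), within the ±2 yr / 10–14 %
range published for tyrannosaur age estimates.  All of these are config
fields, not constants.

What the synthetic data does **not** capture: taphonomic survivorship
bias beyond the age-sampling distribution, retrocalculation error
structure (correlated, not independent), measurement error in dimensions,
and individual growth-curve heterogeneity.  Passing tests therefore
demonstrate the statistical machinery and its failure modes, not the
biology of any taxon.

## The error-analysis experiments

* **Orientation** (`mc_iv_choice`): per replicate, fit the generating
  model in both orientations; report `100 × SD(â_direct)/SD(â_reverse)`.
  Ratios far above 100 % show the cost of treating the noisy age as the
  independent variable.  The direct-orientation spread is heavy-tailed, so
  one-sided statements use a bootstrap quantile of the ratio rather than a
  normal-theory SE.
* **Wrong-model artifact** (`linear_cubic_artifact`): all 62 asymptotic
  models fit to straight-line (or cubic) data.  Sigmoids achieve R² ≈ 1
  while the fitted "asymptotes" span > 10 orders of magnitude — any point
  along the `a → ∞`, `a·c` fixed ridge fits essentially perfectly, so the
  reported asymptote is wherever the optimizer stopped, i.e. a
  mathematical artifact with no predictive content.
* **Finite sampling** (`mc_finite_sample`): juvenile-biased finite samples
  of a genuinely sigmoidal curve are frequently best-fit by increasing
  models once realistic age error is present, and increasingly so at
  higher error; the fraction falls with sample size.  (With exactly zero
  error the winner subset's Gumbel sigmoids dominate deterministically, so
  the interesting behaviour lives at nonzero error.)
* **Selection stability** (`bootstrap_selection`, `mc_age_error`): the
  bundled sparse-sample analogue — nine points, one very young and one
  very old specimen, 5 % age noise — flips to an increasing-class winner
  in a material fraction of bootstrap resamples, and the age-error flip
  fraction grows with the error magnitude (common random numbers across
  magnitudes for the monotonicity comparison).  Winner-class tallies refit
  the subset of models that best-fit at least one real data set, not all
  77, for tractability.

Problem sizes: the acceptance script runs 500 replicates per Monte Carlo
experiment with 20-point samples (9-point for the sparse analogue); the
unit-test suite uses 8–30 replicates for the same properties.

## Degenerate inputs and edge behaviour

Sizes at or above a model's asymptote have no inverse (RangeError; during
fitting such points contribute a smooth penalty that pushes the asymptote
upward).  Data sets where every candidate model overfits return an
explicit "insufficient data" report.  Bootstrap resamples with fewer than
three distinct ages are redrawn and counted.  Non-integer inverse
round-trips are ill-conditioned within ~1e-6 of the asymptote; tests and
simulations stay clear of that band.

## Known limitations

Reverse-orientation fitting assumes the closed-form inverse is exact;
`Persistence 3b` falls back to monotone bisection.  The maturity verdict
inherits the fitted asymptote's fragility — on data that stop short of
the bend it can only be read as "at least this immature under the best
asymptotic model".  The ratio-plateau detector uses a last-decile slope
threshold (config) and cannot distinguish a very slow approach from
divergence on a short grid.
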