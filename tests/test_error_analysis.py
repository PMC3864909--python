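"""Monte Carlo / bootstrap experiments (small-replicate property checks;
the full-scale study conditions run in the acceptance layer)."""

import numpy as np
import pytest

from paleogrowth import growth_models as gm
from paleogrowth.datasets import WholeBoneDataset
from paleogrowth.error_analysis import (bootstrap_selection,
                                        linear_cubic_artifact, mc_age_error,
                                        mc_finite_sample, mc_iv_choice)
from paleogrowth.fitting_selection import fit
from paleogrowth.synthetic_data import (ErrorModel, gen_polynomial,
                                        gen_whole_bone, uniform_ages)


class TestIVChoice:
    def test_reproducible_given_seed(self):
        em = ErrorModel("heteroscedastic", 0.10)
        r1 = mc_iv_choice(em, reps=12, seed=3)
        r2 = mc_iv_choice(em, reps=12, seed=3)
        assert r1.ratio_percent == r2.ratio_percent
        assert np.array_equal(r1.a_direct, r2.a_direct)

    def test_near_zero_error_both_orientations_exact(self):
        # with vanishing age error both fits recover the generating
        # asymptote almost exactly, so neither orientation has meaningful
        # spread left (the ratio of two ~zero spreads is not informative)
        r = mc_iv_choice(ErrorModel("homoscedastic", 1e-7), reps=10, seed=1)
        a_true = 5649.0
        assert np.allclose(r.a_direct, a_true, rtol=1e-4)
        assert np.allclose(r.a_reverse, a_true, rtol=1e-4)
        assert r.sd_direct < 1e-3 * a_true
        assert r.sd_reverse < 1e-3 * a_true

    def test_dropped_replicates_counted(self):
        em = ErrorModel("heteroscedastic", 0.10)
        r = mc_iv_choice(em, reps=10, seed=2)
        assert r.n_converged + r.n_dropped == 10


class TestArtifact:
    def test_sigmoids_fit_linear_data_with_high_r2(self):
        base = gen_polynomial("linear", 20, span=(1.0, 20.0), seed=0)
        tab = linear_cubic_artifact(
            base, models=["Logistic 3", "Gompertz 3", "Extreme Value 3a",
                          "von Bertalanffy 3", "Hyperbolic Tangent 3",
                          "Monomolecular 2", "Michaelis Menten 2"],
            seed=1)
        df = tab.frame
        assert df["converged"].all()
        sig = df[df["class"] == "sigmoidal"]
        assert (sig["r_squared"] >= 0.99).all()

    def test_generating_linear_model_perfect_while_asymptotic_not(self):
        base = gen_polynomial("linear", 20, span=(1.0, 20.0), seed=0)
        f_lin = fit(base, "Linear 2", orientation="direct", seed=0)
        assert f_lin.rss == 0.0
        f_log = fit(base, "Logistic 3", orientation="direct", seed=0)
        assert f_log.rss > 0.0

    def test_asymptote_estimates_are_artifacts_spread_widely(self):
        base = gen_polynomial("linear", 20, span=(1.0, 20.0), seed=0)
        tab = linear_cubic_artifact(
            base, models=["Logistic 3", "Monomolecular 3", "Gompertz 3",
                          "Hyperbolic Tangent 2", "Michaelis Menten 2",
                          "Extreme Value 3a"], seed=1)
        # saturating-exponential families push their "asymptote" to absurd
        # values on asymptote-free data while bounded kernels stay near the
        # data maximum: the parameter is meaningless, not the fit
        assert tab.orders_of_magnitude > 3


class TestFiniteSample:
    def test_fraction_of_increasing_winners_drops_with_sample_size(self):
        em = ErrorModel("heteroscedastic", 0.05)
        r_small = mc_finite_sample(8, reps=25, error=em, seed=5)
        r_large = mc_finite_sample(40, reps=25, error=em, seed=5)
        assert r_small.fraction_increasing > r_large.fraction_increasing
        assert r_small.fraction_increasing > 0.15

    def test_error_magnitude_raises_increasing_fraction(self):
        # common random numbers: same seed, different magnitudes
        r5 = mc_finite_sample(10, reps=25,
                              error=ErrorModel("heteroscedastic", 0.05),
                              seed=11)
        r10 = mc_finite_sample(10, reps=25,
                               error=ErrorModel("heteroscedastic", 0.10),
                               seed=11)
        assert r10.fraction_increasing >= r5.fraction_increasing

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            mc_finite_sample(3, reps=5, seed=0)


class TestAgeError:
    def test_vanishing_error_keeps_unperturbed_winner(self, trex_like_analogue):
        r = mc_age_error(trex_like_analogue,
                         ErrorModel("heteroscedastic", 1e-9), reps=8, seed=2)
        assert r.fraction_increasing == 0.0
        assert r.tallies["sigmoidal"] + r.tallies["attenuating"] == 8

    def test_reproducible(self, trex_like_analogue):
        em = ErrorModel("heteroscedastic", 0.10)
        r1 = mc_age_error(trex_like_analogue, em, reps=10, seed=4)
        r2 = mc_age_error(trex_like_analogue, em, reps=10, seed=4)
        assert r1.tallies == r2.tallies
        assert r1.per_replicate == r2.per_replicate


class TestBootstrap:
    def test_full_span_logistic_never_flips_to_increasing(self):
        ds = gen_whole_bone("Logistic 3", {"a": 100.0, "b": 12.0, "c": 0.4},
                            50, uniform_ages(0.5, 30.0), seed=6)
        r = bootstrap_selection(ds, reps=15, seed=3)
        assert r.fraction_increasing == pytest.approx(0.0, abs=0.08)

    def test_two_point_dataset_tallied_as_insufficient(self):
        ds = WholeBoneDataset(ages=[3.0, 9.0], dimensions=[10.0, 30.0])
        r = bootstrap_selection(ds, reps=5, seed=1)
        assert r.tallies["insufficient data"] == 5

    def test_sparse_analogue_shows_instability(self, trex_like_analogue):
        r = bootstrap_selection(trex_like_analogue, reps=30, seed=9)
        # dropping the lone young/old anchors lets increasing curves win
        assert r.fraction_increasing > 0.0
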