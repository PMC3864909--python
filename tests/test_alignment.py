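"""Offset alignment of longitudinal LAG series and split clustering."""

import numpy as np
import pytest

from paleogrowth import growth_models as gm
from paleogrowth.alignment import (align_series, composite, overlap_cost,
                                   pairwise_cost, split_align)
from paleogrowth.datasets import LAGSeries, ValidationError
from paleogrowth.synthetic_data import gen_longitudinal, gen_mixture

CURVE = "Logistic 3"
PARAMS = {"a": 100.0, "b": 12.0, "c": 0.35}


def _series(offsets, lengths, noise=0.0, seed=0):
    return gen_longitudinal(CURVE, PARAMS, offsets=offsets, lengths=lengths,
                            noise_frac=noise, seed=seed)


class TestOverlapCost:
    def test_identical_series_zero_cost(self):
        s = _series([3.0], [8])[0]
        c, n = overlap_cost(s, s, 0.0)
        assert c == 0.0 and n == s.n

    def test_exact_shift_recovers_zero_cost(self):
        # series b sampled 2.5 yr later on the same curve: cost at the true
        # shift vanishes up to interpolation error
        a = _series([2.0], [10])[0]
        b = _series([4.5], [10])[0]
        c_true, n = overlap_cost(a, b, 2.5)
        assert n > 0
        c_off1, _ = overlap_cost(a, b, 2.0)
        c_off2, _ = overlap_cost(a, b, 3.0)
        assert c_true < c_off1 and c_true < c_off2
        # interpolation error only (piecewise-linear chord vs curve)
        assert c_true < 1e-1

    def test_no_overlap_flagged(self):
        a = _series([0.0], [4])[0]
        b = _series([0.0], [4])[0]
        c, n = overlap_cost(a, b, 100.0)
        assert c == 0.0 and n == 0

    def test_lag_series_must_increase(self):
        with pytest.raises(ValidationError):
            LAGSeries("x", [0, 1, 2], [5.0, 4.0, 6.0])


class TestAlign:
    def test_single_series_trivial(self):
        asn = align_series(_series([2.0], [6]))
        assert asn.offsets.tolist() == [0.0]
        assert asn.total_cost == 0.0

    def test_gauge_invariance_of_total_cost(self):
        series = _series([0.0, 2.0, 4.0], [8, 8, 8], noise=0.01, seed=3)
        taus = np.array([0.0, 1.9, 4.1])
        c1 = pairwise_cost(series, taus)
        c2 = pairwise_cost(series, taus + 7.3)
        assert c1 == pytest.approx(c2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_offset_recovery_within_quarter_year(self, seed):
        """Planted non-integer offsets recovered to 0.25 yr at 1% size noise."""
        series = _series([0.0, 1.7, 4.2, 6.0], [8, 8, 9, 10], noise=0.01,
                         seed=seed)
        true = np.array([s.true_offset for s in series])
        asn = align_series(series)
        rec = np.array([asn.offset_by_id[s.specimen_id] for s in series])
        rec = rec - rec[0] + true[0]
        assert np.max(np.abs(rec - true)) < 0.25

    def test_continuous_beats_best_integer_offsets(self):
        series = _series([0.0, 2.5, 5.3], [8, 9, 9], noise=0.005, seed=1)
        asn = align_series(series)
        best_int = min(
            pairwise_cost(series, np.array([0.0, i, j]))
            for i in range(0, 9) for j in range(0, 12))
        assert asn.total_cost <= best_int + 1e-9

    def test_offset_error_shrinks_with_noise(self):
        errs = {}
        for noise in (0.02, 0.001):
            series = _series([0.0, 2.3, 4.8], [9, 9, 9], noise=noise, seed=6)
            true = np.array([s.true_offset for s in series])
            asn = align_series(series)
            rec = np.array([asn.offset_by_id[s.specimen_id] for s in series])
            rec = rec - rec[0] + true[0]
            errs[noise] = np.max(np.abs(rec - true))
        assert errs[0.001] < errs[0.02]
        assert errs[0.001] < 0.05


class TestComposite:
    def test_single_series_ages_equal_year_indices(self):
        series = _series([0.0], [6])
        asn = align_series(series)
        ds = composite(series, asn, global_shift=0.0)
        assert np.allclose(ds.ages, series[0].year_indices)
        assert ds.n == series[0].n

    def test_point_count_preserved_and_per_specimen_monotone(self):
        series = _series([0.0, 1.5, 3.5], [8, 8, 8], noise=0.01, seed=9)
        asn = align_series(series)
        ds = composite(series, asn)
        assert ds.n == sum(s.n for s in series)
        for sid in {s.specimen_id for s in series}:
            sel = [i for i, x in enumerate(ds.specimen_ids) if x == sid]
            assert np.all(np.diff(ds.dimensions[sel]) > 0)

    def test_merged_points_lie_on_generating_curve(self):
        series = _series([0.0, 2.0, 5.0], [8, 8, 10], noise=0.0, seed=0)
        asn = align_series(series)
        # anchor absolute ages on the known true offset of the first specimen
        shift = series[0].true_offset - asn.offset_by_id[series[0].specimen_id]
        ds = composite(series, asn, global_shift=shift)
        pred = np.asarray(gm.evaluate(CURVE, PARAMS, ds.ages))
        assert np.allclose(ds.dimensions, pred, rtol=5e-3)


class TestSplit:
    def test_two_scale_populations_partitioned(self):
        pa = PARAMS
        pb = {"a": 200.0, "b": 12.0, "c": 0.35}
        # series must span the curve's bend: in the early exponential phase a
        # doubled-scale logistic is indistinguishable from a time-shifted one
        series, labels = gen_mixture(CURVE, pa, CURVE, pb,
                                     [0.0, 3.0, 6.0], [12, 12, 12],
                                     [1.0, 3.0, 6.0], [12, 12, 12],
                                     noise_frac=0.01, seed=4)
        res = split_align(series)
        got = sorted(sorted(g) for g in res.groups)
        assert got == [["A0", "A1", "A2"], ["B0", "B1", "B2"]]
        assert res.improvement > 0

    def test_homogeneous_series_split_gains_little(self):
        series = _series([0.0, 2.0, 4.0, 6.0], [8, 8, 8, 8], noise=0.01,
                         seed=8)
        res = split_align(series)
        # splitting can only shed cross-group terms; with one population the
        # gain stays a small fraction of the single-cluster cost
        assert res.improvement <= res.single_cost
        assert res.split_cost >= 0.0

    def test_split_needs_two_series(self):
        with pytest.raises(ValueError):
            split_align(_series([0.0], [6]))
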