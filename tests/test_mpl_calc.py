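import numpy as np
import pytest

from fibrilmpl.band_sampler import LineProfile, SliceMeasurement
from fibrilmpl.errors import AnalysisError, CalibrationError
from fibrilmpl.mpl_calc import (
    FluctuationReport,
    calibrate,
    fluctuation_analysis,
    measure_fibril,
    mpl_histogram,
    mpl_per_slice,
    summarize,
)
from fibrilmpl.selections import SelectionLine


def make_profile(corrected_values, label="P", kind="standard", backgrounds=None,
                 indices=None, w=22):
    """Build a LineProfile with prescribed corrected intensities by hand."""
    backgrounds = backgrounds if backgrounds is not None else [0.0] * len(corrected_values)
    indices = indices if indices is not None else range(len(corrected_values))
    sel = SelectionLine(kind, label, 10.0, 0.0, 10.0, float(len(corrected_values) + 2), float(w))
    slices = [
        SliceMeasurement(
            slice_index=int(i),
            axial_pos=(10.0, float(i)),
            I=c + b,
            B_left=b,
            B_right=b,
            n_samples=w,
        )
        for i, c, b in zip(indices, corrected_values, backgrounds)
    ]
    return LineProfile(selection=sel, slices=slices, n_dropped=0)


class TestCalibrate:
    def test_constant_standard(self):
        # 22-px band over a 131-valued rod: every corrected slice is 22*131 = 2882
        cal = calibrate([make_profile([2882.0] * 10)], K=131.0)
        assert cal.C_std == 2882.0
        assert cal.n_std_lines == 1
        assert cal.n_std_slices == 10
        assert cal.sd_std == 0.0

    def test_two_standards_equal_counts_average(self):
        cal = calibrate([make_profile([3000.0] * 5, "S1"), make_profile([2000.0] * 5, "S2")])
        assert cal.C_std == 2500.0

    def test_pooling_weights_long_standards_more(self):
        cal = calibrate([make_profile([3000.0] * 9, "S1"), make_profile([2000.0], "S2")])
        assert cal.C_std == 2900.0

    def test_per_standard_mean_restores_equal_weight(self):
        cal = calibrate(
            [make_profile([3000.0] * 9, "S1"), make_profile([2000.0], "S2")],
            per_standard_mean=True,
        )
        assert cal.C_std == 2500.0
        assert cal.n_std_slices == 10

    def test_standard_no_brighter_than_background_rejected(self):
        with pytest.raises(CalibrationError, match="darker than background"):
            calibrate([make_profile([0.0] * 4, backgrounds=[500.0] * 4)])

    def test_no_slices_rejected(self):
        with pytest.raises(CalibrationError, match="no standard slices"):
            calibrate([])

    def test_nonpositive_k_rejected(self):
        with pytest.raises(CalibrationError, match="K"):
            calibrate([make_profile([100.0] * 3)], K=0.0)


class TestMplPerSlice:
    @pytest.fixture()
    def cal(self):
        return calibrate([make_profile([2882.0] * 5)], K=131.0)

    def test_standard_maps_to_its_own_mpl(self, cal):
        slc = SliceMeasurement(0, (0, 0), 2882.0, 0.0, 0.0, 22)
        assert mpl_per_slice(slc, cal) == 131.0

    def test_zero_corrected_is_zero(self, cal):
        slc = SliceMeasurement(0, (0, 0), 500.0, 500.0, 500.0, 22)
        assert mpl_per_slice(slc, cal) == 0.0

    def test_double_corrected_doubles_mpl(self, cal):
        slc = SliceMeasurement(0, (0, 0), 2 * 2882.0, 0.0, 0.0, 22)
        assert mpl_per_slice(slc, cal) == 262.0

    def test_negative_allowed(self, cal):
        slc = SliceMeasurement(0, (0, 0), 0.0, 100.0, 100.0, 22)
        assert mpl_per_slice(slc, cal) < 0.0


class TestMeasureFibril:
    @pytest.fixture()
    def cal(self):
        return calibrate([make_profile([1000.0] * 5)], K=131.0)

    def test_identical_slices(self, cal):
        m = measure_fibril(make_profile([500.0] * 8, kind="fibril"), cal)
        assert m.sd_mpl == 0.0
        assert m.mean_mpl == pytest.approx(500.0 * 131.0 / 1000.0)
        assert m.n_slices == 8

    def test_hand_mean(self, cal):
        # corrected values chosen so slice MPLs are [100, 102, 98] -> mean 100
        corr = [v * 1000.0 / 131.0 for v in (100.0, 102.0, 98.0)]
        m = measure_fibril(make_profile(corr, kind="fibril"), cal)
        assert m.mean_mpl == pytest.approx(100.0, abs=1e-9)

    def test_mean_invariant_under_reordering(self, cal, rng):
        values = list(rng.uniform(0, 2000, 20))
        m1 = measure_fibril(make_profile(values, kind="fibril"), cal)
        m2 = measure_fibril(make_profile(values[::-1], kind="fibril"), cal)
        assert m1.mean_mpl == pytest.approx(m2.mean_mpl, abs=1e-9)
        assert m1.sd_mpl == pytest.approx(m2.sd_mpl, abs=1e-9)

    def test_single_slice_sd_zero(self, cal):
        m = measure_fibril(make_profile([700.0], kind="fibril"), cal)
        assert (m.sd_mpl, m.sem_mpl, m.n_slices) == (0.0, 0.0, 1)


class TestSummarize:
    def fib(self, label, mpls, cal=None):
        corr = list(mpls)
        profile = make_profile(corr, label=label, kind="fibril")
        cal = cal or calibrate([make_profile([1.0] * 2)], K=1.0)  # identity scale
        return measure_fibril(profile, cal)

    def test_single_fibril(self):
        s = summarize([self.fib("F1", [100.0, 100.0])])
        assert s.pooled_mean == s.fibril_mean == 100.0
        assert s.n_fibrils == 1 and s.n_measurements == 2

    def test_weighted_vs_unweighted_means(self):
        # hand-computed: pooled (100 + 3*200)/4 = 175, fibril-level (100+200)/2 = 150
        s = summarize([self.fib("F1", [100.0]), self.fib("F2", [200.0] * 3)])
        assert s.pooled_mean == 175.0
        assert s.fibril_mean == 150.0
        assert s.n_measurements == 4

    def test_pooled_mean_within_slice_range(self, rng):
        fibs = [self.fib(f"F{i}", list(rng.uniform(-50, 300, 7))) for i in range(4)]
        s = summarize(fibs)
        lo = min(min(m.slice_mpls) for m in fibs)
        hi = max(max(m.slice_mpls) for m in fibs)
        assert lo <= s.pooled_mean <= hi

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            summarize([])


class TestFluctuation:
    def test_constant_background_zero_sd(self):
        p = make_profile([500.0] * 6, kind="fibril", backgrounds=[200.0] * 6)
        rep = fluctuation_analysis([p])
        assert rep.sd_bg_diff == 0.0
        assert rep.sd_fibril_diff == 0.0
        assert rep.n_pairs_bg == 5

    def test_dropped_slice_breaks_pairing(self):
        p = make_profile([1.0, 2.0, 3.0], kind="fibril", indices=[3, 4, 6])
        rep = fluctuation_analysis([p, make_profile([5.0, 6.0], kind="fibril", label="Q")])
        # {3,4,6} gives exactly one pair, {0,1} one more
        assert rep.n_pairs_bg == 2

    def test_no_pairing_across_profiles(self):
        profiles = [
            make_profile([1.0, 2.0], kind="fibril", label=f"F{i}") for i in range(3)
        ]
        assert fluctuation_analysis(profiles).n_pairs_bg == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(AnalysisError, match="pairs"):
            fluctuation_analysis([make_profile([1.0, 2.0], kind="fibril")])

    def test_sd_of_known_series(self):
        # backgrounds 0,1,3 -> diffs (-1,-2); sd(ddof=1) = 0.7071...
        p = make_profile(
            [10.0] * 3, kind="fibril", backgrounds=[0.0, 1.0, 3.0]
        )
        rep = fluctuation_analysis([p])
        assert rep.sd_bg_diff == pytest.approx(np.std([-1.0, -2.0], ddof=1))


class TestHistogram:
    def test_alignment_and_counts(self):
        edges, counts = mpl_histogram([1.0, 4.9, 5.1, 12.0], bin_width=5.0)
        assert edges[0] == 0.0 and edges[-1] == 15.0
        assert counts.tolist() == [2, 1, 1]
        assert counts.sum() == 4

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            mpl_histogram([1.0], bin_width=0.0)
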