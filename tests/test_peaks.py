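"""Local-Poisson peak calling, widths, Venn annotation, overlap and profiles."""
import numpy as np
import pandas as pd
import pytest

from calchip import (BinnedTrack, FeatureSet, PeakCallingParams, PeakSet,
                     annotate_peaks, call_peaks, fold_enrichment,
                     make_genome_layout, metaprofile, peak_width_stats,
                     peakset_overlap_fraction)
from calchip.validation import (brute_force_annotation,
                                brute_force_overlap_fraction,
                                _random_interval_instance)


def _track(values, bin_size=10):
    return BinnedTrack(bin_size=bin_size,
                       values={k: np.asarray(v, float) for k, v in values.items()})


class TestCallPeaks:
    def test_default_p_threshold(self):
        assert PeakCallingParams().p_max == 1e-5

    def test_planted_region_yields_one_containing_peak(self):
        layout = make_genome_layout(1, [1_000_000])
        rng = np.random.default_rng(0)
        chip = rng.poisson(2.0, 100_000).astype(float)
        ctrl = rng.poisson(2.0, 100_000).astype(float)
        chip[50_000:50_050] = rng.poisson(20.0, 50)  # 500 bp at 10x
        peaks = call_peaks(_track({"chr1": chip}), _track({"chr1": ctrl}),
                           layout=layout)
        assert len(peaks) == 1
        row = peaks.df.iloc[0]
        assert row["start"] <= 500_000 and row["end"] >= 500_500
        assert row["p_value"] < 1e-10
        assert row["q_value"] >= row["p_value"]
        assert 500_000 <= row["summit"] <= 500_500

    def test_null_track_produces_almost_no_peaks(self):
        rng = np.random.default_rng(1)
        chip = _track({"chr1": rng.poisson(1.0, 100_000)})
        ctrl = _track({"chr1": rng.poisson(1.0, 100_000)})
        peaks = call_peaks(chip, ctrl)
        assert len(peaks) <= 2  # 2 x bins x p_max

    def test_without_control_uses_uniform_background(self):
        rng = np.random.default_rng(2)
        chip = rng.poisson(2.0, 50_000).astype(float)
        chip[10_000:10_050] = 40.0
        peaks = call_peaks(_track({"chr1": chip}), None)
        assert len(peaks) == 1

    def test_chromosome_order_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(2.0, 20_000).astype(float)
        b = rng.poisson(2.0, 20_000).astype(float)
        a[5_000:5_060] = 30.0
        b[7_000:7_060] = 30.0
        ctrl_a = rng.poisson(2.0, 20_000).astype(float)
        ctrl_b = rng.poisson(2.0, 20_000).astype(float)
        p1 = call_peaks(_track({"chrA": a, "chrB": b}),
                        _track({"chrA": ctrl_a, "chrB": ctrl_b}))
        p2 = call_peaks(_track({"chrB": b, "chrA": a}),
                        _track({"chrB": ctrl_b, "chrA": ctrl_a}))
        pd.testing.assert_frame_equal(p1.df, p2.df)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            call_peaks(_track({"chr1": []}), None)

    def test_calibrated_input_rejected(self):
        t = BinnedTrack(bin_size=10, values={"chr1": np.ones(10)},
                        state="calibrated")
        with pytest.raises(ValueError, match="raw"):
            call_peaks(t, None)


class TestPeakWidthStats:
    def test_known_widths(self):
        peaks = PeakSet.from_intervals(
            [("chr1", 0, 400), ("chr1", 1000, 1600), ("chr1", 3000, 3800)])
        median, mean, widths = peak_width_stats(peaks)
        assert median == 600 and mean == 600
        assert sorted(widths) == [400, 600, 800]

    def test_single_peak(self):
        median, _, _ = peak_width_stats(PeakSet.from_intervals([("chr1", 0, 250)]))
        assert median == 250

    def test_many_random_widths_match_sort_oracle(self):
        rng = np.random.default_rng(4)
        starts = np.arange(1001) * 10_000
        widths = rng.integers(50, 5000, 1001)
        peaks = PeakSet.from_intervals(
            [("chr1", int(s), int(s + w)) for s, w in zip(starts, widths)])
        median, _, _ = peak_width_stats(peaks)
        assert median == sorted(widths)[500]  # odd count: middle order statistic

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            peak_width_stats(PeakSet(pd.DataFrame(
                columns=["chrom", "start", "end", "summit", "p_value",
                         "q_value", "label"])))


class TestAnnotatePeaks:
    def _features(self):
        return FeatureSet.from_records([
            ("chr1", 150, 300, "hotspot", 10.0),
            ("chr1", 190, 250, "axis", None),
            ("chr1", 5000, 5100, "centromere", None),
        ])

    def test_multi_class_label(self):
        peaks = PeakSet.from_intervals([("chr1", 100, 200)])
        labeled, counts = annotate_peaks(peaks, self._features())
        assert labeled.df["label"].iloc[0] == "Red1+Spo11"
        assert counts == {"Red1+Spo11": 1}

    def test_no_overlap_is_nil(self):
        peaks = PeakSet.from_intervals([("chr1", 0, 50)])
        labeled, counts = annotate_peaks(peaks, self._features())
        assert labeled.df["label"].iloc[0] == "Nil"
        assert counts == {"Nil": 1}

    def test_bookended_interval_does_not_overlap(self):
        peaks = PeakSet.from_intervals([("chr1", 300, 400)])  # touches hotspot end
        labeled, _ = annotate_peaks(peaks, self._features())
        assert labeled.df["label"].iloc[0] == "Nil"

    def test_matches_bruteforce_on_random_instances(self):
        for i in range(10):
            rng = np.random.default_rng(100 + i)
            peaks, features = _random_interval_instance(rng, 300)
            _, fast = annotate_peaks(peaks, features)
            assert fast == brute_force_annotation(peaks, features)
            assert sum(fast.values()) == len(peaks)


class TestOverlapFraction:
    def test_self_overlap_is_one(self):
        a = PeakSet.from_intervals([("chr1", 0, 100), ("chr1", 500, 700)])
        assert peakset_overlap_fraction(a, a) == 1.0

    def test_disjoint_sets_zero(self):
        a = PeakSet.from_intervals([("chr1", 0, 100)])
        b = PeakSet.from_intervals([("chr1", 200, 300)])
        assert peakset_overlap_fraction(a, b) == 0.0

    def test_half_overlap(self):
        a = PeakSet.from_intervals([("chr1", 0, 100), ("chr1", 200, 300),
                                    ("chr1", 400, 500), ("chr1", 600, 700)])
        b = PeakSet.from_intervals([("chr1", 50, 250)])
        assert peakset_overlap_fraction(a, b) == 0.5

    def test_empty_query_rejected(self):
        empty = PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "summit",
                                              "p_value", "q_value", "label"]))
        with pytest.raises(ValueError):
            peakset_overlap_fraction(empty, empty)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        a, features = _random_interval_instance(rng, 200)
        b = PeakSet.from_intervals([
            (r.chrom, r.start, r.end)
            for r in features.of_class("hotspot").itertuples(index=False)])
        assert peakset_overlap_fraction(a, b) == pytest.approx(
            brute_force_overlap_fraction(a, b))


class TestFoldEnrichment:
    def test_identical_tracks_give_unity(self):
        t = _track({"chr1": [5, 5, 5, 5, 5, 5, 5, 5, 5, 5]})
        fe = fold_enrichment(t, t, [("chr1", 0, 50)])
        assert fe[0] == pytest.approx(1.0)

    def test_depth_normalized_doubling(self):
        chip = _track({"chr1": [20, 20, 10, 10]})  # window holds 2x its share
        unt = _track({"chr1": [10, 10, 10, 10]})
        fe = fold_enrichment(chip, unt, [("chr1", 0, 20)], pseudocount=0.0)
        assert fe[0] == pytest.approx((40 / 60) / (20 / 40))

    def test_pseudocount_prevents_division_error(self):
        chip = _track({"chr1": [4, 0]})
        unt = _track({"chr1": [4, 0]})
        fe = fold_enrichment(chip, unt, [("chr1", 10, 20)], pseudocount=0.5)
        assert np.isfinite(fe[0])

    def test_out_of_bounds_window_rejected(self):
        t = _track({"chr1": [1, 1]})
        with pytest.raises(ValueError, match="bounds"):
            fold_enrichment(t, t, [("chr1", 0, 500)])


class TestMetaprofile:
    def test_symmetric_bump_profile(self):
        v = np.zeros(1000)
        v[490:510] = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 10, 9, 8, 7, 6, 5, 4, 3, 2, 1]
        track = _track({"chr1": v})
        prof = metaprofile(track, [("chr1", 5000)], flank=500)
        assert len(prof) == 100
        assert abs(int(np.argmax(prof)) - 50) <= 1
        np.testing.assert_allclose(prof[:49], prof[51:][::-1], atol=1e-12)

    def test_duplicate_centers_idempotent(self):
        rng = np.random.default_rng(5)
        track = _track({"chr1": rng.poisson(3, 1000)})
        one = metaprofile(track, [("chr1", 5000)])
        two = metaprofile(track, [("chr1", 5000), ("chr1", 5000)])
        np.testing.assert_array_equal(one, two)

    def test_clipped_windows_dropped_and_error_when_none(self):
        track = _track({"chr1": np.ones(20)})
        with pytest.raises(ValueError, match="centers"):
            metaprofile(track, [("chr1", 10)], flank=500)
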