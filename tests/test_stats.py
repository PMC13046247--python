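"""Comparative statistics: rank-sum test, density regression, classification,
SNP density, crossover co-occupancy, qPCR normalization, centromere distance."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from calchip import (FeatureSet, MappedReadSet, PeakSet, QPCRMeasurement,
                     centromere_distance, classify_hotspot_binding,
                     crossover_cooccupancy, density_by_chromosome,
                     make_genome_layout, pearson_correlation, plant_snps,
                     qpcr_enrichment, snp_density_analysis, wilcoxon_rank_sum)
from calchip.simulate import CrossoverSet, SNPMap


def enumeration_ranksum_p(a, b):
    """Independent oracle: two-sided p by enumerating every rank assignment."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in a)
    n, n1 = len(pooled), len(a)
    all_ranks = list(range(1, n + 1))
    sums = [sum(c) for c in itertools.combinations(all_ranks, n1)]
    total = len(sums)
    cdf = sum(s <= w_obs for s in sums) / total
    sf = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxonRankSum:
    def test_two_vs_two_exact(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_not_significant(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0] * 5, [1.0, 2.0, 3.0] * 5)
        assert p > 0.9

    def test_exact_matches_enumeration_on_random_small_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 10 - n1 + 1)) if n1 < 9 else 1
            vals = rng.permutation(100)[: n1 + n2].astype(float)
            a, b = vals[:n1], vals[n1:]
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(enumeration_ranksum_p(list(a), list(b)))

    def test_approximation_close_to_exact_at_12_vs_12(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.permutation(1000)[:24].astype(float)
            a, b = vals[:12], vals[12:]
            _, p_exact = wilcoxon_rank_sum(a, b, mode="exact")
            _, p_approx = wilcoxon_rank_sum(a, b, mode="approx")
            assert abs(p_exact - p_approx) <= 0.01

    def test_agrees_with_library_implementation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        b = rng.normal(0.5, size=40)
        _, p = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, use_continuity=True).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_mode_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            wilcoxon_rank_sum([1, 1], [2, 3], mode="exact")


class TestDensityByChromosome:
    def _reads(self, positions, chrom="chr1"):
        n = len(positions)
        return MappedReadSet.from_arrays(
            "s", [chrom] * n, positions, ["+"] * n, ["target_unique"] * n)

    def test_uniform_density_arithmetic(self):
        layout = make_genome_layout(1, [1_000_000])
        rs = self._reads(list(range(0, 1_000_000, 1000)))  # 1000 reads
        out = density_by_chromosome(rs, layout, total_mapped=1_000_000)
        assert out["density_rpm_per_kb"].iloc[0] == pytest.approx(1.0)

    def test_reads_inside_exclusion_discarded(self):
        layout = make_genome_layout(1, [1_000_000],
                                    exclusions=[("chr1", 0, 500_000)])
        rs = self._reads([100, 200, 300])
        out = density_by_chromosome(rs, layout)
        assert out["reads"].iloc[0] == 0
        assert out["usable_length"].iloc[0] == 500_000

    def test_exclusion_density_hand_computed(self):
        # 8 reads on 1 Mb, 2 inside a 200-kb exclusion: 6 reads / 0.8 Mb
        layout = make_genome_layout(1, [1_000_000],
                                    exclusions=[("chr1", 400_000, 600_000)])
        rs = self._reads([10, 20, 30, 450_000, 500_000, 700_000, 800_000, 900_000])
        out = density_by_chromosome(rs, layout, total_mapped=8)
        expected = (6 / 8 * 1e6) / 800.0
        assert out["density_rpm_per_kb"].iloc[0] == pytest.approx(expected)

    def test_zero_total_mapped_rejected(self):
        layout = make_genome_layout(1, [1000])
        with pytest.raises(ValueError):
            density_by_chromosome(self._reads([1]), layout, total_mapped=0)


class TestPearsonCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_matches_hand_formula_on_five_points(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 7])
        r, _ = pearson_correlation(x, y)
        # independent route: direct product-moment formula
        hand = (np.sum((x - x.mean()) * (y - y.mean()))
                / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(hand)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(1000):
            x = rng.normal(size=16)
            y = rng.normal(size=16)
            ps.append(pearson_correlation(x, y)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [3, 4])


class TestClassifyHotspotBinding:
    def _hotspots(self):
        return FeatureSet.from_records([
            ("chr1", 100, 700, "hotspot", 10.0, "h0"),
            ("chr1", 2000, 2600, "hotspot", 100.0, "h1"),
            ("chr1", 4000, 4600, "hotspot", 1000.0, "h2"),
            ("chr1", 6000, 6600, "hotspot", 500.0, "h3"),
        ])

    def test_partition_and_both_class(self):
        peaks_a = PeakSet.from_intervals([("chr1", 0, 800), ("chr1", 2100, 2200)])
        peaks_b = PeakSet.from_intervals([("chr1", 2500, 2700), ("chr1", 4100, 4200)])
        classes, _ = classify_hotspot_binding(self._hotspots(), peaks_a, peaks_b)
        by_name = classes.set_index("name")["binding_class"]
        assert by_name["h0"] == "A_only"
        assert by_name["h1"] == "both"
        assert by_name["h2"] == "B_only"
        assert by_name["h3"] == "neither"
        assert len(classes) == 4

    def test_comparison_reports_medians_and_p(self):
        peaks_a = PeakSet.from_intervals([("chr1", 100, 700)])
        peaks_b = PeakSet.from_intervals([("chr1", 4000, 4600)])
        _, comp = classify_hotspot_binding(self._hotspots(), peaks_a, peaks_b)
        assert comp["defined"]
        assert comp["median_A_only"] == 10.0
        assert comp["median_B_only"] == 1000.0

    def test_undefined_comparison_reported(self):
        empty = PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "summit",
                                              "p_value", "q_value", "label"]))
        _, comp = classify_hotspot_binding(self._hotspots(), empty, empty)
        assert not comp["defined"]


class TestSnpDensityAnalysis:
    def test_per_peak_density_arithmetic(self):
        layout = make_genome_layout(1, [100_000])
        snps = SNPMap({"chr1": np.array([10_100, 10_400, 10_700, 10_900])})
        peaks = PeakSet.from_intervals([("chr1", 10_000, 11_000)])
        res = snp_density_analysis(snps, peaks, layout)
        assert res["peak_density"][0] == pytest.approx(4.0)

    def test_genome_stats_from_tiles(self):
        layout = make_genome_layout(1, [100_000])
        snps = plant_snps(layout, 4.0, seed=9)
        peaks = PeakSet.from_intervals([("chr1", 5_000, 6_000)])
        res = snp_density_analysis(snps, peaks, layout)
        assert abs(res["genome_mean"] - 4.0) < 1.0

    def test_depleted_peaks_detected(self):
        layout = make_genome_layout(1, [500_000])
        peaks = PeakSet.from_intervals(
            [("chr1", i * 5_000, i * 5_000 + 800) for i in range(50)])
        regions = [(r.chrom, r.start, r.end, 0.0)
                   for r in peaks.df.itertuples(index=False)]
        snps = plant_snps(layout, regions, seed=10, base_density=5.0)
        res = snp_density_analysis(snps, peaks, layout, seed=1)
        assert res["p_value"] < 0.01
        assert res["peak_mean"] < res["genome_mean"]


class TestCrossoverCooccupancy:
    def test_all_inside_shared_peaks(self):
        co = CrossoverSet(2, pd.DataFrame(
            {"tetrad_id": [0, 1], "chrom": ["chr1", "chr1"],
             "midpoint": [5_000, 5_200]}))
        shared = PeakSet.from_intervals([("chr1", 4_000, 6_500)])
        frac = crossover_cooccupancy(co, shared, shared, site_window=2000)
        assert frac["both"] == 1.0

    def test_empty_peaks_all_neither(self):
        co = CrossoverSet(1, pd.DataFrame(
            {"tetrad_id": [0], "chrom": ["chr1"], "midpoint": [5_000]}))
        empty = PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "summit",
                                              "p_value", "q_value", "label"]))
        frac = crossover_cooccupancy(co, empty, empty)
        assert frac["neither"] == 1.0

    def test_toy_set_matches_hand_classification(self):
        mids = [1_000, 3_000, 5_000, 7_000, 9_000, 11_000, 13_000, 15_000,
                17_000, 19_000]
        co = CrossoverSet(1, pd.DataFrame(
            {"tetrad_id": [0] * 10, "chrom": ["chr1"] * 10, "midpoint": mids}))
        peaks_a = PeakSet.from_intervals([("chr1", 500, 1_500),
                                          ("chr1", 4_500, 5_500),
                                          ("chr1", 8_500, 9_500)])
        peaks_b = PeakSet.from_intervals([("chr1", 4_500, 5_500),
                                          ("chr1", 12_500, 13_500)])
        frac = crossover_cooccupancy(co, peaks_a, peaks_b, site_window=1000)
        # hand labels: 1000->A, 5000->both, 9000->A, 13000->B, rest neither
        assert frac == {"both": 0.1, "A_only": 0.2, "B_only": 0.1, "neither": 0.6}
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_empty_crossovers_rejected(self):
        co = CrossoverSet(0, pd.DataFrame(columns=["tetrad_id", "chrom", "midpoint"]))
        peaks = PeakSet.from_intervals([("chr1", 0, 100)])
        with pytest.raises(ValueError):
            crossover_cooccupancy(co, peaks, peaks)


class TestQpcrEnrichment:
    def _measurements(self, tagged_scale=1.0):
        out = []
        for locus in ("cold", "hot1", "axis1"):
            scale = tagged_scale if locus == "hot1" else 1.0
            out.append(QPCRMeasurement(locus, "tagged", 2.0 * scale, 1.0))
            out.append(QPCRMeasurement(locus, "untagged", 2.0, 1.0))
        return out

    def test_all_equal_ratios_give_unity(self):
        fe = qpcr_enrichment(self._measurements(), "cold")
        assert (fe["fold_enrichment"] == 1.0).all()

    def test_doubled_tagged_ratio_doubles_fe(self):
        fe = qpcr_enrichment(self._measurements(tagged_scale=2.0), "cold")
        assert fe.set_index("locus").loc["hot1", "fold_enrichment"] == 2.0

    def test_coldspot_self_normalizes_to_one(self):
        fe = qpcr_enrichment(self._measurements(tagged_scale=3.0), "cold")
        assert fe.set_index("locus").loc["cold", "fold_enrichment"] == 1.0

    def test_input_order_irrelevant(self):
        m = self._measurements(tagged_scale=2.0)
        a = qpcr_enrichment(m, "cold")
        b = qpcr_enrichment(list(reversed(m)), "cold")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_untagged_rejected(self):
        m = [QPCRMeasurement("cold", "tagged", 1.0, 1.0),
             QPCRMeasurement("cold", "untagged", 1.0, 1.0),
             QPCRMeasurement("hot1", "tagged", 1.0, 1.0)]
        with pytest.raises(ValueError, match="untagged"):
            qpcr_enrichment(m, "cold")

    def test_nonpositive_quantity_rejected(self):
        with pytest.raises(ValueError):
            QPCRMeasurement("x", "tagged", 0.0, 1.0)


class TestCentromereDistance:
    def _features(self):
        return FeatureSet.from_records([
            ("chr1", 100_000, 100_120, "centromere", None, "cen1"),
            ("chr1", 100_000 - 60, 100_000 + 180, "hotspot", 5.0, "at_cen"),
            ("chr1", 200_000, 200_600, "hotspot", 5.0, "far1"),
            ("chr1", 210_000, 210_600, "hotspot", 5.0, "far2"),
            ("chr1", 101_000, 101_600, "hotspot", 5.0, "near1"),
            ("chr1", 102_000, 102_600, "hotspot", 5.0, "near2"),
        ])

    def test_feature_at_centromere_has_zero_distance(self):
        dist, _ = centromere_distance(self._features(), {"at_cen": "g1"})
        assert dist["distance_bp"].iloc[0] == 0

    def test_separated_groups_compared(self):
        labels = {"near1": "near", "near2": "near", "at_cen": "near",
                  "far1": "far", "far2": "far"}
        dist, comp = centromere_distance(self._features(), labels)
        assert comp["defined"]
        assert comp["median_near"] < comp["median_far"]

    def test_missing_centromere_rejected(self):
        features = FeatureSet.from_records(
            [("chr2", 0, 600, "hotspot", 1.0, "h")])
        with pytest.raises(ValueError, match="centromere"):
            centromere_distance(features, {"h": "g1"})
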