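"""Synthetic-data generator: layouts, planted features, reads, SNPs, crossovers."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from calchip import (FeatureSet, OccupancyModel, make_genome_layout,
                     plant_features, plant_snps, simulate_crossovers,
                     simulate_experiment, yeast_like_layout)
from calchip.simulate import default_strength_sampler


class TestGenomeLayout:
    def test_total_size_is_sum_of_lengths(self):
        layout = make_genome_layout(2, [1_000_000, 500_000])
        assert layout.total_size == 1_500_000

    def test_rdna_style_exclusion_accepted(self):
        layout = make_genome_layout(
            1, [600_000], exclusions=[("chr1", 451_417, 489_465)])
        assert layout.excluded_bp("chr1") == 489_465 - 451_417
        assert layout.usable_length("chr1") == 600_000 - 38_048

    def test_yeast_layout_carries_rdna_exclusion(self):
        layout = yeast_like_layout()
        assert layout.exclusions_on("chrXII") == [(451_417, 489_465)]
        assert len(layout.chrom_names) == 16

    @pytest.mark.parametrize("lengths", [[0], [-5]])
    def test_nonpositive_length_rejected(self, lengths):
        with pytest.raises(ValueError, match="length"):
            make_genome_layout(1, lengths)

    def test_out_of_bounds_exclusion_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            make_genome_layout(1, [1000], exclusions=[("chr1", 500, 2000)])

    def test_overlapping_exclusions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_genome_layout(
                1, [10_000], exclusions=[("chr1", 0, 500), ("chr1", 400, 900)])


class TestPlantFeatures:
    def test_requested_class_counts(self):
        layout = make_genome_layout(2, [500_000, 500_000])
        fs = plant_features(layout, n_hotspots=25, n_axis=5, n_centromere=2,
                            n_coldspots=25, seed=0)
        counts = fs.class_counts()
        assert counts["hotspot"] == 25 and counts["coldspot"] == 25
        assert counts["axis"] == 5 and counts["centromere"] == 2

    def test_identical_seed_identical_output(self, layout):
        a = plant_features(layout, 10, 5, 2, 5, seed=42)
        b = plant_features(layout, 10, 5, 2, 5, seed=42)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_strength_sampler_support_positive(self):
        rng = np.random.default_rng(0)
        draws = default_strength_sampler(rng, 1000)
        assert (draws > 0).all()

    def test_min_gap_respected_within_class(self, features):
        for fclass in ("hotspot", "axis", "coldspot"):
            df = features.of_class(fclass)
            for chrom, grp in df.groupby("chrom"):
                g = grp.sort_values("start")
                gaps = g["start"].to_numpy()[1:] - g["end"].to_numpy()[:-1]
                assert (gaps >= 500).all()

    def test_error_when_features_do_not_fit(self):
        layout = make_genome_layout(1, [5_000])
        with pytest.raises(ValueError, match="fit"):
            plant_features(layout, n_hotspots=50, n_axis=0, n_centromere=0,
                           n_coldspots=0, min_gap=1000, seed=0)

    def test_more_centromeres_than_chromosomes_rejected(self, layout):
        with pytest.raises(ValueError, match="centromere"):
            plant_features(layout, 1, 1, 5, 1, seed=0)


class TestSimulateExperiment:
    def test_status_counts_conserve_total(self, experiment):
        for sample in experiment.samples:
            assert sum(sample.status_counts().values()) == 60_000

    def test_same_seed_identical_read_sets(self, layout, features):
        model = OccupancyModel()
        a = simulate_experiment(layout, features, model, 5_000, seed=9)
        b = simulate_experiment(layout, features, model, 5_000, seed=9)
        for s1, s2 in zip(a.samples, b.samples):
            pd.testing.assert_frame_equal(s1.df, s2.df)

    def test_spike_fraction_realized(self, experiment):
        for sample in experiment.samples:
            frac = sample.status_counts()["spike_unique"] / 60_000
            assert abs(frac - 0.09) < 0.01

    def test_uniform_model_gives_uniform_positions(self):
        """With all enrichment multipliers at 1 the target positions are uniform."""
        layout = make_genome_layout(1, [1_000_000])
        features = FeatureSet.from_records(
            [("chr1", 10_000, 10_600, "hotspot", 50.0)])
        model = OccupancyModel(enrichment={
            "hotspot": 1.0, "axis": 1.0, "centromere": 1.0, "coldspot": 1.0})
        exp = simulate_experiment(layout, features, model, 100_000,
                                  samples=(("chip", "chip"),), seed=5)
        pos = exp.samples[0].target_unique()["pos"].to_numpy()
        # interior 10-kb bins (edge bins lose reads to clipping of the 5' jitter)
        counts, _ = np.histogram(pos, bins=np.arange(10_000, 1_000_000, 10_000))
        stat, p = sps.chisquare(counts)
        assert p > 0.01

    def test_planted_enrichment_recovered(self):
        """Mean read density in 10x hotspot windows ~ 10x background windows."""
        layout = make_genome_layout(1, [1_000_000])
        records = [("chr1", 20_000 + i * 45_000, 22_000 + i * 45_000,
                    "hotspot", 100.0) for i in range(20)]
        features = FeatureSet.from_records(records)
        model = OccupancyModel(enrichment={
            "hotspot": 10.0, "axis": 1.0, "centromere": 1.0, "coldspot": 1.0})
        exp = simulate_experiment(layout, features, model, 100_000,
                                  samples=(("chip", "chip"),), seed=6)
        pos = np.sort(exp.samples[0].target_unique()["pos"].to_numpy())
        hot = sum(np.searchsorted(pos, e) - np.searchsorted(pos, s)
                  for _, s, e, _, _ in records)
        bg = sum(np.searchsorted(pos, e + 5_000) - np.searchsorted(pos, s + 5_000)
                 for _, s, e, _, _ in records)
        assert abs(hot / bg - 10.0) < 2.0

    def test_untagged_sample_sees_no_enrichment(self, experiment, features):
        unt = experiment.sample("untagged")
        pos = np.sort(unt.target_unique()["pos"].to_numpy())
        gt = experiment.ground_truth
        rows = gt[(gt["sample_id"] == "untagged") & (gt["kind"] == "component")
                  & (gt["name"] != "background")]
        assert (rows["expected_reads"] == 0).all()
        assert pos.size > 0

    def test_ground_truth_rate_recovery(self, experiment):
        """Realized component counts sit within 4 sigma of expectations."""
        gt = experiment.ground_truth
        comp = gt[(gt["kind"] == "component") & (gt["expected_reads"] >= 10)]
        z = (comp["realized_reads"] - comp["expected_reads"]) / np.sqrt(
            comp["expected_reads"])
        assert (z.abs() < 4).all()

    def test_empty_features_with_enrichment_rejected(self, layout):
        empty = FeatureSet(pd.DataFrame(
            columns=["chrom", "start", "end", "feature_class", "strength", "name"]))
        with pytest.raises(ValueError, match="empty feature set"):
            simulate_experiment(layout, empty, OccupancyModel(), 100, seed=0)

    def test_invalid_sample_spec_rejected(self, layout, features):
        with pytest.raises(ValueError, match="role"):
            simulate_experiment(layout, features, OccupancyModel(), 100,
                                samples=(("x", "input"),), seed=0)

    @pytest.mark.parametrize("field,value", [
        ("background_rate", 0.0), ("spike_fraction", 1.5), ("ambiguous_rate", -0.1),
    ])
    def test_invalid_model_rejected(self, field, value):
        with pytest.raises(ValueError):
            OccupancyModel(**{field: value})


class TestPlantSnps:
    def test_zero_density_empty_map(self, layout):
        snps = plant_snps(layout, 0.0, seed=1)
        assert snps.n_snps == 0

    def test_poisson_count_within_3_sigma(self):
        layout = make_genome_layout(1, [100_000])
        snps = plant_snps(layout, 4.0, seed=2)
        assert abs(snps.n_snps - 400) <= 3 * np.sqrt(400)

    def test_same_seed_identical_map(self, layout):
        a = plant_snps(layout, 4.0, seed=7)
        b = plant_snps(layout, 4.0, seed=7)
        for chrom in a.positions:
            np.testing.assert_array_equal(a.positions[chrom], b.positions[chrom])

    def test_positions_unique_and_sorted(self, layout):
        snps = plant_snps(layout, 10.0, seed=3)
        for pos in snps.positions.values():
            assert (np.diff(pos) > 0).all()

    def test_negative_density_rejected(self, layout):
        with pytest.raises(ValueError, match="negative"):
            plant_snps(layout, -1.0, seed=0)

    def test_region_profile_densities(self):
        layout = make_genome_layout(1, [200_000])
        snps = plant_snps(layout, [("chr1", 0, 100_000, 8.0)], seed=4,
                          base_density=1.0)
        in_region = snps.count_in("chr1", 0, 100_000)
        outside = snps.count_in("chr1", 100_000, 200_000)
        assert abs(in_region - 800) <= 3 * np.sqrt(800)
        assert abs(outside - 100) <= 3 * np.sqrt(100)


class TestSimulateCrossovers:
    def test_zero_tetrads_empty(self, layout, features):
        co = simulate_crossovers(layout, features, 0, seed=0)
        assert len(co.df) == 0 and co.n_tetrads == 0

    def test_negative_tetrads_rejected(self, layout, features):
        with pytest.raises(ValueError):
            simulate_crossovers(layout, features, -1, seed=0)

    def test_66_tetrads_recorded(self, layout, features):
        co = simulate_crossovers(layout, features, 66, seed=0)
        assert co.n_tetrads == 66
        assert (co.df["tetrad_id"] < 66).all()

    def test_strength_weighting_prefers_strong_hotspots(self, layout, features):
        co = simulate_crossovers(layout, features, 1500, hotspot_weighting=1.0,
                                 seed=5, uniform_fraction=0.0)
        hot = features.hotspots.sort_values("strength")
        deciles = max(1, len(hot) // 10)
        bottom = hot.head(deciles)
        top = hot.tail(deciles)

        def hits(rows):
            n = 0
            for r in rows.itertuples(index=False):
                mid = (r.start + r.end) // 2
                n += ((co.df["chrom"] == r.chrom)
                      & (co.df["midpoint"] == mid)).sum()
            return int(n)

        k_top, k_bot = hits(top), hits(bottom)
        res = sps.binomtest(k_top, k_top + k_bot, 0.5, alternative="greater")
        assert res.pvalue < 0.05

    def test_midpoints_within_bounds(self, layout, features):
        co = simulate_crossovers(layout, features, 30, seed=8)
        for chrom, grp in co.df.groupby("chrom"):
            assert (grp["midpoint"] < layout.length_of(str(chrom))).all()
            assert (grp["midpoint"] >= 0).all()
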