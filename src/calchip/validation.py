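"""Standard validation experiments for the pipeline.

Each function sets up a seeded synthetic experiment embodying the study
conditions the pipeline is meant to handle (spike-in depth differences,
planted enrichment, occupancy/strength coupling, SNP-density structure),
runs the relevant pipeline stages from scratch, and measures how well the
known ground truth is recovered. They are used by the test suite and by
``scripts/acceptance.py``.

Problem sizes are desk-scale by design: a ~1.2-Mb four-chromosome genome with
realistic hotspot density (~170 hotspots/Mb genome-wide feature density) and
1-4x10^5 reads per library, except where a larger genome is the point (the
null false-positive experiment uses 10 Mb; the chromosome-size regression
uses the 16 real chromosome sizes).
"""
from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np

from .calibrate import bin_reads, calibrate, scale_sample
from .features import FeatureSet
from .genome import GenomeLayout, make_genome_layout, yeast_like_layout
from .peaks import PeakCallingParams, PeakSet, annotate_peaks, call_peaks
from .simulate import (DEFAULT_ENRICHMENT, OccupancyModel, expected_spike_fraction,
                       plant_features, plant_snps, simulate_experiment)
from .stats import (classify_hotspot_binding, density_by_chromosome,
                    pearson_correlation, snp_density_analysis, wilcoxon_rank_sum)
from .tracks import BinnedTrack

SPIKE_MIXING_RATIO = 0.1  # 1:10 spike:target cell mixture


def sub_seed(seed: int, tag: str) -> int:
    """Stable sub-seed below 2^31 derived from (seed, tag)."""
    return (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def _standard_layout() -> GenomeLayout:
    return make_genome_layout(4, [300_000] * 4)


def _standard_features(seed: int, n_hotspots: int = 120) -> FeatureSet:
    layout = _standard_layout()
    return plant_features(
        layout, n_hotspots=n_hotspots, n_axis=40, n_centromere=4,
        n_coldspots=25, min_gap=500, seed=seed,
    )


def _physical_model(layout, features, base: OccupancyModel) -> OccupancyModel:
    """Set the model's spike fraction from the physical 1:10 cell mixture."""
    f = expected_spike_fraction(layout, features, base, SPIKE_MIXING_RATIO)
    return replace(base, spike_fraction=f)


def _simulate_one(layout, features, model, n_reads, role, sample_id, seed):
    exp = simulate_experiment(
        layout, features, model, n_reads=n_reads,
        samples=((sample_id, role),), seed=seed,
    )
    return exp.samples[0]


# ---------------------------------------------------------------------------
# spike-in calibration recovery

def calibration_recovery(
    seed: int,
    n_reads: int = 200_000,
    depth_factor: int = 3,
    k_values: tuple[float, ...] = (0.5, 2.0, 5.0),
) -> dict:
    """Recover depth invariance and occupancy ratios from calibrated sums.

    A strong-IP occupancy model (hotspot 40x, axis 15x over background) is
    simulated against a shared untagged control. Two libraries with identical
    occupancy but ``depth_factor``-different read counts should give
    near-identical calibrated genome-wide sums; scaling the specific occupancy
    by k (with the spike fraction following the physical mixture) should scale
    the calibrated sum by k.
    """
    layout = _standard_layout()
    features = _standard_features(sub_seed(seed, "cal-features"))
    base = OccupancyModel(
        enrichment={"hotspot": 40.0, "axis": 15.0, "centromere": 10.0,
                    "coldspot": 1.0},
    )

    def occupancy_model(k: float) -> OccupancyModel:
        enr = {c: 1.0 + k * (m - 1.0) for c, m in base.enrichment.items()}
        m = replace(base, enrichment=enr)
        return _physical_model(layout, features, m)

    unt_model = _physical_model(layout, features, replace(base, enrichment={
        c: 1.0 for c in base.enrichment}))
    unt = _simulate_one(layout, features, unt_model, n_reads, "untagged",
                        "untagged", sub_seed(seed, "cal-unt"))
    unt_track, unt_sf = scale_sample(unt, layout)

    def calibrated_sum(k: float, depth: int, tag: str) -> float:
        model = occupancy_model(k)
        chip = _simulate_one(layout, features, model, depth, "chip",
                             f"chip_{tag}", sub_seed(seed, f"cal-{tag}"))
        track, sf = scale_sample(chip, layout)
        return calibrate(track, unt_track, sf, unt_sf).total()

    s_base = calibrated_sum(1.0, n_reads, "base")
    s_deep = calibrated_sum(1.0, n_reads * depth_factor, "deep")
    agreement_pct = abs(s_deep - s_base) / s_base * 100.0

    ratio_errors = {}
    for k in k_values:
        s_k = calibrated_sum(k, n_reads, f"k{k}")
        ratio = s_k / s_base
        ratio_errors[k] = abs(ratio - k) / k * 100.0
    return {
        "sum_base": s_base,
        "sum_deep": s_deep,
        "depth_agreement_pct": agreement_pct,
        "ratio_error_pct": ratio_errors,
        "n_reads": n_reads,
    }


# ---------------------------------------------------------------------------
# peak-caller operating characteristics

def _poisson_track(rng, layout, bin_size, mean) -> BinnedTrack:
    vals = {
        c: rng.poisson(mean, layout.n_bins(c, bin_size)).astype(float)
        for c in layout.chrom_names
    }
    return BinnedTrack(bin_size=bin_size, values=vals)


def caller_null_false_positives(
    seed: int, n_seeds: int = 20, background: float = 1.0
) -> dict:
    """Peaks called on a null 10-Mb genome (chip and control both Poisson).

    The nominal bound is 2 x n_bins x p_max merged regions per run.
    """
    layout = make_genome_layout(4, [2_500_000] * 4)
    params = PeakCallingParams()
    counts = []
    for i in range(n_seeds):
        rng = np.random.default_rng(sub_seed(seed, f"null-{i}"))
        chip = _poisson_track(rng, layout, 10, background)
        ctrl = _poisson_track(rng, layout, 10, background)
        counts.append(len(call_peaks(chip, ctrl, params, layout=layout)))
    n_bins = sum(layout.n_bins(c, 10) for c in layout.chrom_names)
    return {
        "peak_counts": counts,
        "max_peaks": max(counts),
        "nominal_bound": 2.0 * n_bins * params.p_max,
        "n_bins": n_bins,
    }


def caller_planted_recovery(
    seed: int,
    n_planted: int = 100,
    background: float = 2.0,
    fold: float = 10.0,
    width: int = 500,
) -> dict:
    """Recovery of planted fold-enriched 500-bp regions on a 10-Mb genome.

    A planted region counts as recovered when some called peak's span fully
    contains it.
    """
    layout = make_genome_layout(4, [2_500_000] * 4)
    bin_size = 10
    rng = np.random.default_rng(sub_seed(seed, "planted"))
    chip = _poisson_track(rng, layout, bin_size, background)
    ctrl = _poisson_track(rng, layout, bin_size, background)
    per_chrom = n_planted // len(layout.chrom_names)
    planted = []
    for chrom in layout.chrom_names:
        length = layout.length_of(chrom)
        spacing = length // (per_chrom + 1)
        for j in range(per_chrom):
            start = (j + 1) * spacing
            planted.append((chrom, start, start + width))
            # enrich every bin touching the interval so it is fully covered
            b0 = start // bin_size
            b1 = -(-(start + width) // bin_size)
            chip.values[chrom][b0:b1] = rng.poisson(background * fold, b1 - b0)
    peaks = call_peaks(chip, ctrl, PeakCallingParams(), layout=layout)
    recovered = 0
    for chrom, s, e in planted:
        sel = peaks.df[(peaks.df["chrom"] == chrom)
                       & (peaks.df["start"] <= s) & (peaks.df["end"] >= e)]
        recovered += int(len(sel) > 0)
    return {
        "n_planted": len(planted),
        "n_recovered": recovered,
        "recovery_fraction": recovered / len(planted),
        "n_peaks": len(peaks),
    }


# ---------------------------------------------------------------------------
# annotation oracle

def brute_force_annotation(peaks: PeakSet, features: FeatureSet) -> dict[str, int]:
    """All-pairs O(n*m) Venn classification, the independent oracle."""
    from .peaks import CLASS_LABELS
    ps = peaks.df[["chrom", "start", "end"]].to_numpy()
    counts: dict[str, int] = {}
    class_rows = {
        label: features.of_class(fclass)[["chrom", "start", "end"]].to_numpy()
        for fclass, label in CLASS_LABELS.items()
    }
    for chrom, start, end in ps:
        hit = []
        for label, rows in class_rows.items():
            m = (rows[:, 0] == chrom) & (rows[:, 1].astype(int) < end) \
                & (rows[:, 2].astype(int) > start)
            if m.any():
                hit.append(label)
        lab = "+".join(sorted(hit)) if hit else "Nil"
        counts[lab] = counts.get(lab, 0) + 1
    return counts


def brute_force_overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    bs = b.df[["chrom", "start", "end"]].to_numpy()
    hits = 0
    for chrom, start, end in a.df[["chrom", "start", "end"]].to_numpy():
        m = (bs[:, 0] == chrom) & (bs[:, 1].astype(int) < end) \
            & (bs[:, 2].astype(int) > start)
        hits += int(m.any())
    return hits / len(a)


def _random_interval_instance(rng, n_intervals: int):
    """Random peaks plus a random 3-class feature set (same-class non-overlap)."""
    chrom_len = 1_000_000
    layout = make_genome_layout(2, [chrom_len] * 2)
    chroms = [layout.chrom_names[i] for i in rng.integers(0, 2, n_intervals)]
    starts = rng.integers(0, chrom_len - 2_500, n_intervals)
    widths = rng.integers(1, 2_500, n_intervals)
    peaks = PeakSet.from_intervals(
        list(zip(chroms, starts, starts + widths))
    )
    step = 2_600
    slots_per_chrom = chrom_len // step
    records = []
    n_per_class = n_intervals // 3
    for fclass in ("hotspot", "axis", "centromere"):
        for chrom in layout.chrom_names:
            slots = rng.choice(slots_per_chrom, size=n_per_class // 2, replace=False)
            for s in np.sort(slots):
                start = int(s) * step + int(rng.integers(0, 50))
                width = int(rng.integers(50, step - 60))
                records.append((
                    chrom, start, start + width, fclass,
                    1.0 if fclass == "hotspot" else None,
                ))
    return peaks, FeatureSet.from_records(records)


def annotation_oracle_check(
    seed: int, n_instances: int = 100, n_intervals: int = 1000
) -> dict:
    """Compare fast annotation and overlap fraction against the brute force.

    Returns the number of mismatching instances (0 expected) and the largest
    Venn-partition deficit (category counts must sum to the peak count).
    """
    mismatches = 0
    partition_deficit = 0
    overlap_mismatches = 0
    for i in range(n_instances):
        rng = np.random.default_rng(sub_seed(seed, f"ann-{i}"))
        peaks, features = _random_interval_instance(rng, n_intervals)
        _, fast = annotate_peaks(peaks, features)
        slow = brute_force_annotation(peaks, features)
        if fast != slow:
            mismatches += 1
        partition_deficit = max(
            partition_deficit, abs(sum(fast.values()) - len(peaks))
        )
        other = PeakSet.from_intervals([
            (r.chrom, r.start, r.end)
            for r in features.of_class("axis").itertuples(index=False)
        ])
        from .peaks import peakset_overlap_fraction
        if abs(peakset_overlap_fraction(peaks, other)
               - brute_force_overlap_fraction(peaks, other)) > 1e-12:
            overlap_mismatches += 1
    return {
        "annotation_mismatches": mismatches,
        "overlap_mismatches": overlap_mismatches,
        "max_partition_deficit": partition_deficit,
        "n_instances": n_instances,
    }


# ---------------------------------------------------------------------------
# smoother oracle

def nadaraya_watson_oracle(
    values: np.ndarray, centers: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Full direct-summation Gaussian NW estimate (no truncation)."""
    sd = 0.25 * bandwidth / 0.6744897501960817
    d = centers[:, None] - centers[None, :]
    w = np.exp(-0.5 * (d / sd) ** 2)
    return (w * values[None, :]).sum(axis=1) / w.sum(axis=1)


def smoother_oracle_discrepancy(seed: int, n_bins: int = 1000) -> float:
    """Max |smooth() - direct summation| on a random 1000-bin track."""
    from .calibrate import smooth
    rng = np.random.default_rng(sub_seed(seed, "smooth"))
    layout = make_genome_layout(1, [n_bins * 10])
    values = rng.normal(size=n_bins) * 5 + rng.poisson(3, n_bins)
    track = BinnedTrack(bin_size=10, values={"chr1": values}, state="calibrated")
    sm = smooth(track, bandwidth=1000.0, layout=layout)
    oracle = nadaraya_watson_oracle(values, track.bin_centers("chr1"), 1000.0)
    return float(np.max(np.abs(sm.values["chr1"] - oracle)))


# ---------------------------------------------------------------------------
# Wilcoxon calibration

def wilcoxon_type1_rate(
    seed: int, n_sims: int = 1000, n: int = 20, alpha: float = 0.05
) -> float:
    """Null rejection rate of the rank-sum test on equal normal samples."""
    rng = np.random.default_rng(sub_seed(seed, "wilcoxon-null"))
    rejections = 0
    for _ in range(n_sims):
        _, p = wilcoxon_rank_sum(rng.normal(size=n), rng.normal(size=n))
        rejections += int(p < alpha)
    return rejections / n_sims


# ---------------------------------------------------------------------------
# directional recovery (two proteins with opposite strength coupling)

def _pooled_chip(layout, features, model, n_reads, n_reps, seed_tag, seed) -> BinnedTrack:
    pooled = None
    for rep in range(n_reps):
        reads = _simulate_one(layout, features, model, n_reads, "chip",
                              f"{seed_tag}_rep{rep}", sub_seed(seed, f"{seed_tag}-{rep}"))
        t = bin_reads(reads, layout, strand_shift=175)
        if pooled is None:
            pooled = t
        else:
            for c in pooled.values:
                pooled.values[c] += t.values[c]
    return pooled


def directional_recovery_run(
    seed: int,
    n_hotspots: int = 200,
    coupling: float = 0.5,
    n_reads: int = 250_000,
) -> dict:
    """One seeded run of the two-protein hotspot-strength experiment.

    Protein A occupies hotspots with multiplier proportional to
    strength^(-coupling), protein B to strength^(+coupling); two replicates
    per protein are pooled and peaks called against a shared untagged control;
    hotspots are classified by overlap and A-specific vs B-specific strengths
    compared by rank-sum.
    """
    layout = _standard_layout()
    features = plant_features(
        layout, n_hotspots=n_hotspots, n_axis=40, n_centromere=4,
        n_coldspots=25, min_gap=500, seed=sub_seed(seed, "dir-features"),
    )
    model_a = _physical_model(layout, features,
                              OccupancyModel(strength_coupling=-coupling))
    model_b = _physical_model(layout, features,
                              OccupancyModel(strength_coupling=+coupling))
    model_u = _physical_model(layout, features, OccupancyModel(
        enrichment={c: 1.0 for c in DEFAULT_ENRICHMENT}))

    pooled_a = _pooled_chip(layout, features, model_a, n_reads, 2, "A", seed)
    pooled_b = _pooled_chip(layout, features, model_b, n_reads, 2, "B", seed)
    unt = bin_reads(
        _simulate_one(layout, features, model_u, n_reads, "untagged",
                      "untagged", sub_seed(seed, "dir-unt")),
        layout, strand_shift=175,
    )
    params = PeakCallingParams()
    peaks_a = call_peaks(pooled_a, unt, params, layout=layout)
    peaks_b = call_peaks(pooled_b, unt, params, layout=layout)
    _, comparison = classify_hotspot_binding(features, peaks_a, peaks_b)
    return comparison


def directional_recovery(seed: int, n_runs: int = 100, **kwargs) -> dict:
    """Repeat the two-protein experiment across seeded runs.

    Reports how often A-specific hotspots are significantly weaker than
    B-specific (p < 0.01), and whether the direction ever inverts.
    """
    n_significant = 0
    n_inverted = 0
    n_defined = 0
    for i in range(n_runs):
        comp = directional_recovery_run(sub_seed(seed, f"dir-{i}"), **kwargs)
        if not comp["defined"]:
            continue
        n_defined += 1
        weaker = comp["median_A_only"] < comp["median_B_only"]
        if weaker and comp["p_value"] < 0.01:
            n_significant += 1
        if (not weaker) and comp["p_value"] < 0.01:
            n_inverted += 1
    return {
        "n_runs": n_runs,
        "n_defined": n_defined,
        "n_significant": n_significant,
        "n_inverted": n_inverted,
    }


# ---------------------------------------------------------------------------
# SNP-density recovery

def _called_peaks_for_snp_run(seed: int):
    layout = _standard_layout()
    features = _standard_features(sub_seed(seed, "snp-features"))
    model = _physical_model(layout, features, OccupancyModel())
    model_u = _physical_model(layout, features, OccupancyModel(
        enrichment={c: 1.0 for c in DEFAULT_ENRICHMENT}))
    chip = bin_reads(
        _simulate_one(layout, features, model, 250_000, "chip", "chip",
                      sub_seed(seed, "snp-chip")),
        layout, strand_shift=175,
    )
    unt = bin_reads(
        _simulate_one(layout, features, model_u, 250_000, "untagged", "untagged",
                      sub_seed(seed, "snp-unt")),
        layout, strand_shift=175,
    )
    peaks = call_peaks(chip, unt, PeakCallingParams(), layout=layout)
    return layout, peaks


def snp_neutrality(seed: int, n_runs: int = 100, density: float = 4.0) -> dict:
    """Uniform SNPs + SNP-independent peaks: the comparison should be null.

    Counts runs where the peak-mean SNP density sits within 3 SE of the
    genome mean and the rank-sum test is non-significant at 0.05.
    """
    n_within = 0
    n_nonsig = 0
    for i in range(n_runs):
        run_seed = sub_seed(seed, f"snpnull-{i}")
        layout, peaks = _called_peaks_for_snp_run(run_seed)
        snps = plant_snps(layout, density, seed=sub_seed(run_seed, "snps"))
        res = snp_density_analysis(snps, peaks, layout,
                                   seed=sub_seed(run_seed, "bg"))
        if abs(res["peak_mean"] - res["genome_mean"]) <= 3 * res["mean_diff_se"]:
            n_within += 1
        if res["p_value"] > 0.05:
            n_nonsig += 1
    return {"n_runs": n_runs, "n_within_3se": n_within, "n_nonsignificant": n_nonsig}


def snp_depletion(
    seed: int, n_runs: int = 100, density: float = 4.0, desert_density: float = 0.5
) -> dict:
    """SNP-avoiding peaks: planted SNP deserts at peaks must be detected."""
    n_detected = 0
    for i in range(n_runs):
        run_seed = sub_seed(seed, f"snpdes-{i}")
        layout, peaks = _called_peaks_for_snp_run(run_seed)
        regions = [
            (row.chrom, row.start, row.end, desert_density)
            for row in peaks.df.itertuples(index=False)
        ]
        snps = plant_snps(layout, regions, seed=sub_seed(run_seed, "snps"),
                          base_density=density)
        res = snp_density_analysis(snps, peaks, layout,
                                   seed=sub_seed(run_seed, "bg"))
        if res["p_value"] < 0.05 and res["peak_mean"] < res["genome_mean"]:
            n_detected += 1
    return {"n_runs": n_runs, "n_detected": n_detected}


# ---------------------------------------------------------------------------
# chromosome-size density pattern

def equal_hotspots_per_chromosome(
    layout: GenomeLayout, per_chrom: int, seed: int, width: int = 300
) -> FeatureSet:
    """Same hotspot count on every chromosome => hotspot density ~ 1/size."""
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for chrom in layout.chrom_names:
        length = layout.length_of(chrom)
        excl = layout.exclusions_on(chrom)
        spacing = length // (per_chrom + 1)
        for j in range(per_chrom):
            start = (j + 1) * spacing + int(rng.integers(-spacing // 4, spacing // 4))
            start = max(0, min(start, length - width))
            for s, e in excl:  # shift a hotspot landing in an exclusion past it
                if start < e and start + width > s:
                    start = e if e + width <= length else s - width
            records.append((chrom, start, start + width, "hotspot",
                            float(rng.lognormal(5.0, 1.2)), f"hotspot_{i}"))
            i += 1
    return FeatureSet.from_records(records)


def size_density_pattern(
    seed: int, per_chrom: int = 8, n_reads: int = 400_000, enrichment: float = 12.0
) -> dict:
    """Pearson correlation of chromosome size vs RPM/kb under 1/size density.

    Uses the 16 real yeast chromosome sizes (rDNA excluded) and equal hotspot
    counts per chromosome; reports the correlation with all chromosomes and
    after dropping the three smallest.
    """
    layout = yeast_like_layout()
    features = equal_hotspots_per_chromosome(
        layout, per_chrom, sub_seed(seed, "size-features"))
    model = _physical_model(layout, features, OccupancyModel(
        enrichment={"hotspot": enrichment, "axis": 1.0, "centromere": 1.0,
                    "coldspot": 1.0}))
    reads = _simulate_one(layout, features, model, n_reads, "chip", "chip",
                          sub_seed(seed, "size-chip"))
    dens = density_by_chromosome(reads, layout)
    x = dens["length"].to_numpy(dtype=float)
    y = dens["density_rpm_per_kb"].to_numpy(dtype=float)
    r_all, p_all = pearson_correlation(x, y)
    keep = np.argsort(x)[3:]  # drop the three smallest chromosomes
    r_big, p_big = pearson_correlation(x[keep], y[keep])
    return {
        "r_all": r_all, "p_all": p_all,
        "r_without_smallest": r_big, "p_without_smallest": p_big,
        "densities": dens,
    }
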