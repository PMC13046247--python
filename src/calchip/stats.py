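"""Comparative statistics on binding profiles and genomic features.

Implements the downstream analyses of the calibrated ChIP-seq pipeline:
chromosome-size vs read-density regression (RPM/kb, with rDNA-style
exclusions), rank-sum comparisons, hotspot binding classification between two
proteins, SNP-density (heterozygosity) analysis of peaks, crossover
co-occupancy, qPCR fold-enrichment normalization, and centromere-distance
summaries.

The Wilcoxon rank-sum test is implemented in-package (exact enumeration for
small tie-free samples, tie- and continuity-corrected normal approximation
otherwise) because every headline comparison routes through it; tests hold it
against full enumeration and an independent library implementation.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureSet
from .genome import GenomeLayout
from .peaks import PeakSet, _interval_index, _overlaps, overlaps_any
from .reads import MappedReadSet
from .simulate import CrossoverSet, SNPMap
from .tracks import BinnedTrack

EXACT_WILCOXON_LIMIT = 12  # exact enumeration when n_a + n_b <= this and no ties


# ---------------------------------------------------------------------------
# rank-sum test

def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks and the tie-group sizes of the pooled sample."""
    ranks = sps.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def _exact_ranksum_distribution(n1: int, n: int) -> np.ndarray:
    """P(W = s) over subsets of size n1 of ranks 1..n; index = rank sum s."""
    max_sum = n1 * n
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(n1, r), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r > 0 else dp[k - 1]
    return dp[n1] / comb(n, n1)


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Returns ``(W, p)`` with W the rank sum of sample ``a`` in the pooled
    ranking (midranks under ties). The exact null distribution is enumerated
    when ``n_a + n_b <= 12`` and there are no ties; otherwise a normal
    approximation with tie and continuity corrections is used. ``mode`` can
    force ``"exact"`` (tie-free inputs only) or ``"approx"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks, tie_counts = _rank_with_ties(pooled)
    has_ties = (tie_counts > 1).any()
    w = float(ranks[:n1].sum())

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_WILCOXON_LIMIT
                                    and not has_ties)
    if use_exact:
        if has_ties:
            raise ValueError("exact enumeration requires tie-free samples")
        dist = _exact_ranksum_distribution(n1, n)
        w_int = int(round(w))
        cdf = dist[: w_int + 1].sum()
        sf = dist[w_int:].sum()
        return w, float(min(1.0, 2.0 * min(cdf, sf)))

    u = w - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0  # all observations identical
    diff = u - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# chromosome-size density regression

def density_by_chromosome(
    data: MappedReadSet | BinnedTrack,
    layout: GenomeLayout,
    total_mapped: int | None = None,
) -> pd.DataFrame:
    """Per-chromosome read density in RPM/kb, honouring layout exclusions.

    Reads falling inside an exclusion interval (e.g. the rDNA repeat locus)
    are discarded and the excluded bp are removed from the usable length.
    Density = (reads / total_mapped x 1e6) / (usable_length / 1000).
    ``total_mapped`` defaults to the genome-wide uniquely mapped read count
    (before exclusion).
    """
    reads_per_chrom: dict[str, float] = {}
    if isinstance(data, MappedReadSet):
        tu = data.target_unique()
        total = len(tu)
        for chrom in layout.chrom_names:
            pos = tu.loc[tu["chrom"] == chrom, "pos"].to_numpy()
            keep = np.ones(len(pos), dtype=bool)
            for s, e in layout.exclusions_on(chrom):
                keep &= ~((pos >= s) & (pos < e))
            reads_per_chrom[chrom] = float(keep.sum())
    elif isinstance(data, BinnedTrack):
        total = data.total()
        bs = data.bin_size
        for chrom in layout.chrom_names:
            v = data.values[chrom]
            kept = v.sum()
            for s, e in layout.exclusions_on(chrom):
                b0 = -(-s // bs)  # bins fully inside the exclusion
                b1 = e // bs
                if b1 > b0:
                    kept -= v[b0:b1].sum()
            reads_per_chrom[chrom] = float(kept)
    else:
        raise TypeError("data must be a MappedReadSet or BinnedTrack")

    if total_mapped is None:
        total_mapped = total
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")

    rows = []
    for chrom in layout.chrom_names:
        usable = layout.usable_length(chrom)
        reads = reads_per_chrom[chrom]
        density = (reads / total_mapped * 1e6) / (usable / 1000.0)
        rows.append((chrom, layout.length_of(chrom), usable, reads, density))
    return pd.DataFrame(
        rows, columns=["chrom", "length", "usable_length", "reads", "density_rpm_per_kb"]
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# hotspot binding classification (two proteins)

def classify_hotspot_binding(
    hotspots: FeatureSet, peaks_a: PeakSet, peaks_b: PeakSet
) -> tuple[pd.DataFrame, dict]:
    """Partition hotspots by >= 1 bp overlap with two peak sets.

    Classes: ``both``, ``A_only``, ``B_only``, ``neither``. The comparison
    reports median strengths of A-only vs B-only hotspots and their rank-sum
    test; it is flagged undefined when either specific class is empty.
    """
    hot = hotspots.hotspots
    if hot["strength"].isna().any():
        raise ValueError("hotspot strengths required")
    idx_a = _interval_index(peaks_a.df)
    idx_b = _interval_index(peaks_b.df)
    classes = []
    for row in hot.itertuples(index=False):
        in_a = _overlaps(idx_a, row.chrom, row.start, row.end)
        in_b = _overlaps(idx_b, row.chrom, row.start, row.end)
        classes.append(
            "both" if in_a and in_b else
            "A_only" if in_a else
            "B_only" if in_b else "neither"
        )
    out = hot[["chrom", "start", "end", "name", "strength"]].copy()
    out["binding_class"] = classes

    a_s = out.loc[out["binding_class"] == "A_only", "strength"].to_numpy()
    b_s = out.loc[out["binding_class"] == "B_only", "strength"].to_numpy()
    if len(a_s) == 0 or len(b_s) == 0:
        comparison = {
            "defined": False,
            "reason": "no hotspots specific to one of the proteins",
        }
    else:
        w, p = wilcoxon_rank_sum(a_s, b_s)
        comparison = {
            "defined": True,
            "median_A_only": float(np.median(a_s)),
            "median_B_only": float(np.median(b_s)),
            "n_A_only": int(len(a_s)),
            "n_B_only": int(len(b_s)),
            "W": w,
            "p_value": p,
        }
    return out, comparison


# ---------------------------------------------------------------------------
# SNP density (heterozygosity) analysis

def snp_density_analysis(
    snps: SNPMap,
    peaks: PeakSet,
    layout: GenomeLayout,
    tile_size: int = 1000,
    n_background: int = 2000,
    seed: int = 0,
) -> dict:
    """Compare SNP density inside peaks to the genome-wide background.

    Per-peak density is SNPs/kb within the peak span. Genome-wide mean and
    median densities are reported over non-overlapping ``tile_size`` tiles
    (full tiles only, tiles touching layout exclusions dropped), matching the
    per-kb unit of the headline summary numbers.

    The rank-sum test, however, compares peak densities against
    *width-matched* background windows (random positions, widths cycled from
    the peak widths themselves): the density of a sub-kilobase window is a
    mean-preserving spread of the 1-kb tile density, so ranking peaks against
    fixed 1-kb tiles is median-biased low even for a uniform SNP process,
    whereas the width-matched null is exact.
    """
    widths = peaks.widths()
    if (widths <= 0).any():
        raise ValueError("zero-width peak")
    peak_density = np.array([
        snps.density_per_kb(row.chrom, row.start, row.end)
        for row in peaks.df.itertuples(index=False)
    ])

    tile_parts = []
    for chrom in layout.chrom_names:
        n_tiles = layout.length_of(chrom) // tile_size
        if n_tiles == 0:
            continue
        edges = np.arange(n_tiles + 1, dtype=np.int64) * tile_size
        pos = snps.positions.get(chrom, np.empty(0, dtype=np.int64))
        counts = np.diff(np.searchsorted(pos, edges))
        keep = np.ones(n_tiles, dtype=bool)
        for s, e in layout.exclusions_on(chrom):
            keep &= ~((edges[:-1] < e) & (edges[1:] > s))
        tile_parts.append(counts[keep] / (tile_size / 1000.0))
    tile_density = np.concatenate(tile_parts) if tile_parts else np.empty(0)

    rng = np.random.default_rng(seed)
    bg_widths = widths[np.arange(n_background) % len(widths)]
    bg_density = np.empty(n_background)
    chrom_lens = np.array([layout.length_of(c) for c in layout.chrom_names],
                          dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    for i, bw in enumerate(bg_widths):
        while True:
            ci = rng.choice(len(chrom_p), p=chrom_p)
            chrom = layout.chrom_names[ci]
            limit = layout.length_of(chrom) - int(bw)
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            if any(start < e and start + bw > s
                   for s, e in layout.exclusions_on(chrom)):
                continue
            bg_density[i] = snps.density_per_kb(chrom, start, start + int(bw))
            break
    w, p = wilcoxon_rank_sum(peak_density, bg_density, mode="approx")
    se = float(np.sqrt(
        np.var(peak_density, ddof=1) / len(peak_density)
        + np.var(tile_density, ddof=1) / len(tile_density)
    )) if len(peak_density) > 1 and len(tile_density) > 1 else float("nan")
    return {
        "peak_density": peak_density,
        "tile_density": tile_density,
        "background_density": bg_density,
        "peak_mean": float(peak_density.mean()),
        "peak_median": float(np.median(peak_density)),
        "genome_mean": float(tile_density.mean()),
        "genome_median": float(np.median(tile_density)),
        "mean_diff_se": se,
        "W": w,
        "p_value": p,
    }


def binned_snp_counts(
    snps: SNPMap, layout: GenomeLayout, bin_size: int = 100
) -> BinnedTrack:
    """SNP counts per ``bin_size`` bin, as a track (display scaling is a writer option)."""
    vals = {}
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom, bin_size)
        pos = snps.positions.get(chrom, np.empty(0, dtype=np.int64))
        vals[chrom] = np.bincount(pos // bin_size, minlength=nb).astype(float)
    return BinnedTrack(bin_size=bin_size, values=vals, state="raw_counts")


# ---------------------------------------------------------------------------
# crossover co-occupancy

def crossover_cooccupancy(
    crossovers: CrossoverSet,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    site_window: int = 2000,
) -> dict:
    """Fractions of crossover sites occupied by protein A, B, both or neither.

    A crossover site is its midpoint +/- ``site_window``/2; occupancy is
    >= 1 bp overlap with the respective peak set. The four fractions sum to 1.
    """
    if len(crossovers.df) == 0:
        raise ValueError("empty crossover set")
    idx_a = _interval_index(peaks_a.df) if len(peaks_a) else {}
    idx_b = _interval_index(peaks_b.df) if len(peaks_b) else {}
    half = site_window // 2
    chroms = crossovers.df["chrom"].to_numpy()
    mids = crossovers.df["midpoint"].to_numpy(dtype=np.int64)
    starts = np.maximum(0, mids - half)
    ends = mids + half
    in_a = overlaps_any(idx_a, chroms, starts, ends)
    in_b = overlaps_any(idx_b, chroms, starts, ends)
    total = len(crossovers.df)
    return {
        "both": float((in_a & in_b).sum()) / total,
        "A_only": float((in_a & ~in_b).sum()) / total,
        "B_only": float((~in_a & in_b).sum()) / total,
        "neither": float((~in_a & ~in_b).sum()) / total,
    }


# ---------------------------------------------------------------------------
# qPCR normalization

@dataclass(frozen=True)
class QPCRMeasurement:
    """One qPCR quantification (linear units from a standard curve)."""

    locus: str
    strain: str  # "tagged" | "untagged"
    ip_quantity: float
    input_quantity: float

    def __post_init__(self):
        if self.strain not in ("tagged", "untagged"):
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.ip_quantity <= 0 or self.input_quantity <= 0:
            raise ValueError("qPCR quantities must be positive")


def qpcr_enrichment(
    measurements: list[QPCRMeasurement], coldspot_locus: str
) -> pd.DataFrame:
    """Input-, coldspot- and untagged-normalized fold enrichment per locus.

    ratio(locus, strain) = mean(ip/input) over that locus/strain's
    measurements; FE(locus) = [ratio(l,tagged)/ratio(cold,tagged)] /
    [ratio(l,untagged)/ratio(cold,untagged)]. The coldspot's FE is exactly 1.
    """
    ratios: dict[tuple[str, str], list[float]] = {}
    for m in measurements:
        ratios.setdefault((m.locus, m.strain), []).append(
            m.ip_quantity / m.input_quantity
        )
    loci = sorted({loc for loc, _ in ratios})
    if coldspot_locus not in loci:
        raise ValueError(f"no measurements for coldspot locus {coldspot_locus!r}")
    mean_ratio = {k: float(np.mean(v)) for k, v in ratios.items()}
    for loc in loci:
        for strain in ("tagged", "untagged"):
            if (loc, strain) not in mean_ratio:
                raise ValueError(f"missing {strain} measurement for locus {loc!r}")
    cold_t = mean_ratio[(coldspot_locus, "tagged")]
    cold_u = mean_ratio[(coldspot_locus, "untagged")]
    rows = [
        (loc,
         (mean_ratio[(loc, "tagged")] / cold_t)
         / (mean_ratio[(loc, "untagged")] / cold_u))
        for loc in loci
    ]
    return pd.DataFrame(rows, columns=["locus", "fold_enrichment"])


# ---------------------------------------------------------------------------
# centromere distance

def centromere_distance(
    features: FeatureSet, group_labels: dict[str, str]
) -> tuple[pd.DataFrame, dict]:
    """Distance of grouped features from their chromosome's centromere.

    ``group_labels`` maps feature names to group labels (two groups). The
    distance is |feature midpoint - centromere midpoint| in bp; groups are
    compared with the rank-sum test. Every chromosome hosting a grouped
    feature must carry exactly one centromere record.
    """
    cen = features.of_class("centromere")
    cen_mid: dict[str, int] = {}
    for row in cen.itertuples(index=False):
        if row.chrom in cen_mid:
            raise ValueError(f"multiple centromeres on {row.chrom}")
        cen_mid[row.chrom] = (row.start + row.end) // 2

    df = features.df[features.df["name"].isin(group_labels)]
    rows = []
    for row in df.itertuples(index=False):
        if row.chrom not in cen_mid:
            raise ValueError(f"chromosome {row.chrom} lacks a centromere record")
        mid = (row.start + row.end) // 2
        rows.append((row.name, row.chrom, group_labels[row.name],
                     abs(mid - cen_mid[row.chrom])))
    out = pd.DataFrame(rows, columns=["name", "chrom", "group", "distance_bp"])
    groups = sorted(out["group"].unique())
    if len(groups) == 2:
        g0 = out.loc[out["group"] == groups[0], "distance_bp"].to_numpy(dtype=float)
        g1 = out.loc[out["group"] == groups[1], "distance_bp"].to_numpy(dtype=float)
        w, p = wilcoxon_rank_sum(g0, g1)
        comparison = {
            "defined": True, "groups": groups, "W": w, "p_value": p,
            "median_" + groups[0]: float(np.median(g0)),
            "median_" + groups[1]: float(np.median(g1)),
        }
    else:
        comparison = {"defined": False,
                      "reason": f"need exactly 2 groups, got {len(groups)}"}
    return out, comparison
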