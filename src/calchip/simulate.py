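"""Seeded synthetic experiments with the statistical structure of spike-in
calibrated meiotic ChIP-seq.

The generator emulates, at the mapped-coordinate level, an experiment in which
tagged-protein ChIP and untagged-control libraries are sequenced from a
mixture of target-genome cells and spike-in cells of a related species at a
1:10 (spike:target) ratio, with chromatin fragmented to ~300-400 bp:

* a fraction of each library's reads maps uniquely to the spike genome
  (``spike_fraction``); a small fraction of target reads is flagged
  ambiguous or unmapped;
* tagged samples draw fragment midpoints from a mixture of uniform background
  and feature-centred enrichment, where a hotspot's rate multiplier couples to
  its strength (Spo11-oligo proxy) through ``strength_coupling`` and to local
  SNP density through ``snp_coupling``; untagged samples are background-only;
* read 5' positions are fragment ends by strand under a truncated-normal
  fragment-length model.

No sequences are generated and no aligner is emulated: mapping ambiguity is a
labelled status, which is where the downstream computation starts. Ground
truth (expected and realized reads per mixture component) is retained in a
sidecar table for parameter-recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_CLASSES, FeatureSet
from .genome import GenomeLayout
from .reads import READ_STATUSES, MappedReadSet

DEFAULT_ENRICHMENT = {"hotspot": 8.0, "axis": 6.0, "centromere": 6.0, "coldspot": 1.0}


@dataclass(frozen=True)
class OccupancyModel:
    """Generative model of protein occupancy and library composition.

    Parameters
    ----------
    background_rate:
        Nonspecific pulldown rate in reads/bp; sets the relative mass of the
        uniform background component (absolute read numbers come from
        ``n_reads``).
    enrichment:
        Per-feature-class rate multipliers over background inside the feature.
    strength_coupling:
        Exponent linking a hotspot's multiplier to its strength, normalised by
        the geometric-mean strength: positive prefers strong hotspots,
        negative prefers weak ones, 0 decouples.
    snp_coupling:
        Exponent linking a feature's multiplier to its local SNP density
        relative to the genome-wide density (0 decouples).
    fragment_length_mean, fragment_length_sd:
        Truncated-normal sonication fragment model (truncated to [100, 1000] bp).
    spike_fraction:
        Expected fraction of reads mapping uniquely to the spike-in genome.
    ambiguous_rate, unmapped_rate:
        Fractions of reads flagged ambiguous (target position retained) or
        unmapped.
    """

    background_rate: float = 0.001
    enrichment: dict = field(default_factory=lambda: dict(DEFAULT_ENRICHMENT))
    strength_coupling: float = 0.0
    snp_coupling: float = 0.0
    fragment_length_mean: float = 350.0
    fragment_length_sd: float = 25.0
    spike_fraction: float = 0.09
    ambiguous_rate: float = 0.05
    unmapped_rate: float = 0.02

    def __post_init__(self):
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        for frac in (self.spike_fraction, self.ambiguous_rate, self.unmapped_rate):
            if not (0 <= frac < 1):
                raise ValueError("fractions must lie in [0, 1)")
        if self.spike_fraction + self.unmapped_rate >= 1:
            raise ValueError("spike_fraction + unmapped_rate must leave target reads")
        if self.fragment_length_mean <= 0 or self.fragment_length_sd <= 0:
            raise ValueError("fragment model parameters must be positive")
        bad = set(self.enrichment) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"enrichment for unknown classes {sorted(bad)}")
        if any(v < 0 for v in self.enrichment.values()):
            raise ValueError("enrichment multipliers must be nonnegative")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    role: str  # "chip" | "untagged"

    def __post_init__(self):
        if self.role not in ("chip", "untagged"):
            raise ValueError(f"unknown sample role {self.role!r}")


DEFAULT_SAMPLES = (
    SampleSpec("chip_rep1", "chip"),
    SampleSpec("chip_rep2", "chip"),
    SampleSpec("untagged", "untagged"),
)


@dataclass
class SNPMap:
    """Sorted heterozygous-marker positions per chromosome."""

    positions: dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if len(arr) > 1 and (np.diff(arr) <= 0).any():
                raise ValueError(f"SNP positions on {chrom} not strictly increasing")
            clean[chrom] = arr
        self.positions = clean

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def density_per_kb(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("zero-width interval")
        return self.count_in(chrom, start, end) / ((end - start) / 1000.0)

    @property
    def n_snps(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


@dataclass
class CrossoverSet:
    """Crossover midpoints from a set of tetrads."""

    n_tetrads: int
    df: pd.DataFrame  # tetrad_id, chrom, midpoint

    def __post_init__(self):
        if self.n_tetrads < 0:
            raise ValueError("n_tetrads must be nonnegative")
        if len(self.df) and (self.df["tetrad_id"] >= self.n_tetrads).any():
            raise ValueError("tetrad_id out of range")


@dataclass
class SimulatedExperiment:
    """Simulated samples plus the ground-truth sidecar table.

    ``ground_truth`` has one row per (sample, mixture component) with the
    expected and realized read counts, and one row per (sample, read status).
    """

    samples: list[MappedReadSet]
    ground_truth: pd.DataFrame

    def sample(self, sample_id: str) -> MappedReadSet:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"no sample {sample_id!r}")

    def by_role(self, role: str) -> list[MappedReadSet]:
        ids = self.ground_truth.loc[
            self.ground_truth["role"] == role, "sample_id"
        ].unique()
        return [self.sample(i) for i in ids]


def default_strength_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Heavy-tailed Spo11-oligo-like counts: log-normal(mu=5, sigma=1.2)."""
    return rng.lognormal(mean=5.0, sigma=1.2, size=n)


def _place_intervals(
    rng: np.random.Generator,
    layout: GenomeLayout,
    occupied: dict[str, list[tuple[int, int]]],
    n: int,
    width: int,
    min_gap: int,
    max_tries: int = 10000,
) -> list[tuple[str, int, int]]:
    """Place ``n`` width-bp intervals, >= min_gap away from anything occupied."""
    lengths = np.array(layout.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    out = []
    for _ in range(n):
        for attempt in range(max_tries):
            ci = rng.choice(len(probs), p=probs)
            chrom = layout.chrom_names[ci]
            limit = layout.chrom_lengths[ci] - width
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + width
            clash = any(
                start - min_gap < e and end + min_gap > s
                for s, e in occupied.get(chrom, [])
            )
            if not clash:
                occupied.setdefault(chrom, []).append((start, end))
                out.append((chrom, start, end))
                break
        else:
            raise ValueError(
                f"could not fit {n} features of width {width} at gap {min_gap}"
            )
    return out


def plant_features(
    layout: GenomeLayout,
    n_hotspots: int,
    n_axis: int,
    n_centromere: int,
    n_coldspots: int,
    strength_sampler=default_strength_sampler,
    min_gap: int = 1000,
    seed: int = 0,
    hotspot_width: int = 600,
    axis_width: int = 400,
    centromere_width: int = 120,
    coldspot_width: int = 600,
) -> FeatureSet:
    """Plant non-overlapping classed features with hotspot strengths.

    Centromeres are placed one per chromosome (centrally, with jitter), on the
    first ``n_centromere`` chromosomes. All placements keep >= ``min_gap`` bp
    from every other feature of any class, so planted coldspots are genuinely
    cold. Identical seeds give identical output.
    """
    if n_centromere > len(layout.chrom_names):
        raise ValueError("more centromeres than chromosomes")
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    records = []

    for i in range(n_centromere):
        chrom = layout.chrom_names[i]
        length = layout.chrom_lengths[i]
        centre = int(length * (0.4 + 0.2 * rng.random()))
        start = max(0, min(centre, length - centromere_width))
        occupied.setdefault(chrom, []).append((start, start + centromere_width))
        records.append((chrom, start, start + centromere_width, "centromere",
                        None, f"CEN_{chrom}"))

    hot = _place_intervals(rng, layout, occupied, n_hotspots, hotspot_width, min_gap)
    strengths = np.asarray(strength_sampler(rng, n_hotspots), dtype=float)
    if (strengths < 0).any():
        raise ValueError("strength sampler produced negative strengths")
    for i, ((chrom, s, e), st) in enumerate(zip(hot, strengths)):
        records.append((chrom, s, e, "hotspot", float(st), f"hotspot_{i}"))

    for i, (chrom, s, e) in enumerate(
        _place_intervals(rng, layout, occupied, n_axis, axis_width, min_gap)
    ):
        records.append((chrom, s, e, "axis", None, f"axis_{i}"))
    for i, (chrom, s, e) in enumerate(
        _place_intervals(rng, layout, occupied, n_coldspots, coldspot_width, min_gap)
    ):
        records.append((chrom, s, e, "coldspot", None, f"coldspot_{i}"))

    fs = FeatureSet.from_records(records)
    fs.validate_against(layout)
    return fs


def _feature_multipliers(
    features: FeatureSet, model: OccupancyModel, snps: SNPMap | None,
    layout: GenomeLayout,
) -> np.ndarray:
    """Rate multiplier over background for each feature row (chip samples)."""
    df = features.df
    mult = np.array([
        model.enrichment.get(fc, 1.0) for fc in df["feature_class"]
    ], dtype=float)
    if model.strength_coupling != 0.0:
        is_hot = (df["feature_class"] == "hotspot").to_numpy()
        s = df["strength"].to_numpy(dtype=float)
        if is_hot.any():
            gmean = np.exp(np.mean(np.log(np.maximum(s[is_hot], 1e-12))))
            mult[is_hot] *= (np.maximum(s[is_hot], 1e-12) / gmean) ** model.strength_coupling
    if model.snp_coupling != 0.0:
        if snps is None:
            raise ValueError("snp_coupling set but no SNP map provided")
        genome_density = snps.n_snps / (layout.total_size / 1000.0)
        dens = np.array([
            snps.density_per_kb(r.chrom, r.start, r.end)
            for r in df.itertuples(index=False)
        ])
        mult *= ((dens + 0.5) / (genome_density + 0.5)) ** model.snp_coupling
    return mult


def _component_masses(
    layout: GenomeLayout, features: FeatureSet, model: OccupancyModel,
    snps: SNPMap | None, chip: bool,
) -> np.ndarray:
    """Mass of [background, feature_0, ...] mixture components."""
    bg = model.background_rate * layout.total_size
    if len(features) == 0 or not chip:
        extras = np.zeros(len(features))
    else:
        widths = (features.df["end"] - features.df["start"]).to_numpy(dtype=float)
        mult = _feature_multipliers(features, model, snps, layout)
        extras = model.background_rate * widths * np.maximum(mult - 1.0, 0.0)
    return np.concatenate([[bg], extras])


def expected_spike_fraction(
    layout: GenomeLayout,
    features: FeatureSet,
    model: OccupancyModel,
    mixing_ratio: float = 0.1,
    snps: SNPMap | None = None,
) -> float:
    """Spike-read fraction implied by a physical spike:target cell mixture.

    The spike-in genome carries no tagged protein, so its read mass is purely
    nonspecific: ``mixing_ratio`` times the target background mass (the two
    genomes are taken as comparable in size). As true occupancy grows, target
    read mass grows and the spike fraction shrinks, exactly as in the
    experiment.
    """
    masses = _component_masses(layout, features, model, snps, chip=True)
    spike_mass = mixing_ratio * masses[0]
    return float(spike_mass / (masses.sum() + spike_mass))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Normal draws with out-of-range values redrawn (truncation by rejection)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _uniform_genome_positions(
    rng: np.random.Generator, layout: GenomeLayout, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom_index, pos) for n positions uniform over the whole genome."""
    cum = np.cumsum(np.array(layout.chrom_lengths, dtype=np.int64))
    offs = rng.integers(0, layout.total_size, size=n)
    ci = np.searchsorted(cum, offs, side="right")
    starts = cum - np.array(layout.chrom_lengths, dtype=np.int64)
    return ci, offs - starts[ci]


def simulate_experiment(
    layout: GenomeLayout,
    features: FeatureSet,
    model: OccupancyModel,
    n_reads: int,
    samples=DEFAULT_SAMPLES,
    seed: int = 0,
    snps: SNPMap | None = None,
    mixing_ratio: float | None = None,
) -> SimulatedExperiment:
    """Simulate mapped-read sets for tagged-ChIP and untagged samples.

    Every sample receives ``n_reads`` total reads. See the module docstring
    for the generative model; ground truth is returned in the sidecar table.

    When ``mixing_ratio`` is given (e.g. 0.1 for a 1:10 spike:target cell
    mixture), each sample's spike fraction is derived from the physical
    mixture — chip samples with more specific pulldown get proportionally
    fewer spike reads — overriding ``model.spike_fraction``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    specs = [s if isinstance(s, SampleSpec) else SampleSpec(*s) for s in samples]
    if not specs:
        raise ValueError("no samples requested")
    if len({s.sample_id for s in specs}) != len(specs):
        raise ValueError("duplicate sample ids")
    if len(features) == 0 and any(
        v != 1.0 for v in model.enrichment.values()
    ) and any(s.role == "chip" for s in specs):
        raise ValueError("empty feature set with nonzero class enrichment")

    frag_lo, frag_hi = 100.0, 1000.0
    chrom_names = np.array(layout.chrom_names)
    chrom_lens = np.array(layout.chrom_lengths, dtype=np.int64)
    feat_df = features.df
    comp_names = ["background"] + list(feat_df["name"])

    out_samples: list[MappedReadSet] = []
    gt_rows = []
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(i,)
        ))
        masses = _component_masses(layout, features, model, snps,
                                   chip=(spec.role == "chip"))
        if mixing_ratio is not None:
            spike_mass = mixing_ratio * masses[0]
            spike_fraction = spike_mass / (masses.sum() + spike_mass)
        else:
            spike_fraction = model.spike_fraction
        n_spike, n_unmapped, n_target = rng.multinomial(
            n_reads,
            [spike_fraction, model.unmapped_rate,
             1.0 - spike_fraction - model.unmapped_rate],
        )
        probs = masses / masses.sum()
        comp_counts = rng.multinomial(n_target, probs)

        ci_parts, mid_parts = [], []
        n_bg = comp_counts[0]
        ci_bg, pos_bg = _uniform_genome_positions(rng, layout, n_bg)
        ci_parts.append(ci_bg)
        mid_parts.append(pos_bg)
        chrom_index = {c: k for k, c in enumerate(layout.chrom_names)}
        for f_i, cnt in enumerate(comp_counts[1:]):
            if cnt == 0:
                continue
            row = feat_df.iloc[f_i]
            mids = rng.integers(row["start"], row["end"], size=cnt)
            ci_parts.append(np.full(cnt, chrom_index[row["chrom"]], dtype=np.int64))
            mid_parts.append(mids)
        ci = np.concatenate(ci_parts)
        mids = np.concatenate(mid_parts).astype(np.int64)

        frag = _truncated_normal(
            rng, model.fragment_length_mean, model.fragment_length_sd,
            frag_lo, frag_hi, n_target,
        )
        minus = rng.integers(0, 2, size=n_target).astype(bool)
        pos = np.where(minus, mids + frag / 2.0, mids - frag / 2.0)
        pos = np.clip(np.rint(pos).astype(np.int64), 0, chrom_lens[ci] - 1)

        ambiguous = rng.random(n_target) < model.ambiguous_rate
        n_off = n_spike + n_unmapped
        chrom_cats = list(layout.chrom_names) + ["."]
        chrom_codes = np.concatenate([
            ci, np.full(n_off, len(layout.chrom_names), dtype=np.int64)
        ])
        all_pos = np.concatenate([pos, np.full(n_off, -1, dtype=np.int64)])
        strand_codes = np.concatenate([
            minus.astype(np.int8), np.full(n_off, 2, dtype=np.int8)
        ])
        # status codes follow READ_STATUSES order
        status_codes = np.concatenate([
            ambiguous.astype(np.int8) * 2,  # 0 target_unique, 2 ambiguous
            np.full(n_spike, 1, dtype=np.int8),
            np.full(n_unmapped, 3, dtype=np.int8),
        ])
        df = pd.DataFrame({
            "chrom": pd.Categorical.from_codes(chrom_codes, categories=chrom_cats),
            "pos": all_pos,
            "strand": pd.Categorical.from_codes(strand_codes,
                                                categories=["+", "-", "."]),
            "status": pd.Categorical.from_codes(status_codes,
                                                categories=list(READ_STATUSES)),
        })
        out_samples.append(MappedReadSet(spec.sample_id, df))

        expected = n_target * probs
        for name, exp, real in zip(comp_names, expected, comp_counts):
            gt_rows.append((spec.sample_id, spec.role, "component", name,
                            float(exp), int(real)))
        for sname, exp, real in (
            ("spike_unique", n_reads * spike_fraction, n_spike),
            ("unmapped", n_reads * model.unmapped_rate, n_unmapped),
            ("target_unique", n_target * (1 - model.ambiguous_rate),
             int((~ambiguous).sum())),
            ("ambiguous", n_target * model.ambiguous_rate, int(ambiguous.sum())),
        ):
            gt_rows.append((spec.sample_id, spec.role, "status", sname,
                            float(exp), int(real)))

    gt = pd.DataFrame(
        gt_rows,
        columns=["sample_id", "role", "kind", "name", "expected_reads", "realized_reads"],
    )
    return SimulatedExperiment(samples=out_samples, ground_truth=gt)


def plant_snps(
    layout: GenomeLayout,
    density_profile,
    seed: int = 0,
    base_density: float = 0.0,
) -> SNPMap:
    """Plant heterozygous-marker positions at a given density (SNPs per kb).

    ``density_profile`` is either a constant density or a list of
    ``(chrom, start, end, density)`` regions; ``base_density`` applies outside
    listed regions. Counts are Poisson with mean density x length/1000;
    positions are unique and sorted.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(density_profile):
        if density_profile < 0:
            raise ValueError("negative SNP density")
        regions = [
            (c, 0, layout.length_of(c), float(density_profile))
            for c in layout.chrom_names
        ]
    else:
        if base_density < 0:
            raise ValueError("negative SNP density")
        listed: dict[str, list[tuple[int, int, float]]] = {c: [] for c in layout.chrom_names}
        for chrom, start, end, dens in density_profile:
            if dens < 0:
                raise ValueError("negative SNP density")
            if not (0 <= start < end <= layout.length_of(chrom)):
                raise ValueError(f"SNP region ({chrom}, {start}, {end}) out of bounds")
            listed[chrom].append((int(start), int(end), float(dens)))
        regions = []
        for chrom in layout.chrom_names:
            cursor = 0
            for start, end, dens in sorted(listed[chrom]):
                if start < cursor:
                    raise ValueError(f"overlapping SNP density regions on {chrom}")
                if start > cursor:
                    regions.append((chrom, cursor, start, base_density))
                regions.append((chrom, start, end, dens))
                cursor = end
            if cursor < layout.length_of(chrom):
                regions.append((chrom, cursor, layout.length_of(chrom), base_density))

    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in layout.chrom_names}
    for chrom, start, end, dens in regions:
        mean = dens * (end - start) / 1000.0
        if mean == 0:
            continue
        count = int(rng.poisson(mean))
        count = min(count, end - start)
        pos = np.unique(rng.integers(start, end, size=count))
        while len(pos) < count:  # top up collision losses
            extra = rng.integers(start, end, size=count - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        per_chrom[chrom].append(pos)
    return SNPMap({
        c: np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
        for c, parts in per_chrom.items()
    })


def simulate_crossovers(
    layout: GenomeLayout,
    features: FeatureSet,
    n_tetrads: int,
    hotspot_weighting: float = 1.0,
    seed: int = 0,
    crossovers_per_tetrad: float | None = None,
    uniform_fraction: float = 0.2,
) -> CrossoverSet:
    """Simulate tetrad crossover midpoints concentrated at DSB hotspots.

    Each tetrad receives a Poisson number of crossovers (default rate: ~90 per
    tetrad scaled to the 12.1-Mb budding-yeast genome). A crossover falls at a
    hotspot midpoint with probability proportional to strength^weighting, or
    uniformly anywhere with probability ``uniform_fraction``.
    """
    if n_tetrads < 0:
        raise ValueError("n_tetrads must be nonnegative")
    rng = np.random.default_rng(seed)
    if crossovers_per_tetrad is None:
        crossovers_per_tetrad = 90.0 * layout.total_size / 12.1e6
    hot = features.hotspots
    rows = []
    if n_tetrads > 0:
        weights = None
        if len(hot):
            s = np.maximum(hot["strength"].to_numpy(dtype=float), 1e-12)
            w = s ** hotspot_weighting
            weights = w / w.sum()
        for tid in range(n_tetrads):
            n_co = rng.poisson(crossovers_per_tetrad)
            if n_co == 0:
                continue
            uniform = (rng.random(n_co) < uniform_fraction) if weights is not None \
                else np.ones(n_co, dtype=bool)
            n_u = int(uniform.sum())
            if n_u:
                ci, pos = _uniform_genome_positions(rng, layout, n_u)
                for c, p in zip(ci, pos):
                    rows.append((tid, layout.chrom_names[c], int(p)))
            n_h = n_co - n_u
            if n_h:
                idx = rng.choice(len(hot), size=n_h, p=weights)
                for f_i in idx:
                    row = hot.iloc[int(f_i)]
                    rows.append((tid, row["chrom"], int((row["start"] + row["end"]) // 2)))
    df = pd.DataFrame(rows, columns=["tetrad_id", "chrom", "midpoint"])
    return CrossoverSet(n_tetrads=n_tetrads, df=df)
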