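"""Pipeline orchestration: config validation, staged runs, report writing.

Stages (``simulate``, ``calibrate``, ``callpeaks``, ``annotate``, ``stats``)
read their inputs from the output directory of upstream stages (or from
configured paths in real-data mode) and write standard-format reports, each
carrying a provenance header (package version, config hash, seed). Runs are
deterministic given (config, seed).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .calibrate import average_replicates, calibrate, scale_sample, smooth
from .features import FeatureSet
from .genome import GenomeLayout, make_genome_layout
from .peaks import (PeakCallingParams, annotate_peaks, call_peaks,
                    peak_width_stats)
from .reads import MappedReadSet
from .simulate import (OccupancyModel, SampleSpec, plant_features, plant_snps,
                       simulate_crossovers, simulate_experiment)
from .stats import density_by_chromosome, pearson_correlation, snp_density_analysis
from .tracks import BinnedTrack

VERSION = "0.1.0"

STAGES = ("simulate", "calibrate", "callpeaks", "annotate", "stats")

_DEFAULT_SIMULATE = {
    "n_chroms": 4,
    "chrom_length": 300_000,
    "n_hotspots": 120,
    "n_axis": 40,
    "n_centromere": 4,
    "n_coldspots": 25,
    "min_gap": 500,
    "n_reads": 150_000,
    "snp_density": 4.0,
    "n_tetrads": 66,
    "strength_coupling": 0.0,
    "mixing_ratio": 0.1,
}


@dataclass
class RunConfig:
    """Validated run configuration (mirrors the YAML config file)."""

    seed: int = 0
    output_dir: str = "calchip_out"
    bin_size: int = 10
    bandwidth: float = 1000.0
    p_max: float = 1e-5
    merge_gap: int = 100
    min_width: int = 50
    site_window: int = 2000
    pseudocount: float = 0.5
    read_shift: int = 175  # half the mean fragment length
    samples: dict = field(default_factory=lambda: {
        "chip_rep1": "chip", "chip_rep2": "chip", "untagged": "untagged",
    })
    simulate: dict = field(default_factory=lambda: dict(_DEFAULT_SIMULATE))
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from a plain dict, reporting every validation problem at once."""
        errors = []
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            errors.append(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        if cfg.bin_size <= 0:
            errors.append("bin_size must be positive")
        if cfg.bandwidth <= 0:
            errors.append("bandwidth must be positive")
        if not (0 < cfg.p_max < 1):
            errors.append("p_max must be in (0, 1)")
        if cfg.merge_gap < 0 or cfg.min_width < 0:
            errors.append("merge_gap and min_width must be nonnegative")
        if cfg.site_window <= 0:
            errors.append("site_window must be positive")
        if cfg.read_shift < 0:
            errors.append("read_shift must be nonnegative")
        roles = set(cfg.samples.values())
        if not roles <= {"chip", "untagged"}:
            errors.append(f"sample roles must be chip/untagged, got {sorted(roles)}")
        if "chip" not in roles or "untagged" not in roles:
            errors.append("need at least one chip sample and one untagged sample")
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))
        merged = dict(_DEFAULT_SIMULATE)
        merged.update(cfg.simulate or {})
        cfg.simulate = merged
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "output_dir": self.output_dir,
            "bin_size": self.bin_size, "bandwidth": self.bandwidth,
            "p_max": self.p_max, "merge_gap": self.merge_gap,
            "min_width": self.min_width, "site_window": self.site_window,
            "pseudocount": self.pseudocount, "read_shift": self.read_shift,
            "samples": dict(self.samples),
            "simulate": dict(self.simulate), "paths": dict(self.paths),
        }


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _provenance(cfg: RunConfig) -> list[str]:
    # hash only analysis-relevant parameters, not where outputs land
    hashed = {k: v for k, v in cfg.to_dict().items() if k != "output_dir"}
    return [
        f"calchip v{VERSION}",
        f"config={cio.config_hash(hashed)}",
        f"seed={cfg.seed}",
    ]


def _write_report(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        for line in _provenance(cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing input {path} "
            "(run the upstream stage or configure its path)"
        )
    return path


def _load_layout(cfg: RunConfig, out: Path) -> GenomeLayout:
    if "chrom_sizes" in cfg.paths:
        return cio.read_chrom_sizes(cfg.paths["chrom_sizes"])
    return cio.read_chrom_sizes(_require(out / "chrom.sizes", "calibrate"))


def _load_reads(cfg: RunConfig, out: Path, sample_id: str, stage: str) -> MappedReadSet:
    path = Path(cfg.paths.get("reads", {}).get(sample_id,
                                               out / f"reads_{sample_id}.tsv"))
    return cio.read_reads_tsv(_require(path, stage))


def _load_features(cfg: RunConfig, out: Path, stage: str) -> FeatureSet:
    path = Path(cfg.paths.get("features", out / "features.bed"))
    fs = cio.read_bed(_require(path, stage))
    assert isinstance(fs, FeatureSet)
    return fs


def run_pipeline(cfg: RunConfig, stages=STAGES) -> Path:
    """Run the requested stages; returns the output directory.

    Reports are byte-stable for a fixed (config, seed).
    """
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if "simulate" in stages:
        _run_simulate(cfg, out)
    if "calibrate" in stages:
        _run_calibrate(cfg, out)
    if "callpeaks" in stages:
        _run_callpeaks(cfg, out)
    if "annotate" in stages:
        _run_annotate(cfg, out)
    if "stats" in stages:
        _run_stats(cfg, out)
    return out


def _run_simulate(cfg: RunConfig, out: Path) -> None:
    sim = cfg.simulate
    seed = stage_seed(cfg.seed, "simulate")
    lengths = sim.get("chrom_lengths") or [sim["chrom_length"]] * sim["n_chroms"]
    layout = make_genome_layout(sim["n_chroms"], list(lengths))
    features = plant_features(
        layout,
        n_hotspots=sim["n_hotspots"], n_axis=sim["n_axis"],
        n_centromere=sim["n_centromere"], n_coldspots=sim["n_coldspots"],
        min_gap=sim["min_gap"], seed=seed,
    )
    model = OccupancyModel(strength_coupling=sim.get("strength_coupling", 0.0))
    specs = [SampleSpec(sid, role) for sid, role in cfg.samples.items()]
    exp = simulate_experiment(
        layout, features, model, n_reads=sim["n_reads"], samples=specs, seed=seed,
        mixing_ratio=sim.get("mixing_ratio", 0.1),
    )
    snps = plant_snps(layout, sim["snp_density"], seed=seed + 1)
    crossovers = simulate_crossovers(layout, features, sim["n_tetrads"], seed=seed + 2)

    cio.write_chrom_sizes(layout, out / "chrom.sizes")
    cio.write_bed(features, out / "features.bed")
    for s in exp.samples:
        cio.write_reads_tsv(s, out / f"reads_{s.sample_id}.tsv")
    cio.write_snps_tsv(snps, out / "snps.tsv")
    cio.write_crossovers_tsv(crossovers, out / "crossovers.tsv")
    _write_report(exp.ground_truth, out / "ground_truth.tsv", cfg)


def _run_calibrate(cfg: RunConfig, out: Path) -> None:
    layout = _load_layout(cfg, out)
    chip_ids = [sid for sid, role in cfg.samples.items() if role == "chip"]
    unt_ids = [sid for sid, role in cfg.samples.items() if role == "untagged"]
    tracks, sfs = {}, {}
    for sid in chip_ids + unt_ids:
        reads = _load_reads(cfg, out, sid, "calibrate")
        tracks[sid], sfs[sid] = scale_sample(reads, layout, bin_size=cfg.bin_size)
    unt = unt_ids[0]
    calibrated = [
        calibrate(tracks[sid], tracks[unt], sfs[sid], sfs[unt]) for sid in chip_ids
    ]
    averaged = average_replicates(calibrated)
    smoothed = smooth(averaged, bandwidth=cfg.bandwidth, layout=layout)

    sf_df = pd.DataFrame(
        [(sid, sfs[sid].sf1, sfs[sid].sf2) for sid in chip_ids + unt_ids],
        columns=["sample_id", "sf1", "sf2"],
    )
    _write_report(sf_df, out / "scaling_factors.tsv", cfg)
    cio.write_bedgraph(averaged, out / "calibrated.bedgraph", layout,
                       header_lines=_provenance(cfg))
    cio.write_bedgraph(smoothed, out / "smoothed.bedgraph", layout,
                       header_lines=_provenance(cfg))


def _pooled_counts(cfg: RunConfig, out: Path, stage: str):
    layout = _load_layout(cfg, out)
    chip_ids = [sid for sid, role in cfg.samples.items() if role == "chip"]
    unt_ids = [sid for sid, role in cfg.samples.items() if role == "untagged"]
    from .calibrate import bin_reads
    pooled: BinnedTrack | None = None
    for sid in chip_ids:
        t = bin_reads(_load_reads(cfg, out, sid, stage), layout, cfg.bin_size,
                      strand_shift=cfg.read_shift)
        if pooled is None:
            pooled = t
        else:
            for c in pooled.values:
                pooled.values[c] += t.values[c]
    control = bin_reads(_load_reads(cfg, out, unt_ids[0], stage), layout,
                        cfg.bin_size, strand_shift=cfg.read_shift)
    return layout, pooled, control


def _run_callpeaks(cfg: RunConfig, out: Path) -> None:
    layout, pooled, control = _pooled_counts(cfg, out, "callpeaks")
    params = PeakCallingParams(
        p_max=cfg.p_max, merge_gap=cfg.merge_gap, min_width=cfg.min_width,
    )
    peaks = call_peaks(pooled, control, params, layout=layout)
    cio.write_peaks_tsv(peaks, out / "peaks.tsv", header_lines=_provenance(cfg))
    cio.write_bed(peaks, out / "peaks.bed")


def _run_annotate(cfg: RunConfig, out: Path) -> None:
    peaks = cio.read_peaks_tsv(_require(out / "peaks.tsv", "annotate"))
    features = _load_features(cfg, out, "annotate")
    labeled, counts = annotate_peaks(peaks, features)
    cio.write_peaks_tsv(labeled, out / "peaks_annotated.tsv",
                        header_lines=_provenance(cfg))
    counts_df = pd.DataFrame(
        sorted(counts.items()), columns=["category", "n_peaks"]
    )
    _write_report(counts_df, out / "category_counts.tsv", cfg)


def _run_stats(cfg: RunConfig, out: Path) -> None:
    layout, pooled, _ = _pooled_counts(cfg, out, "stats")
    peaks = cio.read_peaks_tsv(_require(out / "peaks.tsv", "stats"))

    dens = density_by_chromosome(pooled, layout)
    _write_report(dens, out / "density_by_chromosome.tsv", cfg)

    summary_rows = []
    if len(dens) >= 3 and dens["length"].nunique() > 1:
        r, p = pearson_correlation(dens["length"], dens["density_rpm_per_kb"])
        summary_rows += [("pearson_r_size_vs_density", r),
                         ("pearson_p_size_vs_density", p)]
    if len(peaks):
        median_w, mean_w, _ = peak_width_stats(peaks)
        summary_rows += [("n_peaks", len(peaks)),
                         ("median_peak_width_bp", median_w),
                         ("mean_peak_width_bp", mean_w)]
    snp_path = Path(cfg.paths.get("snps", out / "snps.tsv"))
    if snp_path.exists() and len(peaks):
        snps = cio.read_snps_tsv(snp_path, layout)
        res = snp_density_analysis(snps, peaks, layout, seed=cfg.seed)
        summary_rows += [
            ("snp_density_peak_mean", res["peak_mean"]),
            ("snp_density_peak_median", res["peak_median"]),
            ("snp_density_genome_mean", res["genome_mean"]),
            ("snp_density_genome_median", res["genome_median"]),
            ("snp_density_ranksum_p", res["p_value"]),
        ]
    summary = pd.DataFrame(summary_rows, columns=["quantity", "value"])
    _write_report(summary, out / "summary_stats.tsv", cfg)
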