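"""Readers and writers for the standard text formats the pipeline speaks.

Everything is plain text: BED (features, peaks), bedGraph (tracks),
chrom.sizes, TSV (reads, SNPs, crossovers, reports) and YAML (config). All
coordinates on disk are 0-based half-open; files flagged ``one_based=True``
are converted on ingestion (printed genomics coordinates are typically
1-based inclusive).
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_CLASSES, FeatureSet
from .genome import GenomeLayout
from .peaks import PEAK_COLUMNS, PeakSet
from .reads import READ_COLUMNS, READ_STATUSES, MappedReadSet
from .simulate import CrossoverSet, SNPMap
from .tracks import BinnedTrack


def _parse_error(path, line_no: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{line_no}: {msg}")


# ---------------------------------------------------------------------------
# chrom.sizes

def read_chrom_sizes(path) -> GenomeLayout:
    names, lengths = [], []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise _parse_error(path, i, "expected <chrom>\t<length>")
            try:
                length = int(parts[1])
            except ValueError:
                raise _parse_error(path, i, f"bad length {parts[1]!r}") from None
            names.append(parts[0])
            lengths.append(length)
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED: features and peaks

def read_bed(
    path,
    kind: str = "features",
    feature_class: str | None = None,
    one_based: bool = False,
) -> FeatureSet | PeakSet:
    """Read BED3/BED6 into a FeatureSet (default) or PeakSet (kind="peaks").

    For features, the class comes from ``feature_class`` (single-class file)
    or from a ``class:name`` prefix in the name column; the score column
    carries hotspot strength. ``one_based`` converts 1-based inclusive starts.
    """
    if kind not in ("features", "peaks"):
        raise ValueError(f"unknown kind {kind!r}")
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _parse_error(path, i, "fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise _parse_error(path, i, "non-integer coordinates") from None
            if one_based:
                start -= 1
            if end <= start:
                raise _parse_error(path, i, f"end {end} <= start {start}")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            score = parts[4] if len(parts) > 4 and parts[4] != "." else ""
            rows.append((i, chrom, start, end, name, score))

    if kind == "peaks":
        recs = [(chrom, start, end) for _, chrom, start, end, _, _ in rows]
        ps = PeakSet.from_intervals(recs)
        ps.df["label"] = [name for _, _, _, _, name, _ in rows]
        return ps

    records = []
    for line_no, chrom, start, end, name, score in rows:
        fclass = feature_class
        if ":" in name and name.split(":", 1)[0] in FEATURE_CLASSES:
            fclass, name = name.split(":", 1)
        if fclass is None:
            raise _parse_error(
                path, line_no,
                "cannot infer feature class (pass feature_class= or use class:name names)",
            )
        strength = None
        if fclass == "hotspot":
            try:
                strength = float(score) if score else 0.0
            except ValueError:
                raise _parse_error(path, line_no, f"bad strength {score!r}") from None
        records.append((chrom, start, end, fclass, strength, name or f"{fclass}_{line_no}"))
    return FeatureSet.from_records(records)


def write_bed(obj: FeatureSet | PeakSet, path) -> None:
    """Write a FeatureSet (name = class:name, score = strength) or PeakSet
    (name = label, score = -log10 p) as BED6."""
    with open(path, "w") as fh:
        if isinstance(obj, FeatureSet):
            for row in obj.df.itertuples(index=False):
                score = (repr(float(row.strength))
                         if row.feature_class == "hotspot" else "0")
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{row.feature_class}:{row.name}\t{score}\t+\n")
        elif isinstance(obj, PeakSet):
            for row in obj.df.itertuples(index=False):
                if np.isnan(row.p_value):
                    score = "0"
                else:
                    score = f"{min(1000.0, -np.log10(max(row.p_value, 1e-300))):.3f}"
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{row.label or '.'}\t{score}\t.\n")
        else:
            raise TypeError("expected FeatureSet or PeakSet")


def write_peaks_tsv(peaks: PeakSet, path, header_lines: list[str] | None = None) -> None:
    """narrowPeak-style TSV with p/q values and summits."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        peaks.df.to_csv(fh, sep="\t", index=False)


def read_peaks_tsv(path) -> PeakSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["label"] = df["label"].fillna("")
    return PeakSet(df[PEAK_COLUMNS])


# ---------------------------------------------------------------------------
# mapped reads TSV

def read_reads_tsv(path) -> MappedReadSet:
    """Read a reads TSV (chrom, pos, strand, status, sample_id)."""
    try:
        df = pd.read_csv(
            path, sep="\t",
            dtype={"chrom": str, "pos": np.int64, "strand": str,
                   "status": str, "sample_id": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=READ_COLUMNS + ["sample_id"])
    missing = [c for c in READ_COLUMNS + ["sample_id"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = set(df["status"].unique()) - set(READ_STATUSES)
    if bad:
        raise ValueError(f"{path}: unknown status tokens {sorted(bad)}")
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) > 1:
        raise ValueError(f"{path}: multiple sample ids {list(sample_ids)}")
    sample_id = str(sample_ids[0]) if len(sample_ids) else ""
    return MappedReadSet(sample_id, df[READ_COLUMNS].reset_index(drop=True))


def write_reads_tsv(reads: MappedReadSet, path) -> None:
    df = reads.df.copy()
    df["sample_id"] = reads.sample_id
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(
    track: BinnedTrack,
    path,
    layout: GenomeLayout | None = None,
    scale: float = 1.0,
    header_lines: list[str] | None = None,
) -> None:
    """4-column bedGraph with runs of equal value merged; deterministic order.

    ``scale`` supports display-only transforms (e.g. x2 SNP-count scaling);
    statistics never use scaled tracks.
    """
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for chrom in track.values:
            v = track.values[chrom] * scale
            n = len(v)
            limit = layout.length_of(chrom) if layout is not None else n * track.bin_size
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [n]])
            for b0, b1 in zip(starts, ends):
                s = int(b0) * track.bin_size
                e = min(int(b1) * track.bin_size, limit)
                fh.write(f"{chrom}\t{s}\t{e}\t{v[b0]:.6g}\n")


def read_bedgraph(path, layout: GenomeLayout, bin_size: int) -> BinnedTrack:
    """Expand a bedGraph written by :func:`write_bedgraph` back into bins."""
    track = BinnedTrack.zeros(layout, bin_size=bin_size)
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise _parse_error(path, i, "expected 4 bedGraph columns")
            chrom, s, e, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in track.values:
                raise _parse_error(path, i, f"unknown chromosome {chrom!r}")
            if e > layout.length_of(chrom):
                raise _parse_error(path, i, "interval beyond chromosome end")
            b0 = s // bin_size
            b1 = -(-e // bin_size)
            track.values[chrom][b0:b1] = val
    track.state = "raw_counts" if all(
        (v >= 0).all() for v in track.values.values()) else "calibrated"
    return track


# ---------------------------------------------------------------------------
# SNPs and crossovers

def read_snps_tsv(path, layout: GenomeLayout | None = None) -> SNPMap:
    """TSV (chrom, pos) or VCF-lite (#-comments, first two columns used)."""
    per_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":
                continue
            if len(parts) < 2:
                raise _parse_error(path, i, "expected at least chrom and pos")
            try:
                pos = int(parts[1])
            except ValueError:
                raise _parse_error(path, i, f"bad position {parts[1]!r}") from None
            if layout is not None and (
                parts[0] not in layout.lengths_by_chrom
                or pos >= layout.length_of(parts[0])
            ):
                raise _parse_error(path, i, f"SNP outside genome: {parts[0]}:{pos}")
            per_chrom.setdefault(parts[0], []).append(pos)
    return SNPMap({c: np.array(sorted(set(p)), dtype=np.int64)
                   for c, p in per_chrom.items()})


def write_snps_tsv(snps: SNPMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom in snps.positions:
            for p in snps.positions[chrom]:
                fh.write(f"{chrom}\t{p}\n")


def read_crossovers_tsv(path, n_tetrads: int | None = None) -> CrossoverSet:
    """TSV with columns tetrad_id, chrom, and midpoint (or start+end)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "midpoint" not in df.columns:
        if {"start", "end"} <= set(df.columns):
            df["midpoint"] = (df["start"] + df["end"]) // 2
        else:
            raise ValueError(f"{path}: need a midpoint or start/end columns")
    if n_tetrads is None:
        n_tetrads = int(df["tetrad_id"].max()) + 1 if len(df) else 0
    return CrossoverSet(n_tetrads, df[["tetrad_id", "chrom", "midpoint"]])


def write_crossovers_tsv(crossovers: CrossoverSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_tetrads={crossovers.n_tetrads}\n")
        crossovers.df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# YAML config

def read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(data: dict) -> str:
    blob = yaml.safe_dump(data, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]
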