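"""Local-Poisson peak calling and feature-overlap classification.

The caller is a self-contained implementation of the classic local-lambda
Poisson test: per 10-bp bin, the background rate is the depth-scaled maximum
of the control's mean coverage in several local windows (1/5/10 kb) and the
genome-wide mean, the bin p-value is the Poisson upper tail P(X >= obs), and
significant bins (p <= p_max, default 1e-5) are merged into peaks across gaps
up to ``merge_gap``. Each peak is then extended outward over contiguous bins
whose counts exceed the local background, so the reported span delimits the
whole enriched region around the significant core.

Called peaks are classified Venn-style against DSB-hotspot (Spo11), axis
(Red1) and centromere feature maps by >= 1 bp overlap; peaks overlapping no
feature are labelled ``Nil``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureSet
from .genome import GenomeLayout
from .tracks import BinnedTrack

# feature class -> annotation label used in the Venn partition
CLASS_LABELS = {"hotspot": "Spo11", "axis": "Red1", "centromere": "Centromere"}

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "p_value", "q_value", "label"]


@dataclass(frozen=True)
class PeakCallingParams:
    """Tuning knobs of the local-Poisson caller."""

    p_max: float = 1e-5
    merge_gap: int = 100
    min_width: int = 50
    local_lambda_windows: tuple[int, ...] = (1000, 5000, 10000)

    def __post_init__(self):
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")
        if self.merge_gap < 0 or self.min_width < 0:
            raise ValueError("merge_gap and min_width must be nonnegative")
        if any(w <= 0 for w in self.local_lambda_windows):
            raise ValueError("lambda windows must be positive")


@dataclass
class PeakSet:
    """Called peaks with p/q values, summits and (optional) feature labels."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PEAK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"PeakSet missing columns {missing}")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("peak with start >= end")

    @classmethod
    def from_intervals(cls, intervals) -> "PeakSet":
        """Build an unlabelled PeakSet from (chrom, start, end) triples."""
        rows = [
            (c, int(s), int(e), (int(s) + int(e)) // 2, np.nan, np.nan, "")
            for c, s, e in intervals
        ]
        return cls(pd.DataFrame(rows, columns=PEAK_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


def _rolling_mean(x: np.ndarray, k: int) -> np.ndarray:
    """Centered rolling mean renormalized over available bins at the edges."""
    if k <= 1:
        return x.astype(float)
    n = len(x)
    half = k // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def call_peaks(
    chip_counts: BinnedTrack,
    control_counts: BinnedTrack | None,
    params: PeakCallingParams = PeakCallingParams(),
    layout: GenomeLayout | None = None,
) -> PeakSet:
    """Call enriched regions from raw binned ChIP counts vs a control.

    With no control, a uniform background at the ChIP genome-wide mean is used.
    """
    if chip_counts.state != "raw_counts":
        raise ValueError("peak calling requires raw count tracks")
    if chip_counts.n_bins() == 0:
        raise ValueError("empty chip track")
    bs = chip_counts.bin_size
    chip_total = chip_counts.total()
    if chip_total <= 0:
        raise ValueError("chip track has no reads")

    if control_counts is not None:
        chip_counts.require_compatible(control_counts)
        if control_counts.state != "raw_counts":
            raise ValueError("peak calling requires raw count tracks")
        ctrl_total = control_counts.total()
        if ctrl_total <= 0:
            raise ValueError("control track has no reads")
        depth_ratio = chip_total / ctrl_total
        gw_mean = control_counts.mean_per_bin() * depth_ratio
    else:
        depth_ratio = 1.0
        gw_mean = chip_counts.mean_per_bin()

    # deterministic chromosome order regardless of input dict order
    chrom_order = sorted(chip_counts.values)

    lam_by_chrom: dict[str, np.ndarray] = {}
    p_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chrom_order:
        obs = chip_counts.values[chrom]
        lam = np.full(len(obs), gw_mean)
        if control_counts is not None:
            ctrl = control_counts.values[chrom] * depth_ratio
            for w in params.local_lambda_windows:
                k = 2 * (w // (2 * bs)) + 1  # odd bin count spanning ~w bp
                lam = np.maximum(lam, _rolling_mean(ctrl, k))
        lam_by_chrom[chrom] = lam
        p_by_chrom[chrom] = sps.poisson.sf(obs - 1, lam)

    all_p = np.concatenate([p_by_chrom[c] for c in chrom_order])
    all_q = sps.false_discovery_control(all_p, method="bh")
    q_by_chrom: dict[str, np.ndarray] = {}
    off = 0
    for chrom in chrom_order:
        n = len(p_by_chrom[chrom])
        q_by_chrom[chrom] = all_q[off:off + n]
        off += n

    gap_bins = params.merge_gap // bs
    rows = []
    for chrom in chrom_order:
        obs = chip_counts.values[chrom]
        lam = lam_by_chrom[chrom]
        p = p_by_chrom[chrom]
        q = q_by_chrom[chrom]
        n = len(obs)
        sig = np.flatnonzero(p <= params.p_max)
        if len(sig) == 0:
            continue
        # merge significant bins separated by <= gap_bins non-significant bins
        breaks = np.flatnonzero(np.diff(sig) > gap_bins + 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(sig) - 1]])
        # core = run of significant bins; span = core extended over contiguous
        # enriched (count > lambda) flanking bins
        candidates = []
        for s_i, e_i in zip(starts, ends):
            i0, i1 = int(sig[s_i]), int(sig[e_i])
            left = i0
            while left - 1 >= 0 and obs[left - 1] > lam[left - 1]:
                left -= 1
            right = i1
            while right + 1 < n and obs[right + 1] > lam[right + 1]:
                right += 1
            candidates.append([left, right, i0, i1])
        # extension can make neighbouring spans meet: merge them into one peak
        merged = [candidates[0]]
        for left, right, i0, i1 in candidates[1:]:
            if left <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], right)
                merged[-1][3] = i1
            else:
                merged.append([left, right, i0, i1])
        for left, right, i0, i1 in merged:
            start_bp = left * bs
            end_bp = (right + 1) * bs
            if layout is not None:
                end_bp = min(end_bp, layout.length_of(chrom))
            if end_bp - start_bp < params.min_width:
                continue
            core = slice(i0, i1 + 1)
            span = slice(left, right + 1)
            summit_bin = left + int(np.argmax(obs[span]))
            summit = min(summit_bin * bs + bs // 2, end_bp - 1)
            rows.append((
                chrom, start_bp, end_bp, summit,
                float(p[core].min()), float(q[core].min()), "",
            ))
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return PeakSet(df)


def peak_width_stats(peaks: PeakSet) -> tuple[float, float, np.ndarray]:
    """Median and mean peak width (end - start) in bp, plus the raw widths."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    widths = peaks.widths()
    return float(np.median(widths)), float(np.mean(widths)), widths


def _interval_index(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) of the *union* of intervals, sorted."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        ivals = sorted(zip(grp["start"].to_numpy(), grp["end"].to_numpy()))
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64).reshape(-1, 2)
        out[str(chrom)] = (arr[:, 0], arr[:, 1])
    return out


def _overlaps(index, chrom: str, start: int, end: int) -> bool:
    """>= 1 bp overlap of [start, end) with any indexed interval on chrom."""
    if chrom not in index:
        return False
    starts, ends = index[chrom]
    i = int(np.searchsorted(starts, end, side="left")) - 1
    return i >= 0 and ends[i] > start


def overlaps_any(index, chroms, starts, ends) -> np.ndarray:
    """Vectorized >= 1 bp overlap query against an interval union index.

    Because the indexed intervals are a sorted non-overlapping union, a query
    overlaps iff the last interval starting before its end extends past its
    start.
    """
    chroms = np.asarray(chroms)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    out = np.zeros(len(chroms), dtype=bool)
    for chrom in np.unique(chroms):
        if chrom not in index:
            continue
        istarts, iends = index[chrom]
        sel = chroms == chrom
        i = np.searchsorted(istarts, ends[sel], side="left") - 1
        valid = i >= 0
        hit = np.zeros(int(sel.sum()), dtype=bool)
        hit[valid] = iends[i[valid]] > starts[sel][valid]
        out[sel] = hit
    return out


def annotate_peaks(
    peaks: PeakSet, features: FeatureSet
) -> tuple[PeakSet, dict[str, int]]:
    """Label each peak with every feature class it overlaps by >= 1 bp.

    The label is the exact combination (e.g. ``Red1+Spo11``); peaks overlapping
    nothing are ``Nil``. The returned category counts partition the peak set.
    """
    chroms = peaks.df["chrom"].to_numpy()
    starts = peaks.df["start"].to_numpy()
    ends = peaks.df["end"].to_numpy()
    hits = {}
    for fclass, label in CLASS_LABELS.items():
        idx = _interval_index(features.of_class(fclass))
        hits[label] = overlaps_any(idx, chroms, starts, ends)
    labels = []
    for i in range(len(peaks)):
        hit = sorted(label for label in hits if hits[label][i])
        labels.append("+".join(hit) if hit else "Nil")
    df = peaks.df.copy()
    df["label"] = labels
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return PeakSet(df), counts


def peakset_overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """Fraction of a-peaks overlapping >= 1 b-peak by >= 1 bp (asymmetric)."""
    if len(a) == 0:
        raise ValueError("empty query peak set")
    idx = _interval_index(b.df)
    hits = overlaps_any(
        idx,
        a.df["chrom"].to_numpy(),
        a.df["start"].to_numpy(),
        a.df["end"].to_numpy(),
    )
    return float(hits.sum()) / len(a)


def fold_enrichment(
    chip_counts: BinnedTrack,
    untagged_counts: BinnedTrack,
    windows,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Per-window (chip RPM + pc) / (untagged RPM + pc).

    ``windows`` is an iterable of (chrom, start, end); reads-per-million uses
    each track's own genome-wide total, so depth cancels.
    """
    chip_counts.require_compatible(untagged_counts)
    chip_total = chip_counts.total()
    unt_total = untagged_counts.total()
    if chip_total <= 0 or unt_total <= 0:
        raise ValueError("fold enrichment requires nonempty tracks")
    out = []
    for chrom, start, end in windows:
        rpm_c = chip_counts.window_sum(chrom, start, end) / chip_total * 1e6
        rpm_u = untagged_counts.window_sum(chrom, start, end) / unt_total * 1e6
        out.append((rpm_c + pseudocount) / (rpm_u + pseudocount))
    return np.asarray(out)


def metaprofile(track: BinnedTrack, centers, flank: int = 500) -> np.ndarray:
    """Signal averaged over windows of +/-``flank`` bp aligned at ``centers``.

    ``centers`` is an iterable of (chrom, position). Windows clipped by a
    chromosome edge are dropped. Returns a vector of ``2*flank/bin_size`` bins.
    """
    bs = track.bin_size
    half = flank // bs
    rows = []
    for chrom, pos in centers:
        v = track.values[chrom]
        cb = int(pos) // bs
        lo, hi = cb - half, cb + half
        if lo < 0 or hi > len(v):
            continue
        rows.append(v[lo:hi])
    if not rows:
        raise ValueError("no usable centers (all windows clipped)")
    return np.mean(rows, axis=0)
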