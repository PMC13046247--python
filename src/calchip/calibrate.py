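"""Spike-in calibration of ChIP-seq coverage tracks.

The calibration places tagged-ChIP and untagged-control coverage on a common,
depth-independent scale using reads from a spike-in genome (cells of a related
species mixed at a fixed ratio before immunoprecipitation):

* **SF1** = unique target-genome reads / unique spike-genome reads. Because the
  spike-in chromatin is pulled down only non-specifically, SF1 measures the
  specific+nonspecific IP yield per unit of nonspecific background and is
  independent of sequencing depth.
* **SF2** = SF1 / (the sample's genome-wide mean raw reads per bin). Multiplying
  a sample's binned counts by its SF2 therefore divides out its own sequencing
  depth and rescales by SF1, so calibrated tracks from libraries sequenced to
  different depths are directly comparable.

The calibrated track is the per-bin difference between the SF2-scaled ChIP
track and the SF2-scaled untagged track (nonspecific background subtraction);
negative values are retained. Replicates are averaged after calibration and
the averaged track is smoothed with a Gaussian Nadaraya-Watson kernel whose
quartiles sit at +/-0.25x the bandwidth (1 kb by default).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout
from .reads import MappedReadSet
from .tracks import BinnedTrack

# Gaussian sd per unit bandwidth, placing kernel quartiles at +/-0.25*bandwidth.
_KERNEL_SD_PER_BANDWIDTH = 0.25 / 0.6744897501960817
# Kernel support radius in sd units; the excluded tail mass is ~1e-15.
_KERNEL_RADIUS_SD = 8.0


@dataclass(frozen=True)
class ScalingFactors:
    """Spike-in scaling factors for one sample."""

    sample_id: str
    sf1: float
    sf2: float

    def __post_init__(self):
        if not (self.sf1 > 0 and self.sf2 > 0):
            raise ValueError("scaling factors must be positive")


def count_unique_reads(reads: MappedReadSet) -> tuple[int, int]:
    """Counts of uniquely mapped target-genome and spike-genome reads.

    Ambiguous and unmapped records are excluded from both counts.
    """
    counts = reads.status_counts()
    return counts["target_unique"], counts["spike_unique"]


def compute_scaling(
    n_target_unique: int,
    n_spike_unique: int,
    coverage: float,
    sample_id: str = "",
) -> ScalingFactors:
    """SF1 = target/spike unique reads; SF2 = SF1 / coverage.

    ``coverage`` is the genome-wide mean raw reads per bin of the sample being
    scaled, so that multiplying the sample's binned counts by SF2 removes its
    own sequencing depth.
    """
    if n_spike_unique <= 0:
        raise ValueError("no spike-in signal: zero uniquely mapped spike reads")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    sf1 = n_target_unique / n_spike_unique
    if sf1 <= 0:
        raise ValueError("no target signal: zero uniquely mapped target reads")
    return ScalingFactors(sample_id=sample_id, sf1=sf1, sf2=sf1 / coverage)


def bin_reads(
    reads: MappedReadSet,
    layout: GenomeLayout,
    bin_size: int = 10,
    strand_shift: int = 0,
) -> BinnedTrack:
    """Count uniquely mapped target reads into fixed-width bins (5' positions).

    Only ``target_unique`` records contribute; the total over all bins equals
    the unique target read count. ``strand_shift`` moves each 5' position
    3'-ward by that many bp (half the mean fragment length reunites the
    plus- and minus-strand pileups over the fragment midpoint, the classical
    read-shift used before Poisson peak scoring); 0 bins raw 5' positions.
    """
    reads.validate_against(layout)
    track = BinnedTrack.zeros(layout, bin_size=bin_size)
    tu = reads.target_unique()
    for chrom, grp in tu.groupby("chrom", sort=False, observed=True):
        chrom = str(chrom)
        nb = layout.n_bins(chrom, bin_size)
        pos = grp["pos"].to_numpy()
        if strand_shift:
            offs = np.where(grp["strand"].to_numpy() == "-",
                            -strand_shift, strand_shift)
            pos = np.clip(pos + offs, 0, layout.length_of(chrom) - 1)
        idx = pos // bin_size
        track.values[chrom] += np.bincount(idx, minlength=nb).astype(float)
    track.provenance = {
        "sample_id": reads.sample_id, "bin_size": bin_size,
        "strand_shift": strand_shift,
    }
    return track


def scale_sample(
    reads: MappedReadSet, layout: GenomeLayout, bin_size: int = 10
) -> tuple[BinnedTrack, ScalingFactors]:
    """Bin a sample's reads and compute its scaling factors in one step."""
    track = bin_reads(reads, layout, bin_size=bin_size)
    n_t, n_s = count_unique_reads(reads)
    sf = compute_scaling(n_t, n_s, track.mean_per_bin(), sample_id=reads.sample_id)
    return track, sf


def calibrate(
    chip: BinnedTrack,
    untagged: BinnedTrack,
    sf_chip: ScalingFactors,
    sf_untagged: ScalingFactors,
) -> BinnedTrack:
    """Per-bin SF2-scaled untagged subtraction: chip*sf2_chip - untagged*sf2_untagged.

    Negative output values are retained (clamping would bias genome-wide means).
    """
    chip.require_compatible(untagged)
    vals = {
        c: chip.values[c] * sf_chip.sf2 - untagged.values[c] * sf_untagged.sf2
        for c in chip.values
    }
    return BinnedTrack(
        bin_size=chip.bin_size,
        values=vals,
        state="calibrated",
        provenance={
            "chip": sf_chip.sample_id, "untagged": sf_untagged.sample_id,
            "sf2_chip": sf_chip.sf2, "sf2_untagged": sf_untagged.sf2,
        },
    )


def average_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Per-bin arithmetic mean across replicate tracks of identical shape and state."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        first.require_compatible(t)
        if t.state != first.state:
            raise ValueError("cannot average tracks in different states")
    vals = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.values
    }
    return BinnedTrack(
        bin_size=first.bin_size,
        values=vals,
        state=first.state,
        provenance={"averaged": [t.provenance for t in tracks]},
    )


def _nw_direct(centers: np.ndarray, values: np.ndarray, at: np.ndarray, sd: float) -> np.ndarray:
    """Direct Nadaraya-Watson estimate at positions ``at`` (small inputs only)."""
    d = at[:, None] - centers[None, :]
    w = np.exp(-0.5 * (d / sd) ** 2)
    return (w * values[None, :]).sum(axis=1) / w.sum(axis=1)


def smooth(
    track: BinnedTrack, bandwidth: float = 1000.0, layout: GenomeLayout | None = None
) -> BinnedTrack:
    """Gaussian-kernel Nadaraya-Watson smoothing at every bin center.

    The kernel's quartiles sit at +/-0.25*bandwidth (the convention of the
    classical normal-kernel scatterplot smoother), i.e. sd = 0.25*bandwidth /
    0.6745. Weights renormalize over available bins at chromosome edges, so
    constant tracks are fixed points. If ``layout`` is given, the last
    (possibly partial) bin of each chromosome is evaluated at its true center.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sd = bandwidth * _KERNEL_SD_PER_BANDWIDTH
    bs = track.bin_size
    radius = int(np.ceil(_KERNEL_RADIUS_SD * sd / bs))
    offsets = np.arange(-radius, radius + 1) * bs
    kernel = np.exp(-0.5 * (offsets / sd) ** 2)

    out: dict[str, np.ndarray] = {}
    for chrom, v in track.values.items():
        n = len(v)
        chrom_len = layout.length_of(chrom) if layout is not None else None
        if n <= len(kernel):  # short chromosome: direct evaluation
            centers = track.bin_centers(chrom, chrom_len)
            out[chrom] = _nw_direct(centers, v, centers, sd)
            continue
        num = np.convolve(v, kernel, mode="same")
        den = np.convolve(np.ones(n), kernel, mode="same")
        sm = num / den
        if chrom_len is not None and chrom_len < n * bs:
            # the last bin is partial: its true center shifts, so recompute
            # every bin whose kernel window can reach it
            centers = track.bin_centers(chrom, chrom_len)
            lo = max(0, n - 1 - radius)
            src_lo = max(0, lo - radius)
            sub = _nw_direct(
                centers[src_lo:], v[src_lo:], centers[lo:], sd
            )
            sm[lo:] = sub
        out[chrom] = sm
    return BinnedTrack(
        bin_size=bs,
        values=out,
        state="smoothed",
        provenance={**track.provenance, "bandwidth": bandwidth},
    )
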