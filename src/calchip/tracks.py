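"""Per-chromosome binned signal vectors (raw, normalized, calibrated, smoothed)."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout

TRACK_STATES = ("raw_counts", "normalized", "calibrated", "smoothed")


@dataclass
class BinnedTrack:
    """Signal in fixed-width genomic bins.

    One value per ``bin_size``-bp bin per chromosome; the last bin may be
    shorter than ``bin_size``. Raw counts are nonnegative; calibrated values
    may be negative (background subtraction is not clamped).
    """

    bin_size: int
    values: dict[str, np.ndarray]
    state: str = "raw_counts"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.state not in TRACK_STATES:
            raise ValueError(f"unknown track state {self.state!r}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        if self.state == "raw_counts":
            for c, v in self.values.items():
                if (v < 0).any():
                    raise ValueError(f"negative raw counts on {c}")

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_size: int = 10, state: str = "raw_counts"):
        vals = {c: np.zeros(layout.n_bins(c, bin_size)) for c in layout.chrom_names}
        return cls(bin_size=bin_size, values=vals, state=state)

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.values.values()))

    def mean_per_bin(self) -> float:
        n = self.n_bins()
        if n == 0:
            raise ValueError("empty track")
        return self.total() / n

    def compatible_with(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )

    def require_compatible(self, other: "BinnedTrack") -> None:
        if not self.compatible_with(other):
            raise ValueError("tracks have mismatched layout or bin size")

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of bin values for bins fully or partly inside [start, end)."""
        v = self.values[chrom]
        if not (0 <= start < end <= len(v) * self.bin_size):
            raise ValueError(f"window ({chrom}, {start}, {end}) out of bounds")
        b0 = start // self.bin_size
        b1 = -(-end // self.bin_size)
        return float(v[b0:b1].sum())

    def bin_centers(self, chrom: str, chrom_length: int | None = None) -> np.ndarray:
        """Bin-center coordinates; the last (possibly partial) bin uses its true width."""
        n = len(self.values[chrom])
        centers = np.arange(n, dtype=float) * self.bin_size + self.bin_size / 2.0
        if chrom_length is not None and chrom_length < n * self.bin_size:
            centers[-1] = ((n - 1) * self.bin_size + chrom_length) / 2.0
        return centers
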