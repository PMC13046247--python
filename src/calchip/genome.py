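"""Genome coordinate bookkeeping: chromosome layout and excluded intervals.

All coordinates in the package are 0-based, half-open (BED convention).
Printed 1-based inclusive coordinates (e.g. the budding-yeast rDNA locus,
chrXII 451418-489465) are converted on ingestion.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field


# sacCer3 (R64-1-1) chromosome lengths in bp, used by the yeast-like generator.
_SACCER3_LENGTHS = {
    "chrI": 230218, "chrII": 813184, "chrIII": 316620, "chrIV": 1531933,
    "chrV": 576874, "chrVI": 270161, "chrVII": 1090940, "chrVIII": 562643,
    "chrIX": 439888, "chrX": 745751, "chrXI": 666816, "chrXII": 1078177,
    "chrXIII": 924431, "chrXIV": 784333, "chrXV": 1091291, "chrXVI": 948066,
}

# rDNA repeat locus on chrXII, 0-based half-open (printed 451418-489465,
# 1-based inclusive). Excluded from chromosome-level density statistics.
RDNA_EXCLUSION = ("chrXII", 451417, 489465)


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths, plus intervals excluded from density stats.

    Parameters
    ----------
    chrom_names:
        Ordered chromosome identifiers.
    chrom_lengths:
        Length in bp for each chromosome, same order as ``chrom_names``.
    exclusions:
        ``(chrom, start, end)`` intervals (0-based half-open) to be excluded
        from read-density statistics, e.g. the highly repetitive rDNA locus.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    exclusions: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.exclusions:
            if chrom not in self.lengths_by_chrom:
                raise ValueError(f"exclusion on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.lengths_by_chrom[chrom]):
                raise ValueError(
                    f"exclusion ({chrom}, {start}, {end}) outside chromosome bounds"
                )
            per_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping exclusions on {chrom}")

    @property
    def lengths_by_chrom(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_size(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths_by_chrom[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.length_of(chrom) / bin_size)

    def exclusions_on(self, chrom: str) -> list[tuple[int, int]]:
        return sorted((s, e) for c, s, e in self.exclusions if c == chrom)

    def excluded_bp(self, chrom: str) -> int:
        return sum(e - s for s, e in self.exclusions_on(chrom))

    def usable_length(self, chrom: str) -> int:
        return self.length_of(chrom) - self.excluded_bp(chrom)


def make_genome_layout(
    n_chroms: int,
    lengths: list[int],
    exclusions: list[tuple[str, int, int]] | None = None,
    chrom_names: list[str] | None = None,
) -> GenomeLayout:
    """Build a :class:`GenomeLayout` with ``n_chroms`` chromosomes.

    Chromosomes are named ``chr1 .. chrN`` unless ``chrom_names`` is given.
    """
    if n_chroms != len(lengths):
        raise ValueError(f"n_chroms={n_chroms} but {len(lengths)} lengths given")
    if chrom_names is None:
        chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    return GenomeLayout(
        chrom_names=tuple(chrom_names),
        chrom_lengths=tuple(int(x) for x in lengths),
        exclusions=tuple(exclusions or ()),
    )


def yeast_like_layout(scale: float = 1.0, rdna_exclusion: bool = True) -> GenomeLayout:
    """A 16-chromosome layout with sacCer3 chromosome sizes.

    ``scale`` shrinks every chromosome proportionally for desk-scale runs;
    the rDNA exclusion is only meaningful (and only included) at scale 1.
    """
    names = tuple(_SACCER3_LENGTHS)
    lengths = tuple(max(1, int(round(v * scale))) for v in _SACCER3_LENGTHS.values())
    exclusions = (RDNA_EXCLUSION,) if (rdna_exclusion and scale == 1.0) else ()
    return GenomeLayout(names, lengths, exclusions)
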