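"""Mapped-read records: the substrate of spike-in calibration.

The pipeline starts downstream of alignment: each read is a (chrom, 5'
position, strand) record with a mapping status telling whether it mapped
uniquely to the target genome, uniquely to the spike-in genome, ambiguously,
or not at all. Spike-unique and unmapped records carry no target coordinate
(chrom ``"."``, pos ``-1``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout

READ_STATUSES = ("target_unique", "spike_unique", "ambiguous", "unmapped")

_NO_POS_STATUSES = {"spike_unique", "unmapped"}

READ_COLUMNS = ["chrom", "pos", "strand", "status"]


@dataclass
class MappedReadSet:
    """Per-sample read records with genome-uniqueness status."""

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in READ_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"MappedReadSet missing columns {missing}")
        if self.df["status"].isna().any():
            raise ValueError("missing read status")
        bad = set(self.df["status"].unique()) - set(READ_STATUSES)
        if bad:
            raise ValueError(f"unknown read statuses {sorted(bad)}")
        on_target = ~self.df["status"].isin(_NO_POS_STATUSES)
        if (self.df.loc[on_target, "pos"] < 0).any():
            raise ValueError("target-mapped read with negative position")
        if (self.df.loc[~on_target, "pos"] != -1).any():
            raise ValueError("spike/unmapped read carrying a target position")

    @classmethod
    def from_arrays(cls, sample_id, chrom, pos, strand, status) -> "MappedReadSet":
        df = pd.DataFrame({
            "chrom": pd.Categorical(chrom),
            "pos": np.asarray(pos, dtype=np.int64),
            "strand": pd.Categorical(strand, categories=["+", "-", "."]),
            "status": pd.Categorical(status, categories=list(READ_STATUSES)),
        })
        return cls(sample_id, df)

    @property
    def n_reads(self) -> int:
        return len(self.df)

    def status_counts(self) -> dict[str, int]:
        counts = self.df["status"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in READ_STATUSES}

    def target_unique(self) -> pd.DataFrame:
        return self.df[self.df["status"] == "target_unique"]

    def validate_against(self, layout: GenomeLayout) -> None:
        tu = self.df[~self.df["status"].isin(_NO_POS_STATUSES)]
        for chrom, grp in tu.groupby("chrom", sort=False, observed=True):
            limit = layout.length_of(str(chrom))
            bad = grp[grp["pos"] >= limit]
            if len(bad):
                i = bad.index[0]
                raise ValueError(
                    f"read {i} of sample {self.sample_id!r} at {chrom}:{bad.loc[i, 'pos']} "
                    f"outside chromosome (length {limit})"
                )
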