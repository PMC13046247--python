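"""Classed genomic feature intervals: DSB hotspots, axis sites, centromeres, coldspots.

Hotspots carry a nonnegative ``strength`` (the Spo11-oligo-count proxy); other
classes carry no strength. Intervals of the same class never overlap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout

FEATURE_CLASSES = ("hotspot", "axis", "centromere", "coldspot")

COLUMNS = ["chrom", "start", "end", "feature_class", "strength", "name"]


@dataclass(frozen=True)
class FeatureSet:
    """Immutable table of classed feature intervals.

    ``df`` columns: chrom, start, end, feature_class, strength (NaN except for
    hotspots), name.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"FeatureSet missing columns {missing}")
        bad = set(df["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("feature with start >= end")
        if (df["start"] < 0).any():
            raise ValueError("feature with negative start")
        is_hot = df["feature_class"] == "hotspot"
        if df.loc[is_hot, "strength"].isna().any():
            raise ValueError("hotspot lacking a strength")
        if (df.loc[is_hot, "strength"] < 0).any():
            raise ValueError("negative hotspot strength")
        if df.loc[~is_hot, "strength"].notna().any():
            raise ValueError("strength present on a non-hotspot feature")
        for (chrom, fclass), grp in df.groupby(["chrom", "feature_class"], sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping {fclass} features on {chrom}")

    @classmethod
    def from_records(cls, records) -> "FeatureSet":
        """Build from an iterable of (chrom, start, end, feature_class[, strength[, name]])."""
        rows = []
        for i, rec in enumerate(records):
            rec = tuple(rec)
            chrom, start, end, fclass = rec[:4]
            strength = rec[4] if len(rec) > 4 else None
            name = rec[5] if len(rec) > 5 else f"{fclass}_{i}"
            rows.append((chrom, int(start), int(end), fclass,
                         np.nan if strength is None else float(strength), name))
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    def validate_against(self, layout: GenomeLayout) -> None:
        for _, row in self.df.iterrows():
            if row["chrom"] not in layout.lengths_by_chrom:
                raise ValueError(f"feature on unknown chromosome {row['chrom']!r}")
            if row["end"] > layout.length_of(row["chrom"]):
                raise ValueError(
                    f"feature {row['name']} exceeds chromosome {row['chrom']} bounds"
                )

    def of_class(self, feature_class: str) -> pd.DataFrame:
        if feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {feature_class!r}")
        return self.df[self.df["feature_class"] == feature_class].reset_index(drop=True)

    @property
    def hotspots(self) -> pd.DataFrame:
        return self.of_class("hotspot")

    def __len__(self) -> int:
        return len(self.df)

    def class_counts(self) -> dict[str, int]:
        return self.df["feature_class"].value_counts().to_dict()

    def midpoints(self, feature_class: str | None = None) -> pd.DataFrame:
        df = self.df if feature_class is None else self.of_class(feature_class)
        out = df[["chrom"]].copy()
        out["midpoint"] = (df["start"] + df["end"]) // 2
        return out
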