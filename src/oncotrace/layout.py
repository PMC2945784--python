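"""Genome coordinate frame and planted-truth containers.

All coordinates are 0-based half-open throughout the package; files on
disk use the same convention (BED-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

LOH_STATES = ("normal", "low", "high")
CNV_STATES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with their lengths (bp, 0-based half-open)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return (
            chrom in self.lengths
            and 0 <= start < end <= self.lengths[chrom]
        )

    def check_segments(self, segments: pd.DataFrame, label: str = "segment") -> None:
        """Raise if any (chrom, start, end) row falls outside the layout."""
        for row in segments.itertuples(index=False):
            if not self.contains(row.chrom, int(row.start), int(row.end)):
                raise ValueError(
                    f"{label} {row.chrom}:{row.start}-{row.end} outside layout"
                )


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class TruthSet:
    """Planted ground truth for one synthetic case.

    cnv_segments: chrom, start, end, state (1..5), per timepoint via the
        optional ``timepoint`` column (absent → applies to every tumor).
    loh_segments: chrom, start, end, state ('normal'/'low'/'high'),
        optional ``timepoint``.
    germline_het_sites: chrom, pos — heterozygous in the patient germline.
    somatic_variants: chrom, pos, ref, alt, vaf, timepoints
        (comma-joined tumor labels the variant is present in).
    de_genes: gene_id, direction ('up'/'down'), effect_size (>1 for up,
        <1 for down, multiplicative on the tumor expectation).
    """

    cnv_segments: pd.DataFrame = field(
        default_factory=lambda: _empty(["chrom", "start", "end", "state"])
    )
    loh_segments: pd.DataFrame = field(
        default_factory=lambda: _empty(["chrom", "start", "end", "state"])
    )
    germline_het_sites: pd.DataFrame = field(
        default_factory=lambda: _empty(["chrom", "pos"])
    )
    somatic_variants: pd.DataFrame = field(
        default_factory=lambda: _empty(
            ["chrom", "pos", "ref", "alt", "vaf", "timepoints"]
        )
    )
    de_genes: pd.DataFrame = field(
        default_factory=lambda: _empty(["gene_id", "direction", "effect_size"])
    )

    def validate(self, layout: GenomeLayout) -> None:
        if len(self.cnv_segments):
            layout.check_segments(self.cnv_segments, "CNV truth segment")
            bad = set(self.cnv_segments["state"]) - set(CNV_STATES)
            if bad:
                raise ValueError(f"illegal CNV states {bad}")
            _check_disjoint(self.cnv_segments, "CNV truth")
        if len(self.loh_segments):
            layout.check_segments(self.loh_segments, "LOH truth segment")
            bad = set(self.loh_segments["state"]) - set(LOH_STATES)
            if bad:
                raise ValueError(f"illegal LOH states {bad}")
            _check_disjoint(self.loh_segments, "LOH truth")
        if len(self.somatic_variants):
            vaf = self.somatic_variants["vaf"].astype(float)
            if ((vaf <= 0) | (vaf > 1)).any():
                raise ValueError("somatic allele fractions must lie in (0, 1]")

    def cnv_for(self, timepoint: str) -> pd.DataFrame:
        return _select_timepoint(self.cnv_segments, timepoint)

    def loh_for(self, timepoint: str) -> pd.DataFrame:
        return _select_timepoint(self.loh_segments, timepoint)

    def somatic_for(self, timepoint: str) -> pd.DataFrame:
        if not len(self.somatic_variants):
            return self.somatic_variants
        mask = self.somatic_variants["timepoints"].map(
            lambda t: timepoint in str(t).split(",")
        )
        return self.somatic_variants[mask].reset_index(drop=True)


def _select_timepoint(df: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    if "timepoint" not in df.columns or not len(df):
        return df
    mask = df["timepoint"].isna() | (df["timepoint"] == timepoint)
    return df[mask].reset_index(drop=True)


def _check_disjoint(segments: pd.DataFrame, label: str) -> None:
    group_cols = ["chrom"]
    if "timepoint" in segments.columns:
        group_cols.append("timepoint")
    for _, grp in segments.groupby(group_cols, dropna=False):
        srt = grp.sort_values("start")
        if (srt["start"].values[1:] < srt["end"].values[:-1]).any():
            raise ValueError(f"{label} segments overlap within one track")
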