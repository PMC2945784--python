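"""Interval bookkeeping shared by the segmentation and diff layers."""

from __future__ import annotations

import numpy as np
import pandas as pd


def interval_counts(track: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Overlap-proportional read counts of ``track`` inside each interval.

    ``track`` holds (chrom, start, end, count) windows; reads within a
    window are treated as uniformly spread, so a window split by an
    interval boundary contributes its count pro rata. Returns one float
    per row of ``intervals`` (chrom, start, end).
    """
    out = np.zeros(len(intervals), dtype=float)
    by_chrom = {c: g for c, g in track.groupby("chrom", sort=False)}
    for chrom, idx in intervals.groupby("chrom", sort=False).groups.items():
        g = by_chrom.get(chrom)
        if g is None:
            raise ValueError(f"track has no chromosome {chrom!r}")
        starts = g["start"].to_numpy(float)
        ends = g["end"].to_numpy(float)
        counts = g["count"].to_numpy(float)
        # cumulative count as a piecewise-linear function of position
        cum = np.concatenate([[0.0], np.cumsum(counts)])

        def cum_at(pos: np.ndarray) -> np.ndarray:
            i = np.searchsorted(ends, pos, side="left")
            i = np.clip(i, 0, len(starts) - 1)
            frac = np.clip((pos - starts[i]) / (ends[i] - starts[i]), 0.0, 1.0)
            base = cum[i] + frac * counts[i]
            return np.where(pos >= ends[-1], cum[-1], np.where(pos <= starts[0], 0.0, base))

        sub = intervals.loc[idx]
        out[intervals.index.get_indexer(idx)] = cum_at(
            sub["end"].to_numpy(float)
        ) - cum_at(sub["start"].to_numpy(float))
    return out


def intersect_segmentations(a: pd.DataFrame, b: pd.DataFrame,
                            suffixes: tuple[str, str] = ("_a", "_b")) -> pd.DataFrame:
    """Boundary-intersect two state segmentations of the same layout.

    Both inputs carry (chrom, start, end, state). The result tiles the
    region covered by BOTH inputs, with one row per maximal interval on
    which each input's state is constant.
    """
    sa, sb = suffixes
    rows = []
    chroms = [c for c in a["chrom"].unique() if c in set(b["chrom"])]
    for chrom in chroms:
        ga = a[a["chrom"] == chrom].sort_values("start")
        gb = b[b["chrom"] == chrom].sort_values("start")
        cuts = np.unique(
            np.concatenate(
                [ga["start"], ga["end"], gb["start"], gb["end"]]
            ).astype(int)
        )
        for s, e in zip(cuts[:-1], cuts[1:]):
            mid = (s + e) / 2
            ra = ga[(ga["start"] <= mid) & (ga["end"] > mid)]
            rb = gb[(gb["start"] <= mid) & (gb["end"] > mid)]
            if len(ra) and len(rb):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(s),
                        "end": int(e),
                        f"state{sa}": ra["state"].iloc[0],
                        f"state{sb}": rb["state"].iloc[0],
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", f"state{sa}", f"state{sb}"]
    )


def state_at(segments: pd.DataFrame, chrom: str, pos: float):
    """State of the segment covering ``pos``, or None if uncovered."""
    g = segments[(segments["chrom"] == chrom)
                 & (segments["start"] <= pos) & (segments["end"] > pos)]
    return None if not len(g) else g["state"].iloc[0]


def overlapping_states(segments: pd.DataFrame, chrom: str,
                       start: int, end: int) -> list:
    """States of all segments overlapping [start, end) by >= 1 bp."""
    g = segments[(segments["chrom"] == chrom)
                 & (segments["start"] < end) & (segments["end"] > start)]
    return list(g["state"])
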