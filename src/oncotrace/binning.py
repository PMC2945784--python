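"""Equal-reference-coverage genomic bins and tumor/normal depth ratios.

Bins are defined on the reference (normal) read track so that every
complete bin holds the same number of reference reads; bin width is
therefore inversely proportional to the local mapped-read density.
Tumor counts are then accumulated into those bins and expressed as a
median-centered log2 depth ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import interval_counts

BIN_COLUMNS = ["chrom", "start", "end", "ref_reads", "partial"]


def _check_track(track: pd.DataFrame) -> None:
    if track is None or not len(track):
        raise ValueError("empty read-count track")
    for _, g in track.groupby("chrom", sort=False):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if (np.diff(starts) <= 0).any() or (starts >= ends).any():
            raise ValueError("track windows must be sorted and non-degenerate")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("track windows overlap")


def build_bins(ref_track: pd.DataFrame, reads_per_bin: int = 200) -> pd.DataFrame:
    """Tile each chromosome into bins of exactly ``reads_per_bin``
    reference reads.

    Reads inside a track window are treated as uniformly spread, so a
    bin boundary may split a window pro rata. The trailing bin on a
    chromosome holds the remainder and is flagged ``partial``. Bins
    never span chromosomes.
    """
    if reads_per_bin < 1:
        raise ValueError("reads per bin must be >= 1")
    _check_track(ref_track)

    rows = []
    for chrom, g in ref_track.groupby("chrom", sort=False):
        starts = g["start"].to_numpy(float)
        ends = g["end"].to_numpy(float)
        counts = g["count"].to_numpy(float)
        total = counts.sum()
        cum = np.concatenate([[0.0], np.cumsum(counts)])
        n_complete = int(total // reads_per_bin)
        targets = reads_per_bin * np.arange(1, n_complete + 1, dtype=float)
        # position where the cumulative count reaches each target
        idx = np.searchsorted(cum[1:], targets, side="left")
        idx = np.clip(idx, 0, len(counts) - 1)
        with np.errstate(invalid="ignore"):
            frac = np.where(counts[idx] > 0,
                            (targets - cum[idx]) / counts[idx], 1.0)
        cuts = starts[idx] + frac * (ends[idx] - starts[idx])
        cuts = np.round(cuts).astype(int)
        bounds = np.concatenate([[int(starts[0])], cuts])
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(s), int(max(e, s + 1)),
                         float(reads_per_bin), False))
        leftover = total - reads_per_bin * n_complete
        tail_start = bounds[-1]
        tail_end = int(ends[-1])
        if tail_end > tail_start and leftover > 0:
            rows.append((chrom, int(tail_start), tail_end, float(leftover), True))
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def fill_ratios(bins: pd.DataFrame, tumor_track: pd.DataFrame,
                pseudocount: float = 1.0) -> pd.DataFrame:
    """Add tumor counts and median-centered log2 depth ratios to bins.

    With R and T the reference and tumor library totals, the raw ratio
    for bin i is ``((t_i + pc*T/R)/T) / ((r_i + pc)/R)``: the tumor-side
    pseudocount is expressed in reference-library units so that scaling
    every tumor count by a constant leaves all ratios unchanged. The
    log2 ratios are then re-centered to median 0.
    """
    _check_track(tumor_track)
    missing = set(tumor_track["chrom"]) - set(bins["chrom"])
    if missing:
        raise ValueError(f"tumor track chromosomes absent from bins: {missing}")
    out = bins.copy()
    tumor = interval_counts(
        tumor_track, out[["chrom", "start", "end"]])
    ref = out["ref_reads"].to_numpy(float)
    T = float(tumor_track["count"].sum())
    R = float(ref.sum())
    if T <= 0 or R <= 0:
        raise ValueError("tracks must contain reads")
    ratio = ((tumor + pseudocount * T / R) / T) / ((ref + pseudocount) / R)
    log_ratio = np.log2(ratio)
    log_ratio -= np.median(log_ratio)
    out["tumor_reads"] = tumor
    out["log_ratio"] = log_ratio
    return out
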