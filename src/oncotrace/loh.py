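"""Loss-of-heterozygosity inference from SNP zygosity.

Informative sites are those heterozygous in the germline sample; the
tumor's zygosity at those sites is binned (equal SNP count per bin) and
segmented by a 3-state HMM with binomial emissions: normal
heterozygosity, increased homozygosity ('low' — only part of the cell
population lost an allele), and total homozygosity ('high').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _hmm
from .intervals import intersect_segmentations

LOH_STATE_NAMES = ("normal", "low", "high")

BIN_COLUMNS = ["chrom", "start", "end", "n_snps", "n_het", "het_rate", "partial"]


def classify_zygosity(calls: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Boolean het label per call: het iff p_het >= threshold."""
    p = calls["p_het"].astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("heterozygosity probabilities must lie in [0, 1]")
    return p >= threshold


def bin_het_rate(sites: pd.DataFrame, snps_per_bin: int = 25) -> pd.DataFrame:
    """Bin labelled sites into runs of exactly ``snps_per_bin`` sites.

    ``sites`` needs chrom, pos and boolean ``is_het``, sorted by
    position within chromosome. Bin extents are contiguous within the
    covered span: boundaries fall midway between the flanking sites of
    adjacent bins, so bin width tracks local SNP density. Trailing bins
    with fewer sites are flagged partial.
    """
    if snps_per_bin < 5:
        raise ValueError("need at least 5 SNPs per bin")
    rows = []
    for chrom, g in sites.groupby("chrom", sort=False):
        pos = g["pos"].to_numpy(int)
        if (np.diff(pos) < 0).any():
            raise ValueError("sites must be sorted by position")
        het = g["is_het"].to_numpy(bool)
        n = len(pos)
        edges_idx = list(range(0, n, snps_per_bin)) + [n]
        for a, b in zip(edges_idx[:-1], edges_idx[1:]):
            start = int(pos[a]) if a == 0 else (int(pos[a - 1]) + int(pos[a])) // 2 + 1
            end = int(pos[b - 1]) + 1 if b == n else (int(pos[b - 1]) + int(pos[b])) // 2 + 1
            n_snps = b - a
            n_het = int(het[a:b].sum())
            rows.append((chrom, start, end, n_snps, n_het,
                         n_het / n_snps, n_snps < snps_per_bin))
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


@dataclass
class LohHmmParams:
    """3-state binomial-emission HMM over per-bin het counts.

    rates: expected het fraction among informative (germline-het)
        sites per state — normal retention, 50/50 subclonal loss, and
        complete loss.
    """

    rates: tuple[float, float, float] = (0.95, 0.50, 0.02)
    self_transition: float = 0.999
    initial: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if len(self.rates) != 3 or not np.all(np.diff(self.rates) < 0):
            raise ValueError("need 3 strictly decreasing het rates")
        for r in self.rates:
            if not 0.0 < r < 1.0:
                raise ValueError("het rates must lie in (0, 1)")

    def transition_matrix(self) -> np.ndarray:
        return _hmm.self_transition_matrix(3, self.self_transition)

    def emission_loglik(self, n_het: np.ndarray, n_snps: np.ndarray) -> np.ndarray:
        k = np.asarray(n_het)[:, None]
        n = np.asarray(n_snps)[:, None]
        return stats.binom.logpmf(k, n, np.asarray(self.rates)[None, :])


def segment_loh(bins: pd.DataFrame,
                params: LohHmmParams | None = None,
                include_partial: bool = False) -> pd.DataFrame:
    """Viterbi-decode het-rate bins into LOH segments.

    Returns chrom, start, end, state ('normal'/'low'/'high'), n_bins,
    het_rate (weighted mean). Bins without SNPs are skipped with a
    warning.
    """
    params = params or LohHmmParams()
    use = bins if include_partial else bins[~bins["partial"]]
    empty = use["n_snps"] <= 0
    if empty.any():
        warnings.warn(f"skipping {int(empty.sum())} bins without SNPs")
        use = use[~empty]
    if not len(use):
        raise ValueError("no usable LOH bins")
    log_trans = np.log(params.transition_matrix())
    log_init = np.log(np.asarray(params.initial))

    rows = []
    for chrom, g in use.groupby("chrom", sort=False):
        n_het = g["n_het"].to_numpy(int)
        n_snps = g["n_snps"].to_numpy(int)
        log_emit = params.emission_loglik(n_het, n_snps)
        path = _hmm.viterbi(log_emit, log_trans, log_init)
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        for i0, i1, st in _hmm.run_length_segments(path):
            rows.append((chrom, int(starts[i0]), int(ends[i1 - 1]),
                         LOH_STATE_NAMES[st], i1 - i0,
                         float(n_het[i0:i1].sum() / n_snps[i0:i1].sum())))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state", "n_bins", "het_rate"])


def loh_states_per_bin(bins: pd.DataFrame, segments: pd.DataFrame) -> list[str]:
    """Decoded LOH state per bin (empty string if uncovered)."""
    out = []
    for row in bins.itertuples(index=False):
        mid = (row.start + row.end) / 2
        g = segments[(segments["chrom"] == row.chrom)
                     & (segments["start"] <= mid) & (segments["end"] > mid)]
        out.append(str(g["state"].iloc[0]) if len(g) else "")
    return out


def copy_neutral_loh(loh_segments: pd.DataFrame,
                     cnv_segments: pd.DataFrame) -> pd.DataFrame:
    """Regions with allelic loss but diploid copy number.

    Boundary-intersects the two segmentations and keeps regions where
    the LOH state is not 'normal' while the CNV state is neutral (2);
    LOH over a deletion (state 1) is excluded as deletion LOH.
    """
    if not len(loh_segments) or not len(cnv_segments):
        return pd.DataFrame(
            columns=["chrom", "start", "end", "loh_state", "cnv_state"])
    table = intersect_segmentations(
        loh_segments, cnv_segments, suffixes=("_loh", "_cnv"))
    keep = (table["state_loh"] != "normal") & (table["state_cnv"].astype(int) == 2)
    out = table[keep].rename(
        columns={"state_loh": "loh_state", "state_cnv": "cnv_state"})
    return out.reset_index(drop=True)


def merge_contiguous(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge touching/overlapping regions per chromosome into events.

    Used when counting copy-neutral LOH events: a complete-LOH region
    whose boundary bins decode as 'low' is still one contiguous event.
    """
    if not len(regions):
        return regions.copy()
    rows = []
    for chrom, g in regions.sort_values(["chrom", "start"]).groupby(
            "chrom", sort=False):
        cur_start, cur_end = None, None
        for r in g.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end = int(r.start), int(r.end)
            elif int(r.start) <= cur_end:
                cur_end = max(cur_end, int(r.end))
            else:
                rows.append((chrom, cur_start, cur_end))
                cur_start, cur_end = int(r.start), int(r.end)
        rows.append((chrom, cur_start, cur_end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def loh_genome_fractions(loh_segments: pd.DataFrame) -> dict[str, float]:
    """Fractions of the covered extent in incomplete ('low') and
    complete ('high') LOH."""
    lengths = (loh_segments["end"] - loh_segments["start"]).to_numpy(float)
    total = lengths.sum()
    if total <= 0:
        return {"low": 0.0, "high": 0.0}
    states = loh_segments["state"].to_numpy()
    return {
        "low": float(lengths[states == "low"].sum() / total),
        "high": float(lengths[states == "high"].sum() / total),
    }
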