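"""Five-state copy-number segmentation of binned depth log-ratios.

States follow the loss/neutral/gain/amplification/high-amplification
convention (1..5). Emissions are Student-t (df 4) around fixed,
strictly increasing per-state log2-ratio means with a shared scale
estimated robustly from the data; transitions use a single
self-transition smoothing parameter. Decoding is hard Viterbi so each
bin receives one discrete state, then run-length encoded to segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _hmm
from .intervals import intersect_segmentations, overlapping_states

N_STATES = 5

SEGMENT_COLUMNS = ["chrom", "start", "end", "state", "n_bins", "mean_log_ratio"]


@dataclass
class CnvHmmParams:
    """Parameters of the 5-state copy-number HMM.

    means: per-state emission means in log2-ratio units, strictly
        increasing (defaults correspond to ~1, 2, 3, 4 and 8 copies
    relative to diploid).
    scale: shared Student-t scale; None → 1.4826 x median absolute
        residual to the nearest state mean (floored at ``min_scale``).
    """

    means: tuple[float, ...] = (-1.0, 0.0, 0.58, 1.0, 2.0)
    scale: float | None = None
    min_scale: float = 0.05
    df: float = 4.0
    self_transition: float = 0.999
    initial: tuple[float, ...] = field(
        default_factory=lambda: tuple([1.0 / N_STATES] * N_STATES))

    def __post_init__(self) -> None:
        if len(self.means) != N_STATES:
            raise ValueError("need exactly 5 emission means")
        if not np.all(np.diff(self.means) > 0):
            raise ValueError("emission means must be strictly increasing")
        if abs(sum(self.initial) - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")

    def transition_matrix(self) -> np.ndarray:
        return _hmm.self_transition_matrix(N_STATES, self.self_transition)

    def resolve_scale(self, log_ratios: np.ndarray) -> float:
        if self.scale is not None:
            return float(self.scale)
        means = np.asarray(self.means)
        resid = np.min(np.abs(log_ratios[:, None] - means[None, :]), axis=1)
        return max(self.min_scale, 1.4826 * float(np.median(resid)))

    def emission_loglik(self, log_ratios: np.ndarray,
                        scale: float) -> np.ndarray:
        x = np.asarray(log_ratios, dtype=float)[:, None]
        means = np.asarray(self.means)[None, :]
        return stats.t.logpdf(x, self.df, loc=means, scale=scale)


def viterbi_segment(bins: pd.DataFrame,
                    params: CnvHmmParams | None = None,
                    include_partial: bool = False) -> pd.DataFrame:
    """Decode binned log ratios into maximal constant-state segments.

    Chromosomes are decoded independently; partial trailing bins are
    excluded unless ``include_partial``. Raises on non-finite log
    ratios, naming the offending bin.
    """
    params = params or CnvHmmParams()
    use = bins if include_partial else bins[~bins["partial"]]
    if not len(use):
        raise ValueError("no complete bins to segment")
    lr = use["log_ratio"].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(lr))
    if len(bad):
        row = use.iloc[bad[0]]
        raise ValueError(
            f"non-finite log ratio in bin {row.chrom}:{row.start}-{row.end}")

    scale = params.resolve_scale(lr)
    log_trans = np.log(params.transition_matrix())
    log_init = np.log(np.asarray(params.initial))

    rows = []
    for chrom, g in use.groupby("chrom", sort=False):
        x = g["log_ratio"].to_numpy(float)
        log_emit = params.emission_loglik(x, scale)
        path = _hmm.viterbi(log_emit, log_trans, log_init)
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        for i0, i1, st in _hmm.run_length_segments(path):
            rows.append((chrom, int(starts[i0]), int(ends[i1 - 1]),
                         st + 1, i1 - i0, float(np.mean(x[i0:i1]))))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def states_per_bin(bins: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    """Decoded state for each (complete) bin, from the segment table."""
    out = np.zeros(len(bins), dtype=int)
    for i, row in enumerate(bins.itertuples(index=False)):
        mid = (row.start + row.end) / 2
        g = segments[(segments["chrom"] == row.chrom)
                     & (segments["start"] <= mid) & (segments["end"] > mid)]
        out[i] = int(g["state"].iloc[0]) if len(g) else 0
    return out


def genome_fraction_by_state(segments: pd.DataFrame) -> np.ndarray:
    """Fraction of the covered extent in each of the 5 states (sums to 1)."""
    lengths = (segments["end"] - segments["start"]).to_numpy(float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("segments cover nothing")
    frac = np.zeros(N_STATES)
    for st in range(1, N_STATES + 1):
        frac[st - 1] = lengths[segments["state"].to_numpy() == st].sum() / total
    return frac


def genes_in_state(segments: pd.DataFrame, gene_models: pd.DataFrame,
                   min_state: int) -> list[str]:
    """Genes overlapping (>=1 bp) any segment with state >= min_state.

    Deduplicated, sorted by gene id for determinism.
    """
    hits = set()
    for g in gene_models.itertuples(index=False):
        states = overlapping_states(segments, g.chrom, int(g.start), int(g.end))
        if any(int(s) >= min_state for s in states):
            hits.add(g.gene_id)
    return sorted(hits)


def compare_timepoints(segments_a: pd.DataFrame, segments_b: pd.DataFrame
                       ) -> dict[str, pd.DataFrame]:
    """Per-region state change between two segmentations.

    Regions are formed by intersecting both sets of segment boundaries;
    delta = state_b - state_a. Regions going loss (1) to gain (>=3) or
    gain (>=3) to loss (1) are returned as separate lists.
    """
    table = intersect_segmentations(segments_a, segments_b)
    table["delta"] = table["state_b"].astype(int) - table["state_a"].astype(int)
    loss_to_gain = table[(table["state_a"].astype(int) == 1)
                         & (table["state_b"].astype(int) >= 3)]
    gain_to_loss = table[(table["state_a"].astype(int) >= 3)
                         & (table["state_b"].astype(int) == 1)]
    return {
        "delta": table.reset_index(drop=True),
        "loss_to_gain": loss_to_gain.reset_index(drop=True),
        "gain_to_loss": gain_to_loss.reset_index(drop=True),
    }
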