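"""Shared Viterbi machinery for the copy-number and LOH decoders.

Decoding is done in log space, one chromosome at a time. The decoders in
:mod:`oncotrace.cnv` and :mod:`oncotrace.loh` supply per-bin emission
log-likelihood matrices; this module owns the dynamic program and the
run-length encoding into segments.
"""

from __future__ import annotations

import numpy as np


def uniform_log_init(n_states: int) -> np.ndarray:
    return np.full(n_states, -np.log(n_states))


def self_transition_matrix(n_states: int, self_p: float) -> np.ndarray:
    """Transition matrix with one smoothing knob: P(stay) = self_p,
    remainder spread uniformly over the other states."""
    if not 0.0 < self_p < 1.0:
        raise ValueError("self-transition probability must lie in (0, 1)")
    off = (1.0 - self_p) / (n_states - 1)
    mat = np.full((n_states, n_states), off)
    np.fill_diagonal(mat, self_p)
    return mat


def viterbi(log_emit: np.ndarray, log_trans: np.ndarray,
            log_init: np.ndarray) -> np.ndarray:
    """Maximum a posteriori state path.

    log_emit: (n_obs, n_states) emission log-likelihoods.
    Returns the integer state path of length n_obs. Ties broken toward
    the lower state index (argmax convention), which makes decoding
    deterministic.
    """
    n_obs, n_states = log_emit.shape
    if n_obs == 0:
        return np.zeros(0, dtype=int)
    delta = log_init + log_emit[0]
    psi = np.zeros((n_obs, n_states), dtype=int)
    for t in range(1, n_obs):
        scores = delta[:, None] + log_trans  # (from, to)
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(n_states)] + log_emit[t]
    path = np.empty(n_obs, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n_obs - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def path_log_score(path: np.ndarray, log_emit: np.ndarray,
                   log_trans: np.ndarray, log_init: np.ndarray) -> float:
    """Joint log score of one explicit state path (oracle helper)."""
    path = np.asarray(path, dtype=int)
    score = log_init[path[0]] + log_emit[0, path[0]]
    for t in range(1, len(path)):
        score += log_trans[path[t - 1], path[t]] + log_emit[t, path[t]]
    return float(score)


def brute_force_path(log_emit: np.ndarray, log_trans: np.ndarray,
                     log_init: np.ndarray) -> np.ndarray:
    """Best path by exhaustive enumeration of all n_states**n_obs paths.

    Only feasible for small problems; used as the decoding oracle.
    Vectorized over the full path table so 5**8 paths score in ~0.1 s.
    """
    n_obs, n_states = log_emit.shape
    grids = np.meshgrid(*[np.arange(n_states)] * n_obs, indexing="ij")
    paths = np.stack([g.ravel() for g in grids], axis=1)  # (n_paths, n_obs)
    scores = log_init[paths[:, 0]] + log_emit[0, paths[:, 0]]
    for t in range(1, n_obs):
        scores += log_trans[paths[:, t - 1], paths[:, t]]
        scores += log_emit[t, paths[:, t]]
    return paths[int(np.argmax(scores))]


def run_length_segments(path: np.ndarray) -> list[tuple[int, int, int]]:
    """RLE of a state path: list of (first_idx, last_idx_exclusive, state)."""
    if len(path) == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    bounds = np.concatenate([[0], change, [len(path)]])
    return [
        (int(s), int(e), int(path[s])) for s, e in zip(bounds[:-1], bounds[1:])
    ]
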