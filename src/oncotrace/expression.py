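"""Compendium-outlier differential expression.

A single tumor library has no replicates, so differential expression is
called by combining two orthogonal comparisons: a rank-based outlier
probability of the tumor against a compendium of unrelated tumor
libraries, and Fisher's exact test of the tumor against the patient's
blood on aligned-base counts, with fold-change gates on both axes.

The outlier statistic is the empirical one-sided rank p-value
p = (k + 1) / (N + 1), where k counts compendium libraries at least as
extreme as the tumor in the tested direction. It is deliberately
isolated in :func:`outlier_p` so an alternative (e.g. a median/MAD
z-score) can be swapped in; note its floor of 1/(N+1) — with a
50-library compendium no gene can score below ~0.0196, which is why the
significance gate on this family uses the raw p-value (see call_de).

Fold changes follow the signed convention: ratios below 1 are reported
as the negative reciprocal (a ratio of 0.25 prints as -4.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionMatrix


def normalize(matrix: ExpressionMatrix, per: float = 1e6) -> pd.DataFrame:
    """Counts divided by library totals, scaled per million bases."""
    return matrix.counts.div(matrix.totals[matrix.counts.columns]) * per


def filter_low_information(matrix: ExpressionMatrix,
                           min_nonzero_fraction: float = 0.2) -> list[str]:
    """Genes with enough non-zero compendium data to rank reliably.

    Removes genes with less than ``min_nonzero_fraction`` non-zero
    values across compendium libraries (a tiny tumor count would get
    an inflated rank against all-zero references). The boundary is
    kept: exactly 20% non-zero survives.
    """
    comp = matrix.counts[matrix.libraries("compendium")]
    frac = (comp > 0).mean(axis=1)
    return list(comp.index[frac >= min_nonzero_fraction])


def outlier_p(tumor_value: float, compendium_values: np.ndarray,
              direction: str = "over") -> float:
    """Empirical rank outlier probability against the compendium.

    p = (k + 1)/(N + 1) with k the number of compendium values at
    least as extreme as the tumor ('over': >= tumor, 'under': <=).
    Monotone: raising the tumor value never increases the 'over' p.
    """
    comp = np.asarray(compendium_values, dtype=float)
    if len(comp) < 5:
        raise ValueError("need at least 5 compendium values")
    if direction == "over":
        k = int((comp >= tumor_value).sum())
    elif direction == "under":
        k = int((comp <= tumor_value).sum())
    else:
        raise ValueError("direction must be 'over' or 'under'")
    return (k + 1) / (len(comp) + 1)


def _signed_fc(ratio: float) -> float:
    return ratio if ratio >= 1 else -1.0 / ratio


def fisher_vs_blood(gene_tumor: int, total_tumor: int,
                    gene_blood: int, total_blood: int,
                    max_margin: float = 1e8,
                    pseudocount: float = 1.0) -> tuple[float, float]:
    """Two-sided exact test of one gene's share of tumor vs blood bases.

    The 2x2 table is (gene, rest) x (tumor, blood); the p-value sums
    hypergeometric probabilities of all tables at most as likely as
    the observed one. Margins above ``max_margin`` are proportionally
    down-scaled first (aligned-base totals can reach billions), with a
    warning. Returns (p, signed fold change of normalized values);
    when both gene counts are zero the fold change is NaN and p is 1.
    """
    if min(gene_tumor, gene_blood) < 0 or min(total_tumor, total_blood) <= 0:
        raise ValueError("counts must be non-negative with positive totals")
    norm_t = (gene_tumor + pseudocount) / total_tumor
    norm_b = (gene_blood + pseudocount) / total_blood
    fc = _signed_fc(norm_t / norm_b)
    if gene_tumor == 0 and gene_blood == 0:
        return 1.0, float("nan")

    if max(total_tumor, total_blood) > max_margin:
        scale = max_margin / max(total_tumor, total_blood)
        warnings.warn("down-scaling Fisher table margins for tractability")
        gene_tumor = int(round(gene_tumor * scale))
        gene_blood = int(round(gene_blood * scale))
        total_tumor = int(round(total_tumor * scale))
        total_blood = int(round(total_blood * scale))
        gene_tumor = min(gene_tumor, total_tumor)
        gene_blood = min(gene_blood, total_blood)

    n = gene_tumor + gene_blood  # gene margin
    M = total_tumor + total_blood
    lo = max(0, n - total_blood)
    hi = min(n, total_tumor)
    support = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(support, M, n, total_tumor)
    obs = logpmf[gene_tumor - lo]
    p = float(np.exp(logpmf[logpmf <= obs + 1e-7]).sum())
    return min(1.0, p), fc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEThresholds:
    """Significance and fold-change gates for the up/down calls."""

    p_outlier: float = 0.05
    q_fisher: float = 0.05
    fc_compendium: float = 2.0
    fc_blood: float = 1.5


def call_de(matrix: ExpressionMatrix, tumor_lib: str | None = None,
            thresholds: DEThresholds | None = None,
            min_nonzero_fraction: float = 0.2) -> pd.DataFrame:
    """Per-gene differential-expression table with up/down calls.

    Pipeline: low-information filter, per-million normalization, rank
    outlier p vs the compendium (direction chosen by the side the
    tumor falls on), Fisher exact vs blood on raw base counts, BH
    adjustment within each p family. A gene is called 'up' iff raw
    outlier p < 0.05, BH-adjusted Fisher q < 0.05, FC vs compendium
    > 2 and FC vs blood > 1.5; 'down' mirrors with the reciprocal
    (negative signed) gates. The outlier gate uses the raw p because
    the rank statistic is floored at 1/(N+1) and can never survive an
    FDR correction across thousands of genes.
    """
    thr = thresholds or DEThresholds()
    tumor_lib = tumor_lib or matrix.libraries("tumor")[0]
    blood_lib = matrix.libraries("blood")[0]
    comp_libs = matrix.libraries("compendium")

    kept = filter_low_information(matrix, min_nonzero_fraction)
    norm = normalize(matrix)
    pc_norm = (matrix.counts + 1.0).div(matrix.totals[matrix.counts.columns]) * 1e6

    rows = []
    for gene in kept:
        t = float(pc_norm.at[gene, tumor_lib])
        comp = pc_norm.loc[gene, comp_libs].to_numpy(float)
        comp_med = float(np.median(comp))
        fc_comp = _signed_fc(t / comp_med)
        direction = "over" if fc_comp >= 1 else "under"
        p_out = outlier_p(t, comp, direction)
        p_fish, fc_blood = fisher_vs_blood(
            int(matrix.counts.at[gene, tumor_lib]),
            int(matrix.totals[tumor_lib]),
            int(matrix.counts.at[gene, blood_lib]),
            int(matrix.totals[blood_lib]))
        rows.append({
            "gene_id": gene,
            "expr_tumor": float(norm.at[gene, tumor_lib]),
            "expr_blood": float(norm.at[gene, blood_lib]),
            "expr_comp_median": comp_med,
            "fc_comp": fc_comp, "fc_blood": fc_blood,
            "direction": direction,
            "p_outlier": p_out, "p_fisher": p_fish,
        })
    out = pd.DataFrame(rows)
    if not len(out):
        return out
    out["q_outlier"] = bh_adjust(out["p_outlier"])
    out["q_fisher"] = bh_adjust(out["p_fisher"])

    up = ((out["p_outlier"] < thr.p_outlier)
          & (out["q_fisher"] < thr.q_fisher)
          & (out["fc_comp"] > thr.fc_compendium)
          & (out["fc_blood"] > thr.fc_blood))
    down = ((out["p_outlier"] < thr.p_outlier)
            & (out["q_fisher"] < thr.q_fisher)
            & (out["fc_comp"] < -thr.fc_compendium)
            & (out["fc_blood"] < -thr.fc_blood))
    out["call"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def overlap_sets(a, b, c=None) -> dict[str, int]:
    """Cardinalities of all intersection regions of two or three sets."""
    a, b = set(a), set(b)
    out = {"A": len(a), "B": len(b), "A&B": len(a & b)}
    if c is None:
        out["A|B"] = len(a | b)
        out["A_only"] = len(a - b)
        out["B_only"] = len(b - a)
        return out
    c = set(c)
    out.update({
        "C": len(c), "A&C": len(a & c), "B&C": len(b & c),
        "A&B&C": len(a & b & c), "A|B|C": len(a | b | c),
        "A_only": len(a - b - c), "B_only": len(b - a - c),
        "C_only": len(c - a - b),
    })
    return out
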