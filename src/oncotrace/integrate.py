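"""Joining the evidence layers and prioritizing druggable targets.

Combines copy-number state, LOH state, somatic mutations and
differential expression per gene, tests the association between copy
number and expression change, runs hypergeometric over-representation
against pathway gene sets, and assembles the targetable-gene table
(evidence x pathway membership x drug-target map).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import overlapping_states

LOH_SEVERITY = {"normal": 0, "low": 1, "high": 2}


def build_gene_evidence(gene_models: pd.DataFrame,
                        cnv_segments: pd.DataFrame | None = None,
                        loh_segments: pd.DataFrame | None = None,
                        somatic_variants: pd.DataFrame | None = None,
                        de_results: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per gene joining the four evidence layers.

    Copy-number / LOH state per gene is the maximum (most severe)
    state among overlapping segments, capturing focal events inside
    larger regions. Genes absent from a layer carry explicit nulls.
    """
    mut_by_gene: dict[str, str] = {}
    if somatic_variants is not None and len(somatic_variants):
        for r in somatic_variants.itertuples(index=False):
            gid = getattr(r, "gene_id", None)
            if gid and getattr(r, "consequence", "non-coding") != "non-coding":
                mut_by_gene.setdefault(gid, r.consequence)
    de_by_gene = {}
    if de_results is not None and len(de_results):
        de_by_gene = de_results.set_index("gene_id").to_dict("index")

    rows = []
    for g in gene_models.itertuples(index=False):
        cnv_state = None
        if cnv_segments is not None and len(cnv_segments):
            states = overlapping_states(
                cnv_segments, g.chrom, int(g.start), int(g.end))
            cnv_state = max((int(s) for s in states), default=None)
        loh_state = None
        if loh_segments is not None and len(loh_segments):
            states = overlapping_states(
                loh_segments, g.chrom, int(g.start), int(g.end))
            if states:
                loh_state = max(states, key=LOH_SEVERITY.__getitem__)
        de = de_by_gene.get(g.gene_id, {})
        rows.append({
            "gene_id": g.gene_id,
            "cnv_state": cnv_state,
            "loh_state": loh_state,
            "mutated": g.gene_id in mut_by_gene,
            "consequence": mut_by_gene.get(g.gene_id),
            "de_call": de.get("call", "none"),
            "fc_comp": de.get("fc_comp", np.nan),
            "fc_blood": de.get("fc_blood", np.nan),
        })
    return pd.DataFrame(rows)


def cnv_expression_association(evidence: pd.DataFrame,
                               n_permutations: int = 10000,
                               seed: int = 0) -> dict[str, float]:
    """Spearman association of per-gene CNV state with expression change.

    Uses log fold change vs the compendium (signed FCs are mapped back
    to log2 ratios, so the statistic is invariant under monotone
    transforms of the FC). The p-value comes from permuting the
    FC labels across genes with a fixed seed; two-sided on |rho|.
    """
    use = evidence.dropna(subset=["cnv_state", "fc_comp"])
    if len(use) < 20:
        raise ValueError("need >= 20 genes with both CNV state and FC")
    state = use["cnv_state"].to_numpy(float)
    fc = use["fc_comp"].to_numpy(float)
    log_fc = np.log2(np.where(fc >= 1, fc, -1.0 / fc))
    rho = stats.spearmanr(state, log_fc).statistic

    rng = np.random.default_rng(seed)
    state_rank = stats.rankdata(state)
    fc_rank = stats.rankdata(log_fc)
    sr = (state_rank - state_rank.mean()) / state_rank.std()
    fr = (fc_rank - fc_rank.mean()) / fc_rank.std()
    perms = np.stack([rng.permutation(fr) for _ in range(n_permutations)])
    rho_null = perms @ sr / len(sr)
    p = (np.sum(np.abs(rho_null) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1)
    return {"rho": float(rho), "p": float(p), "n": int(len(use))}


def enrich_gene_sets(query: set[str], universe: set[str],
                     gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    With N = |universe|, K = |set ∩ universe|, n = |query| and k the
    overlap, p = P(X >= k), X ~ Hypergeom(N, K, n); BH across sets.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    rows = []
    for name, members in gene_sets.items():
        K = len(members & universe)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, len(universe), K, len(query)))
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "query_size": len(query), "universe_size": len(universe),
                     "p": min(1.0, p)})
    out = pd.DataFrame(rows)
    from .expression import bh_adjust
    out["q"] = bh_adjust(out["p"])
    return out.sort_values(["p", "set"]).reset_index(drop=True)


def druggable_target_table(evidence: pd.DataFrame,
                           pathway_sets: dict[str, set[str]],
                           drug_targets: dict[str, list[str]],
                           min_amplified_state: int = 3) -> pd.DataFrame:
    """Genes with genomic/transcriptomic evidence that sit in a known
    pathway and are targeted by an approved drug.

    Evidence flags: amplified (CNV state >= min_amplified_state),
    over-expressed (up call), mutated (non-synonymous). Rows require
    at least one flag, at least one pathway membership and at least
    one drug; sorted by evidence count (descending) then gene id.
    """
    rows = []
    for r in evidence.itertuples(index=False):
        amplified = r.cnv_state is not None and int(r.cnv_state) >= min_amplified_state
        over = r.de_call == "up"
        mutated = bool(r.mutated) and r.consequence in ("missense", "nonsense")
        if not (amplified or over or mutated):
            continue
        pathways = sorted(name for name, members in pathway_sets.items()
                          if r.gene_id in members)
        drugs = drug_targets.get(r.gene_id, [])
        if not pathways or not drugs:
            continue
        rows.append({
            "gene_id": r.gene_id,
            "amplified": amplified, "over_expressed": over, "mutated": mutated,
            "n_evidence": int(amplified) + int(over) + int(mutated),
            "pathways": ";".join(pathways),
            "drugs": ";".join(sorted(drugs)),
        })
    out = pd.DataFrame(rows, columns=["gene_id", "amplified", "over_expressed",
                                      "mutated", "n_evidence", "pathways",
                                      "drugs"])
    if len(out):
        out = out.sort_values(["n_evidence", "gene_id"],
                              ascending=[False, True]).reset_index(drop=True)
    return out
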