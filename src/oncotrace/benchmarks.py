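"""Seeded recovery and calibration experiments on planted truth.

Each function simulates data with the synthetic generator, runs the
corresponding pipeline stage, and measures agreement with the planted
truth. They back both the test suite and the reproducibility script, so
problem sizes are chosen to finish in seconds to a couple of minutes on
one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import binning, cnv, expression, integrate, loh, simulate, somatic
from .layout import GenomeLayout, TruthSet


def cnv_recovery(seed: int = 0, segment_len: int = 100_000,
                 states=(1, 2, 3, 5, 2, 1, 3, 2, 5, 2),
                 mean_depth: float = 100.0,
                 reads_per_bin: int = 200) -> dict[str, float]:
    """Bin-level state accuracy on a planted multi-state genome.

    Segments of ``segment_len`` tile one chromosome (~50 bins each at
    the defaults); states avoid 4 because its default depth factor
    (2.5x) sits between the state-4 and state-5 emission means.
    """
    n_seg = len(states) * 4
    layout = GenomeLayout({"chr1": n_seg * segment_len})
    seg_states = [states[i % len(states)] for i in range(n_seg)]
    truth_cnv = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_seg) * segment_len,
        "end": (np.arange(n_seg) + 1) * segment_len,
        "state": seg_states,
    })
    truth = TruthSet(cnv_segments=truth_cnv)
    normal, tumor = simulate.simulate_depth_tracks(
        layout, truth, mean_depth=mean_depth, seed=seed)
    bins = binning.build_bins(normal, reads_per_bin)
    ratios = binning.fill_ratios(bins, tumor)
    segments = cnv.viterbi_segment(ratios)
    complete = ratios[~ratios["partial"]].reset_index(drop=True)
    decoded = cnv.states_per_bin(complete, segments)
    mids = (complete["start"] + complete["end"]) / 2
    truth_states = np.array(
        [seg_states[min(int(m // segment_len), n_seg - 1)] for m in mids])
    return {
        "accuracy": float(np.mean(decoded == truth_states)),
        "n_bins": int(len(complete)),
    }


def null_cnv_fraction(seed: int = 0, genome_len: int = 4_000_000,
                      mean_depth: float = 100.0) -> dict[str, float]:
    """Genome fraction called non-neutral on an all-neutral simulation."""
    layout = GenomeLayout({"chr1": genome_len})
    truth = TruthSet()
    normal, tumor = simulate.simulate_depth_tracks(
        layout, truth, mean_depth=mean_depth, seed=seed)
    bins = binning.build_bins(normal, 200)
    ratios = binning.fill_ratios(bins, tumor)
    segments = cnv.viterbi_segment(ratios)
    frac = cnv.genome_fraction_by_state(segments)
    return {"non_neutral_fraction": float(1.0 - frac[1]),
            "n_bins": int((~ratios["partial"]).sum())}


def loh_recovery(seed: int = 0, block_len: int = 1_000_000,
                 blocks=("normal", "low", "high", "normal", "high", "low"),
                 n_sites: int = 6000) -> dict[str, float]:
    """Bin-level LOH state accuracy on planted allelic-loss blocks."""
    layout = GenomeLayout({"chr1": len(blocks) * block_len})
    truth_loh = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(len(blocks)) * block_len,
        "end": (np.arange(len(blocks)) + 1) * block_len,
        "state": list(blocks),
    })
    truth = TruthSet(loh_segments=truth_loh)
    calls = simulate.simulate_snp_calls(
        layout, truth, n_germline_sites=n_sites, error_rate=0.01, seed=seed)
    het_sites = calls.germline_sites[calls.germline_sites["genotype"] == "het"]
    keys = set(zip(het_sites["chrom"], het_sites["pos"]))
    table = calls.tumors["T1"]
    at_het = table[[k in keys for k in zip(table["chrom"], table["pos"])]]
    sites = at_het[["chrom", "pos"]].copy()
    sites["is_het"] = loh.classify_zygosity(at_het).to_numpy()
    bins = loh.bin_het_rate(sites.sort_values(["chrom", "pos"]))
    segments = loh.segment_loh(bins)
    complete = bins[~bins["partial"]].reset_index(drop=True)
    decoded = loh.loh_states_per_bin(complete, segments)
    mids = (complete["start"] + complete["end"]) / 2
    truth_states = [blocks[min(int(m // block_len), len(blocks) - 1)]
                    for m in mids]
    acc = float(np.mean([d == t for d, t in zip(decoded, truth_states)]))
    return {"accuracy": acc, "n_bins": int(len(complete))}


def somatic_precision_recall(seed: int = 0, n_variants: int = 500,
                             error_rate: float = 0.002,
                             mean_depth: float = 30.0,
                             vaf: float = 0.5) -> dict[str, float]:
    """Precision/recall of the full cascade on planted somatic variants."""
    rng = np.random.default_rng(seed)
    layout = GenomeLayout({f"chr{i}": 10_000_000 for i in (1, 2, 3)})
    chroms = rng.choice(list(layout.lengths), n_variants)
    pos = np.array([rng.integers(0, layout.lengths[c]) for c in chroms])
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_variants)]
    alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, n_variants)) % 4]
    som = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt,
                        "vaf": vaf, "timepoints": "T1"})
    som = som.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    truth = TruthSet(somatic_variants=som)
    calls = simulate.simulate_snp_calls(
        layout, truth, n_germline_sites=2000, error_rate=error_rate,
        mean_depth=mean_depth, seed=seed)
    detected = somatic.call_somatic(calls.tumors["T1"], calls.normal)
    truth_keys = set(zip(som["chrom"], som["pos"], som["alt"]))
    det_keys = set(zip(detected["chrom"], detected["pos"], detected["alt"]))
    tp = len(truth_keys & det_keys)
    precision = tp / len(det_keys) if det_keys else 0.0
    recall = tp / len(truth_keys)
    return {"precision": float(precision), "recall": float(recall),
            "n_planted": int(len(som)), "n_detected": int(len(det_keys))}


def de_recovery(seed: int = 0, n_genes: int = 2000, n_de: int = 100,
                effect_up: float = 10.0, effect_down: float = 0.1,
                dispersion: float = 0.05) -> dict[str, float]:
    """Sensitivity and FDR of the DE caller on planted outlier genes."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    de_idx = rng.choice(n_genes, n_de, replace=False)
    directions = np.where(np.arange(n_de) % 2 == 0, "up", "down")
    truth_de = pd.DataFrame({
        "gene_id": [genes[i] for i in de_idx],
        "direction": directions,
        "effect_size": np.where(directions == "up", effect_up, effect_down),
    })
    matrix = simulate.simulate_expression(
        n_genes=n_genes, n_compendium=50, truth_de=truth_de,
        dispersion=dispersion, seed=seed)
    results = expression.call_de(matrix)
    called = results[results["call"] != "none"]
    truth_map = dict(zip(truth_de["gene_id"], truth_de["direction"]))
    tp = sum(truth_map.get(g) == c
             for g, c in zip(called["gene_id"], called["call"]))
    sensitivity = tp / len(truth_de)
    fdr = 1.0 - tp / len(called) if len(called) else 0.0
    return {"sensitivity": float(sensitivity), "fdr": float(fdr),
            "n_called": int(len(called))}


def null_de_fraction(seed: int = 0, n_genes: int = 2000) -> dict[str, float]:
    """Fraction of genes called DE when nothing is planted."""
    matrix = simulate.simulate_expression(
        n_genes=n_genes, n_compendium=50, truth_de=None, seed=seed)
    results = expression.call_de(matrix)
    return {"called_fraction": float((results["call"] != "none").mean()),
            "n_genes": int(len(results))}


def association_null_pvalues(seed: int = 0, n_replicates: int = 200,
                             n_genes: int = 150,
                             n_permutations: int = 999) -> np.ndarray:
    """Permutation p-values of the CNV-expression association under a
    shuffled (independent) pairing; should be uniform."""
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_replicates):
        states = rng.integers(1, 6, n_genes).astype(float)
        ratios = np.exp(rng.normal(0, 1, n_genes))
        fc = np.where(ratios >= 1, ratios, -1.0 / ratios)
        evidence = pd.DataFrame({"gene_id": [f"G{i}" for i in range(n_genes)],
                                 "cnv_state": states, "fc_comp": fc})
        res = integrate.cnv_expression_association(
            evidence, n_permutations=n_permutations,
            seed=int(rng.integers(2**31)))
        ps.append(res["p"])
    return np.asarray(ps)


def association_coupling(seed: int = 0, n_genes: int = 500,
                         n_permutations: int = 2000) -> dict[str, float]:
    """Association p when copy-number state truly drives expression."""
    rng = np.random.default_rng(seed)
    states = rng.integers(1, 6, n_genes).astype(float)
    factor = np.array([0.5, 1.0, 1.5, 2.5, 4.0])[states.astype(int) - 1]
    ratios = factor * np.exp(rng.normal(0, 0.5, n_genes))
    fc = np.where(ratios >= 1, ratios, -1.0 / ratios)
    evidence = pd.DataFrame({"gene_id": [f"G{i}" for i in range(n_genes)],
                             "cnv_state": states, "fc_comp": fc})
    res = integrate.cnv_expression_association(
        evidence, n_permutations=n_permutations, seed=seed)
    return res
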