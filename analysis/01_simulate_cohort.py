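#!/usr/bin/env python
"""Simulate the two-timepoint tumor case and write all pipeline inputs.

Generates the planted-truth scenario (focal amplification of a
druggable kinase, deleted suppressor, copy-neutral LOH arising at
recurrence, 4 shared + 9 recurrence-only somatic mutations) and writes
depth tracks, SNP call tables, the expression matrix, gene models and
truth files under results/scenario_inputs/.
"""

import sys
from pathlib import Path

import numpy as np

from oncotrace import io, simulate
from oncotrace.scenario import (
    build_gene_models, build_layout, build_truth)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11
OUT = Path(__file__).resolve().parent.parent / "results" / "scenario_inputs"


def main() -> None:
    rng = np.random.default_rng(SEED)
    layout = build_layout()
    gene_models, seqs = build_gene_models(np.random.default_rng(12345))
    truth = build_truth(gene_models, seqs)
    truth.validate(layout)

    normal, tumor1 = simulate.simulate_depth_tracks(
        layout, truth, timepoint="T1", seed=int(rng.integers(2**31)))
    _, tumor2 = simulate.simulate_depth_tracks(
        layout, truth, timepoint="T2", seed=int(rng.integers(2**31)))
    io.write_depth_track(normal, OUT / "depth_normal.tsv")
    io.write_depth_track(tumor1, OUT / "depth_tumor_T1.tsv")
    io.write_depth_track(tumor2, OUT / "depth_tumor_T2.tsv")

    calls = simulate.simulate_snp_calls(
        layout, truth, n_germline_sites=6000, error_rate=0.002,
        timepoints=("T1", "T2"), seed=int(rng.integers(2**31)))
    io.write_table(calls.normal, OUT / "snp_normal.tsv")
    for tp, table in calls.tumors.items():
        io.write_table(table, OUT / f"snp_tumor_{tp}.tsv")
    io.write_table(calls.germline_sites, OUT / "germline_sites.tsv")

    all_genes = list(gene_models["gene_id"]) + [
        f"BG{i:04d}" for i in range(2000 - len(gene_models))]
    matrix = simulate.simulate_expression(
        n_compendium=50, truth_de=truth.de_genes, dispersion=0.01,
        gene_ids=all_genes, seed=int(rng.integers(2**31)))
    io.write_expression(matrix, OUT / "expression.tsv")

    io.write_table(gene_models, OUT / "gene_models.tsv")
    with open(OUT / "cds_sequences.fasta", "w") as fh:
        for gid, seq in seqs.items():
            fh.write(f">{gid}\n{seq}\n")
    io.write_table(truth.cnv_segments, OUT / "truth_cnv.tsv")
    io.write_table(truth.loh_segments, OUT / "truth_loh.tsv")
    io.write_table(truth.somatic_variants, OUT / "truth_somatic.tsv")
    io.write_table(truth.de_genes, OUT / "truth_de.tsv")

    print(f"seed {SEED}: wrote simulated inputs to {OUT}")
    print(f"  {len(normal)} depth windows/sample, "
          f"{len(calls.normal)} germline SNP sites, "
          f"{len(truth.somatic_variants)} planted somatic variants, "
          f"{matrix.counts.shape[0]} genes x {matrix.counts.shape[1]} libraries")


if __name__ == "__main__":
    main()
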