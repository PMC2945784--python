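#!/usr/bin/env python
"""Integration: join CNV/LOH/mutation/expression evidence per gene,
test the CNV-expression association, run pathway over-representation,
and rank druggable targets.

Reads the upstream results; writes the evidence table, enrichment and
the target table under results/integration/.
"""

from pathlib import Path

from oncotrace import integrate, io
from oncotrace.scenario import DRUG_TARGETS, PATHWAYS

BASE = Path(__file__).resolve().parent.parent / "results"
INP = BASE / "scenario_inputs"
OUT = BASE / "integration"


def main() -> None:
    gene_models = io.read_table(INP / "gene_models.tsv")
    cnv_segments = io.read_table(BASE / "copy_number" / "cnv_segments_T1.tsv")
    loh_segments = io.read_table(BASE / "loh" / "loh_segments_T1.tsv")
    somatic = io.read_table(BASE / "somatic" / "somatic_T1.tsv")
    de = io.read_table(BASE / "expression" / "de_results.tsv")

    evidence = integrate.build_gene_evidence(
        gene_models, cnv_segments=cnv_segments, loh_segments=loh_segments,
        somatic_variants=somatic, de_results=de)
    io.write_table(evidence, OUT / "gene_evidence.tsv")

    assoc = integrate.cnv_expression_association(evidence, seed=0)
    print(f"CNV-expression association: Spearman rho {assoc['rho']:.3f}, "
          f"permutation p {assoc['p']:.4f} over {assoc['n']} genes")

    io.write_gmt(PATHWAYS, OUT / "pathways.gmt")
    flagged = set(evidence.loc[
        (evidence["de_call"] != "none") | evidence["mutated"]
        | (evidence["cnv_state"].fillna(2) >= 3), "gene_id"])
    enrich = integrate.enrich_gene_sets(
        flagged, set(gene_models["gene_id"]), PATHWAYS)
    io.write_table(enrich, OUT / "pathway_enrichment.tsv")
    print("pathway over-representation (top):")
    print(enrich.head(3).to_string(index=False))

    targets = integrate.druggable_target_table(evidence, PATHWAYS,
                                               DRUG_TARGETS)
    io.write_table(targets, OUT / "target_table.tsv")
    print(f"{len(targets)} druggable target(s) with genomic or "
          "transcriptomic evidence in a cancer pathway:")
    print(targets.to_string(index=False))


if __name__ == "__main__":
    main()
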