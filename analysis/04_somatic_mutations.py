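#!/usr/bin/env python
"""Somatic mutation analysis: filter cascade, coding annotation, and
the recurrence-only mutation list with single-read re-examination.

Reads SNP tables and gene models from 01; writes annotated somatic
calls per timepoint and the recurrence report under results/somatic/.
"""

from pathlib import Path

from oncotrace import io, somatic

BASE = Path(__file__).resolve().parent.parent / "results"
INP = BASE / "scenario_inputs"
OUT = BASE / "somatic"


def read_cds(path):
    seqs, name = {}, None
    for line in open(path):
        line = line.strip()
        if line.startswith(">"):
            name = line[1:]
            seqs[name] = ""
        elif name:
            seqs[name] += line
    return seqs


def main() -> None:
    normal = io.read_table(INP / "snp_normal.tsv")
    gene_models = io.read_table(INP / "gene_models.tsv")
    seqs = read_cds(INP / "cds_sequences.fasta")

    annotated = {}
    for tp in ("T1", "T2"):
        tumor = io.read_table(INP / f"snp_tumor_{tp}.tsv")
        candidates = somatic.call_somatic(tumor, normal)
        annotated[tp] = somatic.annotate_coding(candidates, gene_models, seqs)
        io.write_table(annotated[tp], OUT / f"somatic_{tp}.tsv")
        coding = annotated[tp][annotated[tp]["consequence"].isin(
            ["missense", "nonsense"])]
        print(f"{tp}: {len(annotated[tp])} somatic calls, "
              f"{len(coding)} protein-changing "
              f"({(coding['consequence'] == 'nonsense').sum()} nonsense)")

    t1_tumor = io.read_table(INP / "snp_tumor_T1.tsv")
    evidence = t1_tumor.rename(columns={"variant_reads": "alt_reads"})[
        ["chrom", "pos", "alt", "alt_reads"]]
    recurrence = somatic.recurrence_new_variants(
        annotated["T2"], annotated["T1"], evidence)
    io.write_table(recurrence, OUT / "recurrence_report.tsv")
    counts = recurrence["recurrence_status"].value_counts()
    print("recurrence comparison:", dict(counts))
    new = recurrence[recurrence["recurrence_status"] == "new"]
    print(f"{len(new)} new protein-coding mutations at recurrence, none "
          "supported by a single T1 read:")
    for r in new.itertuples(index=False):
        print(f"  {r.gene_id} {r.chrom}:{r.pos} {r.ref}>{r.alt} "
              f"{r.ref_aa}{r.protein_pos}{r.alt_aa} ({r.consequence})")


if __name__ == "__main__":
    main()
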