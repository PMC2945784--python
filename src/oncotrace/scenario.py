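"""A packaged two-timepoint tumor-evolution case with planted truth.

The scenario mirrors the qualitative structure of a treated metastatic
tumor profiled before therapy (T1) and at recurrence (T2):

* a focal high-level amplification containing a druggable receptor
  kinase (``RETL1``) that is also massively over-expressed;
* a deleted, under-expressed tumor suppressor (``PTENL1``);
* one region switching loss -> gain and one gain -> loss at recurrence;
* a copy-neutral LOH region appearing only at T2;
* four somatic coding mutations shared by both timepoints and nine
  present only in the recurrence, none of them supported by a single
  read at T1.

Planted allele fractions are clonal in a high-purity tumor (0.7) so
the variant-read-fraction gate is cleared with margin. All counts in
the returned report are recomputed by the pipeline, not copied from
the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import binning, cnv, expression, integrate, loh, simulate, somatic
from .layout import GenomeLayout, TruthSet

CHROM_LEN = 8_000_000
N_GENES = 40
GENE_SPAN = 30_000  # single-exon CDS per gene, divisible by 3

PATHWAYS = {
    "MAPK_signaling": {"RETL1", "GENE03", "GENE07", "GENE11"},
    "PI3K_AKT_signaling": {"PTENL1", "GENE05", "GENE09", "GENE13"},
    "cell_cycle": {"GENE02", "GENE06", "GENE10", "GENE14"},
}

DRUG_TARGETS = {
    "RETL1": ["sunitinib", "sorafenib"],
    "GENE05": ["alpelisib"],
    "GENE10": ["palbociclib"],
}


def build_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": CHROM_LEN, "chr2": CHROM_LEN, "chr3": CHROM_LEN})


def build_gene_models(rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Evenly spaced single-CDS gene models with random sequences.

    RETL1 sits inside the focal amplification on chr1, PTENL1 inside
    the chr2 deletion; the rest tile the genome away from planted
    breakpoints.
    """
    rows = []
    named = {0: ("RETL1", "chr1", 2_150_000), 1: ("PTENL1", "chr2", 1_600_000)}
    k = 2
    for chrom in ("chr1", "chr2", "chr3"):
        for slot in range(13):
            start = 200_000 + slot * 600_000
            if any(c == chrom and abs(s - start) < GENE_SPAN
                   for _, c, s in named.values()):
                start += 50_000
            if k >= N_GENES:
                break
            rows.append((f"GENE{k:02d}", chrom, start))
            k += 1
    rows = [(n, c, s) for n, c, s in [named[0], named[1]] + rows]
    bases = np.array(list("ACGT"))
    models, seqs = [], {}
    for gene_id, chrom, start in rows[:N_GENES]:
        strand = "+" if rng.random() < 0.5 else "-"
        models.append({"gene_id": gene_id, "chrom": chrom, "start": start,
                       "end": start + GENE_SPAN, "strand": strand})
        seqs[gene_id] = "".join(rng.choice(bases, GENE_SPAN))
    return pd.DataFrame(models), seqs


def _plant_variant(gene_models: pd.DataFrame, seqs: dict[str, str],
                   gene_id: str, codon_idx: int,
                   want: str = "missense") -> dict:
    """Choose a genomic SNV inside ``gene_id`` with a set consequence."""
    from Bio.Seq import Seq

    g = gene_models[gene_models["gene_id"] == gene_id].iloc[0]
    cds = seqs[gene_id]
    n_codons = len(cds) // 3
    # scan forward from the requested codon until one admits the
    # wanted consequence (not every codon is one substitution from a stop)
    for idx in range(codon_idx, codon_idx + n_codons):
        result = _try_codon(g, cds, idx % n_codons, want)
        if result is not None:
            return result
    raise RuntimeError(f"no {want} substitution available in {gene_id}")


def _try_codon(g, cds: str, codon_idx: int, want: str) -> dict | None:
    from Bio.Seq import Seq

    codon = cds[codon_idx * 3: codon_idx * 3 + 3]
    ref_aa = str(Seq(codon).translate())
    for in_codon in range(3):
        for alt_base in "ACGT":
            if alt_base == codon[in_codon]:
                continue
            alt_codon = codon[:in_codon] + alt_base + codon[in_codon + 1:]
            alt_aa = str(Seq(alt_codon).translate())
            ok = ((want == "missense" and alt_aa not in (ref_aa, "*"))
                  or (want == "nonsense" and alt_aa == "*" and ref_aa != "*"))
            if not ok:
                continue
            offset = codon_idx * 3 + in_codon
            if g["strand"] == "+":
                pos = int(g["start"]) + offset
                ref_b, alt_b = codon[in_codon], alt_base
            else:
                pos = int(g["end"]) - 1 - offset
                ref_b = str(Seq(codon[in_codon]).reverse_complement())
                alt_b = str(Seq(alt_base).reverse_complement())
            return {"chrom": g["chrom"], "pos": pos, "ref": ref_b,
                    "alt": alt_b, "gene_id": g["gene_id"]}
    return None


def build_truth(gene_models: pd.DataFrame, seqs: dict[str, str]) -> TruthSet:
    cnv_segments = pd.DataFrame([
        # shared focal amplification and flanking gain (chr1)
        ("chr1", 2_000_000, 2_400_000, 5, None),
        ("chr1", 5_000_000, 6_000_000, 3, None),
        # shared deletion holding the suppressor (chr2)
        ("chr2", 1_000_000, 2_500_000, 1, None),
        # evolving regions on chr3
        ("chr3", 4_000_000, 5_000_000, 1, "T1"),
        ("chr3", 4_000_000, 5_000_000, 3, "T2"),
        ("chr3", 6_000_000, 7_000_000, 3, "T1"),
        ("chr3", 6_000_000, 7_000_000, 1, "T2"),
    ], columns=["chrom", "start", "end", "state", "timepoint"])

    loh_segments = pd.DataFrame([
        # deletion LOH strictly inside the chr2 loss: margins exceed one
        # LOH bin (~150 kb) so boundary jitter cannot leak into
        # copy-neutral territory
        ("chr2", 1_300_000, 2_300_000, "low", None),
        # copy-neutral LOH arising only at recurrence
        ("chr3", 1_000_000, 2_000_000, "high", "T2"),
    ], columns=["chrom", "start", "end", "state", "timepoint"])

    shared_genes = [("GENE04", "missense"), ("GENE08", "missense"),
                    ("GENE16", "nonsense"), ("GENE20", "missense")]
    new_genes = [("GENE21", "missense"), ("GENE22", "missense"),
                 ("GENE23", "missense"), ("GENE24", "nonsense"),
                 ("GENE25", "missense"), ("GENE26", "missense"),
                 ("GENE27", "missense"), ("GENE28", "missense"),
                 ("GENE29", "missense")]
    som_rows = []
    for i, (gid, want) in enumerate(shared_genes):
        v = _plant_variant(gene_models, seqs, gid, 100 + i, want)
        som_rows.append({**v, "vaf": 0.7, "timepoints": "T1,T2"})
    for i, (gid, want) in enumerate(new_genes):
        v = _plant_variant(gene_models, seqs, gid, 200 + i, want)
        som_rows.append({**v, "vaf": 0.7, "timepoints": "T2"})
    somatic_variants = pd.DataFrame(som_rows)[
        ["chrom", "pos", "ref", "alt", "vaf", "timepoints", "gene_id"]]

    de_genes = pd.DataFrame([
        ("RETL1", "up", 40.0),
        ("GENE03", "up", 12.0),
        ("PTENL1", "down", 0.02),
        ("GENE09", "down", 0.08),
    ], columns=["gene_id", "direction", "effect_size"])

    return TruthSet(cnv_segments=cnv_segments, loh_segments=loh_segments,
                    germline_het_sites=pd.DataFrame(columns=["chrom", "pos"]),
                    somatic_variants=somatic_variants, de_genes=de_genes)


@dataclass
class ScenarioRun:
    """All intermediate products plus the summary report of one run."""

    layout: GenomeLayout
    truth: TruthSet
    gene_models: pd.DataFrame
    cnv_segments: dict[str, pd.DataFrame]
    loh_segments: dict[str, pd.DataFrame]
    somatic_annotated: dict[str, pd.DataFrame]
    recurrence: pd.DataFrame
    de_results: pd.DataFrame
    evidence: pd.DataFrame
    target_table: pd.DataFrame
    report: dict


def run_two_timepoint_scenario(seed: int = 0, mean_depth: float = 100.0,
                               reads_per_bin: int = 200,
                               n_germline_sites: int = 6000) -> ScenarioRun:
    """Simulate the scenario and push it through the whole pipeline."""
    rng = np.random.default_rng(seed)
    layout = build_layout()
    gene_models, seqs = build_gene_models(np.random.default_rng(12345))
    truth = build_truth(gene_models, seqs)
    truth.validate(layout)

    # --- copy number, both timepoints, one shared normal ---------------
    normal, tumor1 = simulate.simulate_depth_tracks(
        layout, truth, mean_depth=mean_depth, timepoint="T1",
        seed=int(rng.integers(2**31)))
    _, tumor2 = simulate.simulate_depth_tracks(
        layout, truth, mean_depth=mean_depth, timepoint="T2",
        seed=int(rng.integers(2**31)))
    bins = binning.build_bins(normal, reads_per_bin)
    cnv_segments = {}
    for tp, track in (("T1", tumor1), ("T2", tumor2)):
        ratios = binning.fill_ratios(bins, track)
        cnv_segments[tp] = cnv.viterbi_segment(ratios)
    diff = cnv.compare_timepoints(cnv_segments["T1"], cnv_segments["T2"])

    # --- SNP calls, LOH and somatic mutations --------------------------
    calls = simulate.simulate_snp_calls(
        layout, truth, n_germline_sites=n_germline_sites, error_rate=0.002,
        timepoints=("T1", "T2"), seed=int(rng.integers(2**31)))
    loh_segments, cn_loh = {}, {}
    germ_het = calls.germline_sites[calls.germline_sites["genotype"] == "het"]
    het_keys = set(zip(germ_het["chrom"], germ_het["pos"]))
    for tp in ("T1", "T2"):
        table = calls.tumors[tp]
        at_het = table[[k in het_keys for k in zip(table["chrom"], table["pos"])]]
        sites = at_het[["chrom", "pos"]].copy()
        sites["is_het"] = loh.classify_zygosity(at_het).to_numpy()
        bins_loh = loh.bin_het_rate(sites.sort_values(["chrom", "pos"]))
        loh_segments[tp] = loh.segment_loh(bins_loh)
        cn_loh[tp] = loh.copy_neutral_loh(loh_segments[tp], cnv_segments[tp])

    somatic_annotated = {}
    for tp in ("T1", "T2"):
        cands = somatic.call_somatic(calls.tumors[tp], calls.normal)
        somatic_annotated[tp] = somatic.annotate_coding(cands, gene_models, seqs)
    t1_table = calls.tumors["T1"]
    t1_evidence = t1_table.rename(columns={"variant_reads": "alt_reads"})[
        ["chrom", "pos", "alt", "alt_reads"]]
    recurrence = somatic.recurrence_new_variants(
        somatic_annotated["T2"], somatic_annotated["T1"], t1_evidence)

    # --- expression ----------------------------------------------------
    # the 40 model genes sit inside a 2,000-gene transcriptome so a
    # single planted outlier cannot skew the library totals; dispersion
    # is tight because the fixture is built so that exactly the planted
    # DE genes clear the printed gates
    all_genes = list(gene_models["gene_id"]) + [
        f"BG{i:04d}" for i in range(2000 - len(gene_models))]
    matrix = simulate.simulate_expression(
        n_compendium=50, truth_de=truth.de_genes, dispersion=0.01,
        gene_ids=all_genes,
        tumor_libs=("tumor_T1",), seed=int(rng.integers(2**31)))
    de_results = expression.call_de(matrix)

    # --- integration ---------------------------------------------------
    evidence = integrate.build_gene_evidence(
        gene_models, cnv_segments=cnv_segments["T1"],
        loh_segments=loh_segments["T1"],
        somatic_variants=somatic_annotated["T1"], de_results=de_results)
    assoc = integrate.cnv_expression_association(
        evidence, n_permutations=2000, seed=int(rng.integers(2**31)))
    target_table = integrate.druggable_target_table(
        evidence, PATHWAYS, DRUG_TARGETS)

    new = recurrence[recurrence["recurrence_status"] == "new"]
    report = {
        "n_somatic_t1": int(len(somatic_annotated["T1"])),
        "n_somatic_t2": int(len(somatic_annotated["T2"])),
        "n_new_in_recurrence": int(len(new)),
        "n_shared_mutations": int(
            (recurrence["recurrence_status"] == "shared").sum()),
        "loss_to_gain_regions": int(len(diff["loss_to_gain"])),
        "gain_to_loss_regions": int(len(diff["gain_to_loss"])),
        "copy_neutral_loh_t1": int(len(loh.merge_contiguous(cn_loh["T1"]))),
        "copy_neutral_loh_t2": int(len(loh.merge_contiguous(cn_loh["T2"]))),
        "n_up_genes": int((de_results["call"] == "up").sum()),
        "n_down_genes": int((de_results["call"] == "down").sum()),
        "up_genes": sorted(de_results.loc[de_results["call"] == "up",
                                          "gene_id"]),
        "down_genes": sorted(de_results.loc[de_results["call"] == "down",
                                            "gene_id"]),
        "top_target": (target_table["gene_id"].iloc[0]
                       if len(target_table) else None),
        "cnv_expression_rho": assoc["rho"],
        "cnv_expression_p": assoc["p"],
    }
    return ScenarioRun(layout=layout, truth=truth, gene_models=gene_models,
                       cnv_segments=cnv_segments, loh_segments=loh_segments,
                       somatic_annotated=somatic_annotated,
                       recurrence=recurrence, de_results=de_results,
                       evidence=evidence, target_table=target_table,
                       report=report)
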