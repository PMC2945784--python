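"""Somatic SNV filter cascade, coding annotation and recurrence diff.

The cascade mirrors short-read tumor/normal practice: strict quality
thresholds on the tumor calls (consensus >= 30, depth >= 8, mapping
quality >= 60, base quality >= 20, variant-read fraction >= 1/3),
deliberately lax thresholds on the germline calls (10 / 1 / 20) so that
marginal germline evidence still vetoes a somatic candidate, then
subtraction of known-polymorphism sites. Coding consequences are
derived by codon translation under the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

TUMOR_RULES = [
    ("consensus_quality", "consensus_quality >= {v}"),
    ("depth", "depth >= {v}"),
    ("min_mapq", "min_mapq >= {v}"),
    ("base_quality", "base_quality >= {v}"),
    ("variant_fraction", "variant_reads/total_reads >= {v}"),
]


@dataclass(frozen=True)
class FilterThresholds:
    """Quality gates for tumor and germline SNP calls."""

    tumor_consensus: float = 30.0
    tumor_depth: int = 8
    tumor_mapq: float = 60.0
    tumor_baseq: float = 20.0
    tumor_variant_fraction: float = 1.0 / 3.0
    germline_consensus: float = 10.0
    germline_depth: int = 1
    germline_mapq: float = 20.0

    def __post_init__(self) -> None:
        if (self.germline_consensus > self.tumor_consensus
                or self.germline_depth > self.tumor_depth
                or self.germline_mapq > self.tumor_mapq):
            raise ValueError("germline thresholds must not exceed tumor ones")


def _tumor_rule_masks(calls: pd.DataFrame, thr: FilterThresholds) -> dict:
    return {
        "consensus_quality": calls["consensus_quality"] >= thr.tumor_consensus,
        "depth": calls["depth"] >= thr.tumor_depth,
        "min_mapq": calls["min_mapq"] >= thr.tumor_mapq,
        "base_quality": calls["base_quality"] >= thr.tumor_baseq,
        # cross-multiplied with a tiny slack so 3 of 9 reads passes the
        # "at least one-third" rule despite 1/3 being inexact in binary
        "variant_fraction": (calls["variant_reads"]
                             >= thr.tumor_variant_fraction * calls["total_reads"]
                             - 1e-9),
    }


def filter_tumor_calls(calls: pd.DataFrame,
                       thresholds: FilterThresholds | None = None,
                       return_reasons: bool = False):
    """Apply the strict tumor gates (conjunction of all five rules).

    With ``return_reasons`` also returns a Series naming, for each
    rejected call, the first failed rule in the canonical order above
    (the keep set itself is order-independent).
    """
    thr = thresholds or FilterThresholds()
    if (calls["variant_reads"] > calls["total_reads"]).any():
        raise ValueError("variant reads exceed total reads")
    masks = _tumor_rule_masks(calls, thr)
    keep = pd.Series(True, index=calls.index)
    for m in masks.values():
        keep &= m
    passing = calls[keep].reset_index(drop=True)
    if not return_reasons:
        return passing
    reasons = pd.Series("", index=calls.index, dtype=object)
    for name, _ in TUMOR_RULES:
        miss = ~masks[name] & (reasons == "") & ~keep
        reasons[miss] = name
    return passing, reasons[~keep]


def filter_germline_calls(calls: pd.DataFrame,
                          thresholds: FilterThresholds | None = None
                          ) -> pd.DataFrame:
    """Lax germline gates: consensus, depth and mapping quality only."""
    thr = thresholds or FilterThresholds()
    keep = ((calls["consensus_quality"] >= thr.germline_consensus)
            & (calls["depth"] >= thr.germline_depth)
            & (calls["min_mapq"] >= thr.germline_mapq))
    return calls[keep].reset_index(drop=True)


def subtract_known(tumor_passing: pd.DataFrame,
                   germline_passing: pd.DataFrame,
                   known_sets: list[pd.DataFrame] | None = None
                   ) -> pd.DataFrame:
    """Remove germline and known-polymorphism sites from tumor calls.

    A tumor call is dropped if its (chrom, pos) appears among passing
    germline calls, or if a known-site table lists its (chrom, pos)
    (matched on alt too when that table has an ``alt`` column).
    """
    germline_sites = set(zip(germline_passing["chrom"], germline_passing["pos"]))
    known_pos: set[tuple] = set()
    known_alt: set[tuple] = set()
    for ks in known_sets or []:
        if "alt" in ks.columns:
            known_alt |= set(zip(ks["chrom"], ks["pos"], ks["alt"]))
        else:
            known_pos |= set(zip(ks["chrom"], ks["pos"]))
    keep = []
    for row in tumor_passing.itertuples(index=False):
        site = (row.chrom, row.pos)
        if site in germline_sites or site in known_pos:
            keep.append(False)
        elif (row.chrom, row.pos, row.alt) in known_alt:
            keep.append(False)
        else:
            keep.append(True)
    return tumor_passing[pd.Series(keep, index=tumor_passing.index)].reset_index(drop=True)


def annotate_coding(candidates: pd.DataFrame, gene_models: pd.DataFrame,
                    cds_sequences: dict[str, str]) -> pd.DataFrame:
    """Map candidate SNVs onto codons and classify the consequence.

    ``gene_models`` rows carry gene_id, chrom, start, end, strand with
    [start, end) the CDS span (length divisible by 3);
    ``cds_sequences`` maps gene_id to the coding-strand CDS. A variant
    outside every CDS is classed non-coding with no protein fields.
    Classes: missense, nonsense (alt codon is a stop), synonymous,
    non-coding.
    """
    rows = []
    for cand in candidates.itertuples(index=False):
        hit = gene_models[(gene_models["chrom"] == cand.chrom)
                          & (gene_models["start"] <= cand.pos)
                          & (gene_models["end"] > cand.pos)]
        rec = {c: getattr(cand, c) for c in candidates.columns}
        if not len(hit):
            rec.update(gene_id=None, protein_pos=None, ref_aa=None,
                       alt_aa=None, consequence="non-coding")
            rows.append(rec)
            continue
        g = hit.iloc[0]
        cds = cds_sequences[g["gene_id"]].upper()
        if len(cds) % 3:
            raise ValueError(f"CDS length of {g['gene_id']} not divisible by 3")
        if g["strand"] == "+":
            offset = int(cand.pos) - int(g["start"])
            ref_base, alt_base = str(cand.ref), str(cand.alt)
        else:
            offset = int(g["end"]) - 1 - int(cand.pos)
            ref_base = str(Seq(str(cand.ref)).reverse_complement())
            alt_base = str(Seq(str(cand.alt)).reverse_complement())
        if not 0 <= offset < len(cds):
            rec.update(gene_id=g["gene_id"], protein_pos=None, ref_aa=None,
                       alt_aa=None, consequence="non-coding")
            rows.append(rec)
            continue
        codon_idx, in_codon = divmod(offset, 3)
        ref_codon = cds[codon_idx * 3: codon_idx * 3 + 3]
        if ref_codon[in_codon] != ref_base:
            raise ValueError(
                f"reference base mismatch at {cand.chrom}:{cand.pos} "
                f"(CDS has {ref_codon[in_codon]}, call has {ref_base})")
        alt_codon = ref_codon[:in_codon] + alt_base + ref_codon[in_codon + 1:]
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            consequence = "synonymous"
        elif alt_aa == "*":
            consequence = "nonsense"
        else:
            consequence = "missense"
        rec.update(gene_id=g["gene_id"], protein_pos=codon_idx + 1,
                   ref_aa=ref_aa, alt_aa=alt_aa, consequence=consequence)
        rows.append(rec)
    return pd.DataFrame(rows)


def call_somatic(tumor_calls: pd.DataFrame, germline_calls: pd.DataFrame,
                 known_sets: list[pd.DataFrame] | None = None,
                 thresholds: FilterThresholds | None = None) -> pd.DataFrame:
    """Full cascade: tumor gates, germline gates, subtraction."""
    thr = thresholds or FilterThresholds()
    tumor_pass = filter_tumor_calls(tumor_calls, thr)
    germ_pass = filter_germline_calls(germline_calls, thr)
    return subtract_known(tumor_pass, germ_pass, known_sets)


def recurrence_new_variants(t2_somatic: pd.DataFrame,
                            t1_somatic: pd.DataFrame,
                            t1_read_evidence: pd.DataFrame) -> pd.DataFrame:
    """Split recurrence-tumor variants into truly new vs pre-existing.

    A timepoint-2 somatic variant is 'new' only if it is absent from
    the timepoint-1 somatic calls AND the timepoint-1 read evidence
    (chrom, pos, alt, alt_reads) shows zero reads supporting the alt
    allele — a single supporting read downgrades it to
    'pre-existing at low level'.
    """
    t1_sites = set(zip(t1_somatic["chrom"], t1_somatic["pos"], t1_somatic["alt"]))
    evidence = {
        (r.chrom, r.pos, r.alt): int(r.alt_reads)
        for r in t1_read_evidence.itertuples(index=False)
    }
    status = []
    for row in t2_somatic.itertuples(index=False):
        key = (row.chrom, row.pos, row.alt)
        if key in t1_sites:
            status.append("shared")
        elif evidence.get(key, 0) > 0:
            status.append("pre-existing at low level")
        else:
            status.append("new")
    out = t2_somatic.copy()
    out["recurrence_status"] = status
    return out
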