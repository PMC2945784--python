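"""Somatic filter cascade, coding annotation and recurrence logic."""

import itertools

import pandas as pd
import pytest

from oncotrace import somatic


def call_row(**kw):
    base = dict(chrom="chr1", pos=100, ref="A", alt="T",
                consensus_quality=40, depth=30, min_mapq=70,
                base_quality=30, variant_reads=15, total_reads=30, p_het=0.9)
    base.update(kw)
    return base


def calls_frame(rows):
    return pd.DataFrame([call_row(**r) for r in rows])


class TestTumorFilter:
    def test_boundary_values_pass_exactly_as_printed(self):
        calls = calls_frame([dict(consensus_quality=30, depth=8, min_mapq=60,
                                  base_quality=20, variant_reads=3,
                                  total_reads=9)])
        assert len(somatic.filter_tumor_calls(calls)) == 1

    def test_consensus_29_rejected_despite_other_rules_passing(self):
        calls = calls_frame([dict(consensus_quality=29)])
        passing, reasons = somatic.filter_tumor_calls(calls,
                                                      return_reasons=True)
        assert len(passing) == 0
        assert reasons.iloc[0] == "consensus_quality"

    def test_one_third_variant_fraction_is_inclusive(self):
        calls = calls_frame([dict(variant_reads=3, total_reads=9),
                             dict(variant_reads=2, total_reads=9)])
        passing = somatic.filter_tumor_calls(calls)
        assert passing["variant_reads"].tolist() == [3]

    @pytest.mark.parametrize("field,value", [
        ("depth", 7), ("min_mapq", 59), ("base_quality", 19)])
    def test_each_sub_threshold_field_rejects(self, field, value):
        calls = calls_frame([{field: value}])
        assert len(somatic.filter_tumor_calls(calls)) == 0

    def test_rule_conjunction_is_order_independent(self):
        import numpy as np
        rng = np.random.default_rng(0)
        calls = calls_frame([dict(
            consensus_quality=int(rng.integers(0, 60)),
            depth=int(rng.integers(1, 40)),
            min_mapq=int(rng.integers(0, 90)),
            base_quality=int(rng.integers(0, 40)),
            variant_reads=int(v), total_reads=30)
            for v in rng.integers(0, 31, 50)])
        thr = somatic.FilterThresholds()
        masks = somatic._tumor_rule_masks(calls, thr)
        reference = somatic.filter_tumor_calls(calls, thr)
        for order in itertools.permutations(masks):
            keep = pd.Series(True, index=calls.index)
            for name in order:
                keep &= masks[name]
            assert calls[keep].reset_index(drop=True).equals(reference)

    def test_variant_reads_exceeding_total_rejected_as_malformed(self):
        calls = calls_frame([dict(variant_reads=31, total_reads=30)])
        with pytest.raises(ValueError, match="exceed"):
            somatic.filter_tumor_calls(calls)


class TestGermlineFilter:
    def test_boundary_10_1_20_kept(self):
        calls = calls_frame([dict(consensus_quality=10, depth=1, min_mapq=20)])
        assert len(somatic.filter_germline_calls(calls)) == 1

    def test_consensus_9_rejected(self):
        calls = calls_frame([dict(consensus_quality=9)])
        assert len(somatic.filter_germline_calls(calls)) == 0

    def test_no_base_quality_or_fraction_rule_applies(self):
        calls = calls_frame([dict(base_quality=0, variant_reads=1,
                                  total_reads=30)])
        assert len(somatic.filter_germline_calls(calls)) == 1

    def test_noise_free_simulation_gives_full_germline_recall(self):
        from oncotrace import simulate
        from oncotrace.layout import GenomeLayout, TruthSet
        layout = GenomeLayout({"chr1": 1_000_000})
        calls = simulate.simulate_snp_calls(
            layout, TruthSet(), n_germline_sites=300, error_rate=0.0, seed=1)
        passing = somatic.filter_germline_calls(calls.normal)
        assert len(passing) == len(calls.normal)

    def test_germline_thresholds_must_stay_below_tumor_thresholds(self):
        with pytest.raises(ValueError, match="germline"):
            somatic.FilterThresholds(germline_consensus=40)


class TestSubtractKnown:
    tumor = calls_frame([dict(pos=1), dict(pos=2), dict(pos=3)])

    def test_marginal_germline_evidence_vetoes_somatic_call(self):
        germline = calls_frame([dict(pos=1, consensus_quality=11, depth=1,
                                     min_mapq=21)])
        out = somatic.subtract_known(self.tumor, germline)
        assert out["pos"].tolist() == [2, 3]

    def test_known_polymorphism_site_removed(self):
        dbsnp = pd.DataFrame({"chrom": ["chr1"], "pos": [2]})
        out = somatic.subtract_known(self.tumor, self.tumor.iloc[:0], [dbsnp])
        assert out["pos"].tolist() == [1, 3]

    def test_allele_aware_blocklist_requires_matching_alt(self):
        known = pd.DataFrame({"chrom": ["chr1"], "pos": [3], "alt": ["G"]})
        out = somatic.subtract_known(self.tumor, self.tumor.iloc[:0], [known])
        assert out["pos"].tolist() == [1, 2, 3]

    def test_unlisted_site_retained(self):
        out = somatic.subtract_known(self.tumor, self.tumor.iloc[:0], [])
        assert len(out) == 3


class TestAnnotateCoding:
    gene_models = pd.DataFrame([
        ("FWD", "chr1", 100, 109, "+"),
        ("REV", "chr1", 300, 309, "-"),
    ], columns=["gene_id", "chrom", "start", "end", "strand"])
    # FWD protein: GAT TTG GCT = D L A ; REV coding strand likewise
    seqs = {"FWD": "GATTTGGCT", "REV": "GATTTGGCT"}

    def annotate(self, pos, ref, alt):
        cand = pd.DataFrame([call_row(pos=pos, ref=ref, alt=alt)])
        return somatic.annotate_coding(cand, self.gene_models, self.seqs).iloc[0]

    def test_aspartate_to_tyrosine_missense(self):
        # GAT -> TAT : D -> Y
        row = self.annotate(100, "G", "T")
        assert (row["ref_aa"], row["alt_aa"]) == ("D", "Y")
        assert row["consequence"] == "missense"
        assert row["protein_pos"] == 1

    def test_leucine_to_stop_nonsense(self):
        # TTG -> TAG : L -> *
        row = self.annotate(104, "T", "A")
        assert (row["ref_aa"], row["alt_aa"]) == ("L", "*")
        assert row["consequence"] == "nonsense"

    def test_synonymous_substitution_detected(self):
        # GCT -> GCC : A -> A
        row = self.annotate(108, "T", "C")
        assert row["consequence"] == "synonymous"

    def test_minus_strand_codons_read_reverse_complemented(self):
        # genomic end-1 base corresponds to CDS position 0 (G of GAT);
        # genomic C->A reads as G->T on the coding strand: D -> Y
        row = self.annotate(308, "C", "A")
        assert row["gene_id"] == "REV"
        assert (row["ref_aa"], row["alt_aa"]) == ("D", "Y")
        assert row["consequence"] == "missense"

    def test_intergenic_position_classified_non_coding(self):
        row = self.annotate(500, "A", "T")
        assert row["consequence"] == "non-coding"
        assert row["gene_id"] is None

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            self.annotate(100, "C", "T")


class TestRecurrence:
    t1 = pd.DataFrame([{"chrom": "chr1", "pos": 10, "alt": "T"}])
    t2 = pd.DataFrame([
        {"chrom": "chr1", "pos": 10, "alt": "T"},
        {"chrom": "chr1", "pos": 20, "alt": "G"},
        {"chrom": "chr1", "pos": 30, "alt": "C"},
    ])

    def test_zero_supporting_reads_in_t1_means_new(self):
        evidence = pd.DataFrame(
            [{"chrom": "chr1", "pos": 20, "alt": "G", "alt_reads": 0}])
        out = somatic.recurrence_new_variants(self.t2, self.t1, evidence)
        assert out.loc[out["pos"] == 20, "recurrence_status"].iloc[0] == "new"

    def test_single_supporting_read_downgrades_to_pre_existing(self):
        evidence = pd.DataFrame(
            [{"chrom": "chr1", "pos": 30, "alt": "C", "alt_reads": 1}])
        out = somatic.recurrence_new_variants(self.t2, self.t1, evidence)
        assert out.loc[out["pos"] == 30, "recurrence_status"].iloc[0] == \
            "pre-existing at low level"

    def test_variant_called_in_both_timepoints_is_shared(self):
        out = somatic.recurrence_new_variants(self.t2, self.t1,
                                              self.t1.assign(alt_reads=12))
        assert out.loc[out["pos"] == 10, "recurrence_status"].iloc[0] == "shared"
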