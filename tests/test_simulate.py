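"""Contracts of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from oncotrace import simulate
from oncotrace.layout import GenomeLayout, TruthSet


class TestDepthTracks:
    def test_neutral_truth_gives_unit_ratio(self, small_layout, neutral_truth):
        normal, tumor = simulate.simulate_depth_tracks(
            small_layout, neutral_truth, mean_depth=200.0, overdispersion=0.0,
            seed=3)
        ratio = tumor["count"].sum() / normal["count"].sum()
        assert ratio == pytest.approx(1.0, rel=0.02)

    def test_high_amplification_scales_depth_by_state_factor(self):
        # one state-5 segment (factor 4) over 10,000 windows at depth 100
        layout = GenomeLayout({"chr1": 20_000_000})
        truth = TruthSet(cnv_segments=pd.DataFrame(
            [("chr1", 0, 10_000_000, 5)],
            columns=["chrom", "start", "end", "state"]))
        normal, tumor = simulate.simulate_depth_tracks(
            layout, truth, mean_depth=100.0, window=1000, seed=7)
        inside = tumor["end"] <= 10_000_000
        mean_ratio = (tumor.loc[inside, "count"].mean()
                      / normal.loc[inside, "count"].mean())
        assert mean_ratio == pytest.approx(4.0, rel=0.10)

    def test_same_seed_reproduces_different_seed_differs(
            self, small_layout, neutral_truth):
        a = simulate.simulate_depth_tracks(small_layout, neutral_truth, seed=7)
        b = simulate.simulate_depth_tracks(small_layout, neutral_truth, seed=7)
        c = simulate.simulate_depth_tracks(small_layout, neutral_truth, seed=8)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert not a[1]["count"].equals(c[1]["count"])

    def test_truth_segment_outside_layout_rejected(self, small_layout):
        truth = TruthSet(cnv_segments=pd.DataFrame(
            [("chr1", 0, 2_000_000, 3)],
            columns=["chrom", "start", "end", "state"]))
        with pytest.raises(ValueError, match="outside layout"):
            simulate.simulate_depth_tracks(small_layout, truth)

    def test_zero_mean_depth_rejected(self, small_layout, neutral_truth):
        with pytest.raises(ValueError, match="positive"):
            simulate.simulate_depth_tracks(
                small_layout, neutral_truth, mean_depth=0.0)


class TestSnpCalls:
    def test_no_loh_no_error_keeps_germline_zygosity(
            self, small_layout, neutral_truth):
        calls = simulate.simulate_snp_calls(
            small_layout, neutral_truth, n_germline_sites=500,
            error_rate=0.0, seed=5)
        normal_het = calls.normal["p_het"] >= 0.5
        tumor_het = calls.tumors["T1"]["p_het"] >= 0.5
        # same site panel, same order after sorting by position
        assert normal_het.tolist() == tumor_het.tolist()

    def test_somatic_variant_read_counts_follow_binomial_mean(self):
        # 1,000 planted variants at allele fraction 0.5, depth 30
        layout = GenomeLayout({"chr1": 10_000_000})
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(10_000_000, 1000, replace=False))
        som = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": "A",
                            "alt": "T", "vaf": 0.5, "timepoints": "T1"})
        truth = TruthSet(somatic_variants=som)
        calls = simulate.simulate_snp_calls(
            layout, truth, n_germline_sites=0, error_rate=0.0,
            mean_depth=30.0, seed=9)
        assert calls.tumors["T1"]["variant_reads"].mean() == pytest.approx(
            15.0, rel=0.05)

    def test_high_loh_segment_drives_het_fraction_below_5pct(self):
        layout = GenomeLayout({"chr1": 4_000_000})
        truth = TruthSet(loh_segments=pd.DataFrame(
            [("chr1", 0, 4_000_000, "high")],
            columns=["chrom", "start", "end", "state"]))
        calls = simulate.simulate_snp_calls(
            layout, truth, n_germline_sites=1500, error_rate=0.01, seed=2)
        het_sites = calls.germline_sites[
            calls.germline_sites["genotype"] == "het"]
        keys = set(zip(het_sites["chrom"], het_sites["pos"]))
        t = calls.tumors["T1"]
        at_het = t[[k in keys for k in zip(t["chrom"], t["pos"])]]
        assert (at_het["p_het"] >= 0.5).mean() < 0.05

    def test_error_rate_out_of_range_rejected(self, small_layout, neutral_truth):
        with pytest.raises(ValueError, match="error rate"):
            simulate.simulate_snp_calls(
                small_layout, neutral_truth, error_rate=0.5)

    def test_site_panel_exceeding_capacity_rejected(self, neutral_truth):
        tiny = GenomeLayout({"chr1": 100})
        with pytest.raises(ValueError, match="capacity"):
            simulate.simulate_snp_calls(tiny, neutral_truth,
                                        n_germline_sites=200)


class TestExpression:
    def test_extreme_outlier_exceeds_whole_compendium(self):
        truth_de = pd.DataFrame([("G00000", "up", 50.0)],
                                columns=["gene_id", "direction", "effect_size"])
        m = simulate.simulate_expression(
            n_genes=100, n_compendium=50, truth_de=truth_de,
            dispersion=0.01, seed=4)
        comp = m.counts.loc["G00000", m.libraries("compendium")]
        assert m.counts.at["G00000", "tumor_T1"] > comp.max()

    def test_zero_inflated_genes_fail_low_information_filter(self):
        from oncotrace import expression
        zi = [f"G{i:05d}" for i in range(10)]
        m = simulate.simulate_expression(
            n_genes=100, n_compendium=50, zero_inflated_genes=zi,
            zero_inflation=0.95, seed=6)
        kept = expression.filter_low_information(m)
        # with 95% dropout, ~2-3 of 50 libraries stay non-zero (< 20%)
        assert not set(zi) & set(kept)

    def test_invalid_effect_size_rejected(self):
        bad = pd.DataFrame([("G00000", "up", -1.0)],
                           columns=["gene_id", "direction", "effect_size"])
        with pytest.raises(ValueError, match="effect"):
            simulate.simulate_expression(truth_de=bad)

    def test_totals_cover_column_sums(self):
        m = simulate.simulate_expression(n_genes=50, n_compendium=10, seed=1)
        assert (m.totals >= m.counts.sum(axis=0)).all()


def test_truth_tables_round_trip_through_tsv(tmp_path):
    from oncotrace import io
    cnv = pd.DataFrame([("chr1", 0, 1000, 5), ("chr2", 50, 80, 1)],
                       columns=["chrom", "start", "end", "state"])
    io.write_table(cnv, tmp_path / "truth_cnv.tsv")
    back = io.read_table(tmp_path / "truth_cnv.tsv")
    pd.testing.assert_frame_equal(cnv, back)


def test_expression_matrix_round_trips(tmp_path):
    from oncotrace import io
    m = simulate.simulate_expression(n_genes=20, n_compendium=6, seed=3)
    io.write_expression(m, tmp_path / "expr.tsv")
    back = io.read_expression(tmp_path / "expr.tsv")
    pd.testing.assert_frame_equal(m.counts, back.counts, check_dtype=False,
                                  check_names=False)
    assert back.roles.tolist() == m.roles[back.counts.columns].tolist()
    assert back.totals.tolist() == m.totals[back.counts.columns].tolist()
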