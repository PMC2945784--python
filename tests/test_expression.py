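"""Differential expression: normalization, outlier statistic, Fisher
test, BH correction and the combined caller."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from oncotrace import expression, simulate


def exact_fisher_two_sided(a, b, c, d):
    """Independent oracle: exact-rational two-sided Fisher p for the
    2x2 table [[a, b], [c, d]] by full hypergeometric enumeration."""
    n1, n2, m1 = a + b, c + d, a + c
    N = n1 + n2
    denom = comb(N, m1)

    def pmf(x):
        return Fraction(comb(n1, x) * comb(n2, m1 - x), denom)

    obs = pmf(a)
    lo, hi = max(0, m1 - n2), min(m1, n1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= obs)


def make_matrix(counts: dict, roles: dict, totals: dict):
    return simulate.ExpressionMatrix(
        counts=pd.DataFrame(counts),
        roles=pd.Series(roles), totals=pd.Series(totals))


class TestNormalize:
    matrix = make_matrix(
        {"tumor_T1": [100, 0], "blood": [200, 50]},
        {"tumor_T1": "tumor", "blood": "blood"},
        {"tumor_T1": 1_000_000, "blood": 2_000_000})

    def test_per_million_scaling(self):
        norm = expression.normalize(self.matrix)
        assert norm.iloc[0].tolist() == [100.0, 100.0]

    def test_zero_count_stays_zero(self):
        assert expression.normalize(self.matrix).iloc[1, 0] == 0.0

    def test_scaling_a_library_changes_nothing(self):
        doubled = make_matrix(
            {"tumor_T1": [200, 0], "blood": [200, 50]},
            {"tumor_T1": "tumor", "blood": "blood"},
            {"tumor_T1": 2_000_000, "blood": 2_000_000})
        pd.testing.assert_frame_equal(expression.normalize(self.matrix),
                                      expression.normalize(doubled))


class TestLowInformationFilter:
    def _matrix(self, nonzero):
        comp = {f"c{i:02d}": [1 if i < nonzero else 0] for i in range(50)}
        counts = {"tumor_T1": [5], **comp}
        roles = {"tumor_T1": "tumor", **{k: "compendium" for k in comp}}
        totals = {k: 1000 for k in counts}
        return make_matrix(counts, roles, totals)

    def test_18pct_nonzero_removed(self):
        assert expression.filter_low_information(self._matrix(9)) == []

    def test_exactly_20pct_nonzero_kept(self):
        assert len(expression.filter_low_information(self._matrix(10))) == 1

    def test_fully_observed_gene_kept(self):
        assert len(expression.filter_low_information(self._matrix(50))) == 1


class TestOutlierP:
    comp = np.arange(1.0, 51.0)  # 50 distinct compendium values

    def test_above_entire_compendium(self):
        assert expression.outlier_p(100.0, self.comp, "over") == \
            pytest.approx(1 / 51)

    def test_central_value_is_uninformative(self):
        assert expression.outlier_p(25.5, self.comp, "over") == \
            pytest.approx(26 / 51, abs=0.02)

    def test_monotone_in_tumor_value(self):
        rng = np.random.default_rng(0)
        comp = rng.lognormal(3, 1, 50)
        values = np.sort(rng.lognormal(3, 1.5, 30))
        ps = [expression.outlier_p(v, comp, "over") for v in values]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_too_few_compendium_values_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            expression.outlier_p(1.0, np.arange(4), "over")


class TestFisherVsBlood:
    def test_matches_exact_enumeration_small_tables(self):
        # exhaustive over all tables with both totals <= 12
        for ta, tb in itertools.product(range(1, 13), repeat=2):
            for a in range(0, ta + 1, 3):
                for b in range(0, tb + 1, 3):
                    if a == 0 and b == 0:
                        continue
                    p, _ = expression.fisher_vs_blood(a, ta, b, tb)
                    oracle = exact_fisher_two_sided(a, ta - a, b, tb - b)
                    assert p == pytest.approx(float(oracle), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_at_margins_up_to_200(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            ta, tb = rng.integers(20, 201, 2)
            a, b = rng.integers(0, ta + 1), rng.integers(0, tb + 1)
            if a == 0 and b == 0:
                continue
            p, _ = expression.fisher_vs_blood(int(a), int(ta), int(b), int(tb))
            oracle = exact_fisher_two_sided(int(a), int(ta - a),
                                            int(b), int(tb - b))
            assert p == pytest.approx(float(oracle), rel=1e-7, abs=1e-12)

    def test_agrees_with_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact
        p, _ = expression.fisher_vs_blood(9, 10, 1, 10)
        assert p == pytest.approx(
            fisher_exact([[9, 1], [1, 9]]).pvalue, rel=1e-9)

    def test_identical_proportions_uninformative(self):
        p, fc = expression.fisher_vs_blood(50, 1000, 50, 1000)
        assert p == pytest.approx(1.0)
        assert fc == pytest.approx(1.0)

    def test_under_expression_uses_negative_reciprocal_convention(self):
        _, fc = expression.fisher_vs_blood(
            249, 1_000_000, 999, 1_000_000, pseudocount=1.0)
        assert fc == pytest.approx(-4.0)

    def test_double_zero_gene_flagged(self):
        p, fc = expression.fisher_vs_blood(0, 1000, 0, 1000)
        assert p == 1.0 and np.isnan(fc)

    def test_huge_margins_down_scaled_with_warning(self):
        with pytest.warns(UserWarning, match="down-scaling"):
            p, _ = expression.fisher_vs_blood(
                5000, 3_000_000_000, 1000, 2_000_000_000)
        assert 0.0 <= p <= 1.0


class TestBhAdjust:
    def test_step_up_formula_on_worked_example(self):
        adj = expression.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert expression.bh_adjust([0.3]).tolist() == [0.3]

    def test_equal_ps_unchanged(self):
        assert np.allclose(expression.bh_adjust([0.2] * 7), 0.2)

    def test_matches_direct_step_up_computation(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 100)
        # independent re-implementation of the step-up rule
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(expression.bh_adjust(p), expected)


class TestCallDe:
    def test_planted_extremes_called_with_correct_signs(self):
        truth = pd.DataFrame([("G00000", "up", 30.0), ("G00001", "down", 0.03)],
                             columns=["gene_id", "direction", "effect_size"])
        m = simulate.simulate_expression(
            n_genes=300, truth_de=truth, dispersion=0.02, seed=2)
        res = expression.call_de(m).set_index("gene_id")
        assert res.at["G00000", "call"] == "up"
        assert res.at["G00000", "fc_comp"] > 2
        assert res.at["G00001", "call"] == "down"
        assert res.at["G00001", "fc_comp"] < -2

    def test_fold_change_gate_blocks_significant_but_small_effects(self):
        thr = expression.DEThresholds(fc_compendium=50.0)
        truth = pd.DataFrame([("G00000", "up", 10.0)],
                             columns=["gene_id", "direction", "effect_size"])
        m = simulate.simulate_expression(
            n_genes=100, truth_de=truth, dispersion=0.02, seed=3)
        res = expression.call_de(m, thresholds=thr).set_index("gene_id")
        # outlier and Fisher p are tiny, yet the FC gate keeps call at none
        assert res.at["G00000", "p_outlier"] < 0.05
        assert res.at["G00000", "call"] == "none"

    def test_null_matrix_rarely_called(self):
        m = simulate.simulate_expression(n_genes=500, seed=4)
        res = expression.call_de(m)
        assert (res["call"] != "none").mean() <= 0.05


class TestOverlapSets:
    def test_pairwise_intersection(self):
        out = expression.overlap_sets({"a", "b", "c"}, {"b", "c", "d"})
        assert out["A&B"] == 2

    def test_disjoint_sets(self):
        assert expression.overlap_sets({"a"}, {"b"})["A&B"] == 0

    def test_subset_intersection_equals_subset_size(self):
        out = expression.overlap_sets({"a", "b"}, {"a", "b", "c"})
        assert out["A&B"] == 2

    def test_three_way_regions(self):
        out = expression.overlap_sets({"a", "b"}, {"b", "c"}, {"b", "d"})
        assert out["A&B&C"] == 1
        assert out["A|B|C"] == 4
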