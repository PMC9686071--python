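import itertools
import math

import numpy as np
import pandas as pd
import pytest

from m6avar.association_stats import (
    benjamini_hochberg,
    fc_correlation,
    fraction_methylated_by_quartile,
    heat_response_matrix,
    rank_test_one_tailed,
    score_comparison,
    set_overlap_test,
)
from m6avar.formats_io import ExpressionMatrix, GroupKey, SampleKey


def exhaustive_rank_p(x, y, alternative):
    """Exact one-tailed p by enumerating all label assignments (oracle)."""
    pooled = list(x) + list(y)
    n_x = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n_x].sum()
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        stat = ranks[list(combo)].sum()
        if alternative == "less":
            count += stat <= obs
        else:
            count += stat >= obs
        total += 1
    return count / total


class TestRankTest:
    def test_exact_small_sample_p_is_one_twentieth(self):
        res = rank_test_one_tailed([1, 2, 3], [4, 5, 6], "less")
        assert res.p_value == pytest.approx(1 / 20)

    def test_identical_large_samples_give_half(self, rng):
        x = rng.normal(size=500)
        res = rank_test_one_tailed(x, x.copy(), "less")
        assert res.p_value == pytest.approx(0.5, abs=0.02)

    def test_swapping_samples_flips_alternative(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=12) + 0.5
        a = rank_test_one_tailed(x, y, "less")
        b = rank_test_one_tailed(y, x, "greater")
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_test_one_tailed([], [1.0], "less")
        with pytest.raises(ValueError):
            rank_test_one_tailed([1.0], [2.0], "sideways")

    def test_exact_branch_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            n_x = int(rng.integers(1, 5))
            n_y = int(rng.integers(1, 5))
            vals = rng.permutation(20)[: n_x + n_y].astype(float)
            x, y = vals[:n_x], vals[n_x:]
            for alt in ("less", "greater"):
                expected = exhaustive_rank_p(x, y, alt)
                got = rank_test_one_tailed(x, y, alt).p_value
                assert got == pytest.approx(expected, abs=1e-10)


class TestQuartileFractions:
    @staticmethod
    def quartile_map():
        genes = [f"g{i}" for i in range(8)]
        return pd.Series(
            ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"], index=genes
        )

    def test_counting_by_hand(self):
        q = self.quartile_map()
        tab = fraction_methylated_by_quartile(q, {"g0", "g1", "g2"})
        assert list(tab["fraction"]) == [1.0, 0.5, 0.0, 0.0]
        assert tab.attrs["monotone_nonincreasing"] is True

    def test_empty_and_full_methylated_sets(self):
        q = self.quartile_map()
        assert list(fraction_methylated_by_quartile(q, set())["fraction"]) == [0] * 4
        assert list(
            fraction_methylated_by_quartile(q, set(q.index))["fraction"]
        ) == [1] * 4

    def test_empty_quartile_rejected(self):
        q = pd.Series(["Q1", "Q2", "Q3"], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="Q4"):
            fraction_methylated_by_quartile(q, set())


class TestSetOverlap:
    def test_closed_form_full_overlap(self):
        universe = set(range(10))
        a = set(range(5))
        res = set_overlap_test(a, a, universe)
        assert res.overlap == 5
        assert res.p_value == pytest.approx(1 / 252)

    def test_no_overlap_in_large_universe_p_near_one(self):
        universe = set(range(1000))
        res = set_overlap_test(set(range(5)), set(range(5, 10)), universe)
        assert res.p_value > 0.9

    def test_set_a_equal_universe_is_degenerate(self):
        universe = set(range(20))
        res = set_overlap_test(universe, set(range(7)), universe)
        assert res.overlap == 7
        assert res.p_value == pytest.approx(1.0)

    def test_uncontained_set_rejected(self):
        with pytest.raises(ValueError):
            set_overlap_test({"x"}, set(), {"a"})

    def test_matches_direct_hypergeometric_summation(self, rng):
        for _ in range(50):
            n_univ = int(rng.integers(5, 50))
            k_a = int(rng.integers(1, n_univ + 1))
            n_b = int(rng.integers(1, n_univ + 1))
            universe = set(range(n_univ))
            a = set(rng.choice(n_univ, k_a, replace=False).tolist())
            b = set(rng.choice(n_univ, n_b, replace=False).tolist())
            res = set_overlap_test(a, b, universe)
            obs = len(a & b)
            direct = sum(
                math.comb(k_a, i) * math.comb(n_univ - k_a, n_b - i)
                for i in range(obs, min(k_a, n_b) + 1)
            ) / math.comb(n_univ, n_b)
            assert res.p_value == pytest.approx(min(1.0, direct), abs=1e-12)


class TestFcCorrelation:
    @staticmethod
    def expr_from(fc, delta):
        """Engineer input/IP means so log2FC = fc and enrichment change = delta."""
        cols, keys = {}, []
        inp_cs = np.ones_like(fc)
        inp_hs = 2.0 ** fc
        ip_cs = np.ones_like(fc)
        ip_hs = inp_hs * 2.0 ** delta
        for cond, inp, ip in [("CS", inp_cs, ip_cs), ("HS", inp_hs, ip_hs)]:
            for frac, vals in [("input", inp), ("IP", ip)]:
                k = SampleKey("leaf", cond, "wt", frac, 1)
                keys.append(k)
                cols[k.label()] = vals
        genes = [f"g{i}" for i in range(len(fc))]
        return ExpressionMatrix(pd.DataFrame(cols, index=genes), keys)

    def test_perfect_linear_relation_gives_r_one(self):
        fc = np.linspace(-2, 2, 9)
        expr = self.expr_from(fc, 2 * fc + 1)
        r, n = fc_correlation(expr, "leaf", "wt", pseudocount=0.0)
        assert r == pytest.approx(1.0)
        assert n == 9

    def test_perfect_anticorrelation(self):
        fc = np.linspace(-2, 2, 9)
        r, _ = fc_correlation(self.expr_from(fc, -fc), "leaf", "wt", pseudocount=0.0)
        assert r == pytest.approx(-1.0)

    def test_independent_planted_effects_give_near_zero_r(self, rng):
        fc = rng.normal(0, 1, 2000)
        delta = rng.normal(0, 1, 2000)
        r, n = fc_correlation(self.expr_from(fc, delta), "leaf", "wt", pseudocount=0.0)
        assert abs(r) < 0.1 and n == 2000

    def test_too_few_genes_rejected(self):
        expr = self.expr_from(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            fc_correlation(expr, "leaf", "wt")


class TestScoreComparison:
    def test_same_seed_reproduces_draw_and_p(self, rng):
        scores = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
        genes = set(scores.index[:40])
        a = score_comparison(genes, scores, "greater", seed=9)
        b = score_comparison(genes, scores, "greater", seed=9)
        assert a.random_genes == b.random_genes
        assert a.test.p_value == b.test.p_value

    def test_oversized_set_rejected(self, rng):
        scores = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            score_comparison(set(scores.index[:8]), scores, "greater")

    def test_planted_shift_detected(self, rng):
        scores = pd.Series(rng.normal(size=1000), index=[f"g{i}" for i in range(1000)])
        genes = set(scores.index[:500])
        scores.loc[sorted(genes)] += 1.0
        res = score_comparison(genes, scores, "greater", seed=0)
        assert res.test.p_value < 0.05


class TestHeatResponseMatrix:
    def test_on_fixture_selection_and_column_ordering(self, study_data):
        _m, _s, expr, truth, _p = study_data
        mat = heat_response_matrix(expr, selection_fold=2.0)
        assert len(mat) > 0
        # every selected row clears the wt-leaf two-fold boundary
        assert (mat["leaf.wt"] >= 1.0 - 1e-12).all()
        means = mat.attrs["column_means"]
        assert means["leaf.wt"] > means["flower.wt"] > means["flower.mutant"]

    def test_inclusive_two_fold_boundary(self):
        cols, keys = {}, []
        for label in ["leaf.wt", "flower.wt", "leaf.mutant", "flower.mutant"]:
            tissue, geno = label.split(".")
            for cond, v in [("CS", np.array([1.0, 1.0])), ("HS", np.array([2.0, 1.9]))]:
                k = SampleKey(tissue, cond, geno, "input", 1)
                keys.append(k)
                cols[k.label()] = v
        expr = ExpressionMatrix(pd.DataFrame(cols, index=["gBoundary", "gBelow"]), keys)
        mat = heat_response_matrix(expr, selection_fold=2.0, pseudocount=0.0)
        assert list(mat.index) == ["gBoundary"]

    def test_missing_group_rejected(self):
        k = SampleKey("leaf", "CS", "wt", "input", 1)
        expr = ExpressionMatrix(pd.DataFrame({k.label(): [1.0]}, index=["g"]), [k])
        with pytest.raises(ValueError, match="missing group"):
            heat_response_matrix(expr)


def test_benjamini_hochberg_monotone_and_bounded(rng):
    p = rng.uniform(size=50)
    q = benjamini_hochberg(p)
    assert np.all((q >= p - 1e-12) & (q <= 1.0))
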