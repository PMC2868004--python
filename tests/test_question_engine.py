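import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probmde import (
    CountLibrary,
    ExpressionDataset,
    GeneProbability,
    estimate_probability,
    evaluate_question,
    parse_question,
    pool_libraries,
    rank_genes,
)
from probmde.errors import QuestionParseError
from probmde.question_engine import BoolOp, Comparison, normalize_cutoff
from helpers import prob_x_greater_y


class TestParser:
    def test_chained_comparison_desugars_to_conjunction(self):
        ast = parse_question("A < B < C")
        assert isinstance(ast.root, BoolOp) and ast.root.op == "AND"
        assert [str(c) for c in ast.root.children] == ["A < B", "B < C"]

    def test_group_operands_from_comma_lists(self):
        ast = parse_question("GSM383859,GSM383860 > GSM383869,GSM383870")
        cmp_ = ast.root
        assert isinstance(cmp_, Comparison)
        assert cmp_.left.kind == "group"
        assert cmp_.left.ids == ("GSM383859", "GSM383860")
        assert cmp_.right.ids == ("GSM383869", "GSM383870")

    def test_pool_operands_from_plus_lists(self):
        ast = parse_question("A+B > C")
        assert ast.root.left.kind == "pool"
        assert ast.root.left.ids == ("A", "B")

    def test_and_binds_tighter_than_or(self):
        ast = parse_question("A > B AND B > C OR A > D")
        assert isinstance(ast.root, BoolOp) and ast.root.op == "OR"
        assert isinstance(ast.root.children[0], BoolOp)
        assert ast.root.children[0].op == "AND"

    def test_parenthesized_question(self):
        ast = parse_question("(GSM1, GSM2 > GSM3, GSM4)")
        assert ast.root.left.kind == "group"

    def test_malformed_double_operator_errors_with_position(self):
        with pytest.raises(QuestionParseError) as err:
            parse_question("A < < B")
        assert err.value.position == 4

    @pytest.mark.parametrize(
        "text", ["A <", "AND A > B", "A", "A , > B", "A,B+C > D", "(A > B"]
    )
    def test_malformed_questions_rejected(self, text):
        with pytest.raises(QuestionParseError):
            parse_question(text)

    def test_unknown_id_rejected_when_known_ids_given(self):
        with pytest.raises(QuestionParseError, match="nope"):
            parse_question("A > nope", known_ids={"A", "B"})

    def test_shared_operand_has_one_key(self):
        ast = parse_question("A < B AND B < C")
        assert [o.key for o in ast.operands()] == ["A", "B", "C"]


class TestPooling:
    def test_counts_and_totals_sum_before_posterior(self):
        libs = [CountLibrary("A", {"g": 3}, 10), CountLibrary("B", {"g": 2}, 10)]
        post = pool_libraries(libs, "g")
        assert (post.a, post.b) == (6, 16)

    def test_single_library_pool_is_plain_posterior(self):
        lib = CountLibrary("A", {"g": 3}, 10)
        post = pool_libraries([lib], "g")
        assert (post.a, post.b) == (4, 8)

    def test_pooling_equal_libraries_shrinks_variance(self):
        lib = CountLibrary("A", {"g": 30}, 1000)
        one = pool_libraries([lib], "g")
        two = pool_libraries([lib, lib], "g")
        # doubling the evidence roughly halves the posterior variance
        assert two.variance < 0.6 * one.variance

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_libraries([], "g")


class TestEvaluate:
    @pytest.mark.parametrize(
        "draws, expected",
        [
            ({"A": 0.1, "B": 0.2, "C": 0.3}, True),
            ({"A": 0.1, "B": 0.5, "C": 0.3}, False),
        ],
    )
    def test_conjunction_on_scalar_draws(self, draws, expected):
        ast = parse_question("A < B AND B < C")
        assert evaluate_question(ast, draws) is expected

    def test_disjunction(self):
        ast = parse_question("A > B OR A > C")
        assert evaluate_question(ast, {"A": 0.4, "B": 0.5, "C": 0.3}) is True

    def test_missing_operand_draw_errors(self):
        ast = parse_question("A > B")
        with pytest.raises(KeyError):
            evaluate_question(ast, {"A": 0.4})

    def test_vector_draws_give_per_iteration_truth(self):
        ast = parse_question("A < B")
        out = evaluate_question(
            ast, {"A": np.array([0.1, 0.9]), "B": np.array([0.5, 0.5])}
        )
        assert out.tolist() == [True, False]


class TestEstimateProbability:
    def test_identical_libraries_give_half(self):
        ds = ExpressionDataset(
            libraries=[
                CountLibrary("A", {"g": 10}, 100),
                CountLibrary("B", {"g": 10}, 100),
            ]
        )
        ast = parse_question("A > B")
        r = estimate_probability("g", ast, ds, n_sims=10_000, seed=5)
        assert abs(r.p_hat - 0.5) <= 4 * math.sqrt(0.25 / 10_000)

    def test_complement_probabilities_sum_to_one_exactly(self, pair_dataset):
        fwd = estimate_probability(
            "g1", parse_question("A > B"), pair_dataset, n_sims=5000, seed=9
        )
        rev = estimate_probability(
            "g1", parse_question("A < B"), pair_dataset, n_sims=5000, seed=9
        )
        assert fwd.s_true + rev.s_true == 5000
        assert fwd.p_hat + rev.p_hat == 1.0

    def test_chaining_equals_conjunction_for_same_seed(self, toy_dataset):
        chained = estimate_probability(
            "g1", parse_question("L1 < L2 < L3"), toy_dataset, n_sims=4000, seed=3
        )
        explicit = estimate_probability(
            "g1",
            parse_question("L1 < L2 AND L2 < L3"),
            toy_dataset,
            n_sims=4000,
            seed=3,
        )
        assert chained.s_true == explicit.s_true

    def test_matches_quadrature_oracle(self):
        ds = ExpressionDataset(
            libraries=[
                CountLibrary("A", {"g": 20}, 100),
                CountLibrary("B", {"g": 5}, 100),
            ]
        )
        ast = parse_question("A > B")
        n = 10_000
        r = estimate_probability("g", ast, ds, n_sims=n, seed=2)
        truth = prob_x_greater_y(21, 81, 6, 96)
        se = math.sqrt(truth * (1 - truth) / n)
        assert abs(r.p_hat - truth) <= 3 * se

    def test_probability_increases_with_count(self):
        # with T fixed, raising N_A raises P(pi_A > pi_B)
        values = []
        for n_a in (5, 10, 20, 40):
            values.append(prob_x_greater_y(n_a + 1, 100 - n_a + 1, 11, 91))
        assert values == sorted(values)
        assert values[0] < values[-1] - 0.1

    def test_deterministic_for_fixed_seed(self, toy_dataset):
        ast = parse_question("L1 < L2 < L3")
        a = estimate_probability("g1", ast, toy_dataset, n_sims=2000, seed=42)
        b = estimate_probability("g1", ast, toy_dataset, n_sims=2000, seed=42)
        assert a.s_true == b.s_true

    def test_unobserved_gene_is_flagged_but_valid(self, pair_dataset):
        ast = parse_question("A > B")
        r = estimate_probability("ghost", ast, pair_dataset, n_sims=1000, seed=1)
        assert r.all_zero
        assert 0.0 <= r.p_hat <= 1.0

    def test_group_question_exercises_mixture_path(self, toy_dataset):
        ast = parse_question("L1,L2 < L3")
        r = estimate_probability("g1", ast, toy_dataset, n_sims=2000, seed=8)
        assert 0.0 <= r.p_hat <= 1.0

    def test_p_hat_is_exact_ratio(self):
        with pytest.raises(ValueError):
            GeneProbability("g", 0.5, s_true=501, n_sims=1000, seed=0)


class TestRankGenes:
    @staticmethod
    def _results(pairs):
        return [
            GeneProbability(g, s / 1000, s_true=s, n_sims=1000, seed=0)
            for g, s in pairs
        ]

    def test_cutoff_filters_and_sorts(self):
        res = self._results([("g1", 900), ("g2", 600), ("g3", 800)])
        assert [r.gene_id for r in rank_genes(res, 0.70)] == ["g1", "g3"]

    def test_zero_cutoff_keeps_all_sorted(self):
        res = self._results([("g2", 600), ("g1", 900), ("g3", 800)])
        assert [r.gene_id for r in rank_genes(res, 0)] == ["g1", "g3", "g2"]

    def test_percent_cutoff_equals_fraction(self):
        res = self._results([("g1", 900), ("g2", 790), ("g3", 810)])
        assert rank_genes(res, "80") == rank_genes(res, 0.8)

    def test_ties_broken_by_gene_id(self):
        res = self._results([("gB", 700), ("gA", 700)])
        assert [r.gene_id for r in rank_genes(res, 0)] == ["gA", "gB"]

    @pytest.mark.parametrize("bad", [-0.1, 101])
    def test_cutoff_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_cutoff(bad)

    @given(
        st.lists(st.integers(0, 1000), min_size=1, max_size=30),
        st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=50)
    def test_ranked_list_is_sorted_subset(self, s_trues, cutoff):
        res = self._results([(f"g{i}", s) for i, s in enumerate(s_trues)])
        ranked = rank_genes(res, cutoff)
        assert all(r.p_hat >= cutoff for r in ranked)
        assert all(
            ranked[i].p_hat >= ranked[i + 1].p_hat for i in range(len(ranked) - 1)
        )
        assert len(ranked) == sum(1 for r in res if r.p_hat >= cutoff)
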