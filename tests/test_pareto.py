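import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcoselect import (
    CriteriaMatrix,
    ValidationError,
    brute_force_frontier,
    dominates,
    pareto_frontier,
    pareto_frontier_split,
    peel_frontiers,
)

from conftest import random_criteria


def cm_from_rows(rows):
    genes = np.array([f"g{i}" for i in range(len(rows))], dtype=object)
    return CriteriaMatrix(genes, np.asarray(rows, dtype=float))


class TestDominates:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 2), (2, 3), True),    # strictly better everywhere
            ((1, 2), (1, 3), True),    # weakly better, strictly in one
            ((1, 3), (3, 1), False),   # trade-off: incomparable
            ((3, 1), (1, 3), False),
            ((2, 2), (2, 2), False),   # identical rows never dominate
        ],
    )
    def test_truth_table(self, u, v, expected):
        assert dominates(u, v) is expected

    def test_length_mismatch_fails(self):
        with pytest.raises(ValidationError, match="length"):
            dominates((1, 2), (1, 2, 3))


class TestParetoFrontier:
    def test_four_point_example(self):
        cm = cm_from_rows([(1, 2), (2, 1), (2, 2), (3, 3)])
        assert pareto_frontier(cm) == {"g0", "g1"}

    def test_single_gene(self):
        assert pareto_frontier(cm_from_rows([(4, 4, 4)])) == {"g0"}

    def test_all_identical_rows_all_on_frontier(self):
        cm = cm_from_rows([(1, 1)] * 5)
        assert pareto_frontier(cm) == {f"g{i}" for i in range(5)}

    def test_duplicated_frontier_rows_all_retained(self):
        cm = cm_from_rows([(0, 5), (0, 5), (5, 0), (3, 3)])
        assert pareto_frontier(cm) == {"g0", "g1", "g2", "g3"}

    def test_empty_matrix_fails(self):
        cm = cm_from_rows([(1, 1)])
        with pytest.raises(ValidationError, match="no genes"):
            pareto_frontier(cm.take(np.array([], dtype=int)))

    def test_negative_criteria_rejected(self):
        with pytest.raises(ValidationError, match=">= 0"):
            cm_from_rows([(1, -0.5)])

    def test_nonfinite_criteria_rejected(self):
        with pytest.raises(ValidationError, match="finite"):
            cm_from_rows([(1, np.nan)])


class TestOracleEquivalence:
    def test_trivial_pairs(self):
        assert brute_force_frontier(cm_from_rows([(1, 2), (2, 1)])) == {"g0", "g1"}
        assert brute_force_frontier(cm_from_rows([(0, 0), (1, 1)])) == {"g0"}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 300))
        C = int(rng.integers(1, 6))
        genes, X = random_criteria(rng, n, C, ties=bool(seed % 2))
        cm = CriteriaMatrix(genes, X)
        assert pareto_frontier(cm) == brute_force_frontier(cm)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 4), min_size=2, max_size=2),
            min_size=1,
            max_size=25,
        )
    )
    def test_matches_brute_force_on_small_tied_grids(self, rows):
        cm = cm_from_rows(rows)
        assert pareto_frontier(cm) == brute_force_frontier(cm)


class TestSplit:
    def test_s1_equals_plain_frontier(self):
        cm = cm_from_rows([(1, 2), (2, 1), (2, 2), (3, 3)])
        assert pareto_frontier_split(cm, 1) == pareto_frontier(cm)

    def test_example_with_two_blocks(self):
        cm = cm_from_rows([(1, 2), (2, 1), (2, 2), (3, 3)])
        assert pareto_frontier_split(cm, 2) == {"g0", "g1"}

    @pytest.mark.parametrize("S", [2, 5, 10])
    def test_invariant_across_split_counts(self, S):
        rng = np.random.default_rng(42)
        genes, X = random_criteria(rng, 200, 3)
        cm = CriteriaMatrix(genes, X)
        assert pareto_frontier_split(cm, S) == pareto_frontier(cm)

    @pytest.mark.parametrize("S", [0, -1, 5])
    def test_out_of_range_split_fails(self, S):
        cm = cm_from_rows([(1, 1), (2, 2)])
        with pytest.raises(ValidationError, match="S"):
            pareto_frontier_split(cm, S)


class TestPeeling:
    def test_chain_peels_one_per_frontier(self):
        fa = peel_frontiers(cm_from_rows([(1, 1), (2, 2), (3, 3)]), F=3)
        assert [fa.frontier(f) for f in (1, 2, 3)] == [{"g0"}, {"g1"}, {"g2"}]

    def test_f1_matches_single_frontier(self):
        rng = np.random.default_rng(5)
        genes, X = random_criteria(rng, 150, 2)
        cm = CriteriaMatrix(genes, X)
        fa = peel_frontiers(cm, F=1)
        assert fa.frontier(1) == pareto_frontier(cm)

    def test_exhaustion_warns_and_stops(self):
        cm = cm_from_rows([(1, 1), (2, 2), (3, 3)])
        with pytest.warns(UserWarning, match="exhausted"):
            fa = peel_frontiers(cm, F=10)
        assert fa.n_frontiers == 3
        assert fa.ranked_genes() == {"g0", "g1", "g2"}

    def test_f_below_one_fails(self):
        with pytest.raises(ValidationError, match="F"):
            peel_frontiers(cm_from_rows([(1, 1)]), F=0)

    @pytest.mark.parametrize("seed", range(8))
    def test_layer_laws_on_random_matrices(self, seed):
        """Frontiers are disjoint, layered by dominance, and cover all genes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        C = int(rng.integers(2, 5))
        genes, X = random_criteria(rng, n, C, ties=bool(seed % 2))
        cm = CriteriaMatrix(genes, X)
        fa = peel_frontiers(cm, F=n)
        assert fa.ranked_genes() == set(genes)
        pos = {g: i for i, g in enumerate(genes)}
        for f in range(2, fa.n_frontiers + 1):
            upper = [X[pos[g]] for g in fa.frontier(f - 1)]
            for g in fa.frontier(f):
                assert any(dominates(u, X[pos[g]]) for u in upper)

    def test_split_does_not_change_peeling(self):
        rng = np.random.default_rng(11)
        genes, X = random_criteria(rng, 120, 3)
        cm = CriteriaMatrix(genes, X)
        plain = peel_frontiers(cm, F=5, S=1)
        split = peel_frontiers(cm, F=5, S=7)
        assert np.array_equal(plain.frontier_index, split.frontier_index)


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_row_permutation_never_changes_membership(self, seed):
        rng = np.random.default_rng(seed)
        genes, X = random_criteria(rng, 80, 3, ties=True)
        cm = CriteriaMatrix(genes, X)
        perm = rng.permutation(80)
        shuffled = CriteriaMatrix(genes[perm], X[perm])
        assert pareto_frontier(cm) == pareto_frontier(shuffled)
        fa, fb = peel_frontiers(cm, F=4), peel_frontiers(shuffled, F=4)
        for f in range(1, 5):
            assert fa.frontier(f) == fb.frontier(f)

    @pytest.mark.parametrize(
        "transform", [lambda x: x**3, lambda x: np.exp(x), lambda x: 2.5 * x + 0.25]
    )
    def test_columnwise_monotone_transform_preserves_frontiers(self, transform):
        rng = np.random.default_rng(3)
        genes, X = random_criteria(rng, 100, 3, ties=True)
        base = peel_frontiers(CriteriaMatrix(genes, X), F=6)
        warped = peel_frontiers(CriteriaMatrix(genes, transform(X)), F=6)
        assert np.array_equal(base.frontier_index, warped.frontier_index)
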