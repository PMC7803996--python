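import numpy as np
import pandas as pd
import pytest

import ramphylo as rp
from ramphylo.charmatrix import CharacterMatrix
from ramphylo.errors import IncomparableTreesError, NewickParseError
from ramphylo.synth import SynthConfig, simulate_binary_characters, simulate_tree
from ramphylo.treeops import SearchConfig

from oracles import all_unrooted_newicks, brute_force_steps


class TestNewickIO:
    def test_parse_basic_rooted(self):
        tree = rp.parse_newick("((A,B),C);")
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert sorted(leaves) == ["A", "B", "C"]
        assert len(tree.seed_node.child_nodes()) == 2

    def test_root_polytomy_accepted(self):
        tree = rp.parse_newick("((A,B),(C,D),(E,F));")
        assert len(tree.seed_node.child_nodes()) == 3

    def test_round_trip_preserves_leaves_and_bipartitions(self):
        tree = simulate_tree(50, seed=7)
        again = rp.parse_newick(rp.write_newick(tree))
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {
            lf.taxon.label for lf in again.leaf_node_iter()
        }
        assert rp.bipartition_set(tree) == rp.bipartition_set(again)

    @pytest.mark.parametrize("bad", ["((A,B),C;", "(A,(A,B));", "((A,B),C));"])
    def test_malformed_newick_rejected(self, bad):
        with pytest.raises(NewickParseError):
            rp.parse_newick(bad)


class TestBipartitions:
    def test_five_leaf_binary_has_two(self, caterpillar):
        assert len(rp.bipartition_set(caterpillar)) == 2

    def test_star_has_none(self, star6):
        assert rp.bipartition_set(star6) == set()

    def test_caterpillar_splits_enumerated(self, caterpillar):
        # internal edges: AB|CDE and ABC|DE; canonical side omits leaf A
        assert rp.bipartition_set(caterpillar) == {
            frozenset({"C", "D", "E"}),
            frozenset({"D", "E"}),
        }

    def test_ten_leaf_unrooted_has_n_minus_3(self):
        tree = simulate_tree(10, seed=3)
        assert len(rp.bipartition_set(tree)) == 7


class TestBranchPercentIdentity:
    def test_identical_trees_are_100(self):
        tree = simulate_tree(12, seed=5)
        assert rp.branch_percent_identity(tree, tree) == 100.0

    def test_one_nni_on_five_leaves_gives_50(self):
        source = rp.parse_newick("((((A,B),C),D),E);")
        swapped = rp.parse_newick("((((A,C),B),D),E);")  # NNI across the central edge
        assert rp.branch_percent_identity(source, swapped) == 50.0

    def test_resolved_source_vs_star_reference_is_0(self, star6):
        source = rp.parse_newick("(((A,B),(C,D)),(E,F));")
        assert rp.branch_percent_identity(source, star6) == 0.0

    def test_star_source_is_undefined(self, star6):
        resolved = rp.parse_newick("(((A,B),(C,D)),(E,F));")
        assert rp.branch_percent_identity(star6, resolved) is None

    def test_too_few_shared_leaves_raises(self):
        a = rp.parse_newick("((A,B),(C,X));")
        b = rp.parse_newick("((A,B),(Y,Z));")
        with pytest.raises(IncomparableTreesError):
            rp.branch_percent_identity(a, b)

    def test_pruning_to_shared_leaves(self):
        # reference has extra taxa; identity judged on the shared set only
        src = rp.parse_newick("(((A,B),(C,D)),E);")
        ref = rp.parse_newick("((((A,B),(C,D)),E),(X,Y));")
        assert rp.branch_percent_identity(src, ref) == 100.0


def _matrix_from_states(labels, columns):
    """columns: list of dicts label -> 0/1/None"""
    data = {
        f"c{i}": [np.nan if col[lab] is None else float(col[lab]) for lab in labels]
        for i, col in enumerate(columns)
    }
    return CharacterMatrix(pd.DataFrame(data, index=labels))


class TestParsimonyScore:
    def test_clean_matrix_scores_one_per_character(self):
        tree = simulate_tree(12, seed=2)
        matrix, _ = simulate_binary_characters(
            tree, SynthConfig(n_leaves=12, n_characters=30, mode="clean", seed=4)
        )
        assert rp.parsimony_score(tree, matrix) == 30

    def test_all_missing_character_contributes_zero(self, quartet):
        labels = ["A", "B", "C", "D"]
        m = _matrix_from_states(labels, [{lab: None for lab in labels}])
        assert rp.parsimony_score(quartet, m) == 0

    def test_matches_exhaustive_enumeration_on_random_matrices(self, rng):
        labels = [f"t{i}" for i in range(6)]
        for trial in range(20):
            tree = simulate_tree(6, seed=trial)
            tl = [lf.taxon.label for lf in tree.leaf_node_iter()]
            cols = []
            for _ in range(5):
                cols.append({lab: int(rng.integers(2)) for lab in tl})
            m = _matrix_from_states(tl, cols)
            expected = sum(brute_force_steps(tree, col) for col in cols)
            assert rp.parsimony_score(tree, m) == expected

    def test_invariant_to_rerooting(self, rng):
        tree = simulate_tree(8, seed=11)
        tl = [lf.taxon.label for lf in tree.leaf_node_iter()]
        cols = [{lab: int(rng.integers(2)) for lab in tl} for _ in range(10)]
        m = _matrix_from_states(tl, cols)
        before = rp.parsimony_score(tree, m)
        rerooted = rp.parse_newick(rp.write_newick(tree))
        internal = [
            nd for nd in rerooted.preorder_internal_node_iter()
            if nd is not rerooted.seed_node
        ]
        rerooted.reroot_at_edge(internal[2].edge)
        assert rp.parsimony_score(rerooted, m) == before


class TestParsimonySearch:
    def test_recovers_generating_topology_from_clean_characters(self):
        tree = simulate_tree(8, seed=9)
        matrix, _ = simulate_binary_characters(
            tree, SynthConfig(n_leaves=8, n_characters=50, mode="clean", seed=10)
        )
        trees, score = rp.parsimony_search(matrix, SearchConfig(seed=0))
        assert score == 50
        for t in trees:
            assert rp.branch_percent_identity(t, tree) == 100.0

    def test_score_equals_exhaustive_minimum_for_six_taxa(self, rng):
        labels = [f"t{i}" for i in range(6)]
        cols = [{lab: int(rng.integers(2)) for lab in labels} for _ in range(8)]
        m = _matrix_from_states(labels, cols)
        exhaustive = min(
            rp.parsimony_score(rp.parse_newick(nwk), m)
            for nwk in all_unrooted_newicks(labels)
        )
        _, score = rp.parsimony_search(m, SearchConfig(seed=1))
        assert score == exhaustive

    def test_deterministic_under_fixed_seed(self, rng):
        labels = [f"t{i}" for i in range(7)]
        cols = [{lab: int(rng.integers(2)) for lab in labels} for _ in range(12)]
        m = _matrix_from_states(labels, cols)
        t1, s1 = rp.parsimony_search(m, SearchConfig(seed=42))
        t2, s2 = rp.parsimony_search(m, SearchConfig(seed=42))
        assert s1 == s2
        assert [rp.write_newick(t) for t in t1] == [rp.write_newick(t) for t in t2]

    def test_spr_rearrangement_not_worse_than_nni(self, rng):
        labels = [f"t{i}" for i in range(7)]
        cols = [{lab: int(rng.integers(2)) for lab in labels} for _ in range(12)]
        m = _matrix_from_states(labels, cols)
        _, s_nni = rp.parsimony_search(m, SearchConfig(seed=3, rearrangement="nni"))
        _, s_spr = rp.parsimony_search(m, SearchConfig(seed=3, rearrangement="spr"))
        assert s_spr <= s_nni

    def test_score_at_least_number_of_informative_characters(self):
        tree = simulate_tree(8, seed=21)
        matrix, _ = simulate_binary_characters(
            tree, SynthConfig(n_leaves=8, n_characters=40, mode="random", seed=22)
        )
        informative = rp.informative_characters(matrix)
        _, score = rp.parsimony_search(matrix, SearchConfig(seed=2))
        assert score >= len(informative)
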