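import numpy as np
import pytest

from conftest import random_coded
from oracles import brute_tree_length

from partstree import trees as T
from partstree.matrix import CodedMatrix
from partstree.parsimony import (branch_and_bound_search, exhaustive_search,
                                 farris_bound, heuristic_search,
                                 hypothetical_ancestor, lundberg_root,
                                 n_topologies, tree_length, _all_topologies,
                                 _farris)
from partstree.trees import UnrootedTree


def coded(states, n_states=8) -> CodedMatrix:
    states = np.asarray(states)
    return CodedMatrix(part_ids=[f"t{i}" for i in range(states.shape[0])],
                       proteome_ids=[f"c{j}" for j in range(states.shape[1])],
                       states=states, alphabet_size=n_states)


class TestTreeLength:
    def test_worked_quartet(self, quartet_matrix):
        trees = exhaustive_search(quartet_matrix)
        assert trees[0].length == 6
        # the minimal topology pairs the state-adjacent taxa: AB | CD
        split_names = {frozenset(quartet_matrix.part_ids[i] for i in side)
                       for side in trees[0].splits() if len(side) == 2}
        assert frozenset("AB") in split_names or frozenset("CD") in split_names

    def test_constant_character_zero_length(self):
        c = coded([[3], [3], [3], [3]])
        for tree in exhaustive_search(c):
            assert tree.length == 0

    def test_farris_bound_met_with_equality_on_quartet(self, quartet_matrix):
        assert exhaustive_search(quartet_matrix)[0].length == \
            farris_bound(quartet_matrix)

    def test_sankoff_and_farris_agree_with_brute_force(self):
        rng = np.random.default_rng(42)
        for n_taxa in (4, 5, 6):
            for _ in range(5):
                c = random_coded(rng, n_taxa, 2, 7)
                topo_iter = _all_topologies(n_taxa)
                for k, adj in enumerate(topo_iter):
                    if k >= 6:
                        break
                    tree = UnrootedTree(adj=adj, taxa=list(c.part_ids))
                    lf = tree_length(tree, c, "farris")
                    ls = tree_length(tree, c, "sankoff")
                    lb = brute_tree_length(adj, c.states)
                    assert lf == ls == lb

    def test_leaf_taxon_mismatch_rejected(self, quartet_matrix):
        tree = exhaustive_search(quartet_matrix)[0]
        other = coded([[0], [1], [2], [3]])
        with pytest.raises(ValueError, match="leaf set"):
            tree_length(tree, other)

    def test_label_invariance(self):
        rng = np.random.default_rng(7)
        c = random_coded(rng, 6, 3, 5)
        base = exhaustive_search(c)[0].length
        perm = rng.permutation(6)
        c2 = CodedMatrix(part_ids=[c.part_ids[i] for i in perm],
                         proteome_ids=c.proteome_ids,
                         states=c.states[perm], alphabet_size=c.alphabet_size)
        assert exhaustive_search(c2)[0].length == base


class TestSearches:
    def test_four_taxa_enumerates_three_topologies(self):
        assert n_topologies(4) == 3
        assert len(list(_all_topologies(4))) == 3
        assert len(list(_all_topologies(6))) == n_topologies(6) == 105

    def test_three_taxa_single_topology_at_farris_bound(self):
        c = coded([[0, 1], [2, 3], [5, 0]])
        trees = exhaustive_search(c)
        assert len(trees) == 1
        assert trees[0].length == farris_bound(c)

    def test_exhaustive_refuses_large_inputs(self):
        rng = np.random.default_rng(0)
        c = random_coded(rng, 10, 2, 4)
        with pytest.raises(ValueError, match="branch_and_bound"):
            exhaustive_search(c)

    def test_branch_and_bound_equals_exhaustive(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            c = random_coded(rng, 6, 3, 6)
            ex = {t.splits() for t in exhaustive_search(c)}
            bb = {t.splits() for t in branch_and_bound_search(c)}
            assert ex == bb

    def test_branch_and_bound_taxon_order_invariant(self):
        rng = np.random.default_rng(11)
        c = random_coded(rng, 6, 3, 6)
        base = {t.canonical_newick() for t in branch_and_bound_search(c)}
        perm = rng.permutation(6)
        c2 = CodedMatrix(part_ids=[c.part_ids[i] for i in perm],
                         proteome_ids=c.proteome_ids,
                         states=c.states[perm], alphabet_size=c.alphabet_size)
        assert {t.canonical_newick()
                for t in branch_and_bound_search(c2)} == base

    def test_heuristic_never_beats_and_usually_matches_exhaustive(self):
        rng = np.random.default_rng(5)
        matched = 0
        for _ in range(20):
            c = random_coded(rng, 6, 3, 6)
            opt = exhaustive_search(c)[0].length
            found = heuristic_search(c, n_starts=5, seed=1).length
            assert found >= opt
            matched += found == opt
        assert matched >= 19  # matches the optimum on >= 95% of instances

    def test_heuristic_reproducible(self):
        rng = np.random.default_rng(9)
        c = random_coded(rng, 8, 4, 6)
        t1 = heuristic_search(c, n_starts=1, seed=123)
        t2 = heuristic_search(c, n_starts=1, seed=123)
        assert t1.splits() == t2.splits() and t1.length == t2.length

    def test_duplicate_taxon_leaves_length_unchanged(self):
        rng = np.random.default_rng(13)
        c = random_coded(rng, 5, 3, 6)
        dup = CodedMatrix(part_ids=c.part_ids + ["t0_copy"],
                          proteome_ids=c.proteome_ids,
                          states=np.vstack([c.states, c.states[0]]),
                          alphabet_size=c.alphabet_size)
        assert exhaustive_search(dup)[0].length == \
            exhaustive_search(c)[0].length


class TestLundbergRooting:
    def test_worked_quartet_roots_on_max_state_leaf(self, quartet_matrix):
        tree = exhaustive_search(quartet_matrix)[0]
        anc = hypothetical_ancestor(quartet_matrix, "max")
        assert anc.tolist() == [6]
        rooted = lundberg_root(tree, quartet_matrix, anc)
        assert rooted.length == tree.length  # increase 0 on D's branch
        assert rooted.root_branch.startswith("D|")

    def test_ancestor_equal_to_leaf_gives_zero_increase(self):
        c = coded([[1, 4], [3, 0], [5, 2], [2, 2]])
        tree = exhaustive_search(c)[0]
        rooted = lundberg_root(tree, c, ancestor=c.states[2])
        assert rooted.length == tree.length

    def test_rooted_length_conserved_and_nonnegative_increase(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            c = random_coded(rng, 6, 3, 6)
            tree = exhaustive_search(c)[0]
            rooted = lundberg_root(tree, c)
            increase = rooted.length - tree.length
            assert increase >= 0
            # the increase is minimal: check against every branch by brute force
            anc = hypothetical_ancestor(c, "max")
            ext = np.vstack([c.states, anc])
            best = None
            top = max(tree.adj) + 1
            off = top - 6
            shifted = {k + off if k >= 6 else k:
                       [v + off if v >= 6 else v for v in vs]
                       for k, vs in tree.adj.items()}
            for u, v in T.edges(tree.adj):
                su = u + off if u >= 6 else u
                sv = v + off if v >= 6 else v
                cand = T.add_leaf_on_edge(shifted, (su, sv), 6,
                                          max(shifted) + 1)
                inc = brute_tree_length(cand, ext) - tree.length
                best = inc if best is None else min(best, inc)
            assert increase == best

    def test_constant_matrix_ties_break_lexicographically(self):
        c = coded([[2], [2], [2], [2]])
        tree = exhaustive_search(c)[0]
        rooted = lundberg_root(tree, c)
        labels = sorted(T.branch_label(tree.adj, edge, 4, tree.taxa)
                        for edge in T.edges(tree.adj))
        assert rooted.root_branch == labels[0]

    def test_missing_ancestor_states_rejected(self, quartet_matrix):
        tree = exhaustive_search(quartet_matrix)[0]
        with pytest.raises(ValueError, match="ancestor"):
            lundberg_root(tree, quartet_matrix, ancestor=np.array([1, 2]))
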