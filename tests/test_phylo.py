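"""Squared-change parsimony, signal permutation test, Steiner homoplasy."""

import numpy as np
import pytest
from scipy.optimize import minimize

import sciurmorph as sm
from sciurmorph.phylo import (
    enumerate_unrooted_topologies,
    optimized_tree_length,
    star_tree_length,
)
from sciurmorph.simulate import yule_topology


def random_tip_shapes(rng, labels, d=2, scale=1.0):
    return {t: scale * rng.normal(size=d) for t in labels}


class TestReconstruction:
    def test_three_tip_star_worked_example(self):
        tree = sm.PhylogeneticTree.from_newick("(A,B,C);")
        anc = sm.reconstruct_ancestral_shapes(
            tree, {"A": [0.0], "B": [0.0], "C": [3.0]}
        )
        assert anc.states[-1, 0] == pytest.approx(1.0)
        assert anc.tree_length == pytest.approx(6.0)

    def test_four_tip_worked_example(self):
        tree = sm.PhylogeneticTree.from_newick("((A,B),(C,D));")
        anc = sm.reconstruct_ancestral_shapes(
            tree, {"A": [0.0], "B": [0.0], "C": [6.0], "D": [6.0]}
        )
        internals = np.sort(anc.states[4:, 0])
        np.testing.assert_allclose(internals, [1.0, 3.0, 5.0])
        assert anc.tree_length == pytest.approx(12.0)

    def test_identical_tips_collapse(self, rng):
        tree = sm.PhylogeneticTree.from_newick("((A,B),(C,(D,E)));")
        v = rng.normal(size=6)
        anc = sm.reconstruct_ancestral_shapes(tree, {t: v for t in "ABCDE"})
        np.testing.assert_allclose(anc.states - v, 0, atol=1e-12)
        assert anc.tree_length == pytest.approx(0.0, abs=1e-24)

    def test_linear_system_matches_numeric_minimizer(self, rng):
        """Independent oracle: direct minimization of the summed squared
        change over all internal-node coordinates, random 8-tip trees."""
        for trial in range(50):
            r = np.random.default_rng(5000 + trial)
            nwk = yule_topology(8, r)
            tree = sm.PhylogeneticTree.from_newick(nwk)
            tips = random_tip_shapes(r, tree.tip_labels, d=2)
            anc = sm.reconstruct_ancestral_shapes(tree, tips)

            tip_index, edges, n_nodes = tree.adjacency()
            V = np.stack([np.asarray(tips[t]) for t in
                          sorted(tip_index, key=tip_index.get)])
            n_int = n_nodes - len(tip_index)

            def objective(flat):
                states = np.vstack([V, flat.reshape(n_int, 2)])
                diffs = states[[u for u, _ in edges]] - states[[v for _, v in edges]]
                return float((diffs**2).sum())

            x0 = np.tile(V.mean(axis=0), n_int)
            res = minimize(objective, x0, method="L-BFGS-B",
                           options={"ftol": 1e-15, "gtol": 1e-12})
            assert anc.tree_length == pytest.approx(res.fun, abs=1e-8)

    def test_rerooting_preserves_unrooted_length(self, rng):
        """The minimized squared change of the unrooted topology is invariant
        to where the tree is rooted (unit branch lengths)."""

        def unrooted_length(tree, tips):
            tip_index, edges, n_nodes = tree.adjacency(suppress_degree_two=True)
            V = np.stack(
                [np.asarray(tips[t]) for t in sorted(tip_index, key=tip_index.get)]
            )
            return optimized_tree_length(edges, n_nodes, V)

        for trial in range(5):
            r = np.random.default_rng(600 + trial)
            tree = sm.PhylogeneticTree.from_newick(yule_topology(7, r))
            tips = random_tip_shapes(r, tree.tip_labels, d=3)
            base = unrooted_length(tree, tips)
            internal_nodes = [
                nd for nd in tree.dtree.preorder_node_iter() if not nd.is_leaf()
            ]
            for nd in internal_nodes[1:]:
                clone = sm.PhylogeneticTree.from_newick(tree.as_newick())
                # find the matching node in the clone by its tip set
                target_tips = {l.taxon.label for l in nd.leaf_iter()}
                match = next(
                    c for c in clone.dtree.preorder_node_iter()
                    if not c.is_leaf()
                    and {l.taxon.label for l in c.leaf_iter()} == target_tips
                )
                clone.dtree.reroot_at_node(match, update_bipartitions=False)
                clone2 = sm.PhylogeneticTree(clone.dtree)  # re-unit lengths
                assert unrooted_length(clone2, tips) == pytest.approx(
                    base, abs=1e-10
                )

    def test_polytomies_handled(self, rng):
        tree = sm.PhylogeneticTree.from_newick("(A,B,C,D,(E,F));")
        tips = random_tip_shapes(rng, list("ABCDEF"))
        anc = sm.reconstruct_ancestral_shapes(tree, tips)
        assert anc.tree_length > 0
        assert anc.states.shape[0] == 8  # 6 tips + 2 internal


class TestSignalTest:
    def test_identical_shapes_give_p_one(self, rng):
        tree = sm.PhylogeneticTree.from_newick("((A,B),(C,D),E);")
        v = rng.normal(size=4)
        sig = sm.permutation_signal_test(
            tree, {t: v for t in "ABCDE"}, n_perm=99, seed=0
        )
        assert sig.p_value == 1.0

    def test_two_separated_clades_reach_minimal_p(self):
        """Clade means far apart: the observed assignment minimizes tree
        length over (almost) all permutations."""
        nwk = "((a1,(a2,(a3,(a4,a5)))),(b1,(b2,(b3,(b4,b5)))));"
        tree = sm.PhylogeneticTree.from_newick(nwk)
        tips = {}
        for i in range(1, 6):
            tips[f"a{i}"] = np.zeros(2)  # tied within clades: observed is the
            tips[f"b{i}"] = np.full(2, 100.0)  # global optimum, ties included
        sig = sm.permutation_signal_test(tree, tips, n_perm=499, seed=1)
        # only partition-preserving permutations tie the observed length
        # (probability 2*(5!)^2/10! per draw), so p stays near its floor
        assert sig.p_value < 0.05
        assert (sig.permuted_lengths >= sig.observed_length - 1e-9).all()

    def test_observed_is_global_optimum_by_enumeration(self):
        """At 6 tips every relabeling can be enumerated: the two-clade
        arrangement attains the smallest tree length of all 6! assignments."""
        from itertools import permutations

        nwk = "((a1,(a2,a3)),(b1,(b2,b3)));"
        tree = sm.PhylogeneticTree.from_newick(nwk)
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        values = np.array([0.0, 0.0, 0.0, 50.0, 50.0, 50.0])
        observed = sm.reconstruct_ancestral_shapes(
            tree, {t: [values[i]] for i, t in enumerate(labels)}
        ).tree_length
        lengths = [
            sm.reconstruct_ancestral_shapes(
                tree, {t: [values[p[i]]] for i, t in enumerate(labels)}
            ).tree_length
            for p in permutations(range(6))
        ]
        assert observed == pytest.approx(min(lengths), abs=1e-12)

    def test_p_invariant_under_common_rotation(self, rng):
        tree = sm.PhylogeneticTree.from_newick(yule_topology(8, rng))
        tips = random_tip_shapes(rng, tree.tip_labels, d=4)
        # rotate all tip vectors by a common orthogonal matrix
        M = np.linalg.qr(rng.normal(size=(4, 4)))[0]
        rotated = {t: M @ v for t, v in tips.items()}
        s1 = sm.permutation_signal_test(tree, tips, n_perm=199, seed=9)
        s2 = sm.permutation_signal_test(tree, rotated, n_perm=199, seed=9)
        assert s1.p_value == s2.p_value
        assert s1.observed_length == pytest.approx(s2.observed_length, rel=1e-10)

    def test_too_few_tips_rejected(self, rng):
        tree = sm.PhylogeneticTree.from_newick("(A,B,C);")
        with pytest.raises(ValueError):
            sm.permutation_signal_test(
                tree, random_tip_shapes(rng, "ABC"), n_perm=99, seed=0
            )


class TestHomoplasy:
    def test_topology_count(self):
        assert sum(1 for _ in enumerate_unrooted_topologies(5)) == 15
        assert sum(1 for _ in enumerate_unrooted_topologies(6)) == 105

    def test_optimal_observed_tree_gives_unit_indices(self):
        """Two tight clades: the matching topology is Steiner-minimal, so
        SCI = SRI = 1."""
        tree = sm.PhylogeneticTree.from_newick("((a1,a2),(b1,b2),(c1,c2));")
        rng = np.random.default_rng(4)
        tips = {}
        for grp, offset in (("a", [0, 0]), ("b", [50, 0]), ("c", [0, 50])):
            for i in (1, 2):
                tips[f"{grp}{i}"] = np.asarray(offset) + rng.normal(0, 1e-3, 2)
        h = sm.homoplasy_indices(tree, tips)
        assert h.sci == pytest.approx(1.0, abs=1e-6)
        assert h.sri == pytest.approx(1.0, abs=1e-6)

    def test_star_worst_case_has_zero_sri(self, rng):
        """An observed star topology attains the maximal length, so SRI = 0."""
        tree = sm.PhylogeneticTree.from_newick("(A,B,C,D,E);")
        tips = random_tip_shapes(rng, "ABCDE", d=2)
        h = sm.homoplasy_indices(tree, tips)
        assert h.observed_length == pytest.approx(h.max_length, abs=1e-10)
        assert h.sri == pytest.approx(0.0, abs=1e-10)

    def test_enumeration_bounds_on_random_shapes(self, rng):
        """min <= optimized length <= star length over the full 6-tip
        enumeration (105 topologies)."""
        labels = list("ABCDEF")
        V = rng.normal(size=(6, 2))
        star = star_tree_length(V)
        lengths = [
            optimized_tree_length(edges, n_nodes, V)
            for edges, n_nodes in enumerate_unrooted_topologies(6)
        ]
        best = min(lengths)
        assert all(best - 1e-10 <= L <= star + 1e-10 for L in lengths)
        # homoplasy_indices agrees with the direct enumeration
        tree = sm.PhylogeneticTree.from_newick("((A,B),((C,D),(E,F)));")
        h = sm.homoplasy_indices(tree, {l: V[i] for i, l in enumerate(labels)})
        assert h.min_length == pytest.approx(best, abs=1e-10)
        assert h.max_length == pytest.approx(star, abs=1e-12)
        assert h.min_length - 1e-10 <= h.observed_length <= h.max_length + 1e-10

    def test_cap_enforced_and_heuristic_escape(self, rng):
        tree = sm.PhylogeneticTree.from_newick(yule_topology(9, rng))
        tips = random_tip_shapes(rng, tree.tip_labels, d=2)
        with pytest.raises(ValueError, match="heuristic"):
            sm.homoplasy_indices(tree, tips, max_taxa_exhaustive=7)
        h = sm.homoplasy_indices(
            tree, tips, max_taxa_exhaustive=7, heuristic=True
        )
        assert not h.exact
        assert h.min_length <= h.observed_length + 1e-10

    def test_degenerate_identical_tips_flagged(self):
        tree = sm.PhylogeneticTree.from_newick("((A,B),(C,D));")
        h = sm.homoplasy_indices(tree, {t: [1.0, 2.0] for t in "ABCD"})
        assert h.degenerate
        assert np.isnan(h.sci) and np.isnan(h.sri)
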