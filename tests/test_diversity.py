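"""Trait distances, UPGMA, FD/PD and originality against independent oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

import coextdiv as cd
from coextdiv.diversity import _qe_weights
from coextdiv.errors import IncomputableDistanceError, InvalidArgumentError
from coextdiv.trees import TreeIndex, is_ultrametric

from _oracles import brute_fd, brute_pd, grid_qe_argmax


def _traits(rows):
    frame = pd.DataFrame(rows, columns=["species", "sla", "height", "seed_mass"])
    return frame.set_index("species")


class TestTraitDistances:
    def test_identical_vectors_zero(self):
        t = _traits([("A", 1, 2, 3), ("B", 1, 2, 3)])
        d = cd.trait_distance_matrix(t, standardize=False)
        assert d["A", "B"] == 0.0

    def test_plain_euclidean(self):
        t = _traits([("A", 1, 1, 1), ("B", 2, 3, 3)])
        d = cd.trait_distance_matrix(t, standardize=False)
        assert d["A", "B"] == pytest.approx(3.0)  # sqrt(1+4+4)

    def test_shared_trait_rescaling_preserves_zero(self):
        t = _traits([("A", 1, 2, None), ("B", 1, 2, 5)])
        d = cd.trait_distance_matrix(t, standardize=False)
        assert d["A", "B"] == 0.0

    def test_shared_trait_rescaling_factor(self):
        # one shared trait differing by 2 -> distance 2*sqrt(3/1)
        t = _traits([("A", 1, None, 4), ("B", 3, 2, None)])
        d = cd.trait_distance_matrix(t, standardize=False)
        assert d["A", "B"] == pytest.approx(2 * np.sqrt(3))

    def test_no_shared_trait_rejected(self):
        t = _traits([("A", 1, None, None), ("B", None, 2, 5)])
        with pytest.raises(IncomputableDistanceError, match="A.*B"):
            cd.trait_distance_matrix(t, standardize=False)

    def test_log_transform(self):
        t = _traits([("A", 10, 1, 1), ("B", 1000, 1, 1)])
        d = cd.trait_distance_matrix(t, standardize=False,
                                     log_transform=("sla",))
        assert d["A", "B"] == pytest.approx(2.0)  # log10 difference


class TestUpgma:
    def test_two_species(self):
        d = DistanceMatrix([[0, 4], [4, 0]], ids=["A", "B"])
        tree = cd.upgma(d)
        lengths = sorted(lf.edge.length for lf in tree.leaf_nodes())
        assert lengths == [2.0, 2.0]

    def test_worked_example(self, worked_tree):
        index = TreeIndex(worked_tree)
        coph = index.cophenetic()
        assert coph["A", "B"] == pytest.approx(2.0)
        assert coph["A", "C"] == pytest.approx(6.0)
        from coextdiv.trees import total_branch_length

        assert total_branch_length(worked_tree) == pytest.approx(7.0)

    def test_cophenetic_fixed_point_on_ultrametric_input(self, worked_dm):
        tree = cd.upgma(worked_dm)
        coph = TreeIndex(tree).cophenetic()
        np.testing.assert_allclose(np.asarray(coph.data),
                                   np.asarray(worked_dm.data), atol=1e-12)

    def test_matches_scipy_average_linkage_heights(self):
        """Cophenetic distances agree with scipy's average-linkage
        clustering on a generic (tie-free) matrix."""
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 3))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(7)]
        tree = cd.upgma(DistanceMatrix(dist, ids=ids))
        mine = TreeIndex(tree).cophenetic().filter(ids)
        scipy_coph = squareform(cophenet(average(squareform(dist))))
        np.testing.assert_allclose(np.asarray(mine.data), scipy_coph, atol=1e-9)

    def test_output_is_ultrametric(self, small_bundle):
        d = cd.trait_distance_matrix(small_bundle.traits)
        tree = cd.upgma(d)
        assert is_ultrametric(tree, rel_tol=1e-9)

    def test_tie_break_deterministic(self):
        # equidistant species: merges must follow lexicographic label order
        d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("DCBA"))
        t1 = cd.upgma(d)
        t2 = cd.upgma(DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("ABCD")))
        s1 = t1.as_string(schema="newick", suppress_rooting=True)
        s2 = t2.as_string(schema="newick", suppress_rooting=True)
        assert s1 == s2


class TestFdPd:
    def test_worked_values(self, worked_tree):
        assert cd.fd(worked_tree, ["A"]) == 0.0
        assert cd.fd(worked_tree, ["A", "B"]) == pytest.approx(2.0)
        assert cd.fd(worked_tree, ["A", "C"]) == pytest.approx(6.0)
        assert cd.fd(worked_tree, ["A", "B", "C"]) == pytest.approx(7.0)
        assert cd.pd(worked_tree, ["A"]) == pytest.approx(3.0)
        assert cd.pd(worked_tree, ["A", "B"]) == pytest.approx(4.0)
        assert cd.pd(worked_tree, ["A", "B", "C"]) == pytest.approx(7.0)

    def test_empty_set(self, worked_tree):
        assert cd.fd(worked_tree, []) == 0.0
        assert cd.pd(worked_tree, []) == 0.0

    def test_unknown_label_rejected(self, worked_tree):
        with pytest.raises(InvalidArgumentError):
            cd.fd(worked_tree, ["Z"])

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(17)
        for seed in range(10):
            tree = cd.simulate_phylogeny(8, 1.0, seed=seed)
            index = TreeIndex(tree)
            labels = index.labels
            for _ in range(10):
                k = int(rng.integers(1, 9))
                extant = list(rng.choice(labels, size=k, replace=False))
                assert index.fd(extant) == pytest.approx(
                    brute_fd(tree, extant), abs=1e-9)
                assert index.pd(extant) == pytest.approx(
                    brute_pd(tree, extant), abs=1e-9)

    def test_matches_skbio_faith_pd(self):
        """Root-inclusive PD cross-checked against scikit-bio's Faith PD."""
        from io import StringIO

        from skbio import TreeNode
        from skbio.diversity.alpha import faith_pd

        tree = cd.simulate_phylogeny(12, 1.0, seed=3)
        index = TreeIndex(tree)
        newick = tree.as_string(schema="newick", suppress_rooting=True)
        sk_tree = TreeNode.read(StringIO(newick))
        rng = np.random.default_rng(4)
        for _ in range(5):
            extant = list(rng.choice(index.labels, size=5, replace=False))
            counts = [1 if lab in extant else 0 for lab in index.labels]
            expected = faith_pd(counts, index.labels, sk_tree)
            assert index.pd(extant) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 8 - 1), st.integers(0, 2 ** 8 - 1))
    def test_monotone_in_extant_set(self, bits_a, bits_b):
        """Adding species never decreases FD or PD."""
        tree = cd.simulate_phylogeny(8, 1.0, seed=23)
        index = TreeIndex(tree)
        small = [lab for i, lab in enumerate(index.labels)
                 if bits_a & bits_b & (1 << i)]
        big = [lab for i, lab in enumerate(index.labels) if bits_a & (1 << i)]
        assert index.fd(small) <= index.fd(set(small) | set(big)) + 1e-12
        assert index.pd(small) <= index.pd(set(small) | set(big)) + 1e-12


class TestOriginality:
    def test_star_tree_uniform(self):
        import dendropy

        tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1,E:1);", schema="newick")
        orig = cd.originality(tree)
        np.testing.assert_allclose(orig.to_numpy(), 0.2, atol=1e-9)

    def test_sums_to_one(self, small_bundle):
        orig = cd.originality(small_bundle.tree)
        assert orig.sum() == pytest.approx(1.0, abs=1e-9)
        assert (orig >= -1e-12).all()

    def test_worked_tree_matches_grid_search(self, worked_tree):
        orig = cd.originality(worked_tree)
        delta = np.asarray(TreeIndex(worked_tree).cophenetic().data)
        grid = grid_qe_argmax(delta, step=1e-3)
        labels = TreeIndex(worked_tree).labels
        np.testing.assert_allclose(orig.reindex(labels).to_numpy(), grid,
                                   atol=2e-3)

    def test_branch_scale_invariance(self, small_bundle):
        tree = small_bundle.tree
        orig1 = cd.originality(tree)
        scaled = cd.prune_tree(tree, [lf.taxon.label
                                      for lf in tree.leaf_node_iter()])
        for edge in scaled.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 7.5
        orig2 = cd.originality(scaled)
        np.testing.assert_allclose(orig1.sort_index().to_numpy(),
                                   orig2.sort_index().to_numpy(), atol=1e-8)

    def test_leaf_order_permutation_invariance(self, worked_dm):
        tree = cd.upgma(worked_dm)
        perm_dm = worked_dm.filter(["C", "A", "B"])
        tree_perm = cd.upgma(perm_dm)
        a = cd.originality(tree).sort_index()
        b = cd.originality(tree_perm).sort_index()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_qe_weights_on_two_clusters(self):
        # two tight pairs far apart: weight concentrates evenly by symmetry
        delta = np.array([[0, 1, 8, 8], [1, 0, 8, 8],
                          [8, 8, 0, 1], [8, 8, 1, 0]], dtype=float)
        w = _qe_weights(delta)
        np.testing.assert_allclose(w, 0.25, atol=1e-9)


class TestTotalOriginality:
    def test_complement_and_bounds(self, worked_tree):
        orig = cd.originality(worked_tree)
        assert cd.total_originality(orig, orig.index) == pytest.approx(1.0)
        assert cd.total_originality(orig, []) == 0.0
        top = orig.idxmax()
        rest = [x for x in orig.index if x != top]
        assert cd.total_originality(orig, rest) == \
            pytest.approx(1.0 - orig[top], abs=1e-9)
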