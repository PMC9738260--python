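"""Minkowski distances, Ward agglomeration, tree cutting and Newick export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from epletclust.clustering import (
    ClusteringError,
    Dendrogram,
    DistanceMatrix,
    antigen_features,
    cut_tree,
    minkowski_distances,
    to_newick,
    ward_linkage,
)
from epletclust.panel import standardize

from conftest import random_mfi, ward_oracle


def _features(rows, labels):
    return pd.DataFrame(rows, index=labels)


class TestFeatures:
    def test_transpose_orientation(self):
        rng = np.random.default_rng(0)
        s = standardize(random_mfi(rng, 3, 2))
        f = antigen_features(s)
        assert f.shape == (2, 3)
        assert list(f.index) == list(s.data.columns)
        assert np.array_equal(f.to_numpy(), s.data.to_numpy().T)
        assert f.T.equals(s.data)  # involution


class TestMinkowski:
    @pytest.mark.parametrize(("p", "expected"), [(2.0, 5.0), (1.0, 7.0)])
    def test_three_four_five(self, p, expected):
        f = _features([[0.0, 0.0], [3.0, 4.0]], ["a", "b"])
        dm = minkowski_distances(f, p=p)
        assert dm.d[0, 1] == pytest.approx(expected)

    def test_direct_formula_oracle_p3(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 4))
        dm = minkowski_distances(_features(X, list("abcde")), p=3.0)
        for i in range(5):
            for j in range(5):
                expected = (np.abs(X[i] - X[j]) ** 3).sum() ** (1 / 3)
                assert dm.d[i, j] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_p2_equals_euclidean(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(int(rng.integers(2, 8)), int(rng.integers(1, 6))))
        labels = [f"L{i}" for i in range(len(X))]
        dm = minkowski_distances(_features(X, labels), p=2.0)
        euclid = squareform(pdist(X))
        assert np.abs(dm.d - euclid).max() <= 1e-12

    def test_p_below_one_rejected(self):
        with pytest.raises(ClusteringError, match=">= 1"):
            minkowski_distances(_features([[0.0], [1.0]], ["a", "b"]), p=0.5)


class TestWard:
    def test_two_leaves_merge_at_their_distance(self):
        dm = DistanceMatrix(labels=["A", "B"], d=np.array([[0.0, 5.0], [5.0, 0.0]]), p=2)
        t = ward_linkage(dm)
        assert t.merges == [(0, 1, 5.0, 2)]

    def test_unique_minimum_pair_merges_first(self):
        x = np.array([[0.0], [1.0], [10.0]])
        dm = minkowski_distances(_features(x, ["L0", "L1", "L10"]), p=2.0)
        t = ward_linkage(dm)
        first = t.merges[0]
        assert {first[0], first[1]} == {0, 1}
        assert first[2] == pytest.approx(1.0)

    def test_matches_naive_oracle(self):
        """LW-recursion agglomeration equals the from-scratch Ward objective."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(3, 8))
            X = rng.normal(size=(n, 3))
            dm = minkowski_distances(
                _features(X, [f"L{i}" for i in range(n)]), p=2.0
            )
            mine = ward_linkage(dm).merges
            expected = ward_oracle(dm.d)
            for (a1, b1, h1, s1), (a2, b2, h2, s2) in zip(mine, expected):
                assert {a1, b1} == {a2, b2}
                assert h1 == pytest.approx(h2, abs=1e-8)
                assert s1 == s2

    def test_matches_scipy_heights(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(23)
        X = rng.normal(size=(9, 4))
        dm = minkowski_distances(_features(X, [f"L{i}" for i in range(9)]), p=2.0)
        mine = sorted(h for _, _, h, _ in ward_linkage(dm).merges)
        theirs = sorted(linkage(squareform(dm.d), method="ward")[:, 2])
        assert np.allclose(mine, theirs, atol=1e-8)

    def test_heights_monotone(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            X = rng.normal(size=(int(rng.integers(3, 12)), 3))
            dm = minkowski_distances(
                _features(X, [f"L{i}" for i in range(len(X))]),
                p=float(rng.choice([1.0, 2.0, 3.0])),
            )
            heights = [h for _, _, h, _ in ward_linkage(dm).merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_leaf_relabeling_preserves_structure(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(6, 3))
        labels = [f"L{i}" for i in range(6)]
        dm = minkowski_distances(_features(X, labels), p=2.0)
        t1 = ward_linkage(dm)
        renamed = [f"Z{i}" for i in range(6)]
        t2 = ward_linkage(minkowski_distances(_features(X, renamed), p=2.0))
        assert [(a, b, s) for a, b, _, s in t1.merges] == [
            (a, b, s) for a, b, _, s in t2.merges
        ]
        assert np.allclose(
            [h for _, _, h, _ in t1.merges], [h for _, _, h, _ in t2.merges]
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ClusteringError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [2.0, 0.0]]), p=2)


class TestCutTree:
    @pytest.fixture
    def chain_tree(self):
        x = np.array([[0.0], [1.0], [10.0]])
        dm = minkowski_distances(_features(x, ["L0", "L1", "L10"]), p=2.0)
        return ward_linkage(dm)

    def test_extremes(self, chain_tree):
        singletons = cut_tree(chain_tree, 3)
        assert sorted(singletons.assignment.values()) == [1, 2, 3]
        everything = cut_tree(chain_tree, 1)
        assert set(everything.assignment.values()) == {1}

    def test_two_groups_split_outlier(self, chain_tree):
        cut = cut_tree(chain_tree, 2)
        assert cut.assignment["L0"] == cut.assignment["L1"]
        assert cut.assignment["L10"] != cut.assignment["L0"]

    def test_out_of_range(self, chain_tree):
        with pytest.raises(ClusteringError):
            cut_tree(chain_tree, 0)
        with pytest.raises(ClusteringError):
            cut_tree(chain_tree, 4)


class TestNewick:
    def test_two_leaf_convention(self):
        t = Dendrogram(merges=[(0, 1, 5.0, 2)], labels=["A", "B"])
        assert to_newick(t) == "(A:5.0,B:5.0);"

    def test_chain_example_branch_lengths(self):
        x = np.array([[0.0], [1.0], [10.0]])
        dm = minkowski_distances(_features(x, ["L0", "L1", "L10"]), p=2.0)
        t = ward_linkage(dm)
        h = t.merges[1][2]  # second merge height from the oracle-checked agglomerator
        assert to_newick(t) == f"((L0:1.0,L1:1.0):{h - 1.0!r},L10:{h!r});"

    def test_round_trip_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(37)
        X = rng.normal(size=(7, 3))
        labels = [f"DRB1*0{i + 1}:01" for i in range(7)]  # labels need quoting
        dm = minkowski_distances(_features(X, labels), p=2.0)
        t = ward_linkage(dm)
        tree = dendropy.Tree.get(data=to_newick(t), schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(labels)
        root_height = t.merges[-1][2]
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_height, abs=1e-9)
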