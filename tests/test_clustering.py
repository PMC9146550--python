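"""Jaccard distances, hierarchical trees, silhouette/WSS selection, biclustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from coexmix.catalog import build_presence_matrix, map_keywords
from coexmix.clustering import (
    DistanceMatrix,
    assign_clusters,
    average_silhouette,
    biclustered_layout,
    collapse_duplicates,
    cut_at_k,
    hclust_tree,
    jaccard_distance,
    select_k,
    wss,
)
from coexmix.simulate import gen_presence


def _random_binary(n, p, ncol=8, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=(n, ncol))
    x[:, 0] = 1  # no all-zero vectors
    return pd.DataFrame(x, index=[f"r{i:02d}" for i in range(n)],
                        columns=[f"c{j}" for j in range(ncol)])


def brute_jaccard(u, v):
    a = {i for i, x in enumerate(u) if x}
    b = {i for i, x in enumerate(v) if x}
    return 1.0 - len(a & b) / len(a | b)


def brute_silhouette(d, labels):
    """Definitional per-point silhouette, independent of the vectorized path."""
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def brute_wss(d, labels):
    total = 0.0
    for c in set(labels):
        idx = [i for i, l in enumerate(labels) if l == c]
        total += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    return total


def naive_average_linkage_heights(d):
    """O(n^3) UPGMA agglomerator used as an independent merge-height oracle."""
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    nxt = d.shape[0]
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return np.array(heights)


class TestJaccardDistance:
    def test_identity_and_disjoint(self):
        m = pd.DataFrame([[1, 1, 0], [1, 1, 0], [0, 0, 1]],
                         index=list("abc"), columns=list("xyz"))
        d = jaccard_distance(m, "rows")
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_hand_computation(self):
        m = pd.DataFrame([[1, 1, 0, 1], [1, 0, 0, 1]], index=["A", "B"],
                         columns=list("wxyz"))
        d = jaccard_distance(m, "rows")
        assert d.values[0, 1] == pytest.approx(1 / 3, abs=1e-15)

    def test_brute_force_oracle(self):
        m = _random_binary(30, 0.5, seed=1)
        d = jaccard_distance(m, "rows")
        x = m.to_numpy()
        for i in range(30):
            for j in range(30):
                assert d.values[i, j] == pytest.approx(brute_jaccard(x[i], x[j]), abs=1e-12)

    def test_metric_axioms(self):
        m = _random_binary(20, 0.5, seed=2)
        d = jaccard_distance(m, "rows").values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_all_zero_vector_rejected(self):
        m = pd.DataFrame([[1, 1], [0, 0]], index=["a", "zero"], columns=["x", "y"])
        with pytest.raises(ValueError, match="zero"):
            jaccard_distance(m, "rows")

    def test_column_axis(self):
        m = pd.DataFrame([[1, 1], [1, 0]], index=["a", "b"], columns=["x", "y"])
        d = jaccard_distance(m, "columns")
        assert d.labels == ["x", "y"]
        assert d.values[0, 1] == pytest.approx(0.5)


class TestHclustTree:
    def test_two_points(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.3], [0.3, 0.0]]))
        tree = hclust_tree(d, "average")
        assert tree.merge_heights.tolist() == [0.3]

    def test_three_point_hand_agglomeration(self):
        d = DistanceMatrix(
            list("abc"),
            np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]]),
        )
        tree = hclust_tree(d, "average")
        assert tree.merge_heights.tolist() == pytest.approx([0.1, 0.9])

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.random((12, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"p{i}" for i in range(12)], d)
        tree = hclust_tree(dm, "average")
        assert tree.merge_heights == pytest.approx(naive_average_linkage_heights(d))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            hclust_tree(DistanceMatrix(["a"], np.zeros((1, 1))))

    def test_monotone_heights(self):
        m = _random_binary(15, 0.5, seed=4)
        tree = hclust_tree(jaccard_distance(m, "rows"), "average")
        assert (np.diff(tree.merge_heights) >= -1e-12).all()


class TestSilhouette:
    def _two_pairs(self):
        d = np.full((4, 4), 0.95)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.05
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list("abcd"), d)

    def test_tight_far_pairs(self):
        val = average_silhouette(self._two_pairs(), [1, 1, 2, 2])
        assert val == pytest.approx((0.95 - 0.05) / 0.95, abs=1e-12)
        assert val > 0.9

    def test_all_singletons_convention(self):
        assert average_silhouette(self._two_pairs(), [1, 2, 3, 4]) == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            average_silhouette(self._two_pairs(), [1, 1, 1, 1])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        m = _random_binary(20, 0.5, seed=5)
        d = jaccard_distance(m, "rows")
        for _ in range(10):
            labels = rng.integers(1, 5, size=20)
            if len(set(labels)) < 2:
                continue
            assert average_silhouette(d, labels) == pytest.approx(
                brute_silhouette(d.values, list(labels)), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        # independent library cross-check on a labeling with no singletons
        m = _random_binary(24, 0.5, seed=6)
        d = jaccard_distance(m, "rows")
        labels = np.repeat([1, 2, 3], 8)
        assert average_silhouette(d, labels) == pytest.approx(
            silhouette_score(d.values, labels, metric="precomputed"), abs=1e-12
        )


class TestWss:
    def test_singletons_zero(self):
        d = DistanceMatrix(list("ab"), np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert wss(d, [1, 2]) == 0.0

    def test_pair_hand_value(self):
        d = DistanceMatrix(list("ab"), np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert wss(d, [1, 1]) == pytest.approx(0.125, abs=1e-15)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        m = _random_binary(25, 0.5, seed=8)
        d = jaccard_distance(m, "rows")
        for _ in range(10):
            labels = rng.integers(1, 6, size=25)
            assert wss(d, labels) == pytest.approx(brute_wss(d.values, list(labels)),
                                                   abs=1e-12)

    def test_merging_never_decreases_euclidean_wss(self):
        rng = np.random.default_rng(10)
        pts = rng.random((30, 3))
        d = DistanceMatrix(
            [f"p{i}" for i in range(30)],
            np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)),
        )
        labels = rng.integers(1, 6, size=30)
        base = wss(d, labels)
        for a in range(1, 6):
            for b in range(a + 1, 6):
                merged = np.where(labels == b, a, labels)
                assert wss(d, merged) >= base - 1e-12


class TestSelectK:
    def test_kmax_two_single_entry(self):
        m = _random_binary(10, 0.5, seed=11)
        d = jaccard_distance(m, "rows")
        prof = select_k(d, hclust_tree(d), k_max=2)
        assert prof.selected_k == 2
        assert len(prof.silhouette) == 1
        assert prof.k_values[0] == 1  # WSS elbow profile still starts at k=1

    def test_selected_attains_max_silhouette(self):
        m = _random_binary(20, 0.5, seed=12)
        d = jaccard_distance(m, "rows")
        prof = select_k(d, hclust_tree(d), k_max=10)
        sil = dict(zip(prof.k_values[1:], prof.silhouette))
        assert sil[prof.selected_k] == max(prof.silhouette)

    def test_planted_three_blocks_recovered(self):
        recs, kmap, truth = gen_presence(seed=1)
        m = build_presence_matrix(map_keywords(recs, kmap))
        sol = assign_clusters(m)
        assert sol.n_row_clusters == 3
        assert sol.row_profile.selected_k <= 34


class TestAssignClusters:
    def test_planted_dual_recovery_low_noise(self):
        recs, kmap, truth = gen_presence(p_within=0.95, p_between=0.01, seed=2)
        m = build_presence_matrix(map_keywords(recs, kmap))
        sol = assign_clusters(m)
        assert sol.n_row_clusters == 3 and sol.n_col_clusters == 2
        rows = [sol.row_labels[str(c)] for c in m.index]
        true_rows = [truth.row_blocks[str(c)] for c in m.index]
        assert adjusted_rand_score(true_rows, rows) == 1.0
        cols = [sol.col_labels[str(c)] for c in m.columns]
        true_cols = [truth.col_blocks[str(c)] for c in m.columns]
        assert adjusted_rand_score(true_cols, cols) == 1.0

    def test_transpose_swaps_solutions(self):
        recs, kmap, _ = gen_presence(n_chemicals=30, seed=4)
        m = build_presence_matrix(map_keywords(recs, kmap))
        sol = assign_clusters(m)
        tsol = assign_clusters(m.T)
        assert tsol.row_labels == sol.col_labels
        assert tsol.col_labels == sol.row_labels
        assert tsol.row_leaf_order == sol.col_leaf_order

    def test_cluster_numbering_follows_leaf_order(self):
        recs, kmap, _ = gen_presence(n_chemicals=30, seed=5)
        m = build_presence_matrix(map_keywords(recs, kmap))
        sol = assign_clusters(m)
        seen = [sol.row_labels[lbl] for lbl in sol.row_leaf_order]
        firsts = list(dict.fromkeys(seen))
        assert firsts == sorted(firsts)  # 1, 2, 3, ... top to bottom


class TestBiclusteredLayout:
    def _setup(self):
        recs, kmap, _ = gen_presence(n_chemicals=20, seed=6)
        m = build_presence_matrix(map_keywords(recs, kmap))
        return m, assign_clusters(m)

    def test_cells_conserved(self):
        m, sol = self._setup()
        ordered, _, _ = biclustered_layout(m, sol)
        assert sorted(ordered.to_numpy().ravel()) == sorted(m.to_numpy().ravel())
        assert sorted(ordered.sum(axis=1)) == sorted(m.sum(axis=1))

    def test_round_trip(self):
        m, sol = self._setup()
        ordered, _, _ = biclustered_layout(m, sol)
        restored = ordered.loc[m.index, m.columns]
        pd.testing.assert_frame_equal(restored, m)

    def test_label_mismatch_rejected(self):
        m, sol = self._setup()
        with pytest.raises(ValueError, match="labels"):
            biclustered_layout(m.iloc[:5], sol)


def test_collapse_duplicates_groups_identical_profiles():
    m = pd.DataFrame(
        [[1, 0, 1], [1, 0, 1], [0, 1, 1], [1, 0, 1]],
        index=["a", "b", "c", "d"], columns=["x", "y", "z"],
    )
    sub, groups = collapse_duplicates(m, "rows")
    assert groups == {"a": ["a", "b", "d"], "c": ["c"]}
    assert list(sub.index) == ["a", "c"]


def test_cut_at_k_contiguous_from_one():
    m = _random_binary(12, 0.5, seed=13)
    d = jaccard_distance(m, "rows")
    tree = hclust_tree(d)
    for k in (2, 3, 5):
        lab = cut_at_k(tree, k)
        assert sorted(set(lab)) == list(range(1, k + 1))
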