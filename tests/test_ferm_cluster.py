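"""Z-scoring, deterministic agglomeration, elbow selection, enrichment."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from glycoferm.ferm_cluster import (class_enrichment, cut_tree, group_curves,
                                    hcluster, select_k_elbow, wcss_for_cuts,
                                    zscore)


# ------------------------------------------------------------------ oracle
def oracle_hcluster(x, metric="manhattan"):
    """Brute-force O(n^3) agglomeration: inter-cluster dissimilarity is
    recomputed as the max over all leaf pairs at every step.  Same tie rule:
    lowest (a, b) cluster-id pair at the minimal height."""
    n = len(x)

    def dist(i, j):
        if metric == "manhattan":
            return float(np.abs(x[i] - x[j]).sum())
        return float(np.sqrt(((x[i] - x[j]) ** 2).sum()))

    clusters = {i: [i] for i in range(n)}
    merges = []
    for m in range(n - 1):
        best = None
        for a, b in combinations(sorted(clusters), 2):
            h = max(dist(i, j) for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        clusters[n + m] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, h, len(clusters[n + m])))
    return merges


def oracle_partition(merges, n, k):
    parent = list(range(n + len(merges)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for m, (a, b, _h, _s) in enumerate(merges[: n - k]):
        parent[find(a)] = parent[find(b)] = n + m
    return [find(i) for i in range(n)]


# ------------------------------------------------------------------ zscore
class TestZscore:
    def test_three_point_column(self):
        out = zscore(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        out = zscore(rng.normal(size=(30, 5)))
        assert np.allclose(out.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        z = zscore(rng.normal(2, 3, size=(10, 4)))
        assert np.allclose(zscore(z), z, atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore(df)


# ---------------------------------------------------------------- hcluster
class TestHcluster:
    def test_forced_merge_order_1d(self):
        tree = hcluster(np.array([[0.0], [1.0], [10.0]]))
        (a0, b0, h0, _), (_, _, h1, _) = tree.merges
        assert {a0, b0} == {0, 1} and h0 == pytest.approx(1.0)
        assert h1 == pytest.approx(10.0)

    def test_duplicate_rows_merge_first_at_zero(self):
        tree = hcluster(np.array([[1.0, 1.0], [5.0, 0.0], [1.0, 1.0]]))
        a, b, h, _ = tree.merges[0]
        assert {a, b} == {0, 2} and h == 0.0

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        tree = hcluster(rng.normal(size=(25, 4)))
        heights = [m[2] for m in tree.merges]
        assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))

    def test_matches_bruteforce_oracle_small(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            x = rng.normal(size=(n, int(rng.integers(1, 5))))
            mine = hcluster(x).merges
            orac = oracle_hcluster(x)
            for (a, b, h, s), (oa, ob, oh, os) in zip(mine, orac):
                assert {a, b} == {oa, ob}
                assert h == pytest.approx(oh, abs=1e-12)
                assert s == os

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN|finite"):
            hcluster(np.array([[1.0, np.nan], [0.0, 0.0]]))

    def test_row_permutation_preserves_partition(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        perm = rng.permutation(12)
        lab1 = cut_tree(hcluster(x), 3).labels
        lab2 = cut_tree(hcluster(x[perm]), 3).labels
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(lab1[perm], lab2) == 1.0


# ---------------------------------------------------------------- cut_tree
class TestCutTree:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 2))
        tree = hcluster(x)
        assert cut_tree(tree, 1).labels.tolist() == [1] * 8
        assert sorted(cut_tree(tree, 8).labels.tolist()) == list(range(1, 9))

    def test_out_of_range_k(self):
        tree = hcluster(np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError, match="out of range"):
            cut_tree(tree, 3)

    def test_partition_matches_oracle(self):
        rng = np.random.default_rng(6)
        from sklearn.metrics import adjusted_rand_score

        for _ in range(15):
            n = int(rng.integers(3, 11))
            x = rng.normal(size=(n, 3))
            tree = hcluster(x)
            orac = oracle_hcluster(x)
            for k in range(1, n + 1):
                mine = cut_tree(tree, k).labels
                oth = oracle_partition(orac, n, k)
                assert adjusted_rand_score(mine, oth) == 1.0

    def test_labels_ordered_by_group_size(self):
        # 4 near-identical points and 2 outliers: group 1 must be the big one
        x = np.array([[0.0], [0.1], [0.2], [0.05], [10.0], [10.1]])
        lab = cut_tree(hcluster(x), 2).labels
        assert lab.tolist() == [1, 1, 1, 1, 2, 2]


# ------------------------------------------------------------------- elbow
class TestElbow:
    def test_sharp_knee(self):
        assert select_k_elbow([(1, 100), (2, 20), (3, 18), (4, 17), (5, 16)]) == 2

    def test_linear_decay_gives_k1(self):
        assert select_k_elbow([(k, 100 - 10 * k) for k in range(1, 8)]) == 1

    def test_planted_three_clusters(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
        x = np.vstack([c + 0.3 * rng.normal(size=(15, 2)) for c in centers])
        tree = hcluster(x, metric="euclidean")
        assert select_k_elbow(wcss_for_cuts(x, tree, kmax=8)) == 3


# ------------------------------------------------------- curves/enrichment
class TestGroupSummaries:
    def _plate(self, curves):
        rows = []
        for g, y in curves.items():
            for time, v in zip(range(len(y)), y):
                rows.append({"glycan_id": g, "replicate": 1, "time": float(time),
                             "channel": "OD600", "value": float(v)})
        return pd.DataFrame(rows)

    def test_identical_curves_sd_zero(self):
        from glycoferm.ferm_cluster import ClusterAssignment

        plate = self._plate({"a": [1, 2], "b": [1, 2]})
        asg = ClusterAssignment(np.array([1, 1]), 1, ids=("a", "b"))
        out = group_curves(asg, plate, "OD600")
        assert np.allclose(out[1]["sd"], 0)

    def test_two_constant_curves_mean_and_sd(self):
        from glycoferm.ferm_cluster import ClusterAssignment

        plate = self._plate({"a": [0.2, 0.2], "b": [0.4, 0.4]})
        asg = ClusterAssignment(np.array([1, 1]), 1, ids=("a", "b"))
        out = group_curves(asg, plate, "OD600")
        assert np.allclose(out[1]["mean"], 0.3)
        assert np.allclose(out[1]["sd"], np.sqrt(0.02 / 1), atol=1e-6)  # sample SD

    def test_singleton_group_flagged(self):
        from glycoferm.ferm_cluster import ClusterAssignment

        plate = self._plate({"a": [1, 2], "b": [3, 4]})
        asg = ClusterAssignment(np.array([1, 2]), 2, ids=("a", "b"))
        out = group_curves(asg, plate, "OD600")
        assert out[1].attrs["singleton"] and np.allclose(out[1]["sd"], 0)

    def test_perfect_alignment_enrichment_p(self):
        from glycoferm.ferm_cluster import ClusterAssignment

        labels = np.array([1] * 10 + [2] * 10)
        classes = ["ref"] * 10 + ["SG"] * 10
        asg = ClusterAssignment(labels, 2, ids=tuple(range(20)))
        out = class_enrichment(asg, classes)
        p = out[(out["group"] == 1) & (out["class"] == "ref")]["p_value"].iloc[0]
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_independent_classes_p1(self):
        from glycoferm.ferm_cluster import ClusterAssignment

        labels = np.array([1] * 10 + [2] * 10)
        classes = (["ref"] * 5 + ["SG"] * 5) * 2
        asg = ClusterAssignment(labels, 2, ids=tuple(range(20)))
        out = class_enrichment(asg, classes)
        assert np.allclose(out["p_value"], 1.0)
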