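"""Hierarchical clustering, dependence classification, and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import remodelome as rm
from remodelome.clusters import hierarchical_clusters
from conftest import make_table


def frame(arr):
    arr = np.asarray(arr, float)
    return pd.DataFrame(arr, index=[f"F{i}" for i in range(len(arr))])


def brute_force_complete_linkage(arr, k):
    """Agglomerate by exhaustively searching the minimal complete-linkage
    (max pairwise distance) merge at every step; stop at k clusters."""
    d = squareform(pdist(arr))
    clusters = [frozenset([i]) for i in range(len(arr))]
    while len(clusters) > k:
        best, pair = np.inf, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            link = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if link < best - 1e-12:
                best, pair = link, (a, b)
        a, b = pair
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
    return {frozenset(c) for c in clusters}


class TestHierarchicalClusters:
    def test_k_equals_n_gives_singletons(self):
        arr = np.random.default_rng(0).normal(size=(6, 4))
        cs = hierarchical_clusters(frame(arr), k=6)
        assert cs.sizes().tolist() == [1] * 6

    def test_two_identical_groups_split_perfectly(self):
        arr = np.vstack([np.tile([0.0, 1, 2, 3], (3, 1)), np.tile([5.0, 4, 3, 1], (3, 1))])
        arr += np.random.default_rng(1).normal(0, 0.01, arr.shape)
        cs = hierarchical_clusters(frame(arr), k=2)
        labels = cs.assignments.to_numpy()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_linkage_oracle(self, k):
        rng = np.random.default_rng(99)
        for trial in range(5):
            arr = rng.normal(size=(6, 4))
            cs = hierarchical_clusters(frame(arr), k=k)
            got = {
                frozenset(np.flatnonzero(cs.assignments.to_numpy() == c))
                for c in cs.sizes().index
            }
            assert got == brute_force_complete_linkage(arr, k)

    def test_assignments_invariant_under_row_permutation(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(20, 5))
        cs1 = hierarchical_clusters(frame(arr), k=4)
        perm = rng.permutation(20)
        f2 = frame(arr).iloc[perm]
        cs2 = hierarchical_clusters(f2, k=4)
        # same partition up to relabeling
        p1 = {frozenset(cs1.assignments.index[cs1.assignments == c]) for c in range(1, 5)}
        p2 = {frozenset(cs2.assignments.index[cs2.assignments == c]) for c in range(1, 5)}
        assert p1 == p2

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            hierarchical_clusters(frame(np.eye(3)), k=5)

    def test_kmeans_mode_partitions(self):
        arr = np.random.default_rng(3).normal(size=(30, 4))
        cs = hierarchical_clusters(frame(arr), k=5, method="kmeans")
        assert cs.sizes().sum() == 30 and len(cs.sizes()) == 5


class TestClusterMeans:
    def test_singleton_and_cancellation_and_mean(self):
        from remodelome.trajectories import TrajectoryMatrix

        ages = np.array([3.0, 10.0, 25.0])
        data = {"a": pd.DataFrame(
            [[1, 2, 3], [-1, -2, -3], [0, 3, 6], [2, 3, 4]],
            index=["F0", "F1", "F2", "F3"], columns=ages)}
        m = TrajectoryMatrix(ages, data)
        cs = rm.ClusterSet(
            2, pd.Series([1, 1, 2, 2], index=["F0", "F1", "F2", "F3"])
        )
        means = rm.cluster_mean_trajectory(cs, m)
        np.testing.assert_allclose(means["a"].loc[1], [0, 0, 0])  # mirror members
        np.testing.assert_allclose(means["a"].loc[2], [1, 3, 5])  # hand mean

    def test_missing_member_rejected(self):
        from remodelome.trajectories import TrajectoryMatrix

        ages = np.array([3.0, 10.0])
        m = TrajectoryMatrix(ages, {"a": pd.DataFrame([[1, 2]], index=["F0"], columns=ages)})
        cs = rm.ClusterSet(1, pd.Series([1], index=["F9"]))
        with pytest.raises(KeyError):
            rm.cluster_mean_trajectory(cs, m)


class TestDietDependence:
    @staticmethod
    def _table(offset_by_age, noise=0.002, n_features=4, ages=(3, 10, 25)):
        """Two diets; diet B shifted by offset_by_age (log10) at each age."""
        rng = np.random.default_rng(0)
        n_reps = 3
        cols = []
        for diet in ("A", "B"):
            for i_age, age in enumerate(ages):
                shift = offset_by_age[i_age] if diet == "B" else 0.0
                for rep in range(n_reps):
                    cols.append(10 ** (3.0 + shift + rng.normal(0, noise, n_features)))
        values = np.column_stack(cols)
        return make_table(values, diets=("A", "B"), ages=ages, n_reps=n_reps)

    def _classify(self, offsets, **kw):
        table = self._table(offsets)
        cs = rm.ClusterSet(1, pd.Series(1, index=table.feature_ids))
        return rm.classify_diet_dependence(cs, table, **kw)["class"].iloc[0]

    def test_identical_diets_independent(self):
        assert self._classify([0.0, 0.0, 0.0]) == "independent"

    def test_persistent_large_offset_progressive(self):
        assert self._classify([0.5, 0.5, 0.5]) == "progressive"

    def test_single_age_offset_intermittent(self):
        assert self._classify([0.0, 0.5, 0.0]) == "intermittent"

    def test_subtle_offset_below_fold_floor_ignored(self):
        # statistically detectable but biologically below the twofold gate
        assert self._classify([0.1, 0.1, 0.1]) == "independent"

    def test_monotone_in_offset(self):
        # growing every age's offset never demotes the call
        order = {"independent": 0, "intermittent": 1, "progressive": 2}
        last = 0
        for height in (0.0, 0.2, 0.4, 0.6):
            got = order[self._classify([height] * 3)]
            assert got >= last
            last = got

    def test_feature_level_granularity(self):
        table = self._table([0.5, 0.5, 0.5])
        cs = rm.ClusterSet(1, pd.Series(1, index=table.feature_ids))
        out = rm.classify_diet_dependence(cs, table, level="feature")
        assert len(out) == len(table.feature_ids)
        assert (out["class"] == "progressive").all()

    def test_recovers_planted_dependence_fractions(self, recovery_runs):
        fracs = pd.DataFrame([r.dependence.fractions for r in recovery_runs])
        means = fracs.mean()
        assert means["independent"] == pytest.approx(0.62, abs=0.06)
        assert means["progressive"] > means["intermittent"]


class TestDependenceFrequencies:
    def test_all_independent(self):
        cs = rm.ClusterSet(2, pd.Series([1, 1, 2], index=["F0", "F1", "F2"]))
        cs.classification = pd.DataFrame(
            {"class": ["independent", "independent"], "n_features": [2, 1]},
            index=[1, 2],
        )
        summary = rm.dependence_frequencies(cs)
        assert summary.fractions == {"independent": 1.0, "progressive": 0.0, "intermittent": 0.0}

    def test_fractions_sum_to_one(self, default_run):
        assert sum(default_run.dependence.fractions.values()) == pytest.approx(1.0)

    def test_unclassified_rejected(self):
        cs = rm.ClusterSet(1, pd.Series([1], index=["F0"]))
        with pytest.raises(ValueError, match="classify"):
            rm.dependence_frequencies(cs)


class TestPca:
    def test_perfectly_correlated_features_one_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        mat = pd.DataFrame({"f1": x, "f2": 2 * x + 1})
        scores, evr = rm.pca_project(mat)
        assert evr[0] == pytest.approx(1.0)

    def test_scores_invariant_to_feature_order(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(15, 6)))
        s1, _ = rm.pca_project(mat)
        s2, _ = rm.pca_project(mat[list(reversed(mat.columns))])
        np.testing.assert_allclose(np.abs(s1), np.abs(s2), atol=1e-9)

    def test_across_scaling_separates_diets(self, default_run):
        from sklearn.metrics import silhouette_score

        s = default_run.pca["across_diets"]["scores"]
        X = s[["PC1", "PC2"]].to_numpy()
        assert silhouette_score(X, s["diet"]) > silhouette_score(X, s["age_days"])

    def test_within_scaling_orders_by_age(self, default_run):
        from scipy.stats import spearmanr

        s = default_run.pca["within_diet"]["scores"]
        for diet in default_run.diets:
            sub = s[s["diet"] == diet]
            rho = spearmanr(sub["PC1"], sub["age_days"]).statistic
            assert abs(rho) > 0.8

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            rm.pca_project(pd.DataFrame(np.zeros((5, 3))))
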