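"""Cluster validity indices, clustering runners and the random-forest OOB harness."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from madvar_select import FeatureMatrix, InvalidInputError, InvalidParameterError, madvar
from madvar_select.benchmark import (
    bhi,
    connectivity,
    dunn_index,
    oob_harness,
    run_clustering,
)
from madvar_select.synthetic_data import SyntheticSpec, generate_matrix


def matrix_from_samples(X):
    """Samples-as-rows array -> FeatureMatrix (features as rows)."""
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(X.T, [f"f{i}" for i in range(X.shape[1])],
                         [f"s{j}" for j in range(X.shape[0])])


def brute_connectivity(X, labels, L):
    dist = squareform(pdist(X))
    total = 0.0
    for i in range(X.shape[0]):
        others = sorted(j for j in range(X.shape[0]) if j != i)
        others.sort(key=lambda j: (dist[i, j], j))
        for rank, j in enumerate(others[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def brute_dunn(X, labels):
    dist = squareform(pdist(X))
    inter, intra = [], []
    for i, j in itertools.combinations(range(X.shape[0]), 2):
        (intra if labels[i] == labels[j] else inter).append(dist[i, j])
    return min(inter) / max(intra)


def brute_bhi(clusters, annotations):
    vals = []
    for c in set(clusters):
        members = [i for i, ci in enumerate(clusters) if ci == c]
        if len(members) < 2:
            continue
        pairs = list(itertools.combinations(members, 2))
        vals.append(sum(annotations[i] == annotations[j] for i, j in pairs) / len(pairs))
    return sum(vals) / len(vals)


class TestConnectivity:
    def test_well_separated_clusters_score_zero(self):
        X = np.concatenate([np.zeros(10), np.full(10, 100.0)])[:, None]
        X = X + np.linspace(0, 1, 20)[:, None] * 0.01
        m = matrix_from_samples(np.hstack([X, X]))
        labels = np.array([0] * 10 + [1] * 10)
        assert connectivity(m, labels, L=5) == 0.0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 20))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, 3, size=n)
            L = int(rng.integers(1, n - 1))
            m = matrix_from_samples(X)
            assert connectivity(m, labels, L=L) == pytest.approx(
                brute_connectivity(X, labels, L))

    def test_merging_clusters_never_increases_connectivity(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 16))
            X = rng.normal(size=(n, 2))
            labels = rng.integers(0, 3, size=n)
            merged = np.where(labels == 2, 1, labels)
            m = matrix_from_samples(X)
            assert connectivity(m, merged, L=3) <= connectivity(m, labels, L=3)

    def test_L_bounds_enforced(self, rng):
        m = matrix_from_samples(rng.normal(size=(10, 2)))
        labels = np.zeros(10, dtype=int)
        with pytest.raises(InvalidParameterError):
            connectivity(m, labels, L=10)
        with pytest.raises(InvalidParameterError):
            connectivity(m, labels, L=0)


class TestDunnIndex:
    def test_hand_case(self):
        m = matrix_from_samples(np.array([[0.0], [1.0], [10.0], [11.0]]))
        labels = np.array([0, 0, 1, 1])
        assert dunn_index(m, labels) == pytest.approx(9.0)

    def test_duplicating_points_preserves_value(self, rng):
        X = rng.normal(size=(10, 2))
        labels = np.array([0] * 5 + [1] * 5)
        v1 = dunn_index(matrix_from_samples(X), labels)
        v2 = dunn_index(matrix_from_samples(np.vstack([X, X])),
                        np.concatenate([labels, labels]))
        assert v1 == pytest.approx(v2)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 30))
            X = rng.normal(size=(n, 4))
            labels = np.concatenate([[0, 1], rng.integers(0, 2, size=n - 2)])
            m = matrix_from_samples(X)
            assert dunn_index(m, labels) == pytest.approx(brute_dunn(X, labels))

    def test_singleton_only_clustering_is_infinite(self):
        m = matrix_from_samples(np.array([[0.0], [5.0], [9.0]]))
        with pytest.warns(UserWarning, match="singleton"):
            assert dunn_index(m, np.array([0, 1, 2])) == np.inf

    def test_single_cluster_rejected(self):
        m = matrix_from_samples(np.array([[0.0], [1.0]]))
        with pytest.raises(InvalidInputError):
            dunn_index(m, np.array([0, 0]))


class TestBHI:
    def test_perfect_annotation_match(self):
        clusters = np.array([0, 0, 1, 1, 2, 2])
        assert bhi(clusters, clusters.copy()) == 1.0

    def test_even_split_hand_case(self):
        # every size-4 cluster split 2/2 over two classes: 2 matching pairs of 6
        clusters = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        annotations = np.array(["a", "a", "b", "b", "a", "a", "b", "b"])
        assert bhi(clusters, annotations) == pytest.approx(1 / 3)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 30))
            clusters = rng.integers(0, 4, size=n)
            annotations = rng.integers(0, 3, size=n)
            if max(np.bincount(clusters)) < 2:
                continue
            assert bhi(clusters, annotations) == pytest.approx(
                brute_bhi(list(clusters), list(annotations)))

    def test_all_singletons_rejected(self):
        with pytest.raises(InvalidInputError):
            bhi(np.arange(5), np.zeros(5))


class TestRunClustering:
    @pytest.mark.parametrize("method", ["hierarchical_ward", "pam"])
    def test_recovers_two_separated_groups(self, rng, method):
        X = np.vstack([rng.normal(0, 0.3, size=(12, 5)),
                       rng.normal(8, 0.3, size=(12, 5))])
        m = matrix_from_samples(X)
        labels = run_clustering(m, method=method, k=2)
        truth = np.array([0] * 12 + [1] * 12)
        agreement = max(np.mean(labels == truth), np.mean(labels != truth))
        assert agreement == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.normal(size=(8, 3))
        labels = run_clustering(matrix_from_samples(X), "hierarchical_ward", k=8)
        assert len(set(labels)) == 8

    def test_hierarchical_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(10, 4))
        m = matrix_from_samples(X)
        base = run_clustering(m, "hierarchical_ward", k=3)
        perm = rng.permutation(10)
        m2 = matrix_from_samples(X[perm])
        permuted = run_clustering(m2, "hierarchical_ward", k=3)
        # same partition up to label renaming
        def canon(labels):
            groups = {}
            return tuple(groups.setdefault(l, len(groups)) for l in labels)
        inverse = np.empty(10, dtype=int)
        inverse[perm] = np.arange(10)
        assert canon(permuted[inverse]) == canon(base)

    def test_invalid_k_rejected(self, rng):
        m = matrix_from_samples(rng.normal(size=(5, 2)))
        with pytest.raises(InvalidParameterError):
            run_clustering(m, "pam", k=6)
        with pytest.raises(InvalidParameterError):
            run_clustering(m, "pam", k=1)


class TestOOBHarness:
    def test_separable_problem_has_low_error(self, rng):
        X = np.vstack([rng.normal(0, 0.5, size=(15, 10)),
                       rng.normal(6, 0.5, size=(15, 10))])
        m = matrix_from_samples(X)
        labels = np.array([0] * 15 + [1] * 15)
        res = oob_harness(m, labels, n_seeds=4, n_trees=50)
        assert res.error_rates.mean() <= 0.05

    def test_shuffled_labels_approach_majority_error(self, rng):
        X = rng.normal(size=(40, 8))
        labels = np.array([0] * 20 + [1] * 20)
        rng.shuffle(labels)
        res = oob_harness(matrix_from_samples(X), labels, n_seeds=4, n_trees=50)
        assert res.error_rates.mean() > 0.3  # majority error is 0.5 here

    def test_deterministic_for_same_seed_list(self, rng):
        X = rng.normal(size=(20, 6))
        labels = np.array([0, 1] * 10)
        m = matrix_from_samples(X)
        a = oob_harness(m, labels, n_seeds=3, n_trees=20)
        b = oob_harness(m, labels, n_seeds=3, n_trees=20)
        np.testing.assert_array_equal(a.error_rates, b.error_rates)
        assert len(a.error_rates) == 3

    def test_single_class_rejected(self, rng):
        m = matrix_from_samples(rng.normal(size=(10, 4)))
        with pytest.raises(InvalidInputError):
            oob_harness(m, np.zeros(10, dtype=int), n_seeds=1, n_trees=10)


class TestFilteringImprovesBHI:
    def test_madvar_filtering_recovers_bhi_lost_to_noise(self, rng):
        # strong group structure + a majority of pure-noise features
        spec = SyntheticSpec(n_features=400, n_samples=40, frac_invariant=0.0,
                             n_groups=4, group_effect_sd=1.5, seed=12)
        m, labels = generate_matrix(spec)
        noise = rng.normal(5, 0.05, size=(1200, 40))
        noisy = FeatureMatrix(
            np.vstack([m.values, noise]),
            m.feature_ids + [f"noise{i}" for i in range(1200)], m.sample_ids)
        filtered = madvar(noisy, mads=2).matrix
        bhi_noisy = bhi(run_clustering(noisy, "hierarchical_ward", 4), labels.sample_group)
        bhi_filtered = bhi(run_clustering(filtered, "hierarchical_ward", 4),
                           labels.sample_group)
        assert bhi_filtered >= bhi_noisy
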