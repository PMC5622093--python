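import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from rsmp.clustering import (
    ClusterModel,
    assign,
    centre_dendrogram,
    elbow_curve,
    fit_kmeans,
    fourth_root,
)


class TestFourthRoot:
    def test_closed_forms(self):
        assert fourth_root(16.0) == 2.0
        assert fourth_root(1.0) == 1.0  # colonial presence unchanged
        assert fourth_root(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fourth_root(np.array([1.0, -2.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_strictly_monotone(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 50, size=20))
        y = fourth_root(x)
        assert (np.diff(y)[np.diff(x) > 0] > 0).all()


def _two_clouds(rng, n=40, gap=20.0):
    a = rng.standard_normal((n, 3))
    b = rng.standard_normal((n, 3)) + gap
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], n)
    return X, labels


class TestFitKmeans:
    def test_planted_two_clouds_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X, truth = _two_clouds(rng)
        m = fit_kmeans(X, 2, seed=5)
        assert adjusted_rand_score(truth, m.labels) == 1.0

    def test_k_equals_n_gives_zero_wss(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 2))
        m = fit_kmeans(X, 8, seed=3)
        assert m.wss == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_centres(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 4))
        m1 = fit_kmeans(X, 4, seed=9)
        m2 = fit_kmeans(X, 4, seed=9)
        np.testing.assert_array_equal(m1.centres, m2.centres)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_wss_consistent_with_labels_and_centres(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 5))
        m = fit_kmeans(X, 5, seed=11)
        recomputed = ((X - m.centres[m.labels - 1]) ** 2).sum()
        assert m.wss == pytest.approx(recomputed, abs=1e-8)
        assert 0 <= m.wss <= m.tss
        assert 0.0 <= m.explained <= 1.0

    def test_invalid_k(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            fit_kmeans(X, 1, seed=0)
        with pytest.raises(ValueError):
            fit_kmeans(X, 6, seed=0)

    def test_matches_sklearn_objective_on_easy_data(self):
        # independent optimiser should land on the same (global) optimum here
        rng = np.random.default_rng(4)
        X, _ = _two_clouds(rng, n=30, gap=10.0)
        ours = fit_kmeans(X, 2, seed=7)
        sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert ours.wss == pytest.approx(sk.inertia_, rel=1e-6)

    def test_json_round_trip(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 3))
        m = fit_kmeans(X, 3, seed=1, transform_spec="fourth-root",
                       columns=("a", "b", "c"))
        back = ClusterModel.from_json(m.to_json())
        np.testing.assert_allclose(back.centres, m.centres)
        assert back.codes == m.codes
        assert back.transform_spec == "fourth-root"


class TestElbow:
    def test_explained_monotone_in_k(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((70, 4))
        curve = elbow_curve(X, range(2, 10), seed=2, n_restarts=5)
        explained = [e for _, _, e in curve]
        assert all(b >= a - 1e-12 for a, b in zip(explained, explained[1:]))

    def test_k_near_n_explains_almost_all(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((12, 3))
        curve = elbow_curve(X, [11], seed=2, n_restarts=5)
        assert curve[0][2] > 0.95


class TestCentreDendrogram:
    def test_collinear_centres_first_merge(self):
        m = ClusterModel(
            k=3, centres=np.array([[0.0], [1.0], [10.0]]),
            transform_spec="", labels=np.array([1, 2, 3]),
            wss=0.0, tss=1.0, seed=0, n_restarts=1,
        )
        d = centre_dendrogram(m)
        first = sorted(d.linkage[0, :2].astype(int))
        assert first == [0, 1]

    def test_heights_non_decreasing(self, default_root):
        m = fit_kmeans(default_root[:200], 6, seed=4, n_restarts=5)
        d = centre_dendrogram(m)
        h = d.heights
        assert (np.diff(h) >= -1e-12).all()

    def test_identical_centres_merge_at_zero(self):
        m = ClusterModel(
            k=3, centres=np.zeros((3, 2)), transform_spec="",
            labels=np.array([1, 2, 3]), wss=0.0, tss=1.0, seed=0, n_restarts=1,
        )
        d = centre_dendrogram(m)
        assert np.allclose(d.heights, 0.0)

    def test_manhattan_metric_available(self):
        m = ClusterModel(
            k=3, centres=np.array([[0.0, 0], [1, 1], [5, 5]]),
            transform_spec="", labels=np.array([1, 2, 3]),
            wss=0.0, tss=1.0, seed=0, n_restarts=1,
        )
        d = centre_dendrogram(m, metric="cityblock")
        assert d.metric == "cityblock"
        with pytest.raises(ValueError):
            centre_dendrogram(m, metric="cosine")

    def test_codes_reflect_dendrogram_structure(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.standard_normal((20, 2)) + off
                       for off in ([0, 0], [0.5, 0], [40, 40], [41, 40])])
        m = fit_kmeans(X, 4, seed=3)
        codes = set(m.codes.values())
        # two well-separated pairs -> two letters, two numbers each
        letters = {c[0] for c in codes}
        assert len(letters) == 2
        assert all(len(c) == 2 for c in codes)


class TestAssign:
    def test_training_rows_reassigned_identically(self):
        rng = np.random.default_rng(9)
        X, _ = _two_clouds(rng, n=25)
        m = fit_kmeans(X, 2, seed=6)
        np.testing.assert_array_equal(assign(m, X), m.labels)

    def test_tie_goes_to_lowest_group_index(self):
        m = ClusterModel(
            k=2, centres=np.array([[-1.0], [1.0]]), transform_spec="",
            labels=np.array([1, 2]), wss=0.0, tss=1.0, seed=0, n_restarts=1,
        )
        assert assign(m, [[0.0]])[0] == 1

    def test_column_mismatch_rejected(self):
        m = ClusterModel(
            k=2, centres=np.zeros((2, 3)), transform_spec="",
            labels=np.array([1, 2]), wss=0.0, tss=1.0, seed=0, n_restarts=1,
            columns=("a", "b", "c"),
        )
        with pytest.raises(ValueError, match="column"):
            assign(m, np.zeros((1, 2)))
        with pytest.raises(ValueError, match="column"):
            assign(m, np.zeros((1, 3)), columns=("b", "a", "c"))

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(10)
        X, _ = _two_clouds(rng, n=15)
        m = fit_kmeans(X, 2, seed=6)
        perm = rng.permutation(len(X))
        np.testing.assert_array_equal(assign(m, X[perm]), assign(m, X)[perm])

    def test_new_draws_from_planted_group_assigned_back(self, default_dataset,
                                                        default_root):
        m = fit_kmeans(default_root, 12, seed=31, n_restarts=10)
        truth = default_dataset.truth.faunal_group
        # map planted group -> fitted label by majority vote
        agree = 0
        total = 0
        for g in np.unique(truth):
            members = np.flatnonzero(truth == g)
            fitted = m.labels[members]
            majority = np.bincount(fitted).argmax()
            agree += (fitted == majority).sum()
            total += len(members)
        assert agree / total >= 0.95
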