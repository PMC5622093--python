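import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from rsmp.environment import (
    ZeroVarianceError,
    balanced_subsample,
    bioenv,
    permanova,
    transform_env,
    vif_prune,
)


class TestVifPrune:
    def test_independent_normals_retained(self):
        rng = np.random.default_rng(0)
        env = pd.DataFrame(rng.standard_normal((200, 2)), columns=["x", "y"])
        retained, trace = vif_prune(env)
        assert retained == ["x", "y"] and trace == []

    def test_constructed_collinearity_removed(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        z = x + y + 0.1 * rng.standard_normal(300)
        env = pd.DataFrame({"x": x, "y": y, "z": z})
        retained, trace = vif_prune(env)
        assert len(trace) == 1
        from rsmp.environment import _vif_scores

        assert (_vif_scores(env[retained]) <= 2.5).all()

    def test_perfect_collinearity_tie_alphabetical(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        env = pd.DataFrame({"b": x.copy(), "a": x.copy(), "c": rng.standard_normal(100)})
        retained, trace = vif_prune(env)
        assert trace[0][0] == "a"  # infinite VIFs tie; alphabetical victim
        assert "b" in retained

    def test_synthetic_collinear_pairs_pruned_not_drivers(self, default_dataset):
        retained, trace = vif_prune(default_dataset.table.env)
        removed = {t[0] for t in trace}
        # exactly one of each planted collinear pair goes; closure trio loses
        # Gravel by the alphabetical tie-break; drivers always survive
        assert "Gravel" in removed
        assert len(removed & {"Temp", "Lat"}) == 1
        assert len(removed & {"Chl_a", "SPM"}) == 1
        assert len(removed & {"Stress", "AvCur"}) == 1
        assert {"AvCur", "Sand", "Mud"} <= set(retained)


class TestTransformEnv:
    def test_constant_column_reported(self):
        env = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ZeroVarianceError, match="a"):
            transform_env(env, log_vars=())

    def test_normalisation_identity(self):
        rng = np.random.default_rng(3)
        env = pd.DataFrame({"SPM": rng.gamma(2, 2, 100), "x": rng.standard_normal(100)})
        out = transform_env(env)
        assert np.allclose(out.mean(), 0.0, atol=1e-9)
        assert np.allclose(out.std(ddof=1), 1.0, atol=1e-9)

    def test_log_offset_closed_form(self):
        env = pd.DataFrame({"SPM": [0.0, 1.0, 10.0], "x": [1.0, 2.0, 3.0]})
        out_manual = np.log(env["SPM"] + 0.1)
        zs = (out_manual - out_manual.mean()) / out_manual.std(ddof=1)
        out = transform_env(env)
        np.testing.assert_allclose(out["SPM"], zs)

    def test_negative_log_var_rejected(self):
        env = pd.DataFrame({"Mud": [-0.1, 1.0, 2.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="Mud"):
            transform_env(env)


class TestBalancedSubsample:
    def test_full_scale_balanced_subset(self):
        labels = np.repeat(np.arange(12), 300)
        idx = balanced_subsample(labels, 297, seed=0)
        assert len(idx) == 3564
        counts = pd.Series(labels[idx]).value_counts()
        assert (counts == 297).all()

    def test_whole_group_any_seed(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        i1 = balanced_subsample(labels, 5, seed=1)
        i2 = balanced_subsample(labels, 5, seed=2)
        assert sorted(i1) == sorted(i2) == list(range(10))

    def test_two_seeds_differ_same_counts(self):
        labels = np.repeat([0, 1], 50)
        i1 = balanced_subsample(labels, 10, seed=1)
        i2 = balanced_subsample(labels, 10, seed=2)
        assert sorted(i1) != sorted(i2)
        assert len(i1) == len(i2) == 20

    def test_undersized_group_named(self):
        labels = np.array(["big"] * 10 + ["tiny"] * 2)
        with pytest.raises(ValueError, match="tiny"):
            balanced_subsample(labels, 5, seed=0)


class TestBioenv:
    def test_noiseless_monotone_driver_found(self):
        rng = np.random.default_rng(4)
        n = 40
        v = rng.uniform(0, 1, n)
        env = pd.DataFrame({"driver": v, "noise1": rng.standard_normal(n),
                            "noise2": rng.standard_normal(n)})
        # community is a smooth function of the driver alone
        Y = np.column_stack([np.exp(-((v - c) ** 2) / 0.1) for c in
                             np.linspace(0, 1, 15)])
        d = pdist(Y, metric="braycurtis")
        envz = (env - env.mean()) / env.std(ddof=1)
        res = bioenv(d, envz)
        best = [b for b in res if b.best_overall][0]
        assert best.subset == ("driver",)
        assert best.rho > 0.9

    def test_rho_matches_direct_recomputation(self):
        rng = np.random.default_rng(5)
        n = 25
        env = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        Y = rng.poisson(4, size=(n, 10))
        d = pdist(Y, metric="braycurtis")
        res = bioenv(d, env, max_size=3)
        for b in res:
            de = pdist(env[list(b.subset)].to_numpy())
            rho = spearmanr(d, de).statistic
            assert b.rho == pytest.approx(rho, abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        n = 20
        env = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        Y = rng.poisson(4, size=(n, 8))
        D = squareform(pdist(Y, metric="braycurtis"))
        perm = rng.permutation(n)
        r1 = bioenv(squareform(D), env)
        r2 = bioenv(squareform(D[np.ix_(perm, perm)]), env.iloc[perm])
        for b1, b2 in zip(r1, r2):
            assert b1.subset == b2.subset
            assert b1.rho == pytest.approx(b2.rho, abs=1e-12)

    def test_combinatorial_guard(self):
        env = pd.DataFrame(np.zeros((30, 21)))
        with pytest.raises(ValueError, match="max_size"):
            bioenv(np.zeros(30 * 29 // 2), env)

    def test_agrees_with_skbio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import bioenv as sk_bioenv

        rng = np.random.default_rng(7)
        n = 30
        env = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("ABCD"),
                           index=[f"s{i}" for i in range(n)])
        Y = rng.poisson(3, size=(n, 20)) + (env[["A"]].to_numpy() ** 2).astype(int)
        d = pdist(Y, metric="braycurtis")
        envz = (env - env.mean()) / env.std(ddof=1)
        ours = bioenv(d, envz, max_size=4)
        theirs = sk_bioenv(DistanceMatrix(squareform(d), ids=env.index), env)
        np.testing.assert_allclose(
            [b.rho for b in ours], theirs["correlation"].to_numpy(), atol=1e-10
        )


class TestPermanova:
    def test_single_predictor_matches_brute_force(self):
        rng = np.random.default_rng(8)
        n = 12
        D = squareform(pdist(rng.standard_normal((n, 3))))
        pred = pd.DataFrame({"x": rng.standard_normal(n)})
        res = permanova(D, pred, n_perm=99, seed=0)
        A = -0.5 * D**2
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ A @ J
        X = np.column_stack([np.ones(n), pred["x"]])
        H = X @ np.linalg.pinv(X.T @ X) @ X.T
        ss = np.trace(H @ G) - np.trace((np.ones((n, n)) / n) @ G)
        assert res.terms[0].ss == pytest.approx(ss, abs=1e-10)
        assert res.total_ss == pytest.approx(np.trace(G), abs=1e-10)

    def test_r2_sums_to_one(self):
        # Euclidean distances keep the centred matrix PSD, so every term's
        # share is non-negative (semi-metric dissimilarities can produce
        # slightly negative components, a known property of this partition)
        rng = np.random.default_rng(9)
        n = 25
        D = squareform(pdist(rng.standard_normal((n, 4)), metric="euclidean"))
        pred = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        res = permanova(D, pred, n_perm=99, seed=1)
        total_r2 = sum(t.r2 for t in res.terms) + res.residual_r2
        assert total_r2 == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= t.r2 <= 1 for t in res.terms)
        assert all(0 < t.p <= 1 for t in res.terms)

    def test_orthogonal_terms_order_invariant(self):
        rng = np.random.default_rng(10)
        n = 24
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        Y = rng.standard_normal((n, 5)) + np.outer(a, np.ones(5))
        D = squareform(pdist(Y))
        r_ab = permanova(D, pd.DataFrame({"a": a, "b": b}), n_perm=99, seed=2)
        r_ba = permanova(D, pd.DataFrame({"b": b, "a": a}), n_perm=99, seed=2)
        ss_ab = {t.name: t.r2 for t in r_ab.terms}
        ss_ba = {t.name: t.r2 for t in r_ba.terms}
        for k in ("a", "b"):
            assert ss_ab[k] == pytest.approx(ss_ba[k], abs=1e-9)

    def test_small_nperm_warns(self):
        n = 10
        D = squareform(pdist(np.random.default_rng(11).standard_normal((n, 2))))
        with pytest.warns(UserWarning, match="n_perm"):
            permanova(D, pd.DataFrame({"x": np.arange(n, dtype=float)}),
                      n_perm=9, seed=0)
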