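import numpy as np
import pandas as pd
import pytest

from rsmp.clustering import ClusterModel, centre_dendrogram
from rsmp.envelopes import (
    GroupKey,
    NeedsAugmentation,
    SedimentEnvelope,
    augment_from_dendrogram,
    augmentation_order,
    cumulative_distribution,
    describe_sediment,
    fit_envelope,
    make_groups,
    mvdisp,
    wentworth_summary,
)
from rsmp.sieves import WENTWORTH_FRACTIONS


def _comp_frame(rows, index=None):
    return pd.DataFrame(rows, columns=list(WENTWORTH_FRACTIONS), index=index)


class TestGroupKey:
    def test_label_concatenation(self):
        assert GroupKey("B1a", 4).label == "B1a_4"
        assert GroupKey("D1").label == "D1"

    def test_parse_round_trip(self):
        for label in ("B1a_4", "D1", "A2b_10"):
            assert GroupKey.parse(label).label == label

    def test_make_groups_alignment_checked(self):
        keys = make_groups(["A1", "B1"], [2, None])
        assert [k.label for k in keys] == ["A1_2", "B1"]
        with pytest.raises(ValueError, match="length"):
            make_groups(["A1"], [1, 2])


class TestFitEnvelope:
    def test_closed_form_mean_and_variance(self):
        comps = _comp_frame([[10, 90, 0, 0, 0, 0, 0], [20, 80, 0, 0, 0, 0, 0]])
        env = fit_envelope(comps, GroupKey("G"), min_n=2)
        assert env.mean[0] == 15.0 and env.mean[1] == 85.0
        assert env.cov[0, 0] == pytest.approx(50.0)

    def test_single_sample_needs_augmentation(self):
        comps = _comp_frame([[10, 90, 0, 0, 0, 0, 0]])
        with pytest.raises(NeedsAugmentation) as err:
            fit_envelope(comps, GroupKey("G"), min_n=30)
        assert err.value.shortfall == 29

    def test_logistic_normal_simulation_recovers_truth(self):
        rng = np.random.default_rng(0)
        mu = np.log(np.array([0.05, 0.1, 0.25, 0.3, 0.15, 0.1, 0.05]))
        n = 400
        logits = mu + rng.standard_normal((n, 7)) * 0.2
        e = np.exp(logits)
        comps = _comp_frame(100 * e / e.sum(1, keepdims=True))
        env = fit_envelope(comps, GroupKey("G"), min_n=30)
        truth = comps.mean(axis=0).to_numpy()
        se = comps.std(ddof=1, axis=0).to_numpy() / np.sqrt(n)
        # columnwise mean is the MLE here; should sit within 3 SE trivially
        assert (np.abs(env.mean - truth) <= 3 * se + 1e-12).all()

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        raw = rng.dirichlet(np.ones(7), size=40) * 100
        comps = _comp_frame(raw)
        e1 = fit_envelope(comps, GroupKey("G"), min_n=2)
        e2 = fit_envelope(comps.iloc[::-1], GroupKey("G"), min_n=2)
        np.testing.assert_allclose(e1.mean, e2.mean)
        np.testing.assert_allclose(e1.cov, e2.cov)

    def test_closure_makes_cov_rows_sum_to_zero(self):
        rng = np.random.default_rng(2)
        raw = rng.dirichlet(np.ones(7) * 3, size=100) * 100  # exactly closed
        env = fit_envelope(_comp_frame(raw), GroupKey("G"), min_n=2)
        assert np.abs(env.cov.sum(axis=1)).max() < 1e-9

    def test_json_round_trip(self):
        rng = np.random.default_rng(3)
        raw = rng.dirichlet(np.ones(7), size=50) * 100
        env = fit_envelope(_comp_frame(raw), GroupKey("B1a", 4), min_n=2)
        env.mvdisp = 1.1
        back = SedimentEnvelope.from_json(env.to_json())
        assert back.key == env.key and back.n == env.n
        np.testing.assert_allclose(back.cov, env.cov)


def _chain_dendrogram():
    # four physical groups on a line: 1 and 2 close, 3 further, 4 far
    centres = np.array([[0.0], [1.0], [5.0], [20.0]])
    model = ClusterModel(k=4, centres=centres, transform_spec="",
                         labels=np.arange(1, 5), wss=0.0, tss=1.0,
                         seed=0, n_restarts=1)
    return centre_dendrogram(model)


class TestAugmentation:
    def test_short_group_tops_up_from_sibling_only(self):
        dend = _chain_dendrogram()
        rows = []
        for code, count in [(1, 25), (2, 50), (3, 40)]:
            for i in range(count):
                rows.append([10, 50, 20, 10, 5, 3, 2] + [code])
        comps = pd.DataFrame(rows, columns=list(WENTWORTH_FRACTIONS) + ["physical_code"])
        aug, provenance = augment_from_dendrogram(GroupKey("A1", 1), dend, comps, min_n=30)
        assert len(aug) == 75  # 25 own + all 50 of nearest sibling (group 2)
        assert provenance == [("A1_1", 25), ("A1_2", 50)]

    def test_already_sufficient_is_noop(self):
        dend = _chain_dendrogram()
        comps = pd.DataFrame(
            [[10, 50, 20, 10, 5, 3, 2, 1]] * 40,
            columns=list(WENTWORTH_FRACTIONS) + ["physical_code"],
        )
        aug, provenance = augment_from_dendrogram(GroupKey("A1", 1), dend, comps, min_n=30)
        assert len(aug) == 40 and provenance == [("A1_1", 40)]

    def test_order_follows_cophenetic_proximity(self):
        dend = _chain_dendrogram()
        assert augmentation_order(1, dend) == [2, 3, 4]
        assert augmentation_order(4, dend)[-1] != 4

    def test_exhausted_groups_still_short_raises(self):
        dend = _chain_dendrogram()
        comps = pd.DataFrame(
            [[10, 50, 20, 10, 5, 3, 2, 1]] * 3,
            columns=list(WENTWORTH_FRACTIONS) + ["physical_code"],
        )
        with pytest.raises(NeedsAugmentation):
            augment_from_dendrogram(GroupKey("A1", 1), dend, comps, min_n=30)


class TestMvdisp:
    def test_symmetric_groups_both_unity(self):
        rng = np.random.default_rng(4)
        block = rng.dirichlet(np.ones(7), size=15) * 100
        comps = _comp_frame(np.vstack([block, block]))
        labels = ["a"] * 15 + ["b"] * 15
        disp = mvdisp(comps, labels)
        assert disp["a"] == pytest.approx(1.0, abs=1e-9)
        assert disp["b"] == pytest.approx(1.0, abs=1e-9)

    def test_tight_below_one_diffuse_above(self):
        rng = np.random.default_rng(5)
        base = np.array([5.0, 10, 25, 30, 15, 10, 5])
        tight = base + rng.standard_normal((20, 7)) * 0.1
        diffuse = base + rng.standard_normal((20, 7)) * 8.0
        comps = _comp_frame(np.clip(np.vstack([tight, diffuse]), 0.01, None))
        disp = mvdisp(comps, ["t"] * 20 + ["d"] * 20)
        assert disp["t"] < 1.0 < disp["d"]

    def test_pair_weighted_mean_is_unity(self, default_dataset):
        ds = default_dataset
        went = ds.table.wentworth()[list(WENTWORTH_FRACTIONS)]
        labels = pd.Series(ds.truth.faunal_group, index=went.index)
        disp = mvdisp(went, labels)
        sizes = labels.value_counts()
        weights = np.array([sizes[g] * (sizes[g] - 1) / 2 for g in disp.index])
        weighted = float((disp.to_numpy() * weights).sum() / weights.sum())
        assert weighted == pytest.approx(1.0, abs=1e-9)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.dirichlet(np.ones(7), size=10) * 100
        b = rng.dirichlet(np.ones(7) * 5, size=12) * 100
        comps = _comp_frame(np.vstack([a, b]))
        labels = ["a"] * 10 + ["b"] * 12
        d1 = mvdisp(comps, labels)
        comps2 = _comp_frame(np.vstack([a, a, b]))
        labels2 = ["a"] * 20 + ["b"] * 12
        d2 = mvdisp(comps2, labels2)
        # ranks of duplicated dissimilarities are unchanged relative to b's
        assert np.sign(d1["a"] - 1) == np.sign(d2["a"] - 1)

    def test_singleton_group_excluded(self):
        comps = _comp_frame([[10, 50, 20, 10, 5, 3, 2]] * 3)
        with pytest.warns(UserWarning, match="single sample"):
            disp = mvdisp(comps, ["a", "a", "solo"])
        assert "solo" not in disp.index


class TestCumulativeDistribution:
    def test_single_sample_is_own_curve(self):
        std = pd.DataFrame([{0.0: 40.0, 0.125: 60.0}]).fillna(0.0)
        curve = cumulative_distribution(std)
        assert curve.iloc[0] == 40.0
        assert curve.iloc[-1] == pytest.approx(100.0)

    def test_non_decreasing_and_conserving(self, default_dataset):
        std = default_dataset.table.standard_psd()
        curve = cumulative_distribution(std)
        assert (np.diff(curve.to_numpy()) >= -1e-12).all()
        assert curve.iloc[-1] == pytest.approx(std.sum(axis=1).mean(), abs=1e-9)


class TestWentworthSummary:
    def test_reference_group_means_aggregate(self):
        mean = np.array([1.0, 4.3, 24.2, 26.8, 22.8, 12.4, 8.6])
        env = SedimentEnvelope(key=GroupKey("B1a", 4), n=948, mean=mean,
                               cov=np.eye(7))
        s = wentworth_summary(env)
        assert s["sand_pct"] == pytest.approx(55.3)
        assert s["gravel_pct"] == pytest.approx(43.8)
        assert s["mud_pct"] == pytest.approx(1.0)
        assert "gravel" in s["description"]

    @pytest.mark.parametrize(
        "mud,sand,gravel,expected",
        [
            (0.0, 100.0, 0.0, "sand"),
            (4.0, 46.0, 50.0, "sandy gravel"),
            (0.0, 0.0, 90.0, "gravel"),
            (60.0, 35.0, 5.0, "gravelly sandy mud"),
        ],
    )
    def test_descriptions(self, mud, sand, gravel, expected):
        assert describe_sediment(mud, sand, gravel) == expected

    def test_slightly_gravelly_modifiers(self):
        out = describe_sediment(0.5, 96.5, 3.0)
        assert out.startswith("slightly gravelly")
        assert out.endswith("sand")
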