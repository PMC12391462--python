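import numpy as np
import pytest

from placeseq import plasticity as pl
from placeseq.session import SpikeTrain
from placeseq.synthetic import apply_remapping_plan, gaussian_tuning


class TestPlasticElastic:
    def test_fully_plastic_unit_scores_plus_one(self):
        pre = np.array([[1.0, 0.0, 0.0, 0.0]])
        det = np.array([[0.0, 0.0, 1.0, 0.0]])
        res = pl.plastic_elastic(pre, det, post=det.copy())
        assert res.index[0] == pytest.approx(1.0)
        assert res.label[0] == "plastic"

    def test_fully_elastic_unit_scores_minus_one(self):
        pre = np.array([[1.0, 0.0, 0.0, 0.0]])
        det = np.array([[0.0, 0.0, 1.0, 0.0]])
        res = pl.plastic_elastic(pre, det, post=pre.copy())
        assert res.index[0] == pytest.approx(-1.0)
        assert res.label[0] == "elastic"

    def test_stable_unit_scores_zero(self):
        v = np.array([[0.3, 0.8, 0.1, 0.5]])
        res = pl.plastic_elastic(v, v, v)
        assert res.index[0] == pytest.approx(0.0)
        assert res.label[0] == "neutral"

    def test_antisymmetric_under_pre_det_swap(self, rng):
        pre = rng.random((20, 30))
        det = rng.random((20, 30))
        post = rng.random((20, 30))
        a = pl.plastic_elastic(pre, det, post).index
        b = pl.plastic_elastic(det, pre, post).index
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_planted_fraction_recovery_within_tolerance(self, rng):
        pre, _ = gaussian_tuning(200, 300, rng)
        det, post, labels = apply_remapping_plan(
            pre, {"stable": 0.5, "plastic": 0.2, "elastic": 0.3}, rng)
        res = pl.plastic_elastic(pre, det, post)
        est_plastic = np.mean(res.label == "plastic")
        est_elastic = np.mean(res.label == "elastic")
        assert abs(est_plastic - 0.2) <= 0.07
        assert abs(est_elastic - 0.3) <= 0.07


class TestSessionPairGroups:
    def test_group_labels_and_lags(self, rng):
        tunings = {f"Run{k}": rng.random((5, 20)) for k in range(1, 5)}
        df = pl.session_pair_similarity_groups(
            tunings, detour_session="Run2",
            session_order=["Run1", "Run2", "Run3", "Run4"])
        pair = df[(df.session_a == "Run1") & (df.session_b == "Run2")]
        assert (pair.group == "before-vs-detour").all()
        pair = df[(df.session_a == "Run3") & (df.session_b == "Run4")]
        assert (pair.group == "no-detour").all()
        pair = df[(df.session_a == "Run1") & (df.session_b == "Run4")]
        assert (pair.group == "before-vs-after").all()
        assert set(df.lag) == {1, 2, 3}

    def test_single_session_errors(self, rng):
        with pytest.raises(ValueError, match=">= 2 sessions"):
            pl.session_pair_similarity_groups({"Run1": rng.random((3, 5))}, "Run1")

    def test_detour_remap_lowers_before_vs_detour_similarity(self, rng):
        pre, _ = gaussian_tuning(40, 300, rng)
        det, post, _lab = apply_remapping_plan(pre, {"plastic": 1.0}, rng)
        tunings = {"Run1": pre, "Run2": det, "Run3": post}
        df = pl.session_pair_similarity_groups(
            tunings, "Run2", session_order=["Run1", "Run2", "Run3"])
        lag1 = df[df.lag == 1]
        bvd = lag1[lag1.group == "before-vs-detour"].cosine.mean()
        avd = lag1[lag1.group == "after-vs-detour"].cosine.mean()
        assert bvd < avd  # post == det under an all-plastic plan


class TestAssemblies:
    def test_mp_bound_closed_form(self, rng):
        Z = rng.normal(size=(10, 1000))
        det = pl.AssemblyDetector().fit(Z)
        assert det.mp_bound_ == pytest.approx((1 + np.sqrt(10 / 1000)) ** 2)

    def test_pure_noise_rarely_yields_assemblies(self):
        n_with = 0
        for seed in range(20):
            Z = np.random.default_rng(seed).normal(size=(20, 5000))
            Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
            n_with += pl.AssemblyDetector().fit(Z).n_assemblies_ > 0
        assert n_with <= 1  # 0 assemblies in >= 95% of seeds

    def test_planted_cofiring_group_recovered(self, rng):
        Z = rng.normal(size=(40, 5000))
        Z[:5] += rng.normal(size=5000)  # shared drive for units 0-4
        Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
        det = pl.AssemblyDetector().fit(Z)
        assert det.n_assemblies_ == 1
        np.testing.assert_array_equal(det.members_[0], np.arange(5))
        assert det.eigenvalues_[0] > det.mp_bound_

    def test_rank_one_duplicated_population(self, rng):
        base = rng.normal(size=2000)
        Z = np.tile(base, (6, 1)) + 0.01 * rng.normal(size=(6, 2000))
        Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
        det = pl.AssemblyDetector().fit(Z)
        assert det.n_assemblies_ == 1

    def test_fewer_bins_than_units_errors(self, rng):
        with pytest.raises(ValueError, match="Marchenko"):
            pl.AssemblyDetector().fit(rng.normal(size=(10, 8)))

    def test_sign_convention_deterministic(self, rng):
        Z = rng.normal(size=(15, 3000))
        Z[:4] += 0.8 * rng.normal(size=3000)
        det = pl.AssemblyDetector().fit(Z)
        for w in det.patterns_:
            assert w[np.argmax(np.abs(w))] > 0


class TestActivation:
    def test_single_unit_bin_contributes_nothing(self):
        w = np.zeros(6)
        w[:2] = 1 / np.sqrt(2)
        Z = np.zeros((6, 4))
        Z[0, 1] = 3.0  # only one member active
        act = pl.assembly_activation(w, Z)
        assert act[1] == pytest.approx(0.0)

    def test_coactive_members_positive(self):
        w = np.zeros(6)
        w[:2] = 1 / np.sqrt(2)
        Z = np.zeros((6, 3))
        Z[0, 2] = Z[1, 2] = 2.0
        act = pl.assembly_activation(w, Z)
        assert act[2] > 0

    def test_transform_matches_single_pattern_activation(self, rng):
        Z = rng.normal(size=(10, 500))
        Z[:3] += rng.normal(size=500)
        Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
        det = pl.AssemblyDetector().fit(Z)
        if det.n_assemblies_:
            np.testing.assert_allclose(
                det.transform(Z)[0],
                pl.assembly_activation(det.patterns_[0], Z),
            )

    def test_planted_reactivations_align_with_events(self, rng):
        # quiet background; bursts of the member trio at known bins
        Z = 0.1 * rng.normal(size=(20, 2000))
        events = [100, 500, 900, 1500]
        for b in events:
            Z[:3, b] += 3.0
        Zn = (Z - Z.mean(1, keepdims=True)) / Z.std(1, keepdims=True)
        det = pl.AssemblyDetector().fit(Zn)
        assert det.n_assemblies_ >= 1
        act = det.transform(Zn)[0]
        top = np.argsort(act)[-4:]
        assert set(top) == set(events)


class TestAssemblySimilarity:
    def test_identical_sets_give_one(self, rng):
        P = rng.normal(size=(3, 20))
        assert pl.assembly_similarity_across_sessions(P, P) == pytest.approx(1.0)

    def test_disjoint_random_sets_match_permutation_null(self, rng):
        # max-of-correlations has a positive expected value under the null;
        # estimate it by a permutation oracle and compare
        sims, nulls = [], []
        for _ in range(40):
            A = rng.normal(size=(2, 30))
            B = rng.normal(size=(4, 30))
            sims.append(pl.assembly_similarity_across_sessions(A, B))
            Bp = rng.permuted(B, axis=1)
            nulls.append(pl.assembly_similarity_across_sessions(A, Bp))
        assert abs(np.mean(sims) - np.mean(nulls)) < 0.1


class TestRegressionVarianceExplained:
    def _regressors(self, rng, n=50, f=40):
        return {k: np.abs(rng.normal(size=(n, f)))
                for k in ("Pre", "Det", "OT", "T1", "T3")}

    def test_post_from_pre_only(self, rng):
        regs = self._regressors(rng)
        post = 2.0 * regs["Pre"] + 0.05 * rng.normal(size=regs["Pre"].shape)
        out = pl.regression_variance_explained(post, regs, n_shuffles=100, rng=rng)
        assert out["shares"]["Pre"] > 1.0
        assert out["shares"]["Det"] < 0.01
        assert out["percentiles"]["Pre"] > 95
        assert 5 < out["percentiles"]["Det"] < 95

    def test_post_equals_det_dominant(self, rng):
        regs = self._regressors(rng)
        post = regs["Det"].copy()
        out = pl.regression_variance_explained(post, regs, n_shuffles=50, rng=rng)
        assert out["shares"]["Det"] == max(out["shares"].values())

    def test_shares_nonnegative_since_models_nest(self, rng):
        regs = self._regressors(rng, n=30, f=20)
        post = np.abs(rng.normal(size=(30, 20)))
        out = pl.regression_variance_explained(post, regs, n_shuffles=20, rng=rng)
        for v in out["shares"].values():
            assert v >= -1e-10

    def test_missing_regressor_errors(self, rng):
        with pytest.raises(ValueError, match="missing regressor"):
            pl.regression_variance_explained(
                np.ones((4, 5)), {"Pre": np.ones((4, 5))})


class TestDriftStablePrediction:
    def _model_from(self, seqs, n_units):
        from placeseq.motifs import MarkovSequenceModel

        return MarkovSequenceModel(n_units).fit(seqs)

    def test_identical_models_give_identical_scores(self, rng):
        U = 20
        run4 = np.zeros((U, 60))
        run1 = np.zeros((U, 60))
        for i in range(U):
            run4[i, 3 * i] = 10.0
            # first half stable (same peak), second half drifted
            run1[i, 3 * i if i < U // 2 else (3 * i + 30) % 60] = 10.0
        seqs = [tuple(rng.permutation(U)[:6]) for _ in range(300)]
        m = self._model_from(seqs, U)
        out = pl.drift_stable_prediction(run4, run1, m, m, n_shuffles=2000,
                                         rng=rng)
        for grp in ("stable", "drift"):
            assert out[grp]["Sleep1"]["norm_prob"] == pytest.approx(
                out[grp]["Sleep3"]["norm_prob"])

    def test_sleep3_seeded_with_drift_sequence_scores_higher(self, rng):
        U = 20
        run4 = np.zeros((U, 60))
        run1 = np.zeros((U, 60))
        for i in range(U):
            run4[i, 3 * i] = 10.0
            run1[i, 3 * i if i < U // 2 else (3 * i + 30) % 60] = 10.0
        drift_units = tuple(range(U // 2, U))  # peak order = unit order
        sleep3_seqs = [drift_units] * 100 + \
            [tuple(rng.permutation(U)[:6]) for _ in range(100)]
        sleep1_seqs = [tuple(rng.permutation(U)[:6]) for _ in range(200)]
        m1 = self._model_from(sleep1_seqs, U)
        m3 = self._model_from(sleep3_seqs, U)
        out = pl.drift_stable_prediction(run4, run1, m1, m3, n_shuffles=2000,
                                         rng=rng)
        assert out["drift"]["Sleep3"]["norm_prob"] > \
            out["drift"]["Sleep1"]["norm_prob"]
        assert out["drift"]["Sleep3"]["percentile"] > 95

    def test_empty_drift_branch_flagged(self, rng):
        U = 10
        maps = np.zeros((U, 30))
        for i in range(U):
            maps[i, 3 * i] = 10.0
        seqs = [tuple(rng.permutation(U)[:5]) for _ in range(100)]
        m = self._model_from(seqs, U)
        out = pl.drift_stable_prediction(maps, maps.copy(), m, m, rng=rng)
        assert out["drift"].get("empty", False)
        assert out["stable"]["n_units"] == U
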