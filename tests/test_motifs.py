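import numpy as np
import pytest
from scipy.stats import chisquare

from placeseq import motifs as mf
from placeseq.brainstates import Frame


def _frame(order, t0=0.0, dt=0.02):
    members = [(u, t0 + k * dt) for k, u in enumerate(order)]
    return Frame(t0, t0 + len(order) * dt, members)


class TestFrameSequence:
    def test_center_of_mass_ordering(self):
        f = Frame(0.0, 0.3, [(2, 0.01), (0, 0.10), (2, 0.05), (1, 0.20)])
        seq = mf.frame_sequence(f)
        # unit 2 CoM = 0.03, unit 0 = 0.10, unit 1 = 0.20
        assert seq.units == (2, 0, 1)

    def test_com_tie_broken_by_unit_id(self):
        f = Frame(0.0, 0.1, [(5, 0.05), (3, 0.05)])
        assert mf.frame_sequence(f).units == (3, 5)


class TestTransitionModel:
    def test_counts_give_equal_conditionals(self):
        m = mf.fit_transition_model([(0, 1), (0, 2)], n_units=3)
        assert m.p2_[0, 1] == pytest.approx(0.5)
        assert m.p2_[0, 2] == pytest.approx(0.5)
        assert m.p1_[0] == pytest.approx(2 / 4)

    def test_zero_entries_clipped_to_min_nonzero(self):
        m = mf.fit_transition_model([(0, 1), (0, 1), (0, 2)], n_units=3)
        # P2(1|0)=2/3, P2(2|0)=1/3; zeros elsewhere -> min nonzero = 1/3
        assert m.p2_.min() == pytest.approx(1 / 3)
        assert m.clipped_["zeros"] > 0

    def test_all_singletons_error(self):
        with pytest.raises(ValueError, match="no transitions"):
            mf.fit_transition_model([(0,), (1,)], n_units=2)

    def test_planted_chain_recovered(self, rng):
        U = 12
        P = rng.dirichlet(np.ones(U), size=U)
        seqs = []
        for _ in range(2000):
            s = [int(rng.integers(U))]
            for _ in range(6):
                p = P[s[-1]].copy()
                p[s] = 0
                if p.sum() <= 0:
                    break
                s.append(int(rng.choice(U, p=p / p.sum())))
            seqs.append(tuple(s))
        fit = mf.MarkovSequenceModel(U).fit(seqs)
        # compare against the no-repeat-renormalized first-step conditionals:
        # the first transition of each sequence is an unconstrained draw
        firsts = np.zeros((U, U))
        for s in seqs:
            if len(s) >= 2:
                firsts[s[0], s[1]] += 1
        for i in range(U):
            n_i = firsts[i].sum()
            if n_i < 100:
                continue
            renorm = P[i].copy()
            renorm[i] = 0.0  # no-repeat constraint bars the self-transition
            renorm = renorm / renorm.sum()
            emp = firsts[i] / n_i
            # ~150 draws per row: 3 sigma of a p~0.2 cell is ~0.1
            assert np.max(np.abs(emp - renorm)) < 0.12


class TestSequenceProbability:
    def test_two_step_hand_example(self):
        m = mf.MarkovSequenceModel(2)
        m.p1_ = np.array([0.5, 0.5])
        m.p2_ = np.array([[0.5, 0.5], [0.5, 0.5]])
        m.log_p1_ = np.log(m.p1_)
        m.log_p2_ = np.log(m.p2_)
        assert m.probability((0, 1)) == pytest.approx(0.25)
        assert m.probability((0, 1), normalized=True) == pytest.approx(0.5)

    def test_length_one_is_p1(self):
        m = mf.fit_transition_model([(0, 1), (1, 0)], n_units=2)
        assert m.probability((0,)) == pytest.approx(m.p1_[0])

    def test_matches_naive_product_oracle_in_log_space(self, rng):
        seqs = [tuple(rng.permutation(10)[:5]) for _ in range(200)]
        m = mf.fit_transition_model(seqs, n_units=10)
        for _ in range(20):
            s = tuple(rng.permutation(10)[:6])
            # independent oracle: explicit scalar product in log space
            expected = np.log(m.p1_[s[0]])
            for a, b in zip(s[:-1], s[1:]):
                expected += np.log(m.p2_[a, b])
            assert m.log_probability(s) == pytest.approx(expected, abs=1e-12)


class TestSequenceSignificance:
    def test_random_sequences_uniform_percentiles(self, rng):
        seqs = [tuple(rng.permutation(15)[:6]) for _ in range(400)]
        m = mf.fit_transition_model(seqs, n_units=15)
        pcts = [m.significance(tuple(rng.permutation(15)[:6]),
                               n_shuffles=2000, rng=rng) for _ in range(300)]
        sig_frac = np.mean(np.asarray(pcts) > 95.0)
        assert 0.02 < sig_frac < 0.09  # ~5% chance level
        assert 35 < np.mean(pcts) < 65

    def test_planted_motif_exceeds_95th_percentile(self, rng):
        motif = (0, 1, 2, 3, 4, 5)
        seqs = [motif] * 50 + [tuple(rng.permutation(12)[:6]) for _ in range(50)]
        m = mf.fit_transition_model(seqs, n_units=12)
        assert m.significance(motif, n_shuffles=5000, rng=rng) > 95

    def test_uniform_model_is_degenerate_tie(self):
        m = mf.MarkovSequenceModel(8)
        m.p1_ = np.full(8, 1 / 8)
        m.p2_ = np.full((8, 8), 1 / 7)
        m.log_p1_ = np.log(m.p1_)
        m.log_p2_ = np.log(m.p2_)
        # all same-length sequences share one probability: strict-greater
        # percentile is 0 (tie convention)
        assert m.significance((0, 1, 2), n_shuffles=500) == 0.0


class TestPredictThetaCycles:
    def test_self_fit_cycles_score_near_ceiling(self, rng):
        # cycles drawn from a strongly structured process, model fit on them
        base = list(range(10))
        cycles = [tuple(base[k:k + 6]) for k in range(5) for _ in range(40)]
        m = mf.fit_transition_model(cycles, n_units=10)
        out = mf.predict_theta_cycles(m, cycles, n_shuffles=2000, rng=rng)
        assert out["fraction"] > 0.9
        assert out["p"] < 1e-10

    def test_cell_id_shuffled_model_drops_to_chance(self, rng):
        base = list(range(12))
        cycles = [tuple(base[k:k + 6]) for k in range(7) for _ in range(40)]
        m = mf.fit_transition_model(cycles, n_units=12)
        m_shuf = m.cell_id_shuffled(rng)
        out = mf.predict_theta_cycles(m_shuf, cycles, n_shuffles=2000, rng=rng)
        assert out["fraction"] < 0.25  # far below the self-fit ceiling


class TestTuplets:
    def test_contiguous_candidate_enumeration(self):
        subs = mf._subsequences((0, 1, 2))
        assert set(subs) == {(0, 1), (1, 2), (0, 1, 2)}

    def test_planted_pair_detected_and_reverse_not(self, rng):
        frames = []
        for _ in range(50):
            rest = list(rng.choice(np.arange(2, 20), 4, replace=False))
            frames.append(tuple([0, 1] + rest))
        tuplets = mf.extract_tuplets(frames, 20, n_shuffle_sleeps=200, rng=rng)
        by_units = {t.units: t for t in tuplets}
        assert by_units[(0, 1)].significant
        assert (1, 0) not in by_units or not by_units[(1, 0)].significant

    def test_order_free_sleep_near_five_percent_false_positives(self, rng):
        frames = [tuple(rng.permutation(20)[:6]) for _ in range(150)]
        tuplets = mf.extract_tuplets(frames, 20, n_shuffle_sleeps=200, rng=rng)
        if tuplets:
            frac = np.mean([t.significant for t in tuplets])
            assert frac < 0.15

    def test_no_frames_empty(self):
        assert mf.extract_tuplets([], 5) == []

    def test_shuffle_sleep_preserves_unit_frequencies(self, rng):
        seqs = [tuple(rng.choice(20, size=6, replace=False,
                                 p=np.linspace(1, 3, 20) / np.linspace(1, 3, 20).sum()))
                for _ in range(400)]
        weights = np.zeros(20)
        for s in seqs:
            for u in s:
                weights[u] += 1
        pooled = np.zeros(20)
        for _ in range(5):
            for s in mf._shuffle_sleep(seqs, weights, rng):
                for u in s:
                    pooled[u] += 1
        expected = weights / weights.sum() * pooled.sum()
        stat = chisquare(pooled, expected)
        assert stat.pvalue > 0.001


class TestTupletRecruitment:
    def test_template_cycles_recruit_planted_tuplets(self, rng):
        frames = []
        for _ in range(60):
            rest = list(rng.choice(np.arange(3, 20), 4, replace=False))
            frames.append(tuple([0, 1, 2] + rest))
        tuplets = mf.extract_tuplets(frames, 20, n_shuffle_sleeps=200, rng=rng)
        cycles_hit = [(0, 1, 2, 7, 9)] * 20
        cycles_null = [tuple(rng.permutation(np.arange(3, 20))[:5])
                       for _ in range(20)]
        assert mf.tuplet_recruitment(tuplets, cycles_hit) > \
            mf.tuplet_recruitment(tuplets, cycles_null)

    def test_no_tuplets_zero_recruitment(self):
        assert mf.tuplet_recruitment([], [(0, 1, 2)]) == 0.0


class TestPairwiseOrder:
    def test_deterministic_order_gives_unit_probability(self):
        M = mf.pairwise_order_matrix([(0, 1)] * 10, 3)
        assert M[0, 1] == 1.0
        assert M[1, 0] == 0.0
        assert np.isnan(M[0, 2])

    def test_antisymmetry_for_observed_pairs(self, rng):
        seqs = [tuple(rng.permutation(10)[:5]) for _ in range(300)]
        M = mf.pairwise_order_matrix(seqs, 10)
        obs = np.isfinite(M)
        np.testing.assert_allclose(M[obs] + M.T[obs], 1.0)

    def test_random_orders_score_chance_level(self, rng):
        M = mf.pairwise_order_matrix(
            [tuple(rng.permutation(15)[:6]) for _ in range(2000)], 15)
        cycles = [tuple(rng.permutation(15)[:5]) for _ in range(3000)]
        assert abs(mf.score_cycle_orders(M, cycles)) < 0.01

    def test_consistent_ordering_scores_positive(self, rng):
        base = tuple(range(10))
        frames = [base] * 100
        M = mf.pairwise_order_matrix(frames, 10)
        cycles = [tuple(sorted(rng.permutation(10)[:5])) for _ in range(50)]
        assert mf.score_cycle_orders(M, cycles) == pytest.approx(0.5)


class TestFrameCycleRankCorrelation:
    def test_identical_orderings_all_significant(self, rng):
        seq = tuple(range(8))
        out = mf.frame_cycle_rank_correlation([seq] * 3, [seq] * 3,
                                              n_perm=200, rng=rng)
        assert out["fraction"] == 1.0

    def test_pairs_below_common_unit_gate_excluded(self, rng):
        out = mf.frame_cycle_rank_correlation(
            [(0, 1, 2, 3)], [(0, 1, 9, 8)], min_common=5, n_perm=50, rng=rng)
        assert out["n_pairs"] == 0

    def test_independent_orders_near_five_percent(self, rng):
        frames = [tuple(rng.permutation(10)) for _ in range(15)]
        cycles = [tuple(rng.permutation(10)) for _ in range(15)]
        out = mf.frame_cycle_rank_correlation(frames, cycles, n_perm=200, rng=rng)
        assert out["fraction"] < 0.15
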