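import numpy as np
import pytest

from placeseq import placefields as pf
from placeseq.session import SpikeTrain, TrajectorySession
from placeseq.synthetic import BIN_CM


def _straight_trajectory(n=3000, speed=30.0, fs=30.0):
    """Constant-speed sweep 0 -> n*speed/fs cm (single direction)."""
    t = np.arange(n) / fs
    x = speed * t
    return TrajectorySession(
        t=t, pos_2d=np.column_stack([x, np.zeros(n)]), lin_pos=x,
        track_id=np.ones(n, np.int64), segment_id=np.full(n, "seg"),
        direction=np.ones(n, np.int64), velocity=np.full(n, speed),
    )


class TestComputePlaceMaps:
    def test_rate_is_counts_over_occupancy(self):
        # 0.5 s occupancy per 2 cm bin at 4 cm/s, one spike in one bin
        fs, speed = 30.0, 4.0
        n = 1500
        t = np.arange(n) / fs
        x = speed * t
        traj = TrajectorySession(
            t=t, pos_2d=np.column_stack([x, 0 * x]), lin_pos=x,
            track_id=np.ones(n, np.int64), segment_id=np.full(n, "s"),
            direction=np.ones(n, np.int64), velocity=np.full(n, 12.0),
        )
        spike_t = 10.0 / speed  # spike exactly at 10 cm -> bin 5
        maps = pf.compute_place_maps({0: SpikeTrain(0, [spike_t])}, traj,
                                     smooth_cm=1e-9)
        occ_per_bin = BIN_CM / speed
        assert maps.rate[0, 5] == pytest.approx(1.0 / occ_per_bin, rel=1e-6)

    def test_mass_conservation(self, run_session):
        _spec, sess, _gt = run_session
        spikes = sess.pyramidal_spikes()
        maps = pf.compute_place_maps(spikes, sess.trajectory)
        # total raw counts equal the number of velocity-filtered spikes
        vel_at = sess.trajectory.velocity_at
        for r, u in enumerate(maps.unit_ids):
            n_filtered = int(np.sum(vel_at(spikes[u].times) > 10.0))
            assert abs(maps.counts[r].sum() - n_filtered) <= 2  # edge samples

    def test_empty_filter_errors(self):
        traj = _straight_trajectory()
        traj.velocity[:] = 0.0
        with pytest.raises(ValueError, match="no running samples"):
            pf.compute_place_maps({0: SpikeTrain(0, [1.0])}, traj)

    def test_field_recovery_across_population(self, run_session):
        _spec, sess, gt = run_session
        maps = pf.compute_place_maps(sess.pyramidal_spikes(), sess.trajectory)
        loc_err, rate_err = [], []
        for (i, c, sg, pk) in gt.field_params:
            peak_bin = maps.rate[i].argmax()
            loc_err.append(abs(maps.bin_centers[peak_bin] - c))
            rate_err.append(abs(maps.rate[i].max() - pk) / pk)
        assert np.median(loc_err) <= 4.0
        assert np.median(rate_err) <= 0.35

    def test_well_sampled_field_recovered_tightly(self):
        # one strong field, many laps: peak within 2 cm and 20% of truth
        from placeseq.session import MazeConfig
        from placeseq.synthetic import GeneratorSpec, generate_run_session

        spec = GeneratorSpec(n_units=1, n_laps=24, pause_s=0.0, seed=6)
        tuning = np.zeros((1, 300))
        x = (np.arange(300) + 0.5) * 2.0
        tuning[0] = 15.0 * np.exp(-0.5 * ((x - 301.0) / 10.0) ** 2)
        sess, _gt = generate_run_session(spec, MazeConfig(), "R", tuning=tuning)
        maps = pf.compute_place_maps(sess.pyramidal_spikes(), sess.trajectory)
        peak_bin = maps.rate[0].argmax()
        assert abs(maps.bin_centers[peak_bin] - 301.0) <= 2.0
        assert maps.rate[0].max() == pytest.approx(15.0, rel=0.2)


class TestSpatialInformation:
    def test_flat_map_zero_bits(self):
        assert pf.spatial_information(np.full(8, 3.0), np.ones(8)) == pytest.approx(0.0)

    def test_single_hot_bin_of_four_is_two_bits(self):
        # all rate in 1 of 4 equally occupied bins: SI = log2(4) = 2
        si = pf.spatial_information(np.array([8.0, 0, 0, 0]), np.ones(4))
        assert si == pytest.approx(2.0)

    def test_silent_map_undefined(self):
        assert np.isnan(pf.spatial_information(np.zeros(4), np.ones(4)))

    def test_nonnegative_on_random_maps(self, rng):
        for _ in range(50):
            rate = rng.random(20) * 10
            occ = rng.random(20) + 0.1
            assert pf.spatial_information(rate, occ) >= -1e-12


class TestStability:
    def test_deterministic_identical_laps_give_one(self, run_session):
        _spec, sess, _gt = run_session
        stab = pf.within_session_stability(
            sess.pyramidal_spikes(), sess.trajectory, n_repeats=5,
        )
        # generator fields are stationary across laps: high split-half similarity
        assert np.nanmedian(stab) > 0.8

    def test_single_lap_errors(self):
        traj = _straight_trajectory()
        with pytest.raises(ValueError, match="laps"):
            pf.within_session_stability({0: SpikeTrain(0, [1.0])}, traj, n_repeats=2)


class TestSegmentPairSimilarity:
    def test_identical_maps_correlate_above_shuffle(self, rng):
        rate = rng.random((12, 25)) * 8 + 1
        m = pf.PlaceMapSet(rate=rate, occupancy=np.ones(25),
                           valid=np.ones(25, bool), unit_ids=np.arange(12))
        res = pf.segment_pair_similarity(m, m, n_shuffles=200, rng=rng)
        assert np.all(res.correlations > 0.999)
        assert res.pvalue() < 0.01

    def test_independent_maps_match_shuffle_distribution(self, rng):
        from scipy.stats import ks_2samp

        a = pf.PlaceMapSet(rate=rng.random((30, 25)) * 8,
                           occupancy=np.ones(25), valid=np.ones(25, bool),
                           unit_ids=np.arange(30))
        b = pf.PlaceMapSet(rate=rng.random((30, 25)) * 8,
                           occupancy=np.ones(25), valid=np.ones(25, bool),
                           unit_ids=np.arange(30))
        res = pf.segment_pair_similarity(a, b, n_shuffles=500, rng=rng)
        assert ks_2samp(res.correlations, res.shuffle).pvalue > 0.05

    def test_bin_count_mismatch_errors(self, rng):
        a = pf.PlaceMapSet(rate=rng.random((5, 25)), occupancy=np.ones(25),
                           valid=np.ones(25, bool), unit_ids=np.arange(5))
        b = pf.PlaceMapSet(rate=rng.random((5, 30)), occupancy=np.ones(30),
                           valid=np.ones(30, bool), unit_ids=np.arange(5))
        with pytest.raises(ValueError, match="mismatch"):
            pf.segment_pair_similarity(a, b)

    def test_rebin_matches_stretched_resolution(self, rng):
        # 150 cm at 2 cm bins (75) rebinned to 25 bins = 6 cm resolution
        m = pf.PlaceMapSet(rate=rng.random((5, 75)), occupancy=np.ones(75),
                           valid=np.ones(75, bool), unit_ids=np.arange(5))
        r = pf.rebin_to(m, 25)
        assert r.n_bins == 25
        assert r.bin_cm == pytest.approx(6.0)


class TestPopulationVector:
    def test_diagonal_is_one_for_identical_sets(self, rng):
        rate = rng.random((10, 30)) + 0.1
        m = pf.PlaceMapSet(rate=rate, occupancy=np.ones(30),
                           valid=np.ones(30, bool), unit_ids=np.arange(10))
        S = pf.population_vector_similarity(m, m)
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)

    def test_swap_transposes(self, rng):
        a = pf.PlaceMapSet(rate=rng.random((10, 20)) + 0.1, occupancy=np.ones(20),
                           valid=np.ones(20, bool), unit_ids=np.arange(10))
        b = pf.PlaceMapSet(rate=rng.random((10, 25)) + 0.1, occupancy=np.ones(25),
                           valid=np.ones(25, bool), unit_ids=np.arange(10))
        np.testing.assert_allclose(
            pf.population_vector_similarity(a, b),
            pf.population_vector_similarity(b, a).T,
        )

    def test_orthogonal_populations_near_zero(self):
        a_rate = np.zeros((10, 5))
        a_rate[:5] = 1.0
        b_rate = np.zeros((10, 5))
        b_rate[5:] = 1.0
        a = pf.PlaceMapSet(rate=a_rate, occupancy=np.ones(5),
                           valid=np.ones(5, bool), unit_ids=np.arange(10))
        b = pf.PlaceMapSet(rate=b_rate, occupancy=np.ones(5),
                           valid=np.ones(5, bool), unit_ids=np.arange(10))
        S = pf.population_vector_similarity(a, b)
        assert np.nanmax(np.abs(S)) < 1e-12

    def test_zero_bin_masked(self, rng):
        rate = rng.random((5, 10)) + 0.1
        rate[:, 3] = 0.0
        m = pf.PlaceMapSet(rate=rate, occupancy=np.ones(10),
                           valid=np.ones(10, bool), unit_ids=np.arange(5))
        S = pf.population_vector_similarity(m, m)
        assert np.all(np.isnan(S[3, :]))


class TestSequenceRankCorrelation:
    def test_identical_and_reversed(self, rng):
        rate = np.zeros((10, 50))
        for i in range(10):
            rate[i, 5 * i] = 10.0
        m = pf.PlaceMapSet(rate=rate, occupancy=np.ones(50),
                           valid=np.ones(50, bool), unit_ids=np.arange(10))
        rev = pf.PlaceMapSet(rate=rate[:, ::-1].copy(), occupancy=np.ones(50),
                             valid=np.ones(50, bool), unit_ids=np.arange(10))
        rho_same, _ = pf.sequence_rank_correlation(m, m)
        rho_rev, _ = pf.sequence_rank_correlation(m, rev)
        assert rho_same == pytest.approx(1.0)
        assert rho_rev == pytest.approx(-1.0)

    def test_random_remap_near_zero_over_repeats(self, rng):
        rhos = []
        for _ in range(30):
            ra = np.zeros((12, 60))
            rb = np.zeros((12, 60))
            pa = rng.permutation(12)
            pb = rng.permutation(12)
            for i in range(12):
                ra[i, 5 * pa[i]] = 10.0
                rb[i, 5 * pb[i]] = 10.0
            a = pf.PlaceMapSet(rate=ra, occupancy=np.ones(60),
                               valid=np.ones(60, bool), unit_ids=np.arange(12))
            b = pf.PlaceMapSet(rate=rb, occupancy=np.ones(60),
                               valid=np.ones(60, bool), unit_ids=np.arange(12))
            rho, _ = pf.sequence_rank_correlation(a, b)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.15


class TestBidirectionality:
    def test_identical_directional_maps_give_one(self, rng):
        rate = rng.random((6, 30)) + 0.1
        m1 = pf.PlaceMapSet(rate=rate, occupancy=np.ones(30),
                            valid=np.ones(30, bool), unit_ids=np.arange(6), direction=1)
        m2 = pf.PlaceMapSet(rate=rate.copy(), occupancy=np.ones(30),
                            valid=np.ones(30, bool), unit_ids=np.arange(6), direction=2)
        np.testing.assert_allclose(pf.bidirectionality(m1, m2), 1.0, atol=1e-12)
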