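"""Observable pipelines on hand-built fixtures and simulated ensembles."""

import numpy as np
import pytest
import scipy.stats

from kinnet.engine import SimulationParams, run_ensemble
from kinnet.kinetics import MotorParams
from kinnet.observables import (
    cargo_velocity,
    classify_fast,
    compute_observables,
    distribution_stats,
    first_passage_times,
    mean_intermotor_distance,
    motor_activity,
    motor_correlations,
)

from conftest import make_record

TIMES = [0.0, 0.1, 0.2, 0.3]


class TestCargoVelocity:
    def test_stationary_cargo_has_zero_velocity(self):
        recs = [make_record(TIMES, [5.0] * 4, [[0, 0]] * 4)]
        _, vc = cargo_velocity(recs, window=0.1)
        np.testing.assert_allclose(vc[1:], 0.0)
        assert np.isnan(vc[0])

    def test_linear_motion_recovers_speed(self):
        x = [100.0 * t for t in TIMES]
        recs = [make_record(TIMES, x, [[0, 0]] * 4)]
        _, vc = cargo_velocity(recs, window=0.1)
        np.testing.assert_allclose(vc[1:], 100.0, rtol=1e-9)

    def test_ensemble_mean_of_two_replicates(self):
        recs = [
            make_record(TIMES, [50.0 * t for t in TIMES], [[0, 0]] * 4),
            make_record(TIMES, [150.0 * t for t in TIMES], [[0, 0]] * 4),
        ]
        _, vc = cargo_velocity(recs, window=0.1)
        np.testing.assert_allclose(vc[1:], 100.0, rtol=1e-9)

    def test_window_shorter_than_stride_rejected(self):
        recs = [make_record(TIMES, [0.0] * 4, [[0, 0]] * 4)]
        with pytest.raises(ValueError):
            cargo_velocity(recs, window=0.01)


class TestMotorCorrelations:
    def test_always_same_mt(self):
        recs = [make_record(TIMES, [0.0] * 4, [[2, 2]] * 4)] * 3
        _, same, diff = motor_correlations(recs)
        np.testing.assert_allclose(same, 1.0)
        np.testing.assert_allclose(diff, 0.0)

    def test_detached_motor_zeroes_both_indicators(self):
        recs = [make_record(TIMES, [0.0] * 4, [[-1, 2]] * 4)]
        _, same, diff = motor_correlations(recs)
        np.testing.assert_allclose(same, 0.0)
        np.testing.assert_allclose(diff, 0.0)

    def test_hand_counted_three_replicate_fixture(self):
        # t0: patterns (same, diff, detached) -> same=1/3, diff=1/3
        # t1: (same, same, diff)              -> same=2/3, diff=1/3
        r1 = make_record(TIMES[:2], [0, 0], [[1, 1], [3, 3]])
        r2 = make_record(TIMES[:2], [0, 0], [[1, 2], [4, 4]])
        r3 = make_record(TIMES[:2], [0, 0], [[-1, 5], [5, 6]])
        _, same, diff = motor_correlations([r1, r2, r3])
        np.testing.assert_allclose(same, [1 / 3, 2 / 3])
        np.testing.assert_allclose(diff, [1 / 3, 1 / 3])


class TestMotorActivity:
    def test_slack_springs_give_zero_activity(self):
        recs = [make_record(TIMES, [0.0] * 4, [[0, 1]] * 4)]
        _, ma = motor_activity(recs)
        np.testing.assert_allclose(ma, 0.0)

    def test_taut_springs_give_full_activity(self):
        recs = [
            make_record(TIMES, [0.0] * 4, [[0, 1]] * 4, motor_forces=[[1.0, 2.0]] * 4)
        ] * 2
        _, ma = motor_activity(recs)
        np.testing.assert_allclose(ma, 1.0)

    def test_one_taut_motor_gives_half(self):
        recs = [
            make_record(TIMES, [0.0] * 4, [[0, 1]] * 4, motor_forces=[[1.5, 0.0]] * 4)
        ] * 3
        _, ma = motor_activity(recs)
        np.testing.assert_allclose(ma, 0.5)


class TestMeanIntermotorDistance:
    def test_both_detached_is_zero(self):
        pos = [[[7.0, 1.0], [7.0, 1.0]]] * 4  # both at the cargo
        recs = [make_record(TIMES, [0.0] * 4, [[-1, -1]] * 4, motor_pos=pos)]
        _, mid = mean_intermotor_distance(recs)
        np.testing.assert_allclose(mid, 0.0)

    def test_fixed_separation(self):
        pos = [[[0.0, 0.0], [80.0, 0.0]]] * 4
        recs = [make_record(TIMES, [0.0] * 4, [[0, 1]] * 4, motor_pos=pos)] * 2
        _, mid = mean_intermotor_distance(recs)
        np.testing.assert_allclose(mid, 80.0)

    def test_hand_computed_mixed_fixture(self):
        r1 = make_record(
            TIMES[:1], [0.0], [[0, 1]], motor_pos=[[[0.0, 0.0], [30.0, 40.0]]]
        )  # 50 nm
        r2 = make_record(
            TIMES[:1], [0.0], [[-1, -1]], motor_pos=[[[2.0, 2.0], [2.0, 2.0]]]
        )  # 0 nm
        _, mid = mean_intermotor_distance([r1, r2])
        np.testing.assert_allclose(mid, [25.0])


class TestFirstPassage:
    def test_engine_flagged_fpt_is_used(self):
        recs = [make_record(TIMES, [0.0] * 4, [[0, 0]] * 4, fpt=12.34)]
        s = first_passage_times(recs, target=10000.0)
        assert s.sample.tolist() == [12.34]
        assert s.censored == 0

    def test_trajectory_crossing_detected_from_displacement(self):
        times = np.arange(0.0, 20.0, 1.0)
        x = 1000.0 * times  # crosses 10000 nm at t=10
        recs = [make_record(times, x, [[0, 0]] * len(times))]
        s = first_passage_times(recs, target=10000.0)
        assert s.sample.tolist() == [10.0]

    def test_noncrossing_trajectory_is_censored(self):
        recs = [
            make_record(TIMES, [0.0] * 4, [[0, 0]] * 4, fpt=10.0),
            make_record(TIMES, [0.0] * 4, [[0, 0]] * 4),  # censored
        ]
        s = first_passage_times(recs, target=10000.0)
        assert s.censored == 1 and s.n_total == 2

    def test_all_censored_sample_raises(self):
        recs = [make_record(TIMES, [0.0] * 4, [[0, 0]] * 4)]
        with pytest.raises(ValueError):
            first_passage_times(recs, target=10000.0)

    def test_summary_statistics_of_known_sample(self):
        recs = [
            make_record(TIMES, [0.0] * 4, [[0, 0]] * 4, fpt=f) for f in (10, 12, 14)
        ]
        s = first_passage_times(recs, target=10000.0)
        assert s.mean == pytest.approx(12.0)
        assert s.std == pytest.approx(np.sqrt(8 / 3), rel=1e-9)  # population, 1.633
        assert s.fast_fraction == pytest.approx(1.0)


class TestDistributionStats:
    def test_symmetric_sample_has_zero_skewness(self):
        mean, mode, std, skew = distribution_stats(np.array([1.0, 2.0, 2.0, 3.0]))
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(2.0)

    def test_mean_of_simple_sample(self):
        assert distribution_stats(np.array([1.0, 2.0, 3.0]))[0] == pytest.approx(2.0)

    def test_fisher_skewness_matches_moment_oracle(self):
        sample = np.array([0.0, 0.0, 0.0, 10.0])
        skew = distribution_stats(sample)[3]
        assert skew == pytest.approx(scipy.stats.skew(sample, bias=True), rel=1e-12)
        assert skew == pytest.approx(2 / np.sqrt(3), rel=1e-9)  # closed form

    def test_mode_is_center_of_fullest_half_second_bin(self):
        sample = np.array([14.2, 14.3, 14.4, 19.9, 2.0])
        mode = distribution_stats(sample)[1]
        assert mode == pytest.approx(14.25)


class TestClassifyFast:
    def test_all_fast(self):
        assert classify_fast(np.array([10.0, 10.0])) == 1.0

    def test_all_censored_counts_as_slow(self):
        assert classify_fast(np.array([]), n_total=5) == 0.0

    def test_boundary_is_inclusive(self):
        assert classify_fast(np.array([10.0, 20.0]), threshold=18.8) == 0.5


@pytest.fixture(scope="module")
def transport_ensemble():
    # a high-Ad (slow-unbinding) setting where directed transport occurs
    p = SimulationParams(
        structure="NRS",
        n_mts=80,
        duration=8.0,
        n_replicates=30,
        motor=MotorParams(Ad=20.0),
    )
    return run_ensemble(p, master_seed=17)


class TestEnsembleProperties:
    def test_correlations_are_non_complementary(self, transport_ensemble):
        _, same, diff = motor_correlations(transport_ensemble)
        assert np.all(same + diff <= 1.0 + 1e-12)
        assert np.all((same >= 0) & (same <= 1) & (diff >= 0) & (diff <= 1))

    def test_activity_and_velocity_profiles_correlate(self, transport_ensemble):
        obs = compute_observables(transport_ensemble, window=0.5)
        sel = obs.times >= 1.0  # post-transient window
        r, _ = scipy.stats.pearsonr(obs.ma[sel], obs.vc[sel])
        assert r > 0

    def test_mid_nonnegative_and_activity_bounded(self, transport_ensemble):
        obs = compute_observables(transport_ensemble)
        assert np.all(obs.mid >= 0)
        assert np.all((obs.ma >= 0) & (obs.ma <= 1))
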