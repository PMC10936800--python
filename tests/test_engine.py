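"""Engine behaviour: initialization, invariants, determinism, transport."""


import numpy as np
import pytest

from kinnet.cargo import CargoParams
from kinnet.engine import (
    MINUS_END_ZONE_SITES,
    SimulationParams,
    initialize,
    run_ensemble,
    run_simulation,
    with_ad,
)
from kinnet.kinetics import MotorParams
from kinnet.network import generate_nrs


def quiet_params(**kwargs) -> SimulationParams:
    """Small, fast parameter set for invariant checks."""
    defaults = dict(structure="NRS", n_mts=20, duration=2.0, n_replicates=1)
    defaults.update(kwargs)
    return SimulationParams(**defaults)


class TestInitialize:
    def test_single_mt_places_motors_on_distinct_sites(self, single_mt_network):
        params = quiet_params()
        for seed in range(50):
            rng = np.random.default_rng(seed)
            mts, sites, cargo0 = initialize(params, single_mt_network, rng)
            assert mts.tolist() == [0, 0]
            assert sites[0] != sites[1]
            assert all(0 <= s < MINUS_END_ZONE_SITES for s in sites)

    def test_cargo_starts_at_motor_midpoint(self, two_mt_network):
        params = quiet_params()
        rng = np.random.default_rng(3)
        mts, sites, cargo0 = initialize(params, two_mt_network, rng)
        from kinnet.network import site_position

        pos = [
            site_position(two_mt_network.mts[m], s) for m, s in zip(mts, sites)
        ]
        np.testing.assert_allclose(cargo0, np.mean(pos, axis=0))

    def test_same_mt_fraction_matches_uniform_sampling(self):
        # each motor picks an MT uniformly: P(same) = 1/n_mts
        net = generate_nrs(80, seed=1)
        params = quiet_params(n_mts=80)
        n = 1000
        same = sum(
            initialize(params, net, np.random.default_rng(s))[0].tolist()[0]
            == initialize(params, net, np.random.default_rng(s))[0].tolist()[1]
            for s in range(n)
        )
        p = 1.0 / 80
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(same - n * p) <= 3 * sigma + 1


class TestDeterminism:
    def test_same_seed_same_trajectory(self, single_mt_network):
        p = quiet_params()
        a = run_simulation(p, network=single_mt_network, seed=5)
        b = run_simulation(p, network=single_mt_network, seed=5)
        np.testing.assert_array_equal(a.cargo, b.cargo)
        np.testing.assert_array_equal(a.motor_mt, b.motor_mt)
        np.testing.assert_array_equal(a.motor_site, b.motor_site)

    def test_same_master_seed_same_ensemble(self):
        p = quiet_params(n_replicates=3, duration=0.5)
        e1 = run_ensemble(p, master_seed=11)
        e2 = run_ensemble(p, master_seed=11)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.cargo, b.cargo)

    def test_single_replicate_ensemble_is_singleton(self):
        assert len(run_ensemble(quiet_params(duration=0.1), master_seed=0)) == 1


class TestRunBasics:
    def test_zero_duration_records_initial_state_only(self, single_mt_network):
        p = quiet_params(duration=0.0)
        tr = run_simulation(p, network=single_mt_network, seed=1)
        assert len(tr.times) == 1
        assert tr.times[0] == 0.0

    def test_record_grid_matches_stride(self, single_mt_network):
        p = quiet_params(duration=1.0, record_stride=0.01)
        tr = run_simulation(p, network=single_mt_network, seed=1)
        assert len(tr.times) == 101
        np.testing.assert_allclose(np.diff(tr.times), 0.01, rtol=1e-9)

    def test_invalid_structure_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(structure="RADIAL")


@pytest.fixture(scope="module")
def small_ensemble():
    # Ad=20 keeps motors attached long enough to exercise stepping,
    # switching and exclusion
    p = SimulationParams(
        structure="NRS",
        n_mts=20,
        duration=5.0,
        n_replicates=10,
        motor=MotorParams(Ad=20.0),
    )
    return run_ensemble(p, master_seed=4)


class TestInvariants:
    def test_no_two_attached_motors_share_a_site(self, small_ensemble):
        for tr in small_ensemble:
            both = (tr.motor_mt >= 0).all(axis=1)
            same = (tr.motor_mt[:, 0] == tr.motor_mt[:, 1]) & (
                tr.motor_site[:, 0] == tr.motor_site[:, 1]
            )
            assert not np.any(both & same)

    def test_motor_count_conserved(self, small_ensemble):
        for tr in small_ensemble:
            assert tr.motor_mt.shape[1] == 2
            assert np.all((tr.motor_mt >= -1)) and np.all(tr.motor_mt < 20)

    def test_detached_motors_ride_the_cargo(self, small_ensemble):
        for tr in small_ensemble:
            detached = tr.motor_mt < 0
            for i in range(2):
                idx = detached[:, i]
                np.testing.assert_allclose(
                    tr.motor_pos[idx, i], tr.cargo[idx], atol=1e-9
                )

    def test_attached_motors_sit_on_their_lattice_site(self, small_ensemble):
        for tr in small_ensemble:
            attached = tr.motor_mt >= 0
            assert np.all(tr.motor_site[attached] >= 0)
            assert np.all(tr.motor_site[attached] < 1500)

    def test_activity_flag_tracks_positive_spring_force(self, small_ensemble):
        for tr in small_ensemble:
            assert np.array_equal(tr.active, tr.motor_force > 0)


class TestTransportPhysics:
    def test_single_motor_unloaded_velocity_matches_stepping_rate(
        self, single_mt_network
    ):
        # one motor, detachment off, thermal noise off: after the spring
        # engages, the cargo tracks the motor at ~8 nm x net stepping rate
        p = SimulationParams(
            n_motors=1,
            duration=20.0,
            n_replicates=1,
            motor=MotorParams(Ad=float("inf")),
            cargo=CargoParams(kBT=1e-12),
            fpt_target=0.0,
        )
        tr = run_simulation(p, network=single_mt_network, seed=2)
        sel = tr.times >= 2.0
        v = (tr.cargo[-1, 0] - tr.cargo[sel][0, 0]) / (
            tr.times[-1] - tr.times[sel][0]
        )
        assert v == pytest.approx(143.7, rel=0.05)

    def test_detachment_coefficient_orders_motor_activity(self):
        # the unbinding rate scales as 1/Ad, so larger Ad keeps motors
        # attached and taut for longer: ma(Ad=5) > ma(Ad=0.2)
        from kinnet.observables import motor_activity

        base = SimulationParams(
            structure="NRS", n_mts=80, duration=5.0, n_replicates=20
        )
        ma_means = {}
        for ad in (0.2, 5.0):
            recs = run_ensemble(with_ad(base, ad), master_seed=8)
            _, ma = motor_activity(recs)
            ma_means[ad] = ma.mean()
        assert ma_means[5.0] > ma_means[0.2]

    def test_motor_cargo_separation_stays_bounded_on_a_single_track(
        self, single_mt_network
    ):
        p = quiet_params(duration=5.0, motor=MotorParams(Ad=20.0))
        tr = run_simulation(p, network=single_mt_network, seed=3)
        assert tr.max_separation < 500.0

    def test_free_diffusion_msd_through_engine(self, single_mt_network):
        # near-instant detachment and no reattachment: the cargo diffuses
        # freely, exercising the all-detached fast path end to end
        p = SimulationParams(
            duration=1.0,
            n_replicates=200,
            record_stride=0.5,
            motor=MotorParams(Ad=1e-7, Pi_attach=1e-9),
            fpt_target=0.0,
        )
        recs = [
            run_simulation(p, network=single_mt_network, seed=s) for s in range(200)
        ]
        cp = CargoParams()
        disp = np.array([tr.cargo[-1] - tr.cargo[0] for tr in recs])
        expected = 2.0 * cp.kBT / cp.gamma * 1.0
        for axis in range(2):
            assert np.mean(disp[:, axis] ** 2) == pytest.approx(expected, rel=0.25)
            assert abs(np.mean(disp[:, axis])) < 3 * np.sqrt(expected / 200) * 1.5
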