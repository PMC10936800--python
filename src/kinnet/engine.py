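"""Simulation engine: couple motors, cargo and network into replicate runs.

Each replicate builds (or reuses) a network, attaches the motor team at
random minus-end sites, and iterates the fixed-step loop compiled in
``kinnet._kernel``.  Replicates draw independent seed streams from a master
seed via ``numpy.random.SeedSequence``, so ensembles are reproducible and
order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .cargo import CargoParams
from .kinetics import MotorParams
from .network import Network, RegionGeometry, generate_nrs, generate_qrs, site_position

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "TrajectoryRecord",
    "initialize",
    "run_simulation",
    "run_ensemble",
]

MINUS_END_ZONE_SITES = 10  # initialization zone: first 10 lattice sites
SOFT_SEPARATION_BOUND = 500.0  # nm, logged if exceeded post-initialization


@dataclass(frozen=True)
class SimulationParams:
    """Full configuration of one ensemble experiment."""

    structure: str = "NRS"  # "NRS" | "QRS"
    n_mts: int = 80
    motor: MotorParams = field(default_factory=MotorParams)
    cargo: CargoParams = field(default_factory=CargoParams)
    n_motors: int = 2
    duration: float = 25.0  # s
    n_replicates: int = 2000
    fpt_target: float = 10000.0  # nm, transport-axis displacement
    fpt_cap: float = 200.0  # s, horizon when stopping at first passage
    stop_at_target: bool = False
    record_stride: float = 1e-2  # s
    fixed_network: bool = False  # reuse one network realization per ensemble
    region: RegionGeometry = field(default_factory=RegionGeometry)

    def __post_init__(self) -> None:
        if self.structure.upper() not in ("NRS", "QRS"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.n_motors < 1:
            raise ValueError("n_motors must be >= 1")
        if self.record_stride < self.cargo.dt:
            raise ValueError("record_stride must be >= dt")


@dataclass
class TrajectoryRecord:
    """Sampled trajectory of one replicate."""

    times: np.ndarray  # (n_rec,)
    cargo: np.ndarray  # (n_rec, 2)
    motor_mt: np.ndarray  # (n_rec, n_motors), -1 when detached
    motor_site: np.ndarray  # (n_rec, n_motors)
    motor_pos: np.ndarray  # (n_rec, n_motors, 2)
    motor_load: np.ndarray  # (n_rec, n_motors), signed pN
    motor_force: np.ndarray  # (n_rec, n_motors), spring force magnitude pN
    fpt: float | None  # first-passage time (s) or None if censored
    censored: bool
    seed: int
    max_separation: float  # max attached motor-cargo distance seen (nm)

    @property
    def active(self) -> np.ndarray:
        """Activity indicator per motor per time point (f_i > 0)."""
        return self.motor_force > 0


def _generate_network(params: SimulationParams, seed: int) -> Network:
    gen = generate_nrs if params.structure.upper() == "NRS" else generate_qrs
    return gen(params.n_mts, params.region, seed)


def initialize(
    params: SimulationParams, network: Network, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random initial attachment in the minus-end zone.

    Each motor independently picks an MT uniformly at random (same or
    different) and a site uniform over the first 10 lattice sites; draws
    colliding with an already-placed motor are resampled.  The cargo starts
    at the centroid of the motor positions.
    """
    n = params.n_motors
    mt_ids = np.empty(n, dtype=np.int64)
    sites = np.empty(n, dtype=np.int64)
    for i in range(n):
        for _ in range(1000):
            m = int(rng.integers(network.n_mts))
            s = int(rng.integers(MINUS_END_ZONE_SITES))
            if not any(mt_ids[j] == m and sites[j] == s for j in range(i)):
                mt_ids[i] = m
                sites[i] = s
                break
        else:
            raise RuntimeError("cannot place motors without site collision")
    positions = np.array(
        [site_position(network.mts[m], s) for m, s in zip(mt_ids, sites)]
    )
    cargo0 = positions.mean(axis=0)
    return mt_ids, sites, cargo0


def _pack_network(network: Network):
    """Flatten network geometry and the crossing map into kernel arrays."""
    n_sites_set = {mt.n_sites for mt in network.mts}
    if len(n_sites_set) != 1:
        raise ValueError("kernel requires a uniform lattice across MTs")
    n_sites = n_sites_set.pop()
    spacing = network.mts[0].lattice_spacing
    minus = np.array([mt.minus_end for mt in network.mts])
    units = np.array([mt.unit_vector for mt in network.mts])
    n_mts = network.n_mts
    # CSR over flattened (mt, site) keys
    counts = np.zeros(n_mts * n_sites + 1, dtype=np.int64)
    entries: dict[tuple[int, int], list[tuple[int, int]]] = network._crossing_map
    for (m, s), branches in entries.items():
        counts[m * n_sites + s + 1] = len(branches)
    cs_start = np.cumsum(counts)
    total = int(cs_start[-1])
    cs_mt = np.zeros(total, dtype=np.int64)
    cs_site = np.zeros(total, dtype=np.int64)
    for (m, s), branches in entries.items():
        base = cs_start[m * n_sites + s]
        for j, (bm, bs) in enumerate(branches):
            cs_mt[base + j] = bm
            cs_site[base + j] = bs
    return (
        np.ascontiguousarray(minus[:, 0]),
        np.ascontiguousarray(minus[:, 1]),
        np.ascontiguousarray(units[:, 0]),
        np.ascontiguousarray(units[:, 1]),
        n_sites,
        spacing,
        cs_start,
        cs_mt,
        cs_site,
    )


def run_simulation(
    params: SimulationParams,
    network: Network | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> TrajectoryRecord:
    """Run one replicate; bit-reproducible for a fixed seed."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    net_state, init_state, kernel_state = (int(x) for x in ss.generate_state(3))
    if network is None:
        network = _generate_network(params, net_state % 2**31)
    rng = np.random.default_rng(init_state)
    mt_ids, sites, cargo0 = initialize(params, network, rng)

    horizon = params.fpt_cap if params.stop_at_target else params.duration
    dt = params.cargo.dt
    n_steps = int(round(horizon / dt))
    stride = max(int(round(params.record_stride / dt)), 1)
    mp, cp = params.motor, params.cargo

    (
        rec_t,
        rec_cx,
        rec_cy,
        rec_mt,
        rec_site,
        rec_x,
        rec_y,
        rec_load,
        rec_f,
        fpt,
        max_sep,
    ) = _kernel.run_core(
        *_pack_network(network),
        mp.a1,
        mp.a2,
        mp.a3,
        mp.a4,
        mp.A,
        mp.F0,
        mp.Fd,
        mp.Ad,
        mp.Pi_attach,
        cp.k,
        cp.r0,
        cp.gamma,
        cp.kBT,
        dt,
        mt_ids,
        sites,
        float(cargo0[0]),
        float(cargo0[1]),
        n_steps,
        stride,
        float(params.fpt_target) if params.fpt_target else -1.0,
        params.stop_at_target,
        kernel_state % 2**31,
    )
    if max_sep > SOFT_SEPARATION_BOUND:
        logger.debug(
            "motor-cargo separation reached %.0f nm (soft bound %.0f nm)",
            max_sep,
            SOFT_SEPARATION_BOUND,
        )
    censored = fpt < 0
    return TrajectoryRecord(
        times=rec_t,
        cargo=np.stack([rec_cx, rec_cy], axis=1),
        motor_mt=rec_mt,
        motor_site=rec_site,
        motor_pos=np.stack([rec_x, rec_y], axis=2),
        motor_load=rec_load,
        motor_force=rec_f,
        fpt=None if censored else float(fpt),
        censored=bool(censored),
        seed=kernel_state % 2**31,
        max_separation=float(max_sep),
    )


def run_ensemble(
    params: SimulationParams,
    master_seed: int = 0,
    progress: bool = False,
) -> list[TrajectoryRecord]:
    """Independent replicates with per-replicate seed streams.

    By default a fresh network realization is generated per replicate, so
    ensemble averages marginalize over geometry; ``fixed_network=True``
    reuses the realization drawn from the first replicate's stream.
    """
    if params.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(params.n_replicates)
    network = None
    if params.fixed_network:
        net_seed = int(children[0].generate_state(1)[0]) % 2**31
        network = _generate_network(params, net_seed)
    records = []
    for idx, child in enumerate(children):
        records.append(run_simulation(params, network=network, seed=child))
        if progress and (idx + 1) % 50 == 0:
            logger.info("replicate %d/%d", idx + 1, params.n_replicates)
    return records


def with_ad(params: SimulationParams, ad: float) -> SimulationParams:
    """Copy of ``params`` with the detachment coefficient replaced."""
    return replace(params, motor=replace(params.motor, Ad=ad))
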