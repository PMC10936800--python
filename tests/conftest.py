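"""Shared fixtures: tiny networks and hand-built trajectory records."""

import numpy as np
import pytest

from kinnet.engine import TrajectoryRecord
from kinnet.network import (
    LATTICE_SPACING,
    N_SITES,
    Microtubule,
    Network,
    RegionGeometry,
    compute_crossings,
)


def make_mt(mt_id: int, minus_end, angle_deg: float = 0.0, n_sites: int = N_SITES):
    theta = np.deg2rad(angle_deg)
    return Microtubule(
        id=mt_id,
        minus_end=np.asarray(minus_end, dtype=float),
        unit_vector=np.array([np.cos(theta), np.sin(theta)]),
        n_sites=n_sites,
        lattice_spacing=LATTICE_SPACING,
    )


def make_network(mts, tag="NRS", region=None) -> Network:
    return Network(
        mts=list(mts),
        crossings=compute_crossings(list(mts)),
        structure_tag=tag,
        region=region or RegionGeometry(),
        seed=-1,
    )


@pytest.fixture
def single_mt_network():
    """One straight axial MT through the middle of the region."""
    return make_network([make_mt(0, (50.0, 3500.0))])


@pytest.fixture
def two_mt_network():
    """Two well-separated parallel axial MTs (no crossings)."""
    return make_network([make_mt(0, (50.0, 2000.0)), make_mt(1, (50.0, 5000.0))])


def make_record(
    times,
    cargo_x,
    motor_mts,
    motor_forces=None,
    motor_pos=None,
    cargo_y=None,
    fpt=None,
):
    """Assemble a TrajectoryRecord from plain lists (2 motors)."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    cargo = np.stack(
        [
            np.asarray(cargo_x, dtype=float),
            np.zeros(n) if cargo_y is None else np.asarray(cargo_y, dtype=float),
        ],
        axis=1,
    )
    mts = np.asarray(motor_mts, dtype=np.int64).reshape(n, 2)
    forces = (
        np.zeros((n, 2))
        if motor_forces is None
        else np.asarray(motor_forces, dtype=float).reshape(n, 2)
    )
    pos = (
        np.zeros((n, 2, 2))
        if motor_pos is None
        else np.asarray(motor_pos, dtype=float).reshape(n, 2, 2)
    )
    return TrajectoryRecord(
        times=times,
        cargo=cargo,
        motor_mt=mts,
        motor_site=np.zeros((n, 2), dtype=np.int64),
        motor_pos=pos,
        motor_load=np.zeros((n, 2)),
        motor_force=forces,
        fpt=fpt,
        censored=fpt is None,
        seed=0,
        max_separation=0.0,
    )
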