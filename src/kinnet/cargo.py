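"""Cargo-motor spring coupling and overdamped Langevin cargo dynamics.

The cargo is a point particle in 2-D obeying

    gamma * dr/dt = xi(t) + sum_i f_i,

with isotropic thermal noise <xi xi'> = 2 gamma kBT delta(t-t') applied
independently per Cartesian axis, integrated with explicit Euler-Maruyama at
fixed dt.  Each motor is tethered to the cargo by a dead-zone spring: zero
force below the critical extension r0 and Hookean k*(Delta - r0) beyond it,
always attractive.

The drag gamma = 9.42e-4 pN s/nm follows from the Stokes formula for a 0.5 um
cargo in a medium 100x as viscous as water (6*pi*eta*r with eta = 0.1 Pa s),
and kBT = 4.1 pN nm is the room-temperature value; the spring relaxation time
gamma/k ~ 3 ms is much longer than the default dt = 1e-5 s, so the explicit
scheme is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .network import Microtubule

__all__ = [
    "CargoParams",
    "CargoState",
    "spring_force_on_cargo",
    "cargo_step",
    "load_on_motor",
]


@dataclass(frozen=True)
class CargoParams:
    k: float = 0.32  # pN/nm, spring constant
    r0: float = 110.0  # nm, dead-zone (critical) distance
    gamma: float = 9.42e-4  # pN s/nm, Stokes drag (0.5 um cargo, 100x water)
    kBT: float = 4.1  # pN nm
    dt: float = 1e-5  # s

    def __post_init__(self) -> None:
        for name in ("k", "r0", "gamma", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CargoParams.{name} must be > 0")
        if self.kBT < 0:
            raise ValueError("CargoParams.kBT must be >= 0")


class CargoState(NamedTuple):
    position: np.ndarray  # (..., 2) nm
    time: float  # s


def spring_force_on_cargo(
    cargo: np.ndarray, motor: np.ndarray, params: CargoParams = CargoParams()
) -> np.ndarray:
    """Attractive dead-zone spring force on the cargo from one motor (pN).

    Zero inside the dead zone (separation < r0); magnitude k*(Delta - r0)
    directed from cargo toward motor beyond it.  Continuous at Delta = r0.
    Broadcasts over leading axes.
    """
    cargo = np.asarray(cargo, dtype=float)
    motor = np.asarray(motor, dtype=float)
    rel = motor - cargo
    dist = np.linalg.norm(rel, axis=-1, keepdims=True)
    stretch = np.maximum(dist - params.r0, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        force = np.where(dist > 0, params.k * stretch * rel / dist, 0.0)
    return force


def cargo_step(
    state: CargoState,
    forces: list[np.ndarray] | np.ndarray,
    params: CargoParams = CargoParams(),
    rng: np.random.Generator | None = None,
) -> CargoState:
    """One Euler-Maruyama update of the cargo position.

    dx = (sum F_x / gamma) dt + sqrt(2 (kBT/gamma) dt) N(0,1), per axis.
    ``forces`` is a list of 2-vectors (or an array summing over axis 0);
    positions with leading batch axes update independently (one noise draw
    per axis per batch element).
    """
    rng = rng or np.random.default_rng()
    pos = np.asarray(state.position, dtype=float)
    total = np.sum(np.asarray(forces, dtype=float), axis=0) if len(forces) else 0.0
    drift = total / params.gamma * params.dt
    sigma = np.sqrt(2.0 * params.kBT / params.gamma * params.dt)
    noise = sigma * rng.standard_normal(pos.shape) if sigma > 0 else 0.0
    return CargoState(position=pos + drift + noise, time=state.time + params.dt)


def load_on_motor(
    cargo: np.ndarray,
    motor_position: np.ndarray,
    mt: Microtubule,
    params: CargoParams = CargoParams(),
) -> float:
    """Signed scalar load on an attached motor (pN).

    The spring reaction on the motor is minus the force applied to the cargo
    (Newton's third law).  The load entering the rate laws is its projection
    onto the MT axis, with sign flipped so that F > 0 when the cargo pulls
    the motor toward the minus end (resisting plus-end stepping) and F < 0
    for assisting pulls.  Zero inside the dead zone or for purely transverse
    stretch.
    """
    f_cargo = spring_force_on_cargo(cargo, motor_position, params)
    # reaction on motor = -f_cargo; load = -(reaction . u) = f_cargo . u
    return float(np.asarray(f_cargo) @ mt.unit_vector)
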