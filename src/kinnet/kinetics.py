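"""Single-kinesin rate laws and fixed-step Monte Carlo event sampling.

The motor is described by four load-dependent quantities (load F in pN,
positive when the spring force on the motor points toward the MT minus end,
i.e. resists plus-end stepping; negative loads assist):

* dwell time      tau_D(F) = a1 + a2 * (1 + tanh(a3 * (F - a4)))
* step ratio      R(F)     = A * exp(-F * ln(A) / F0)
* step rates      P_f(F)   = [R/(1+R)] / tau_D,   P_b(F) = [1/(1+R)] / tau_D
* detach rate     P_det(F) = exp(-F / Fd) / (Ad * tau_D)

``log A`` is the natural logarithm so that R(F0) = 1: at the stall force the
forward and backward step rates balance.  The detachment law decreases with
resisting load (catch-bond-like) and grows for assisting loads, reproducing
the experimental detachment asymmetry; ``Ad`` rescales the overall unbinding
rate (P_det ~ 1/Ad).

Defaults correspond to Kif5B at high ATP concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotorParams",
    "dwell_time",
    "step_ratio",
    "step_rates",
    "detach_rate",
    "sample_motor_event",
    "EVENT_DETACH",
    "EVENT_FORWARD",
    "EVENT_BACKWARD",
    "EVENT_HOLD",
]

EVENT_DETACH = "detach"
EVENT_FORWARD = "step_forward"
EVENT_BACKWARD = "step_backward"
EVENT_HOLD = "hold"

# cap on exponents so extreme loads saturate instead of overflowing
_EXP_MAX = 700.0


@dataclass(frozen=True)
class MotorParams:
    """Kinesin parameters (high-ATP defaults)."""

    a1: float = 0.0098  # s
    a2: float = 0.07  # s
    a3: float = 0.06  # 1/pN
    a4: float = 6.0  # pN
    A: float = 1000.0  # forward/backward ratio at zero load
    F0: float = 6.0  # pN, stall force
    Fd: float = 3.18  # pN, detaching force
    Ad: float = 1.0  # detachment coefficient (P_det ~ 1/Ad)
    Pi_attach: float = 5.0  # 1/s, reattachment rate

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4", "A", "F0", "Fd", "Ad", "Pi_attach"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MotorParams.{name} must be > 0")


def dwell_time(F, params: MotorParams = MotorParams()):
    """Mean time between steps at load F (s); a1 < tau_D < a1 + 2*a2."""
    return params.a1 + params.a2 * (1.0 + np.tanh(params.a3 * (F - params.a4)))


def step_ratio(F, params: MotorParams = MotorParams()):
    """Forward/backward step-rate ratio R(F); R(0)=A, R(F0)=1."""
    return params.A * np.exp(
        np.minimum(-np.asarray(F, dtype=float) * np.log(params.A) / params.F0, _EXP_MAX)
    )


def step_rates(F, params: MotorParams = MotorParams()):
    """Forward and backward step rates (1/s); P_f + P_b = 1/tau_D exactly.

    Computed through the logistic form 1/(1 + exp(-+z)) with
    z = ln R = ln(A) * (1 - F/F0), which is stable for strongly assisting
    loads where R itself overflows.
    """
    F = np.asarray(F, dtype=float)
    tau = dwell_time(F, params)
    z = np.log(params.A) * (1.0 - F / params.F0)  # ln R
    p_f = _logistic(z) / tau
    p_b = _logistic(-z) / tau
    if p_f.ndim == 0:
        return float(p_f), float(p_b)
    return p_f, p_b


def _logistic(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def detach_rate(F, params: MotorParams = MotorParams()):
    """Unbinding rate at load F (1/s); decreasing in resisting load, ~1/Ad."""
    F = np.asarray(F, dtype=float)
    tau = dwell_time(F, params)
    rate = np.exp(np.minimum(-F / params.Fd, _EXP_MAX)) / (params.Ad * tau)
    return float(rate) if rate.ndim == 0 else rate


def sample_motor_event(
    F: float,
    dt: float,
    params: MotorParams = MotorParams(),
    rng: np.random.Generator | None = None,
) -> str:
    """Draw one Monte Carlo event for an attached motor over a time step dt.

    Events are mutually exclusive with per-step probabilities P_det*dt,
    P_f*dt, P_b*dt (first-order in dt); otherwise the motor holds.  Raises if
    the total probability reaches 1, signalling that dt is too large for the
    given parameters/load.
    """
    rng = rng or np.random.default_rng()
    p_f, p_b = step_rates(F, params)
    p_det = detach_rate(F, params)
    total = (p_det + p_f + p_b) * dt
    if total >= 1.0:
        raise ValueError(
            f"event probability {total:.3g} >= 1 at F={F}: dt too large"
        )
    u = rng.random()
    if u < p_det * dt:
        return EVENT_DETACH
    if u < (p_det + p_f) * dt:
        return EVENT_FORWARD
    if u < total:
        return EVENT_BACKWARD
    return EVENT_HOLD
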