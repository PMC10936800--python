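"""Ensemble observables and first-passage statistics.

All ensemble quantities are averages over replicates at each recorded time
point, following the overdamped transport conventions of the model:

* ``vc``   cargo velocity: trailing-window displacement along the transport
           (x) axis divided by the window, averaged over replicates.
* ``mc``   motor correlations: fraction of replicates with both motors
           simultaneously bound to the same (mc_same) or to different
           (mc_diff) MTs; any detached motor contributes 0 to both, so the
           two curves are not complementary.
* ``ma``   motor activity: fraction of motor-replicate pairs whose spring
           force on the cargo is non-zero (f_i > 0).
* ``mid``  mean intermotor distance; a detached motor sits at the cargo, so
           when both are detached mid = 0 automatically.

First-passage times are the earliest times the cargo's x displacement from
its start reaches a target distance; runs that never reach it within their
horizon are censored and counted as slow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import TrajectoryRecord

__all__ = [
    "EnsembleObservables",
    "FptSummary",
    "cargo_velocity",
    "motor_correlations",
    "motor_activity",
    "mean_intermotor_distance",
    "first_passage_times",
    "distribution_stats",
    "classify_fast",
    "compute_observables",
]

FAST_THRESHOLD = 18.8  # s, third-quartile cutoff separating fast trajectories
MODE_BIN_WIDTH = 0.5  # s, histogram bin for the mode estimate


@dataclass
class EnsembleObservables:
    times: np.ndarray
    vc: np.ndarray  # nm/s (NaN before the first full window)
    mc_same: np.ndarray
    mc_diff: np.ndarray
    ma: np.ndarray
    mid: np.ndarray  # nm


@dataclass
class FptSummary:
    sample: np.ndarray  # uncensored first-passage times (s)
    mean: float
    mode: float
    std: float
    skewness: float
    fast_fraction: float
    censored: int
    n_total: int


def _common_grid(trajectories: list[TrajectoryRecord]) -> np.ndarray:
    n = min(len(tr.times) for tr in trajectories)
    return trajectories[0].times[:n]


def cargo_velocity(
    trajectories: list[TrajectoryRecord], window: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean transport-axis velocity over a trailing window.

    Returns ``(times, vc)``; entries before the first complete window are
    NaN.  The window must be at least the recording stride.
    """
    times = _common_grid(trajectories)
    if len(times) < 2:
        raise ValueError("need at least two recorded time points")
    stride = times[1] - times[0]
    if window < stride - 1e-12:
        raise ValueError("window shorter than the recording stride")
    lag = max(int(round(window / stride)), 1)
    n = len(times)
    acc = np.zeros(n)
    for tr in trajectories:
        x = tr.cargo[:n, 0]
        v = np.full(n, np.nan)
        v[lag:] = (x[lag:] - x[:-lag]) / (lag * stride)
        acc += np.where(np.isnan(v), 0.0, v)
    vc = acc / len(trajectories)
    vc[:lag] = np.nan
    return times, vc


def motor_correlations(
    trajectories: list[TrajectoryRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble indicators for both motors on the same / different MTs."""
    times = _common_grid(trajectories)
    n = len(times)
    same = np.zeros(n)
    diff = np.zeros(n)
    for tr in trajectories:
        mts = tr.motor_mt[:n]
        attached = (mts >= 0).all(axis=1)
        both_same = attached & (mts[:, 0] == mts[:, 1])
        same += both_same
        diff += attached & ~both_same
    nsim = len(trajectories)
    return times, same / nsim, diff / nsim


def motor_activity(trajectories: list[TrajectoryRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Mean activity indicator over (n_motors x nsim) at each time point."""
    times = _common_grid(trajectories)
    n = len(times)
    acc = np.zeros(n)
    n_motors = trajectories[0].motor_force.shape[1]
    for tr in trajectories:
        acc += (tr.motor_force[:n] > 0).sum(axis=1)
    return times, acc / (n_motors * len(trajectories))


def mean_intermotor_distance(
    trajectories: list[TrajectoryRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean Euclidean distance between the two motors.

    Detached motors are co-located with the cargo, so two detached motors
    contribute 0 with no special-casing.
    """
    times = _common_grid(trajectories)
    n = len(times)
    acc = np.zeros(n)
    for tr in trajectories:
        d = np.linalg.norm(tr.motor_pos[:n, 0] - tr.motor_pos[:n, 1], axis=1)
        acc += d
    return times, acc / len(trajectories)


def first_passage_times(
    trajectories: list[TrajectoryRecord],
    target: float = 10000.0,
    fast_threshold: float = FAST_THRESHOLD,
    mode_bin: float = MODE_BIN_WIDTH,
    ddof: int = 0,
) -> FptSummary:
    """Summarize the first-passage sample of an ensemble.

    Uses the per-replicate passage time recorded by the engine when the run
    was in first-passage mode; otherwise detects the earliest recorded time
    the x displacement reaches ``target``.  Censored replicates are excluded
    from the summary statistics but counted (and classified as slow).
    """
    if target <= 0:
        raise ValueError("target must be > 0")
    fpts = []
    censored = 0
    for tr in trajectories:
        if tr.fpt is not None:
            fpts.append(tr.fpt)
            continue
        disp = tr.cargo[:, 0] - tr.cargo[0, 0]
        hit = np.nonzero(disp >= target)[0]
        if hit.size:
            fpts.append(float(tr.times[hit[0]]))
        else:
            censored += 1
    sample = np.asarray(fpts, dtype=float)
    n_total = len(trajectories)
    fast = classify_fast(sample, fast_threshold, n_total=n_total)
    if sample.size < 2:
        if sample.size == 0:
            raise ValueError("empty uncensored first-passage sample")
        return FptSummary(
            sample, float(sample[0]), float(sample[0]), 0.0, 0.0, fast, censored, n_total
        )
    mean, mode, std, skew = distribution_stats(sample, mode_bin=mode_bin, ddof=ddof)
    return FptSummary(sample, mean, mode, std, skew, fast, censored, n_total)


def distribution_stats(
    sample: np.ndarray, mode_bin: float = MODE_BIN_WIDTH, ddof: int = 1
) -> tuple[float, float, float, float]:
    """Mean, histogram mode, standard deviation and Fisher skewness.

    The mode is the center of the most populated histogram bin (``mode_bin``
    wide, anchored at 0; first-encountered bin wins ties).  Fisher skewness
    is g1 = m3 / m2^(3/2) on central moments without small-sample bias
    correction.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("need at least two values")
    mean = float(sample.mean())
    std = float(sample.std(ddof=ddof))
    m2 = float(((sample - mean) ** 2).mean())
    m3 = float(((sample - mean) ** 3).mean())
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    edges = np.arange(0.0, sample.max() + 2 * mode_bin, mode_bin)
    counts, edges = np.histogram(sample, bins=edges)
    mode = float(edges[int(np.argmax(counts))] + mode_bin / 2.0)
    return mean, mode, std, skew


def classify_fast(
    fpt_sample: np.ndarray,
    threshold: float = FAST_THRESHOLD,
    n_total: int | None = None,
) -> float:
    """Fraction of trajectories with FPT <= threshold; censored count as slow.

    ``n_total`` is the full replicate count including censored runs; it
    defaults to the sample size (no censoring).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    fpt_sample = np.asarray(fpt_sample, dtype=float)
    n = n_total if n_total is not None else fpt_sample.size
    if n == 0:
        return 0.0
    return float((fpt_sample <= threshold).sum() / n)


def compute_observables(
    trajectories: list[TrajectoryRecord], window: float = 0.1
) -> EnsembleObservables:
    """All time-series observables of an ensemble on the common time grid."""
    times, vc = cargo_velocity(trajectories, window)
    _, mc_same, mc_diff = motor_correlations(trajectories)
    _, ma = motor_activity(trajectories)
    _, mid = mean_intermotor_distance(trajectories)
    return EnsembleObservables(times, vc, mc_same, mc_diff, ma, mid)
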