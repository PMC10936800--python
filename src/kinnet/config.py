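"""Run configuration: YAML round-trip, validation, and experiment drivers.

A :class:`RunConfig` holds every knob of an ensemble experiment (network
spec, motor and cargo parameters, durations, replicate count, master seed)
and serializes to a flat YAML document.  Unknown keys are rejected so typos
fail loudly.  Sweep drivers derive one deterministic child seed per swept
value from the master seed, so any subset of a sweep is reproducible in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cargo import CargoParams
from .engine import SimulationParams, run_ensemble
from .kinetics import MotorParams
from .network import RegionGeometry
from .observables import (
    FAST_THRESHOLD,
    compute_observables,
    first_passage_times,
)

__all__ = ["RunConfig", "run", "sweep", "report", "MT_NUMBER_PRESET", "AD_PRESET"]

MT_NUMBER_PRESET = (20, 40, 60, 70, 80, 100)
AD_PRESET = (0.002, 0.004, 0.01, 0.2, 1.0, 1.5, 5.0)


@dataclass
class RunConfig:
    """Flat, serializable view of one experiment configuration."""

    structure: str = "NRS"
    n_mts: int = 80
    n_motors: int = 2
    duration: float = 25.0
    n_replicates: int = 2000
    fpt_target: float = 10000.0
    fpt_cap: float = 200.0
    stop_at_target: bool = False
    record_stride: float = 1e-2
    fixed_network: bool = False
    region_length: float = 12100.0
    region_width: float = 7000.0
    seed: int = 0
    # motor parameters
    a1: float = 0.0098
    a2: float = 0.07
    a3: float = 0.06
    a4: float = 6.0
    A: float = 1000.0
    F0: float = 6.0
    Fd: float = 3.18
    Ad: float = 1.0
    Pi_attach: float = 5.0
    # cargo parameters
    k: float = 0.32
    r0: float = 110.0
    gamma: float = 9.42e-4
    kBT: float = 4.1
    dt: float = 1e-5
    # analysis / output
    vc_window: float = 0.1
    fast_threshold: float = FAST_THRESHOLD
    write_trajectories: bool = False

    def validate(self) -> None:
        self.to_simulation_params()  # dataclass validators do the work

    def to_simulation_params(self) -> SimulationParams:
        return SimulationParams(
            structure=self.structure,
            n_mts=self.n_mts,
            motor=MotorParams(
                a1=self.a1, a2=self.a2, a3=self.a3, a4=self.a4, A=self.A,
                F0=self.F0, Fd=self.Fd, Ad=self.Ad, Pi_attach=self.Pi_attach,
            ),
            cargo=CargoParams(
                k=self.k, r0=self.r0, gamma=self.gamma, kBT=self.kBT, dt=self.dt
            ),
            n_motors=self.n_motors,
            duration=self.duration,
            n_replicates=self.n_replicates,
            fpt_target=self.fpt_target,
            fpt_cap=self.fpt_cap,
            stop_at_target=self.stop_at_target,
            record_stride=self.record_stride,
            fixed_network=self.fixed_network,
            region=RegionGeometry(self.region_length, self.region_width),
        )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _summary_row(cfg: RunConfig, records) -> dict:
    """One summary-table row: FPT statistics + steady-window observable means."""
    obs = compute_observables(records, window=cfg.vc_window)
    steady = (obs.times >= 5.0) & (obs.times <= 15.0)
    if not steady.any():  # short runs: use the latter half
        steady = obs.times >= obs.times[-1] / 2
    row = {
        "structure": cfg.structure,
        "n_mts": cfg.n_mts,
        "Ad": cfg.Ad,
        "n_replicates": cfg.n_replicates,
        "vc_steady": float(np.nanmean(obs.vc[steady])),
        "ma_steady": float(obs.ma[steady].mean()),
        "mid_steady": float(obs.mid[steady].mean()),
        "mc_same_steady": float(obs.mc_same[steady].mean()),
        "mc_diff_steady": float(obs.mc_diff[steady].mean()),
    }
    try:
        fpt = first_passage_times(
            records, target=cfg.fpt_target, fast_threshold=cfg.fast_threshold
        )
        row.update(
            fpt_mean=fpt.mean, fpt_mode=fpt.mode, fpt_std=fpt.std,
            fpt_skewness=fpt.skewness, fast_fraction=fpt.fast_fraction,
            censored=fpt.censored,
        )
    except ValueError:  # fully censored sample
        row.update(
            fpt_mean=float("nan"), fpt_mode=float("nan"), fpt_std=float("nan"),
            fpt_skewness=float("nan"), fast_fraction=0.0,
            censored=len(records),
        )
    return row


def _trajectory_table(records) -> pd.DataFrame:
    """Long-format per-replicate trajectory store (one row per time point)."""
    frames = []
    for rep, tr in enumerate(records):
        frame = {
            "replicate": np.full(len(tr.times), rep),
            "time": tr.times,
            "cargo_x": tr.cargo[:, 0],
            "cargo_y": tr.cargo[:, 1],
        }
        for i in range(tr.motor_mt.shape[1]):
            frame[f"m{i}_mt"] = tr.motor_mt[:, i]
            frame[f"m{i}_site"] = tr.motor_site[:, i]
            frame[f"m{i}_x"] = tr.motor_pos[:, i, 0]
            frame[f"m{i}_y"] = tr.motor_pos[:, i, 1]
            frame[f"m{i}_load"] = tr.motor_load[:, i]
            frame[f"m{i}_active"] = (tr.motor_force[:, i] > 0).astype(int)
        frames.append(pd.DataFrame(frame))
    return pd.concat(frames, ignore_index=True)


def run(cfg: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Execute one ensemble; write observables, summary and provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.to_simulation_params()
    records = run_ensemble(params, master_seed=cfg.seed)
    obs = compute_observables(records, window=cfg.vc_window)
    obs_df = pd.DataFrame(
        {
            "time": obs.times,
            "vc": obs.vc,
            "mc_same": obs.mc_same,
            "mc_diff": obs.mc_diff,
            "ma": obs.ma,
            "mid": obs.mid,
        }
    )
    obs_df.to_csv(out / "observables.csv", index=False)
    summary = pd.DataFrame([_summary_row(cfg, records)])
    summary.to_csv(out / "summary.csv", index=False)
    fpts = [tr.fpt if tr.fpt is not None else float("nan") for tr in records]
    pd.DataFrame({"replicate": range(len(fpts)), "fpt": fpts}).to_csv(
        out / "first_passage.csv", index=False
    )
    if cfg.write_trajectories:
        _trajectory_table(records).to_csv(out / "trajectories.csv", index=False)
    cfg.to_yaml(out / "config.yaml")
    from . import __version__

    (out / "provenance.json").write_text(
        json.dumps(
            {"version": __version__, "seed": cfg.seed, "n_replicates": cfg.n_replicates},
            indent=2,
        )
    )
    return summary


def sweep(
    axis: str,
    values: list,
    base: RunConfig,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """One ensemble per value of ``axis`` (n_mts | Ad | structure).

    Per-value seeds are spawned deterministically from the base seed, so a
    sweep subset rerun in isolation reproduces the full-sweep rows.
    """
    if axis not in ("n_mts", "Ad", "structure"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    if not values:
        raise ValueError("empty sweep values")
    rows = []
    children = np.random.SeedSequence(base.seed).spawn(len(values))
    for value, child in zip(values, children):
        cfg = dataclasses.replace(base, **{axis: value})
        cfg.seed = int(child.generate_state(1)[0]) % 2**31
        cfg.validate()
        records = run_ensemble(cfg.to_simulation_params(), master_seed=cfg.seed)
        row = _summary_row(cfg, records)
        row[axis] = value
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep_summary.csv", index=False)
    return table


def report(bundle_dir: str | Path) -> str:
    """Human-readable summary of a run bundle produced by :func:`run`."""
    out = Path(bundle_dir)
    summary_path = out / "summary.csv"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary table in bundle: {summary_path}")
    row = pd.read_csv(summary_path).iloc[0]
    lines = [
        f"structure={row['structure']} n_mts={int(row['n_mts'])} "
        f"Ad={row['Ad']} replicates={int(row['n_replicates'])}",
        "first-passage statistics (s):",
    ]
    if np.isnan(row["fpt_mean"]):
        lines.append("  mean=undefined (all replicates censored)")
    else:
        lines.append(
            f"  mean={row['fpt_mean']:.2f} mode={row['fpt_mode']:.2f} "
            f"std={row['fpt_std']:.2f} skewness={row['fpt_skewness']:.2f}"
        )
    lines.append(
        f"  fast_fraction={row['fast_fraction']:.3f} censored={int(row['censored'])}"
    )
    lines.append(
        "steady-window (5-15 s) means: "
        f"vc={row['vc_steady']:.1f} nm/s ma={row['ma_steady']:.3f} "
        f"mid={row['mid_steady']:.1f} nm mc_same={row['mc_same_steady']:.3f} "
        f"mc_diff={row['mc_diff_steady']:.3f}"
    )
    return "\n".join(lines)
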