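"""Structured outputs: CSV tables, JSON summaries and run manifests.

Every CLI invocation writes its tabular result(s) as CSV with a fixed,
public header plus a JSON manifest capturing the fully resolved parameter
set, seed(s), package version and output paths — enough to reproduce the
files bit-for-bit (wall time is informational only).  Numbers are
serialized at full precision (shortest round-tripping repr).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import TRAJECTORY_COLUMNS, SimulationResult
from .experiments import EnsembleResult, SweepResult
from .macro import FixedPoint, MacroTrajectory
from .society import ModelParams

__all__ = [
    "RunManifest",
    "write_manifest",
    "simulation_frame",
    "write_simulation",
    "read_simulation_csv",
    "write_macro",
    "write_ensemble",
    "write_sweep",
]


@dataclass
class RunManifest:
    """Reproducibility sidecar for one CLI invocation."""

    command: str
    params: dict
    seeds: list[int]
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    wall_time_s: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "command": self.command,
            "params": self.params,
            "seeds": self.seeds,
            "version": self.version,
            "outputs": self.outputs,
            "wall_time_s": self.wall_time_s,
        }
        d.update(self.extra)
        return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def write_manifest(manifest: RunManifest, path) -> None:
    write_json(manifest.to_dict(), path)


def write_csv(frame: pd.DataFrame, path) -> None:
    # repr() gives the shortest float representation that round-trips
    # exactly; a fixed line terminator keeps re-runs byte-identical
    frame.to_csv(
        path,
        index=False,
        lineterminator="\n",
        float_format=lambda v: repr(float(v)),
    )


_write_csv = write_csv


def simulation_frame(result: SimulationResult) -> pd.DataFrame:
    """Trajectory table with the fixed public header."""
    frame = result.to_dataframe()
    return frame[list(TRAJECTORY_COLUMNS)]


def write_simulation(result: SimulationResult, out_dir) -> list[str]:
    """Write trajectory.csv + result.json; returns the written paths."""
    out_dir = _ensure_dir(out_dir)
    csv_path = out_dir / "trajectory.csv"
    _write_csv(simulation_frame(result), csv_path)
    json_path = out_dir / "result.json"
    write_json(
        {
            "params": result.params.asdict(),
            "survival_time": result.survival_time,
            "censored": result.censored,
            "terminal_cause": result.terminal_cause,
        },
        json_path,
    )
    return [str(csv_path), str(json_path)]


def read_simulation_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return frame


def write_macro(
    trajectory: MacroTrajectory,
    fixed_points: list[FixedPoint],
    p_e_crit: float,
    out_dir,
) -> list[str]:
    """Write macro.csv (t, N_A, N_A_share, E_per_capita) + fixed_points.json."""
    out_dir = _ensure_dir(out_dir)
    csv_path = out_dir / "macro.csv"
    _write_csv(
        pd.DataFrame(
            {
                "t": trajectory.times,
                "N_A": trajectory.n_a_path,
                "N_A_share": trajectory.admin_share,
                "E_per_capita": trajectory.e_per_capita,
            }
        ),
        csv_path,
    )
    json_path = out_dir / "fixed_points.json"
    write_json(
        {
            "params": trajectory.params.asdict(),
            "survival_time": trajectory.survival_time,
            "censored": trajectory.censored,
            "p_e_critical": p_e_crit,
            "fixed_points": [dataclasses.asdict(fp) for fp in fixed_points],
        },
        json_path,
    )
    return [str(csv_path), str(json_path)]


def write_ensemble(result: EnsembleResult, out_dir) -> list[str]:
    """Write ensemble.csv (one row per run) + summary.json."""
    from .experiments import median_survival

    out_dir = _ensure_dir(out_dir)
    csv_path = out_dir / "ensemble.csv"
    _write_csv(result.to_dataframe(), csv_path)
    med, at_cap = median_survival(result)
    json_path = out_dir / "summary.json"
    write_json(
        {
            "params": result.params.asdict(),
            "n_runs": result.n_runs,
            "seeds": result.seeds,
            "median_survival": med,
            "median_at_cap": at_cap,
            "n_censored": int(result.censored_flags.sum()),
        },
        json_path,
    )
    return [str(csv_path), str(json_path)]


def write_sweep(result: SweepResult, out_dir) -> list[str]:
    """Write sweep.csv (one row per grid cell) + summary.json."""
    out_dir = _ensure_dir(out_dir)
    csv_path = out_dir / "sweep.csv"
    _write_csv(result.to_dataframe(), csv_path)
    median_path = out_dir / "median_over_rho.csv"
    _write_csv(result.median_over_rho(), median_path)
    json_path = out_dir / "summary.json"
    write_json(
        {
            "params": result.base_params.asdict(),
            "rho_values": result.rho_values,
            "c_values": result.c_values,
            "pe_values": result.pe_values,
            "t_max": result.t_max,
            "n_censored_cells": int(result.censored.sum()),
        },
        json_path,
    )
    return [str(csv_path), str(median_path), str(json_path)]


def _ensure_dir(out_dir):
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir
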