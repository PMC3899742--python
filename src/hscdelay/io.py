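"""Configuration files, trajectory CSV round-trip, metrics JSON, logging.

Configs are YAML (JSON is a subset and therefore accepted).  Trajectory
tables are written with 17 significant digits so that a written-and-reread
table is bit-identical to the in-memory one — the model is deterministic
and outputs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

from .model import ModelParameters, TreatmentSchedule
from .presets import available_presets, load_preset
from .scenarios import ScenarioResult
from .solver import SolverOptions, Trajectory

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_metrics",
    "read_metrics",
]

log = logging.getLogger("hscdelay")

TRAJECTORY_COLUMNS = ["t", "P", "N", "g_HIA", "g_C", "beta_N"]
_FLOAT_FMT = "%.17g"


class ConfigError(ValueError):
    """A configuration problem, naming the offending key or value."""


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    for k in section:
        if k not in allowed:
            raise ConfigError(f"unknown key {k!r} in {where}")


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved simulation run.

    Built either from a named preset (optionally overridden) or from a
    complete inline parameter set.  Round-trips losslessly through
    :meth:`to_dict` / :func:`load_config`.
    """

    params: ModelParameters
    P0: float
    N0: float
    schedule: TreatmentSchedule = TreatmentSchedule.off()
    solver: SolverOptions = SolverOptions()
    t_end: float = 500.0
    out_dir: str = "."
    log_level: str = "INFO"
    preset: Optional[str] = None

    def to_dict(self) -> dict:
        d: dict[str, Any] = {}
        if self.preset is not None:
            d["preset"] = self.preset
        d["parameters"] = dataclasses.asdict(self.params)
        d["initial"] = {"P0": self.P0, "N0": self.N0}
        d["schedule"] = dataclasses.asdict(self.schedule)
        sv = dataclasses.asdict(self.solver)
        sv["breakpoints"] = list(sv["breakpoints"])
        d["solver"] = sv
        d["t_end"] = self.t_end
        d["out_dir"] = self.out_dir
        d["log_level"] = self.log_level
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_TOP_KEYS = {
    "preset", "parameters", "initial", "schedule", "solver",
    "t_end", "out_dir", "log_level",
}


def config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    preset_name = raw.get("preset")
    overrides = dict(raw.get("parameters") or {})
    param_names = {f.name for f in dataclasses.fields(ModelParameters)}
    _check_keys(overrides, param_names, "parameters")

    if preset_name is not None:
        if preset_name not in available_presets():
            raise ConfigError(
                f"unknown preset {preset_name!r}; "
                f"available: {available_presets()}"
            )
        preset = load_preset(preset_name)
        params = preset.params.with_overrides(**overrides)
        P0, N0 = preset.P0, preset.N0
    else:
        # ModelParameters has full defaults, so inline partial sets are fine
        params = ModelParameters(**overrides)
        P0, N0 = 50.0, 70.0

    init = dict(raw.get("initial") or {})
    _check_keys(init, {"P0", "N0"}, "initial")
    P0 = float(init.get("P0", P0))
    N0 = float(init.get("N0", N0))
    if P0 < 0 or N0 < 0:
        raise ConfigError("initial cell counts must be >= 0")

    sched_raw = dict(raw.get("schedule") or {})
    sched_names = {f.name for f in dataclasses.fields(TreatmentSchedule)}
    _check_keys(sched_raw, sched_names, "schedule")
    try:
        schedule = TreatmentSchedule(**sched_raw)
    except ValueError as e:
        raise ConfigError(f"invalid schedule: {e}") from e

    solver_raw = dict(raw.get("solver") or {})
    solver_names = {f.name for f in dataclasses.fields(SolverOptions)}
    _check_keys(solver_raw, solver_names, "solver")
    if "breakpoints" in solver_raw:
        solver_raw["breakpoints"] = tuple(solver_raw["breakpoints"])
    try:
        solver = SolverOptions(**solver_raw)
    except ValueError as e:
        raise ConfigError(f"invalid solver options: {e}") from e

    t_end = float(raw.get("t_end", 500.0))
    if t_end <= 0:
        raise ConfigError(f"t_end must be > 0, got {t_end}")

    return RunConfig(
        params=params,
        P0=P0,
        N0=N0,
        schedule=schedule,
        solver=solver,
        t_end=t_end,
        out_dir=str(raw.get("out_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
        preset=preset_name,
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if raw is None:
        raise ConfigError(f"{path} is empty")
    return config_from_dict(raw)


def write_trajectory(
    traj: Trajectory, path: str | Path, resample_dt: Optional[float] = None
) -> None:
    """Write a trajectory CSV (accepted steps, or a uniform resampling)."""
    frame = traj.to_frame() if resample_dt is None else traj.resample(resample_dt)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_trajectory` output."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory file {path} lacks columns {sorted(missing)}")
    return frame[TRAJECTORY_COLUMNS]


def _provenance(params: ModelParameters, schedule: TreatmentSchedule) -> dict:
    from . import __version__

    return {
        "tool": "hscdelay",
        "version": __version__,
        "parameters": dataclasses.asdict(params),
        "schedule": dataclasses.asdict(schedule),
        "deterministic": True,  # no stochastic elements; reruns are bit-identical
    }


def write_metrics(result: ScenarioResult, path: str | Path) -> None:
    """Write a scenario's metrics JSON (nadir is null when no treatment)."""
    payload = result.metrics()
    payload["initial"] = {"P0": result.initial[0], "N0": result.initial[1]}
    payload["provenance"] = _provenance(result.params, result.schedule)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_metrics(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
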