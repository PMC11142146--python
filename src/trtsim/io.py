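"""Configuration files, tabular writers and run manifests."""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import STATE_COLUMNS, DoseSchedule, SimulationResult
from .params import ModelParameters

__all__ = [
    "default_parameter_path", "load_parameters", "save_parameters",
    "load_schedule", "save_schedule", "write_outputs", "read_trajectory",
]


def default_parameter_path() -> Path:
    """Path of the packaged basic-parameter file."""
    return Path(resources.files("trtsim") / "data" / "default_parameters.yaml")


def load_parameters(path: str | Path | None = None) -> ModelParameters:
    """Load a parameter file (YAML or JSON), filling defaults.

    Keys must be ModelParameters field names; unknown keys are rejected so
    that typos cannot silently fall back to defaults. An empty file yields
    the full basic parameterization.
    """
    if path is None:
        path = default_parameter_path()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must map keys to numbers")
    known = set(ModelParameters.field_names())
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return ModelParameters(**{k: float(v) for k, v in raw.items()})


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def load_schedule(path: str | Path) -> DoseSchedule:
    """Read a schedule file: JSON/YAML with ``doses: [{t_days, A_pmol}, ...]``
    and optional ``eta``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    doses = raw.get("doses", [])
    injections = tuple((float(d["t_days"]), float(d["A_pmol"])) for d in doses)
    eta = raw.get("eta")
    return DoseSchedule(injections, eta_override=None if eta is None else float(eta))


def save_schedule(schedule: DoseSchedule, path: str | Path) -> None:
    payload = {
        "eta": schedule.eta_override,
        "doses": [{"t_days": t, "A_pmol": a} for t, a in schedule.injections],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _versions() -> dict[str, str]:
    import scipy
    from importlib.metadata import version

    return {"python": sys.version.split()[0], "numpy": np.__version__,
            "scipy": scipy.__version__, "trtsim": version("trtsim")}


def write_outputs(result: SimulationResult, outdir: str | Path,
                  seed: int | None = None,
                  solver: dict | None = None) -> dict[str, Path]:
    """Write trajectory CSV, outcome JSON and a run manifest.

    The manifest records parameters, schedule, seed, solver settings and
    library versions - enough to re-run the simulation exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": outdir / "trajectory.csv",
        "outcome": outdir / "outcome.json",
        "manifest": outdir / "manifest.json",
    }
    result.to_dataframe().to_csv(paths["trajectory"], index=False,
                                 float_format="%.12g")
    outcome = {
        "n_min": result.n_min, "t_nmin": result.t_nmin,
        "cured": bool(result.cured), "death_time": result.death_time,
        "toxicity_time": result.toxicity_time,
        "survival_time": result.survival_time, "cause": result.cause,
        "final_cum_blood_decays": result.final_state.cum_blood_decays,
    }
    paths["outcome"].write_text(json.dumps(outcome, indent=2))
    manifest = {
        "parameters": result.params.to_dict(),
        "schedule": {"eta": result.schedule.eta(result.params),
                     "doses": [{"t_days": t, "A_pmol": a}
                               for t, a in result.schedule.injections]},
        "horizon": result.horizon,
        "seed": seed,
        "solver": solver or {},
        "versions": _versions(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def read_trajectory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["time", *STATE_COLUMNS]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected trajectory columns in {path}")
    return df
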