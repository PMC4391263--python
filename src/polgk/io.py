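"""Reading and writing the package's tabular and config formats.

Time courses travel as tidy CSV with columns
``experiment_id, series_value, series_unit, time_s, observable, value_nM``;
a dataset written by the generators carries a sidecar JSON recording the
generating truth parameters, seed, design, config hash and package version,
so recovery studies are fully reproducible from files alone.

Mechanism/fit configs are YAML or JSON with the schema::

    scheme: scheme1 | scheme2 | burst | exponential
    variant: WT | S305R | P1073L        # optional preset
    rates: {k1: ..., ...}               # truth / guesses
    fixed: [k2]  or  {k2: 0.5}
    free: [k1, k_minus1, k_minus2, k3]
    initial: {E_total: 100, D_total: 75}
    observable: product26
    noise: {rel: 0.05, add: 0.5}
    seed: 1
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .global_fit import ExperimentSet
from .kinetic_model import TimeCourse

__all__ = [
    "timecourses_to_frame",
    "write_timecourses",
    "read_timecourses",
    "write_sidecar",
    "read_sidecar",
    "load_config",
    "config_hash",
]

CSV_COLUMNS = ("experiment_id", "series_value", "series_unit",
               "time_s", "observable", "value_nM")

_SCHEMES = ("scheme1", "scheme2", "burst", "exponential")


def _courses(data) -> list[TimeCourse]:
    if isinstance(data, ExperimentSet):
        return data.courses
    if isinstance(data, TimeCourse):
        return [data]
    return list(data)


def timecourses_to_frame(data) -> pd.DataFrame:
    """Flatten courses to the tidy CSV layout."""
    rows = []
    for c in _courses(data):
        for t, v in zip(c.times, c.values):
            rows.append({
                "experiment_id": c.meta.get("experiment_id", ""),
                "series_value": c.meta.get("series_value"),
                "series_unit": c.meta.get("series_unit", ""),
                "time_s": t,
                "observable": c.observable,
                "value_nM": v,
            })
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_timecourses(path, data) -> None:
    timecourses_to_frame(data).to_csv(path, index=False)


def read_timecourses(path, scheme_id: str | None = None,
                     initial_specs: list[dict] | None = None,
                     titration: str = "") -> list[TimeCourse] | ExperimentSet:
    """Read the tidy CSV back into TimeCourses.

    With ``scheme_id`` (and per-course ``initial_specs``) the result is an
    :class:`ExperimentSet` ready for fitting; otherwise a plain list.
    Courses are keyed by (experiment_id, observable) in file order.
    """
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    courses: list[TimeCourse] = []
    for (eid, obs), g in df.groupby(["experiment_id", "observable"], sort=False):
        g = g.sort_values("time_s")
        sv = g["series_value"].iloc[0]
        courses.append(TimeCourse(
            g["time_s"].to_numpy(), g["value_nM"].to_numpy(), str(obs),
            {"experiment_id": eid,
             "series_value": None if pd.isna(sv) else sv,
             "series_unit": str(g["series_unit"].iloc[0] or "")}))
    if scheme_id is None:
        return courses
    if initial_specs is None:
        raise ConfigError("initial_specs are required to build an ExperimentSet")
    return ExperimentSet(courses, scheme_id, initial_specs, titration)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sidecar(path, payload: Mapping) -> None:
    """Write the truth/seed/config-hash sidecar JSON next to a dataset."""
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a config mapping (order-independent)."""
    blob = json.dumps(_jsonable(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run configuration."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        cfg = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{p}: not valid YAML/JSON ({e})") from e
    if not isinstance(cfg, dict):
        raise ConfigError(f"{p}: config must be a mapping")
    scheme = cfg.get("scheme")
    if scheme not in _SCHEMES:
        raise ConfigError(f"{p}: scheme must be one of {_SCHEMES}, got {scheme!r}")
    for key in ("rates", "initial", "noise"):
        if key in cfg and not isinstance(cfg[key], dict):
            raise ConfigError(f"{p}: {key!r} must be a mapping")
    if "free" in cfg and not isinstance(cfg["free"], list):
        raise ConfigError(f"{p}: 'free' must be a list of parameter names")
    return cfg
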