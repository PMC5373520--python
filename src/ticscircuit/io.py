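"""Readers/writers and run manifests.

Parameters round-trip through flat JSON (sorted keys, so files have stable
digests); traces and tables through tidy CSV; experiment configs through
YAML or JSON.  Every CLI run writes a manifest (config snapshot, master
seed, parameter digest, package version, timestamp) from which the run can
be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import connection_table
from .inputs import PulseSpec
from .params import validate_params
from .protocol import AREAS, CohortDataset, SessionConfig, TrialRecording

__all__ = [
    "read_params",
    "write_params",
    "params_digest",
    "write_traces",
    "read_traces",
    "recordings_to_frame",
    "label_manifest",
    "load_config",
    "write_connection_csv",
    "RunManifest",
]


# ---------------------------------------------------------------- parameters
def write_params(params: dict, path) -> None:
    path = Path(path)
    path.write_text(json.dumps(dict(sorted(params.items())), indent=1) + "\n")


def read_params(path) -> dict:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}:{e.lineno}: malformed parameter JSON: {e.msg}")
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: parameter file must hold a JSON object")
    return validate_params({k: float(v) for k, v in raw.items()})


def params_digest(params: dict) -> str:
    payload = json.dumps(dict(sorted(params.items())), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ------------------------------------------------------------------- traces
def recordings_to_frame(recordings) -> pd.DataFrame:
    """Long-format tidy table of pooled area traces:
    (subject, trial, area, step, time_s, activity)."""
    frames = []
    for rec in recordings:
        steps = np.arange(len(rec.m1_units))
        for area in AREAS:
            frames.append(
                pd.DataFrame(
                    {
                        "subject": rec.subject if rec.subject is not None else -1,
                        "trial": rec.trial if rec.trial is not None else -1,
                        "area": area,
                        "step": steps,
                        "time_s": np.round(steps * rec.dt, 6),
                        "activity": rec.traces[area],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_traces(recordings, path) -> None:
    recordings_to_frame(recordings).to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "trial", "area", "step", "time_s", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trace CSV missing columns {sorted(missing)}")
    return df


def label_manifest(cohort: CohortDataset) -> pd.DataFrame:
    rows = []
    for subj, (seed, recs) in enumerate(cohort.subjects):
        for rec in recs:
            rows.append(
                {
                    "subject": subj,
                    "seed": seed,
                    "trial": rec.trial,
                    "label": rec.label,
                    "m1_peak": rec.m1_peak,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- config
def _pulse_from_dict(d: dict, where: str) -> PulseSpec:
    try:
        return PulseSpec(
            height=float(d["height"]),
            sd=float(d.get("sd", 1.0)),
            center=float(d.get("center", 1.0)),
            per_channel_uniform_scaling=bool(
                d.get("per_channel_uniform_scaling", False)
            ),
        )
    except KeyError as e:
        raise ValueError(f"config field {where}.{e.args[0]} is missing")


def load_config(path) -> SessionConfig:
    """Read and validate a session config (YAML or JSON).

    Config files are complete snapshots: every protocol field must be
    present, so a stored config reproduces its run exactly.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    scalar_fields = {
        "dt": float,
        "session_length": float,
        "n_trials": int,
        "trial_length": float,
        "inter_trial_gap": float,
        "tic_threshold": float,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in scalar_fields:
            kwargs[key] = scalar_fields[key](value)
        elif key in ("da_burst", "cortical_input"):
            kwargs[key] = _pulse_from_dict(value, key)
        else:
            raise ValueError(f"{path}: unknown config field {key!r}")
    missing = (set(scalar_fields) | {"da_burst", "cortical_input"}) - set(kwargs)
    if missing:
        raise ValueError(
            f"{path}: config missing field(s) {', '.join(sorted(missing))}"
        )
    return SessionConfig(**kwargs)


def dump_config(config: SessionConfig) -> dict:
    d = asdict(config)
    return d


def write_connection_csv(path) -> None:
    """Emit the architecture's edge list for inspection."""
    pd.DataFrame(connection_table()).to_csv(path, index=False)


# ----------------------------------------------------------------- manifest
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    def __init__(self, command: str, seed: int, params: dict,
                 config: SessionConfig = None, extra: dict = None):
        self.payload = {
            "command": command,
            "seed": int(seed),
            "params_digest": params_digest(params),
            "config": dump_config(config) if config is not None else None,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        if extra:
            self.payload["extra"] = extra

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(self.payload, indent=1, default=str) + "\n")
        return path
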