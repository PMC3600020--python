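"""File formats and round-trip readers/writers.

Per-trial layout (one directory per trial):

* ``emg_sol.csv``, ``emg_ta.csv``, ``force.csv``, ``hip.csv`` — ``time,value``
* ``meta.yaml`` — body weight, condition, rates, identifiers
* ``ground_truth.json`` — optional generator truth
* ``processed.csv`` — ``time,emg_sol,emg_ta,F,HA`` after preprocessing
* ``strides.json`` — detected stride events

Fit results, stats reports and run manifests are JSON with sorted keys, so
a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .fitting import FitResult
from .oscillator import OscillatorParameters
from .preprocessing import ProcessedTrial, StrideEvent, TrialRecording
from .synthetic import GroundTruth

__all__ = [
    "write_trial",
    "read_trial",
    "write_processed",
    "read_processed",
    "write_fit_result",
    "read_fit_result",
    "write_json",
    "read_json",
]

_CHANNEL_FILES = {
    "emg_sol_raw": "emg_sol.csv",
    "emg_ta_raw": "emg_ta.csv",
    "force_raw": "force.csv",
    "hip_raw": "hip.csv",
}


def _write_channel(path: Path, rate: float, values: np.ndarray) -> None:
    t = np.arange(values.size) / rate
    pd.DataFrame({"time": t, "value": values}).to_csv(path, index=False)


def _read_channel(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, required=("time", "value"))
    return df["time"].to_numpy(), df["value"].to_numpy()


def _read_csv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def write_trial(
    trial_dir: str | Path,
    rec: TrialRecording,
    truth: GroundTruth | None = None,
) -> Path:
    trial_dir = Path(trial_dir)
    trial_dir.mkdir(parents=True, exist_ok=True)
    rates = {
        "emg_sol_raw": rec.emg_rate,
        "emg_ta_raw": rec.emg_rate,
        "force_raw": rec.force_rate,
        "hip_raw": rec.kin_rate,
    }
    for attr, fname in _CHANNEL_FILES.items():
        _write_channel(trial_dir / fname, rates[attr], getattr(rec, attr))
    meta = {
        "body_weight": float(rec.body_weight),
        "condition": rec.condition,
        "emg_rate": float(rec.emg_rate),
        "force_rate": float(rec.force_rate),
        "kin_rate": float(rec.kin_rate),
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "side": rec.side,
    }
    (trial_dir / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    if truth is not None:
        write_json(trial_dir / "ground_truth.json", _truth_to_dict(truth))
    return trial_dir


def read_trial(trial_dir: str | Path) -> tuple[TrialRecording, GroundTruth | None]:
    trial_dir = Path(trial_dir)
    meta_path = trial_dir / "meta.yaml"
    if not meta_path.exists():
        raise ParseError(f"{meta_path}: missing trial metadata")
    meta = yaml.safe_load(meta_path.read_text())
    channels = {}
    for attr, fname in _CHANNEL_FILES.items():
        _, values = _read_channel(trial_dir / fname)
        channels[attr] = values
    rec = TrialRecording(
        emg_sol_raw=channels["emg_sol_raw"],
        emg_ta_raw=channels["emg_ta_raw"],
        force_raw=channels["force_raw"],
        hip_raw=channels["hip_raw"],
        body_weight=float(meta["body_weight"]),
        condition=str(meta["condition"]),
        emg_rate=float(meta["emg_rate"]),
        force_rate=float(meta["force_rate"]),
        kin_rate=float(meta["kin_rate"]),
        subject_id=str(meta.get("subject_id", "S1")),
        trial_id=str(meta.get("trial_id", "T1")),
        side=str(meta.get("side", "left")),
    )
    truth = None
    truth_path = trial_dir / "ground_truth.json"
    if truth_path.exists():
        truth = _truth_from_dict(read_json(truth_path))
    return rec, truth


def _truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "stride_events": [list(e) for e in truth.stride_events],
        "condition": truth.condition,
        "emg_mode": truth.emg_mode,
        "seed": truth.seed,
        "true_params": (
            truth.true_params.to_dict() if truth.true_params is not None else None
        ),
        "condition_effects": truth.condition_effects,
    }


def _truth_from_dict(d: dict) -> GroundTruth:
    params = d.get("true_params")
    return GroundTruth(
        stride_events=[tuple(e) for e in d["stride_events"]],
        condition=d["condition"],
        emg_mode=d["emg_mode"],
        seed=d.get("seed"),
        true_params=(
            OscillatorParameters.from_dict(params) if params is not None else None
        ),
        condition_effects=d.get("condition_effects", {}),
    )


def write_processed(trial_dir: str | Path, trial: ProcessedTrial) -> Path:
    trial_dir = Path(trial_dir)
    trial_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time": trial.timebase,
            "emg_sol": trial.emg_sol,
            "emg_ta": trial.emg_ta,
            "F": trial.F,
            "HA": trial.HA,
        }
    ).to_csv(trial_dir / "processed.csv", index=False)
    write_json(
        trial_dir / "strides.json",
        {
            "stride_events": [list(e.to_tuple()) for e in trial.stride_events],
            "condition": trial.condition,
            "subject_id": trial.subject_id,
            "trial_id": trial.trial_id,
            "side": trial.side,
            "body_weight": float(trial.body_weight),
        },
    )
    return trial_dir


def read_processed(trial_dir: str | Path) -> ProcessedTrial:
    trial_dir = Path(trial_dir)
    df = _read_csv(
        trial_dir / "processed.csv",
        required=("time", "emg_sol", "emg_ta", "F", "HA"),
    )
    meta = read_json(trial_dir / "strides.json")
    return ProcessedTrial(
        timebase=df["time"].to_numpy(),
        emg_sol=df["emg_sol"].to_numpy(),
        emg_ta=df["emg_ta"].to_numpy(),
        F=df["F"].to_numpy(),
        HA=df["HA"].to_numpy(),
        stride_events=[StrideEvent(*e) for e in meta["stride_events"]],
        condition=meta["condition"],
        subject_id=meta["subject_id"],
        trial_id=meta["trial_id"],
        side=meta["side"],
        body_weight=float(meta["body_weight"]),
    )


def write_fit_result(path: str | Path, result: FitResult) -> Path:
    write_json(path, result.to_dict())
    return Path(path)


def read_fit_result(path: str | Path) -> FitResult:
    return FitResult.from_dict(read_json(path))


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path):
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
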