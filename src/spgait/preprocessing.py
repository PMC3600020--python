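"""Raw multirate trial channels -> filtered, normalized, stride-annotated trial.

Acquisition rates differ per channel (surface EMG at 2000 Hz, insole
vertical force at 200 Hz, hip angle at 100 Hz); everything is conditioned at
its native rate, resampled onto one uniform timebase and annotated with
stride events detected from the force profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from .errors import (
    AlignmentError,
    InsufficientDataError,
    InsufficientStridesError,
    InvalidParameterError,
    InvalidValueError,
)

__all__ = [
    "TrialRecording",
    "ProcessedTrial",
    "StrideEvent",
    "condition_emg",
    "normalize_force",
    "resample_common",
    "detect_strides",
    "preprocess_trial",
]

CONDITIONS = ("3.5", "4.0", "4.5", "self-selected", "silly")


@dataclass
class TrialRecording:
    """Raw per-trial channels at their native rates plus metadata.

    EMG in volts, force in newtons, hip angle in radians, body weight in
    newtons.
    """

    emg_sol_raw: np.ndarray
    emg_ta_raw: np.ndarray
    force_raw: np.ndarray
    hip_raw: np.ndarray
    body_weight: float
    condition: str
    emg_rate: float = 2000.0
    force_rate: float = 200.0
    kin_rate: float = 100.0
    subject_id: str = "S1"
    trial_id: str = "T1"
    side: str = "left"

    def __post_init__(self):
        for name in ("emg_rate", "force_rate", "kin_rate"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.body_weight <= 0:
            raise InvalidParameterError("body_weight must be > 0")
        for name in ("emg_sol_raw", "emg_ta_raw", "force_raw", "hip_raw"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise InvalidValueError(f"{name} is empty")
            setattr(self, name, arr)
        if self.side not in ("left", "right"):
            raise InvalidValueError(f"side must be left/right, got {self.side!r}")


@dataclass(frozen=True)
class StrideEvent:
    """One stride: heel strike, toe off, and the next heel strike [s]."""

    heel_strike: float
    toe_off: float
    next_heel_strike: float

    def __post_init__(self):
        if not self.heel_strike < self.toe_off < self.next_heel_strike:
            raise InvalidValueError(
                "stride events must satisfy hs < to < next_hs, got "
                f"({self.heel_strike}, {self.toe_off}, {self.next_heel_strike})"
            )

    @property
    def duration(self) -> float:
        return self.next_heel_strike - self.heel_strike

    @property
    def stance_duration(self) -> float:
        return self.toe_off - self.heel_strike

    def to_tuple(self):
        return (self.heel_strike, self.toe_off, self.next_heel_strike)


@dataclass
class ProcessedTrial:
    """Single-rate, conditioned, stride-annotated trial ready for fitting."""

    timebase: np.ndarray
    emg_sol: np.ndarray
    emg_ta: np.ndarray
    F: np.ndarray
    HA: np.ndarray
    stride_events: list[StrideEvent]
    condition: str = "self-selected"
    subject_id: str = "S1"
    trial_id: str = "T1"
    side: str = "left"
    body_weight: float = 750.0

    def __post_init__(self):
        for name in ("timebase", "emg_sol", "emg_ta", "F", "HA"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.emg_sol < 0) or np.any(self.emg_ta < 0):
            raise InvalidValueError("conditioned EMG must be nonnegative")
        if np.any(self.F < 0):
            raise InvalidValueError("normalized force must be nonnegative")

    @property
    def n_strides(self) -> int:
        return len(self.stride_events)

    @property
    def rate(self) -> float:
        return 1.0 / float(self.timebase[1] - self.timebase[0])


def condition_emg(
    raw,
    rate: float,
    cutoff_hz: float = 40.0,
    order: int = 5,
    zero_phase: bool = True,
):
    """Centre, rectify and low-pass filter a raw EMG series into an envelope.

    The low-pass is an order-5 Butterworth at 40 Hz.  By default it is
    applied forward-backward (zero phase, order effectively doubled) so the
    envelope keeps the burst timing that the model fit depends on; set
    ``zero_phase=False`` for a single causal pass.  Filtering a rectified
    signal can undershoot slightly below zero, so the output is clamped at 0.
    """
    raw = np.asarray(raw, dtype=float)
    if rate <= 2.0 * cutoff_hz:
        raise InvalidParameterError(
            f"sampling rate {rate} Hz must exceed twice the cutoff {cutoff_hz} Hz"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=rate, output="sos")
    # forward-backward filtering needs ~3 reflected samples per 2nd-order stage
    min_len = 3 * (2 * sos.shape[0] + 1)
    if raw.size <= min_len:
        raise InsufficientDataError(
            f"EMG series of length {raw.size} too short to filter (need > {min_len})"
        )
    rectified = np.abs(raw - np.mean(raw))
    if zero_phase:
        env = sosfiltfilt(sos, rectified)
    else:
        env = sosfilt(sos, rectified)
    return np.maximum(0.0, env)


def normalize_force(force_raw, body_weight: float):
    """Divide vertical force [N] by body weight [N]; negative sensor
    readings are clamped to zero first (pressure insoles cannot pull)."""
    if body_weight <= 0:
        raise InvalidParameterError(f"body_weight must be > 0, got {body_weight}")
    force = np.maximum(0.0, np.asarray(force_raw, dtype=float))
    return force / body_weight


def resample_common(
    channels: dict[str, tuple[np.ndarray, np.ndarray]],
    rate: float = 200.0,
):
    """Linearly interpolate all channels onto one uniform timebase.

    ``channels`` maps name -> (time, values).  The timebase covers the
    overlapping interval of all channels at the requested rate.

    Returns ``(timebase, resampled)`` with ``resampled`` keyed like the
    input.
    """
    if rate <= 0:
        raise InvalidParameterError("rate must be > 0")
    starts, ends = [], []
    for name, (t, v) in channels.items():
        t = np.asarray(t, dtype=float)
        if t.size < 2:
            raise InsufficientDataError(f"channel {name!r} has < 2 samples")
        starts.append(t[0])
        ends.append(t[-1])
    t_start, t_end = max(starts), min(ends)
    if t_end <= t_start:
        raise AlignmentError(
            f"channels share no overlapping interval ({t_start:.4g} .. {t_end:.4g})"
        )
    n = int(np.floor((t_end - t_start) * rate)) + 1
    timebase = t_start + np.arange(n) / rate
    resampled = {
        name: np.interp(timebase, np.asarray(t, float), np.asarray(v, float))
        for name, (t, v) in channels.items()
    }
    return timebase, resampled


def detect_strides(
    F,
    timebase,
    threshold: float = 0.05,
    debounce_s: float = 0.05,
    min_stride_s: float = 0.4,
) -> list[StrideEvent]:
    """Segment a normalized force profile into strides.

    Heel strike is the upward crossing of ``threshold`` [body weights], toe
    off the downward crossing.  Contact/swing intervals shorter than
    ``debounce_s`` are merged away; strides shorter than ``min_stride_s`` or
    without a swing interval are rejected.
    """
    F = np.asarray(F, dtype=float)
    t = np.asarray(timebase, dtype=float)
    if F.shape != t.shape:
        raise InvalidValueError("F and timebase must have equal length")
    dt = float(t[1] - t[0])
    min_samples = max(1, int(round(debounce_s / dt)))

    contact = F > threshold
    contact = _debounce(contact, min_samples)

    # rising/falling edges
    d = np.diff(contact.astype(np.int8))
    rises = np.flatnonzero(d == 1) + 1
    falls = np.flatnonzero(d == -1) + 1
    if contact[0]:
        # trial starts mid-stance: that contact has no heel strike, drop it
        falls = falls[falls > (rises[0] if rises.size else len(contact))]

    strides: list[StrideEvent] = []
    for k in range(len(rises) - 1):
        hs, next_hs = t[rises[k]], t[rises[k + 1]]
        fall_idx = falls[(falls > rises[k]) & (falls < rises[k + 1])]
        if fall_idx.size == 0:
            continue  # no swing interval inside this stride
        to = t[fall_idx[0]]
        if next_hs - hs < min_stride_s:
            continue
        strides.append(StrideEvent(hs, to, next_hs))
    if len(strides) < 2:
        raise InsufficientStridesError(
            f"detected only {len(strides)} stride(s); need at least 2"
        )
    return strides


def _debounce(contact: np.ndarray, min_samples: int) -> np.ndarray:
    """Remove contact or swing runs shorter than ``min_samples``."""
    out = contact.copy()
    for target in (False, True):  # first fill short gaps, then drop short contacts
        idx = 0
        n = out.size
        while idx < n:
            if out[idx] == target:
                j = idx
                while j < n and out[j] == target:
                    j += 1
                interior = idx > 0 and j < n
                if interior and (j - idx) < min_samples:
                    out[idx:j] = not target
                idx = j
            else:
                idx += 1
    return out


def preprocess_trial(
    rec: TrialRecording,
    rate: float = 200.0,
    cutoff_hz: float = 40.0,
    filter_order: int = 5,
    zero_phase: bool = True,
    stride_threshold: float = 0.05,
    debounce_s: float = 0.05,
    min_stride_s: float = 0.4,
) -> ProcessedTrial:
    """Full conditioning chain for one trial.

    EMG is conditioned at its native rate, force normalized to body weight,
    all channels resampled to a common uniform timebase (default 200 Hz, the
    force rate) and strides detected from the force profile.
    """
    env_sol = condition_emg(
        rec.emg_sol_raw, rec.emg_rate, cutoff_hz, filter_order, zero_phase
    )
    env_ta = condition_emg(
        rec.emg_ta_raw, rec.emg_rate, cutoff_hz, filter_order, zero_phase
    )
    F = normalize_force(rec.force_raw, rec.body_weight)

    t_emg = np.arange(env_sol.size) / rec.emg_rate
    t_force = np.arange(F.size) / rec.force_rate
    t_hip = np.arange(rec.hip_raw.size) / rec.kin_rate
    timebase, res = resample_common(
        {
            "emg_sol": (t_emg, env_sol),
            "emg_ta": (t_emg, env_ta),
            "F": (t_force, F),
            "HA": (t_hip, rec.hip_raw),
        },
        rate=rate,
    )
    strides = detect_strides(
        res["F"], timebase, stride_threshold, debounce_s, min_stride_s
    )
    return ProcessedTrial(
        timebase=timebase,
        emg_sol=res["emg_sol"],
        emg_ta=res["emg_ta"],
        F=res["F"],
        HA=res["HA"],
        stride_events=strides,
        condition=rec.condition,
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
        side=rec.side,
        body_weight=rec.body_weight,
    )
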