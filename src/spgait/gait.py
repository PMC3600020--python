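"""Per-stride gait components: stance/swing %, hip ROM, peak load, IEMG.

Stance percentage is the force-contact fraction of the stride period;
swing is its complement by definition (measured stance and swing means
need not sum to exactly 100 when computed independently from noisy force
profiles, so the complement convention is made explicit here).  IEMG is
the cumulative trapezoidal integral of the conditioned envelope over the
stride; across conditions it is normalized so that, per muscle, the
largest condition mean equals 1.00 exactly and every other mean is
expressed relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InvalidStrideError,
    InvalidValueError,
    UndefinedNormalizationError,
)
from .preprocessing import ProcessedTrial

__all__ = [
    "GaitComponents",
    "stride_components",
    "trial_components",
    "components_frame",
    "normalize_iemg",
]

COMPONENT_COLUMNS = (
    "stance_pct",
    "swing_pct",
    "hip_rom",
    "max_F",
    "iemg_sol",
    "iemg_ta",
)


@dataclass(frozen=True)
class GaitComponents:
    """One stride's components.

    stance_pct/swing_pct in % of stride period, hip_rom in radians, max_F
    in body weights, iemg_* in envelope*seconds (arbitrary units until the
    cross-condition normalization).
    """

    stride_index: int
    stance_pct: float
    swing_pct: float
    hip_rom: float
    max_F: float
    iemg_sol: float
    iemg_ta: float

    def to_dict(self) -> dict:
        return {
            "stride_index": self.stride_index,
            "stance_pct": self.stance_pct,
            "swing_pct": self.swing_pct,
            "hip_rom": self.hip_rom,
            "max_F": self.max_F,
            "iemg_sol": self.iemg_sol,
            "iemg_ta": self.iemg_ta,
        }


def stride_components(trial: ProcessedTrial, stride_index: int) -> GaitComponents:
    """Components of one stride of a processed trial."""
    if not 0 <= stride_index < trial.n_strides:
        raise InvalidValueError(
            f"stride_index {stride_index} out of range (0..{trial.n_strides - 1})"
        )
    ev = trial.stride_events[stride_index]
    period = ev.next_heel_strike - ev.heel_strike
    if period <= 0:
        raise InvalidStrideError(f"stride {stride_index} has nonpositive duration")
    t = trial.timebase
    mask = (t >= ev.heel_strike) & (t <= ev.next_heel_strike)
    if int(mask.sum()) < 2:
        raise InvalidStrideError(f"stride {stride_index} spans < 2 samples")

    stance_pct = 100.0 * (ev.toe_off - ev.heel_strike) / period
    ha = trial.HA[mask]
    tt = t[mask]
    return GaitComponents(
        stride_index=stride_index,
        stance_pct=stance_pct,
        swing_pct=100.0 - stance_pct,
        hip_rom=float(ha.max() - ha.min()),
        max_F=float(trial.F[mask].max()),
        iemg_sol=float(np.trapezoid(trial.emg_sol[mask], tt)),
        iemg_ta=float(np.trapezoid(trial.emg_ta[mask], tt)),
    )


def trial_components(trial: ProcessedTrial) -> list[GaitComponents]:
    """Components for every stride of the trial."""
    return [stride_components(trial, k) for k in range(trial.n_strides)]


def components_frame(trials: list[ProcessedTrial]) -> pd.DataFrame:
    """One row per stride across trials, with trial identifiers attached."""
    rows = []
    for trial in trials:
        for comp in trial_components(trial):
            row = comp.to_dict()
            row.update(
                condition=trial.condition,
                subject_id=trial.subject_id,
                trial_id=trial.trial_id,
                side=trial.side,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def normalize_iemg(
    strides: pd.DataFrame,
    muscles: tuple[str, ...] = ("iemg_sol", "iemg_ta"),
    by: str = "condition",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize IEMG so the largest condition mean is 1.00 per muscle.

    Returns ``(condition_means, per_stride)``: the per-condition normalized
    means (max exactly 1.0 for each muscle) and a copy of ``strides`` with
    the same per-muscle divisor applied to every stride.
    """
    if strides.empty:
        raise UndefinedNormalizationError("no strides to normalize")
    for col in muscles:
        if (np.asarray(strides[col]) < 0).any():
            raise InvalidValueError(f"{col} contains negative values")
    means = strides.groupby(by)[list(muscles)].mean()
    per_stride = strides.copy()
    for col in muscles:
        ref = means[col].max()
        if ref <= 0:
            raise UndefinedNormalizationError(
                f"all condition means of {col} are zero"
            )
        means[col] = means[col] / ref
        per_stride[col] = per_stride[col] / ref
    return means, per_stride
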