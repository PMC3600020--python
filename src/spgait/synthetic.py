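"""Seeded synthetic treadmill-gait generator.

No recordings ship with this package, so every pipeline stage is exercised
on synthetic trials that emulate steady-state treadmill walking at five
conditions (3.5, 4.0, 4.5 km/h, self-selected ~4.8 km/h, and exaggerated
"silly" walking): quasi-periodic vertical force with a double-peaked stance
profile and exactly zero force in swing, a near-sinusoidal hip
flexion/extension angle peaking shortly before heel strike, and alternating
SOL/TA envelopes (SOL bursting in stance, TA around swing).

Condition defaults follow the usual speed trends of treadmill gait: stance
fraction decreases and hip range, peak load and integrated EMG increase
with speed, with the silly condition largest in hip range and EMG and most
variable stride to stride.

Two EMG modes exist.  ``template`` paints raised-cosine bursts whose
per-stride integral is controlled exactly; ``oscillator`` forward-simulates
a documented ground-truth parameter set driven by the generated force and
hip angle, which gives fitting tests a recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .oscillator import (
    DriveSignals,
    OscillatorParameters,
    default_initial_state,
    simulate,
)
from .preprocessing import ProcessedTrial, StrideEvent, TrialRecording

__all__ = [
    "ConditionSpec",
    "SyntheticConfig",
    "GroundTruth",
    "GROUND_TRUTH_PARAMS",
    "generate_force",
    "generate_hip",
    "generate_emg",
    "make_processed_trial",
    "generate_trial",
    "generate_dataset",
]

#: A fixed, documented parameter set that produces stable alternating
#: SOL/TA bursts under the generated drives: SOL active through stance, TA
#: bursting around swing, for every default condition.  It was found once by
#: matching the model output to alternating burst templates and then frozen.
#: With the 1 s membrane constant, burst shaping is carried mainly by the
#: hip-angle terms and the drive-rate terms (large w, v) rather than by the
#: load magnitude alone; adaptation is fast in the flexor pathway
#: (T2 << T1), strong in both.
GROUND_TRUTH_PARAMS = OscillatorParameters(
    a_self=0.0,
    a_mut=-3.6,
    b1=5.1,
    b2=4.4,
    T1=0.6,
    T2=0.06,
    m1=7.3,
    m2=9.5,
    n1=-7.5,
    n2=5.1,
    w1=5.6,
    w2=-12.0,
    v1=-6.4,
    v2=7.1,
    r1=2.4,
    r2=80.0,
)


@dataclass(frozen=True)
class ConditionSpec:
    """Per-condition gait morphology.

    ``hip_amplitude`` is the half-range [rad]; ``iemg_sol``/``iemg_ta`` the
    target per-stride EMG integrals [envelope*s]; ``amp_jitter`` the SD of
    the multiplicative stride-to-stride amplitude jitter.
    """

    speed_kmh: float
    stride_s: float
    stance_fraction: float
    hip_amplitude: float
    force_peak: float
    iemg_sol: float
    iemg_ta: float
    amp_jitter: float = 0.02

    def __post_init__(self):
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        for name in ("stride_s", "hip_amplitude", "force_peak", "iemg_sol", "iemg_ta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _default_conditions() -> dict[str, ConditionSpec]:
    return {
        "3.5": ConditionSpec(3.5, 1.16, 0.666, 0.335, 1.11, 0.47, 0.42),
        "4.0": ConditionSpec(4.0, 1.10, 0.656, 0.365, 1.17, 0.51, 0.47),
        "4.5": ConditionSpec(4.5, 1.06, 0.652, 0.380, 1.23, 0.53, 0.51),
        "self-selected": ConditionSpec(4.8, 1.03, 0.650, 0.385, 1.26, 0.55, 0.53),
        "silly": ConditionSpec(3.8, 1.25, 0.633, 0.420, 1.25, 0.69, 0.65, 0.06),
    }


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the conditions the pipeline is
    tested under (six consecutive steady-state strides per trial, three
    trials per condition, native rates 2000/200/100 Hz)."""

    conditions: dict[str, ConditionSpec] = field(default_factory=_default_conditions)
    n_strides: int = 6
    n_trials: int = 3
    seed: int = 0
    emg_mode: str = "oscillator"  # or "template"
    noise_sd: float = 0.0  # envelope noise as fraction of envelope peak
    emg_rate: float = 2000.0
    force_rate: float = 200.0
    kin_rate: float = 100.0
    body_weight: float = 749.6  # N (76.4 kg subject)
    hip_offset: float = 0.10  # rad, mean hip angle
    hip_phase_lead: float = 0.05  # peak flexion this fraction of a stride before HS
    phase_jitter_s: float = 0.0  # SD of per-trial hip phase jitter
    lead_in_s: float = 0.30  # swing time before the first heel strike

    def __post_init__(self):
        if self.emg_mode not in ("oscillator", "template"):
            raise ValueError(f"unknown emg_mode {self.emg_mode!r}")
        if self.n_strides < 2 or self.n_trials < 1:
            raise ValueError("need n_strides >= 2 and n_trials >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knows: truth for recovery tests downstream."""

    stride_events: list[tuple[float, float, float]]
    condition: str
    emg_mode: str
    seed: int | None = None
    true_params: OscillatorParameters | None = None
    condition_effects: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# waveform primitives

def _raised_cosine(u, center, half_width, flat=0.0):
    """cos^2-shaped bump of unit peak on phase axis u (no wraparound).

    ``flat`` widens the apex into a plateau covering that fraction of the
    half-width, so a sampled series attains the peak value exactly.
    """
    z = np.abs(u - center) / half_width
    zz = np.clip((z - flat) / (1.0 - flat), 0.0, 1.0)
    return np.where(z < 1.0, 0.5 * (1.0 + np.cos(np.pi * zz)), 0.0)


def _stride_grid(cfg: SyntheticConfig, spec: ConditionSpec):
    """Heel-strike times (n_strides + 1 of them) and total trial duration."""
    hs = cfg.lead_in_s + np.arange(cfg.n_strides + 1) * spec.stride_s
    t_end = hs[-1] + 0.35 * spec.stride_s
    return hs, t_end


def _stance_profile(u, base=0.15):
    """Normalized double-peak stance shape on u in [0, 1], unit maximum.

    Two flat-topped raised-cosine bumps peak at 25% and 75% of stance above
    a plateau ``base``.  Contact starts and ends discontinuously at the
    stance boundaries (load >= base everywhere in stance, exactly zero in
    swing), so threshold-crossing stride detection lands within one sample
    of the true events, and the plateaued apex makes the sampled maximum
    equal the nominal peak exactly.
    """
    bumps = _raised_cosine(u, 0.25, 0.25, flat=0.10) + _raised_cosine(
        u, 0.75, 0.25, flat=0.10
    )
    return base + (1.0 - base) * np.minimum(bumps, 1.0)


def generate_force(
    cfg: SyntheticConfig,
    condition: str,
    rng: np.random.Generator,
    timebase: np.ndarray | None = None,
):
    """Normalized vertical force series for one trial.

    Returns ``(timebase, F)`` at the insole rate unless a timebase is
    given.  Swing samples are exactly zero; with jitter off the trial
    maximum equals the condition's ``force_peak`` exactly.
    """
    spec = cfg.conditions[condition]
    hs, t_end = _stride_grid(cfg, spec)
    if timebase is None:
        timebase = np.arange(0.0, t_end, 1.0 / cfg.force_rate)
    F = np.zeros_like(timebase)
    stance_dur = spec.stance_fraction * spec.stride_s
    jitter = 1.0 + spec.amp_jitter * rng.standard_normal(hs.size)
    jitter = np.clip(jitter, 0.2, None)
    if spec.amp_jitter == 0.0:
        jitter[:] = 1.0
    for k, h in enumerate(hs):
        mask = (timebase >= h) & (timebase < h + stance_dur)
        u = (timebase[mask] - h) / stance_dur
        F[mask] = spec.force_peak * jitter[k] * _stance_profile(u)
    return timebase, F


def generate_hip(
    cfg: SyntheticConfig,
    condition: str,
    rng: np.random.Generator,
    timebase: np.ndarray | None = None,
):
    """Hip flexion/extension angle series [rad] for one trial.

    A sinusoid at stride frequency with range ``2 * hip_amplitude``, peak
    flexion ``hip_phase_lead`` of a stride before each heel strike, plus an
    optional seeded per-trial phase jitter.
    """
    spec = cfg.conditions[condition]
    hs, t_end = _stride_grid(cfg, spec)
    if timebase is None:
        timebase = np.arange(0.0, t_end, 1.0 / cfg.kin_rate)
    phase_shift = (
        rng.normal(0.0, cfg.phase_jitter_s) if cfg.phase_jitter_s > 0 else 0.0
    )
    t_peak = hs[0] - cfg.hip_phase_lead * spec.stride_s + phase_shift
    HA = cfg.hip_offset + spec.hip_amplitude * np.cos(
        2.0 * np.pi * (timebase - t_peak) / spec.stride_s
    )
    return timebase, HA


def _template_envelopes(cfg, spec, timebase, hs0, rng):
    """Raised-cosine SOL (20-60% of stride) and TA (55-105%) bursts whose
    per-stride integral matches the condition's IEMG targets exactly
    (jitter and noise off)."""
    phase = (timebase - hs0) / spec.stride_s
    stride_idx = np.floor(phase).astype(int)
    u = phase - stride_idx
    # unit-peak bumps; integral over one stride = half_width * stride_s
    sol_shape = _raised_cosine(u, 0.40, 0.20)
    ta_shape = _raised_cosine(u, 0.80, 0.25) + _raised_cosine(u - 1.0, 0.80, 0.25)
    amp_sol = spec.iemg_sol / (0.20 * spec.stride_s)
    amp_ta = spec.iemg_ta / (0.25 * spec.stride_s)
    n_str = int(stride_idx.max()) + 2
    jit = 1.0 + spec.amp_jitter * rng.standard_normal((2, max(n_str, 1) + 1))
    jit = np.clip(jit, 0.2, None)
    if spec.amp_jitter == 0.0:
        jit[:] = 1.0
    idx = np.clip(stride_idx, 0, jit.shape[1] - 1)
    sol = amp_sol * sol_shape * jit[0, idx]
    ta = amp_ta * ta_shape * jit[1, idx]
    return sol, ta


def _oscillator_envelopes(params, timebase, F, HA):
    drives = DriveSignals(timebase, F, HA)
    out = simulate(params, drives, default_initial_state(drives))
    return out.y1, out.y2


def generate_emg(
    cfg: SyntheticConfig,
    condition: str,
    force: tuple[np.ndarray, np.ndarray],
    hip: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    timebase: np.ndarray | None = None,
):
    """SOL/TA EMG envelopes for one trial, plus the generator's ground truth.

    ``force``/``hip`` are (time, values) pairs for the same condition.  In
    ``oscillator`` mode the documented ground-truth parameter set is
    forward-simulated under those drives; in ``template`` mode alternating
    raised-cosine bursts are painted with exact per-stride integrals.
    Seeded Gaussian envelope noise (SD = ``noise_sd`` x envelope peak) is
    added and clamped at zero.
    """
    spec = cfg.conditions[condition]
    hs, t_end = _stride_grid(cfg, spec)
    if timebase is None:
        timebase = np.arange(0.0, t_end, 1.0 / cfg.emg_rate)
    tF, Fv = force
    tH, Hv = hip
    F = np.interp(timebase, tF, Fv)
    HA = np.interp(timebase, tH, Hv)

    true_params = None
    if cfg.emg_mode == "oscillator":
        true_params = GROUND_TRUTH_PARAMS
        sol, ta = _oscillator_envelopes(true_params, timebase, F, HA)
    else:
        sol, ta = _template_envelopes(cfg, spec, timebase, hs[0], rng)

    if cfg.noise_sd > 0:
        sol = sol + cfg.noise_sd * sol.max() * rng.standard_normal(sol.size)
        ta = ta + cfg.noise_sd * ta.max() * rng.standard_normal(ta.size)
        sol = np.maximum(0.0, sol)
        ta = np.maximum(0.0, ta)

    stance_dur = spec.stance_fraction * spec.stride_s
    events = [
        (hs[k], hs[k] + stance_dur, hs[k + 1]) for k in range(cfg.n_strides)
    ]
    truth = GroundTruth(
        stride_events=events,
        condition=condition,
        emg_mode=cfg.emg_mode,
        true_params=true_params,
        condition_effects={
            "speed_kmh": spec.speed_kmh,
            "stride_s": spec.stride_s,
            "stance_fraction": spec.stance_fraction,
            "hip_range": 2.0 * spec.hip_amplitude,
            "force_peak": spec.force_peak,
            "iemg_sol": spec.iemg_sol,
            "iemg_ta": spec.iemg_ta,
        },
    )
    return (sol, ta), truth


def make_processed_trial(
    cfg: SyntheticConfig,
    condition: str,
    seed: int | None = None,
    rate: float = 200.0,
    subject_id: str = "SYN",
    trial_id: str = "T1",
    side: str = "left",
) -> tuple[ProcessedTrial, GroundTruth]:
    """Generate a trial directly at the common analysis rate.

    Bypasses raw-signal synthesis and conditioning: the envelopes, force and
    hip series are placed on one uniform timebase and annotated with the
    generator's true stride events.  This is the route for fitting tests,
    where the EMG must equal the ground-truth model output exactly when
    noise is off.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    spec = cfg.conditions[condition]
    hs, t_end = _stride_grid(cfg, spec)
    timebase = np.arange(0.0, t_end, 1.0 / rate)
    _, F = generate_force(cfg, condition, rng, timebase)
    _, HA = generate_hip(cfg, condition, rng, timebase)
    (sol, ta), truth = generate_emg(
        cfg, condition, (timebase, F), (timebase, HA), rng, timebase
    )
    truth.seed = cfg.seed if seed is None else seed
    trial = ProcessedTrial(
        timebase=timebase,
        emg_sol=sol,
        emg_ta=ta,
        F=F,
        HA=HA,
        stride_events=[StrideEvent(*e) for e in truth.stride_events],
        condition=condition,
        subject_id=subject_id,
        trial_id=trial_id,
        side=side,
        body_weight=cfg.body_weight,
    )
    return trial, truth


def generate_trial(
    cfg: SyntheticConfig,
    condition: str,
    seed: int,
    subject_id: str = "SYN",
    trial_id: str = "T1",
    side: str = "left",
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one raw-level trial at the native mixed rates.

    EMG is synthesized as the envelope amplitude-modulating a zero-mean
    Gaussian carrier at 2000 Hz, so the preprocessing chain (centring,
    rectification, 40 Hz low-pass) is exercised realistically; force is in
    newtons at 200 Hz and hip angle in radians at 100 Hz.
    """
    rng = np.random.default_rng(seed)
    t_force, F = generate_force(cfg, condition, rng)
    t_hip, HA = generate_hip(cfg, condition, rng)
    (sol_env, ta_env), truth = generate_emg(
        cfg, condition, (t_force, F), (t_hip, HA), rng
    )
    truth.seed = seed
    carrier_sol = rng.standard_normal(sol_env.size)
    carrier_ta = rng.standard_normal(ta_env.size)
    rec = TrialRecording(
        emg_sol_raw=sol_env * carrier_sol,
        emg_ta_raw=ta_env * carrier_ta,
        force_raw=F * cfg.body_weight,
        hip_raw=HA,
        body_weight=cfg.body_weight,
        condition=condition,
        emg_rate=cfg.emg_rate,
        force_rate=cfg.force_rate,
        kin_rate=cfg.kin_rate,
        subject_id=subject_id,
        trial_id=trial_id,
        side=side,
    )
    return rec, truth


def generate_dataset(
    cfg: SyntheticConfig,
) -> list[tuple[TrialRecording, GroundTruth]]:
    """All conditions x n_trials raw trials, deterministically seeded from
    ``cfg.seed`` (same seed, byte-identical dataset)."""
    out = []
    for ci, condition in enumerate(cfg.conditions):
        for ti in range(cfg.n_trials):
            seed = int(
                np.random.SeedSequence([cfg.seed, ci, ti]).generate_state(1)[0]
                % (2**31)
            )
            rec, truth = generate_trial(
                cfg,
                condition,
                seed,
                subject_id="SYN",
                trial_id=f"{condition}-{ti + 1:02d}",
                side="left" if ti % 2 == 0 else "right",
            )
            out.append((rec, truth))
    return out
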