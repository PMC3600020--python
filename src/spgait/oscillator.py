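"""Two-neuron Matsuoka oscillator with adaptation and afferent drive.

The model is a mutually inhibiting pair of leaky neurons, one driving the
soleus (subscript 1) and one the tibialis anterior (subscript 2).  Each
neuron ``i`` has an inner state ``x_i``, a rectified output
``y_i = max(0, x_i)`` and a slow adaptation (fatigue) state ``f_i``:

.. math::

    \\dot x_i + x_i = a_{self}\\, y_i + a_{mut}\\, y_j + s_i - b_i f_i,
    \\qquad T_i \\dot f_i + f_i = y_i

with the membrane time constant taken as 1 s, so all dynamics are expressed
in seconds.  Sensory drive enters through first-order-smoothed copies of the
body-weight-normalized vertical load ``F`` and the hip flexion/extension
angle ``HA``:

.. math::

    s_i = m_i p + n_i \\dot p + w_i q + v_i \\dot q, \\qquad
    \\dot p = r_1 (F - p), \\qquad \\dot q = r_2 (HA - q)

Mutual inhibition (``a_mut < 0``) plus adaptation lets the pair alternate;
with ``b = 0`` there is no adaptation and a constant drive produces a
constant output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields

import numpy as np

from . import _integrate
from .errors import (
    InvalidParameterError,
    InvalidValueError,
    SimulationDivergedError,
)

__all__ = [
    "PARAM_NAMES",
    "OscillatorParameters",
    "OscillatorState",
    "DriveSignals",
    "OscillatorOutput",
    "rectify",
    "input_signal",
    "state_derivative",
    "simulate",
    "default_initial_state",
]

#: canonical ordering of the 16 free constants (fit vector layout)
PARAM_NAMES = (
    "a_self", "a_mut", "b1", "b2", "T1", "T2",
    "m1", "m2", "n1", "n2", "w1", "w2", "v1", "v2", "r1", "r2",
)


@dataclass(frozen=True)
class OscillatorParameters:
    """The 16 constants governing dynamics and input weighting.

    The neuron pair is symmetric by construction: a single ``a_self``
    (= a11 = a22, self-excitation, >= 0) and a single ``a_mut``
    (= a12 = a21, mutual inhibition, < 0).  ``b_i``/``T_i`` set the
    strength and lag of adaptation, ``m, n, w, v`` weight the smoothed
    force/hip drives and their rates, and ``r1``/``r2`` are the smoothing
    rates of force and hip angle [1/s].
    """

    a_self: float = 0.0
    a_mut: float = -2.0
    b1: float = 2.5
    b2: float = 2.5
    T1: float = 0.2
    T2: float = 0.2
    m1: float = 1.0
    m2: float = 1.0
    n1: float = 1.0
    n2: float = 1.0
    w1: float = 1.0
    w2: float = 1.0
    v1: float = 1.0
    v2: float = 1.0
    r1: float = 10.0
    r2: float = 10.0

    def __post_init__(self):
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError("all oscillator parameters must be finite")
        if self.a_mut >= 0:
            raise InvalidParameterError(
                f"a_mut must be < 0 (mutual inhibition), got {self.a_mut}"
            )
        if self.a_self < 0:
            raise InvalidParameterError(
                f"a_self must be >= 0 (self-excitation), got {self.a_self}"
            )
        for name in ("T1", "T2", "r1", "r2"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("b1", "b2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "OscillatorParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise InvalidParameterError(
                f"expected {len(PARAM_NAMES)} parameters, got shape {arr.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "OscillatorParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_json(cls, s: str) -> "OscillatorParameters":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class OscillatorState:
    """The 6 dynamical variables: inner states x1/x2, adaptations f1/f2,
    smoothed force p [body weights] and smoothed hip angle q [rad]."""

    x1: float = 0.0
    x2: float = 0.0
    f1: float = 0.0
    f2: float = 0.0
    p: float = 0.0
    q: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.to_array())):
            raise InvalidValueError("oscillator state must be finite")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.x1, self.x2, self.f1, self.f2, self.p, self.q], dtype=float
        )

    @classmethod
    def from_array(cls, arr) -> "OscillatorState":
        arr = np.asarray(arr, dtype=float)
        return cls(*arr.tolist())

    @property
    def y1(self) -> float:
        return max(0.0, self.x1)

    @property
    def y2(self) -> float:
        return max(0.0, self.x2)


class DriveSignals:
    """Afferent drive series: uniform timebase [s], normalized force F
    [body weights, >= 0] and hip angle HA [rad]."""

    def __init__(self, timebase, F, HA):
        self.timebase = np.asarray(timebase, dtype=float)
        self.F = np.asarray(F, dtype=float)
        self.HA = np.asarray(HA, dtype=float)
        if not (self.timebase.shape == self.F.shape == self.HA.shape):
            raise InvalidValueError("timebase, F and HA must have equal length")
        if self.timebase.ndim != 1 or self.timebase.size < 2:
            raise InvalidValueError("need at least two samples")
        dt = np.diff(self.timebase)
        if np.any(dt <= 0):
            raise InvalidValueError("timebase must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise InvalidValueError("timebase must be uniformly spaced")
        if not np.all(np.isfinite(self.F)) or not np.all(np.isfinite(self.HA)):
            raise InvalidValueError("drive signals must be finite")
        if np.any(self.F < 0):
            raise InvalidValueError("normalized force must be >= 0 everywhere")

    @property
    def dt(self) -> float:
        return float(self.timebase[1] - self.timebase[0])

    def __len__(self) -> int:
        return self.timebase.size


@dataclass
class OscillatorOutput:
    """Simulated muscle activations on the drive timebase.

    ``y1``/``y2`` are the rectified SOL/TA outputs; ``state_trajectory``
    holds the full (n, 6) state history.
    """

    timebase: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    state_trajectory: np.ndarray


def rectify(x):
    """Half-wave rectification ``y = max(0, x)`` applied to a scalar or array."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidValueError("rectify: input must be finite")
    out = np.maximum(0.0, arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def input_signal(p, p_dot, q, q_dot, params: OscillatorParameters, neuron_index: int):
    """Afferent drive ``s_i = m_i p + n_i ṗ + w_i q + v_i q̇`` for neuron 1 or 2."""
    if neuron_index not in (1, 2):
        raise InvalidParameterError(f"neuron_index must be 1 or 2, got {neuron_index}")
    i = str(neuron_index)
    m = getattr(params, "m" + i)
    n = getattr(params, "n" + i)
    w = getattr(params, "w" + i)
    v = getattr(params, "v" + i)
    s = m * p + n * p_dot + w * q + v * q_dot
    if not np.all(np.isfinite(s)):
        raise InvalidValueError("input_signal: non-finite result")
    return s


def state_derivative(
    state: OscillatorState,
    F_t: float,
    HA_t: float,
    params: OscillatorParameters,
) -> np.ndarray:
    """Time derivative of the 6-vector (ẋ1, ẋ2, ḟ1, ḟ2, ṗ, q̇).

    The drive rates ṗ and q̇ entering s_i are the analytic first-order-lag
    expressions evaluated at this same instant, not numerical differences.
    """
    y1, y2 = state.y1, state.y2
    p_dot = params.r1 * (F_t - state.p)
    q_dot = params.r2 * (HA_t - state.q)
    s1 = input_signal(state.p, p_dot, state.q, q_dot, params, 1)
    s2 = input_signal(state.p, p_dot, state.q, q_dot, params, 2)
    dx1 = -state.x1 + params.a_self * y1 + params.a_mut * y2 + s1 - params.b1 * state.f1
    dx2 = -state.x2 + params.a_self * y2 + params.a_mut * y1 + s2 - params.b2 * state.f2
    df1 = (y1 - state.f1) / params.T1
    df2 = (y2 - state.f2) / params.T2
    return np.array([dx1, dx2, df1, df2, p_dot, q_dot], dtype=float)


def default_initial_state(
    drives: DriveSignals, x1: float = 0.0, x2: float = 0.0
) -> OscillatorState:
    """Steady-state-consistent start: f_i = y_i(0), p = F(0), q = HA(0).

    ``x1``/``x2`` default to zero; the fitting stage sets them to the first
    conditioned-EMG sample of each muscle.
    """
    return OscillatorState(
        x1=x1,
        x2=x2,
        f1=max(0.0, x1),
        f2=max(0.0, x2),
        p=float(drives.F[0]),
        q=float(drives.HA[0]),
    )


def simulate(
    params: OscillatorParameters,
    drives: DriveSignals,
    initial_state: OscillatorState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OscillatorOutput:
    """Integrate the oscillator over the drive timebase.

    Uses an adaptive Dormand-Prince 5(4) stepper with the drives linearly
    interpolated between samples; on step failure (the system turns stiff
    for very small T_i) it falls back to the implicit Radau method.

    Raises :class:`SimulationDivergedError`, naming the time reached, if
    both integrators fail.
    """
    if initial_state is None:
        initial_state = default_initial_state(drives)
    y0 = initial_state.to_array()
    P = params.to_array()
    traj, status, t_reached = _integrate.integrate_dp54(
        P, drives.timebase, drives.F, drives.HA, y0, rtol, atol
    )
    if status != _integrate.OK:
        traj = _simulate_radau(P, drives, y0, rtol, atol)
    y1 = np.maximum(0.0, traj[:, 0])
    y2 = np.maximum(0.0, traj[:, 1])
    return OscillatorOutput(
        timebase=drives.timebase.copy(), y1=y1, y2=y2, state_trajectory=traj
    )


def _simulate_radau(P, drives: DriveSignals, y0, rtol, atol):
    """Implicit fallback for stiff parameter corners."""
    from scipy.integrate import solve_ivp

    t = drives.timebase
    t0, dts = t[0], drives.dt
    F, HA = drives.F, drives.HA
    k = np.empty(6)

    def rhs(ti, yi):
        _integrate._eval_rhs(ti, yi, P, F, HA, t0, dts, k)
        return k.copy()

    sol = solve_ivp(
        rhs, (t[0], t[-1]), y0, method="Radau", t_eval=t, rtol=rtol, atol=atol
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        t_reached = sol.t[-1] if sol.t.size else t[0]
        raise SimulationDivergedError(t_reached)
    return sol.y.T
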