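"""Nonlinear least-squares estimation of oscillator parameters from EMG.

The two neuron outputs are fitted simultaneously: the residual vector
concatenates (y1 - SOL) and (y2 - TA) over all samples from the second
stride onward (the model output is oscillatory only after the first stride,
which is discarded).  Inner states start from the first conditioned-EMG
sample of each muscle; the smoothed drives start at the first force/hip
sample.  Optimization is bound-constrained trust-region-reflective least
squares, terminating once the relative change in summed squared error
between two iterations falls below ``rel_tol`` (default 0.001), with
seeded randomized restarts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitFailedError,
    InvalidParameterError,
    SimulationDivergedError,
    UndefinedCorrelationError,
)
from .oscillator import (
    PARAM_NAMES,
    DriveSignals,
    OscillatorOutput,
    OscillatorParameters,
    OscillatorState,
    simulate,
)
from .preprocessing import ProcessedTrial

__all__ = [
    "FitOptions",
    "FitResult",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
    "objective",
    "fit_trial",
    "correlation",
    "r_average",
]

log = logging.getLogger(__name__)

_EPS_T = 1e-3  # lower bound on time constants / smoothing-rate floor
_PENALTY = 1e3  # finite residual magnitude for diverged simulations

#: box constraints encoding the sign structure: mutual inhibition strictly
#: negative, self-excitation nonnegative, time constants and smoothing
#: rates positive, adaptation gains nonnegative, input weights free.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a_self": (0.0, 10.0),
    "a_mut": (-20.0, -1e-6),
    "b1": (0.0, 20.0),
    "b2": (0.0, 20.0),
    "T1": (_EPS_T, 10.0),
    "T2": (_EPS_T, 10.0),
    "m1": (-50.0, 50.0),
    "m2": (-50.0, 50.0),
    "n1": (-50.0, 50.0),
    "n2": (-50.0, 50.0),
    "w1": (-50.0, 50.0),
    "w2": (-50.0, 50.0),
    "v1": (-50.0, 50.0),
    "v2": (-50.0, 50.0),
    "r1": (_EPS_T, 100.0),
    "r2": (_EPS_T, 100.0),
}

DEFAULT_INIT = OscillatorParameters()  # a_self=0, a_mut=-2, b=2.5, T=0.2, r=10, weights 1


@dataclass
class FitOptions:
    """Optimizer settings.

    ``rel_tol`` is the relative SSE-change termination threshold;
    ``max_iter`` caps trust-region iterations (each costs roughly one
    Jacobian, i.e. n_params + 1 simulations); ``muscle_weighting`` is the
    (SOL, TA) residual weight pair.
    """

    rel_tol: float = 1e-3
    max_iter: int = 50
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    n_restarts: int = 5
    seed: int = 0
    muscle_weighting: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.rel_tol <= 0:
            raise InvalidParameterError("rel_tol must be > 0")
        if self.max_iter < 1:
            raise InvalidParameterError("max_iter must be >= 1")
        if self.n_restarts < 1:
            raise InvalidParameterError("n_restarts must be >= 1")
        if any(w < 0 for w in self.muscle_weighting):
            raise InvalidParameterError("muscle weights must be >= 0")
        unknown = set(self.bounds) - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(f"unknown bound keys: {sorted(unknown)}")

    def bounds_arrays(self):
        lo = np.array([self.bounds[n][0] for n in PARAM_NAMES])
        hi = np.array([self.bounds[n][1] for n in PARAM_NAMES])
        return lo, hi


@dataclass
class FitResult:
    """Fitted parameters with per-muscle fit quality.

    ``R_sol``/``R_ta`` are Pearson correlations between model output and
    conditioned EMG from stride 2 onward; ``R_ave`` their arithmetic mean.
    """

    params: OscillatorParameters
    R_sol: float
    R_ta: float
    R_ave: float
    sse: float
    n_iter: int
    converged: bool
    strides_used: list[int]
    restart_costs: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "R_sol": self.R_sol,
            "R_ta": self.R_ta,
            "R_ave": self.R_ave,
            "sse": self.sse,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "strides_used": list(self.strides_used),
            "restart_costs": [float(c) for c in self.restart_costs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            params=OscillatorParameters.from_dict(d["params"]),
            R_sol=float(d["R_sol"]),
            R_ta=float(d["R_ta"]),
            R_ave=float(d["R_ave"]),
            sse=float(d["sse"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            strides_used=[int(i) for i in d["strides_used"]],
            restart_costs=[float(c) for c in d.get("restart_costs", [])],
        )


def _fit_mask(trial: ProcessedTrial, from_stride: int = 1) -> np.ndarray:
    """Samples entering the objective: from the heel strike of
    ``stride_events[from_stride]`` through the end of the last stride."""
    if trial.n_strides < from_stride + 1:
        raise InvalidParameterError(
            f"trial has {trial.n_strides} strides; need > {from_stride}"
        )
    t = trial.timebase
    t_lo = trial.stride_events[from_stride].heel_strike
    t_hi = trial.stride_events[-1].next_heel_strike
    return (t >= t_lo) & (t <= t_hi)


def _simulate_trial(params: OscillatorParameters, trial: ProcessedTrial):
    drives = DriveSignals(trial.timebase, trial.F, trial.HA)
    x1_0 = float(trial.emg_sol[0])
    x2_0 = float(trial.emg_ta[0])
    init = OscillatorState(
        x1=x1_0,
        x2=x2_0,
        f1=max(0.0, x1_0),
        f2=max(0.0, x2_0),
        p=float(trial.F[0]),
        q=float(trial.HA[0]),
    )
    return simulate(params, drives, init)


def objective(
    params: OscillatorParameters,
    trial: ProcessedTrial,
    muscle_weighting: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Weighted residual vector (model minus EMG), strides 2+ only.

    A diverged simulation yields finite large-penalty residuals rather than
    an exception, so a line search can retreat from a bad parameter region.
    """
    mask = _fit_mask(trial)
    sw, tw = math.sqrt(muscle_weighting[0]), math.sqrt(muscle_weighting[1])
    try:
        out = _simulate_trial(params, trial)
    except SimulationDivergedError as exc:
        log.warning("simulation diverged during fit: %s", exc)
        return np.full(2 * int(mask.sum()), _PENALTY)
    res_sol = sw * (out.y1[mask] - trial.emg_sol[mask])
    res_ta = tw * (out.y2[mask] - trial.emg_ta[mask])
    res = np.concatenate([res_sol, res_ta])
    if not np.all(np.isfinite(res)):
        return np.full(res.size, _PENALTY)
    return res


def correlation(
    model: OscillatorOutput,
    trial: ProcessedTrial,
    from_stride: int = 1,
) -> tuple[float, float, float]:
    """Pearson R per muscle over concatenated samples from ``from_stride``
    onward, plus their arithmetic mean R_ave."""
    mask = _fit_mask(trial, from_stride)
    if int(mask.sum()) < 3:
        raise UndefinedCorrelationError("need at least 3 overlapping samples")
    rs = _pearson(model.y1[mask], trial.emg_sol[mask])
    rt = _pearson(model.y2[mask], trial.emg_ta[mask])
    return rs, rt, r_average(rs, rt)


def r_average(r_sol: float, r_ta: float) -> float:
    """Arithmetic mean of the two per-muscle correlations."""
    return (r_sol + r_ta) / 2.0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        raise UndefinedCorrelationError("zero-variance channel")
    return float(np.corrcoef(a, b)[0, 1])


def _jitter_params(
    x0: np.ndarray, rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Randomized restart point: log-uniform factor on positive scale
    parameters (b, T, r) and |a_mut|, uniform +/-50%-of-scale shift on the
    input weights."""
    x = x0.copy()
    for i, name in enumerate(PARAM_NAMES):
        if name in ("b1", "b2", "T1", "T2", "r1", "r2"):
            x[i] = x0[i] * rng.uniform(0.5, 2.0)
        elif name == "a_mut":
            x[i] = x0[i] * rng.uniform(0.5, 2.0)
        elif name == "a_self":
            x[i] = x0[i] + rng.uniform(0.0, 0.5)
        else:  # input weights
            scale = max(1.0, abs(x0[i]))
            x[i] = x0[i] + rng.uniform(-0.5, 0.5) * scale
    return np.clip(x, lo, hi)


def fit_trial(
    trial: ProcessedTrial,
    init: OscillatorParameters | None = None,
    opts: FitOptions | None = None,
) -> FitResult:
    """Fit the oscillator to one processed trial.

    The first restart starts exactly at ``init`` (default
    :data:`DEFAULT_INIT`); later restarts jitter it with the seeded RNG.
    The best restart by final SSE wins.  Raises :class:`FitFailedError`
    with per-restart diagnostics if every restart ended in the divergence
    penalty.
    """
    opts = opts or FitOptions()
    init = init or DEFAULT_INIT
    lo, hi = opts.bounds_arrays()
    x_init = np.clip(init.to_array(), lo, hi)
    if not np.array_equal(x_init, init.to_array()):
        raise InvalidParameterError("initial parameters lie outside the bounds")

    n_par = len(PARAM_NAMES)
    max_nfev = opts.max_iter * (n_par + 1)
    rng = np.random.default_rng(opts.seed)
    mask = _fit_mask(trial)
    n_res = 2 * int(mask.sum())
    penalty_cost = 0.5 * n_res * _PENALTY**2

    best = None
    diagnostics = []
    restart_costs = []
    for k in range(opts.n_restarts):
        x0 = x_init if k == 0 else _jitter_params(x_init, rng, lo, hi)
        res = least_squares(
            lambda x: objective(
                OscillatorParameters.from_array(x), trial, opts.muscle_weighting
            ),
            x0,
            bounds=(lo, hi),
            method="trf",
            ftol=opts.rel_tol,
            xtol=1e-14,
            gtol=1e-14,
            max_nfev=max_nfev,
        )
        restart_costs.append(float(res.cost))
        diagnostics.append(
            {"restart": k, "cost": float(res.cost), "status": int(res.status),
             "nfev": int(res.nfev), "message": res.message}
        )
        if res.cost >= 0.5 * penalty_cost:  # never escaped the penalty region
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailedError(diagnostics)

    params = OscillatorParameters.from_array(best.x)
    out = _simulate_trial(params, trial)
    try:
        R_sol, R_ta, R_ave = correlation(out, trial, from_stride=1)
    except UndefinedCorrelationError:
        # a degenerate fit with a flat output channel has no linear
        # association with the EMG; report R = 0 rather than failing
        log.warning("flat model output; reporting R = 0 for this fit")
        R_sol = R_ta = R_ave = 0.0
    return FitResult(
        params=params,
        R_sol=R_sol,
        R_ta=R_ta,
        R_ave=R_ave,
        sse=float(2.0 * best.cost),
        n_iter=int(best.nfev),
        converged=bool(best.status > 0),
        strides_used=list(range(1, trial.n_strides)),
        restart_costs=restart_costs,
    )
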