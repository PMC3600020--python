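"""Compiled ODE kernels for the two-neuron oscillator.

The right-hand side and a Dormand-Prince 5(4) adaptive stepper are jitted
with numba so that a single trial simulation costs milliseconds; the fitting
stage evaluates the model thousands of times per trial, which makes this the
hot path of the whole pipeline.

Parameter vector layout (shared with :mod:`spgait.oscillator`):
``a_self, a_mut, b1, b2, T1, T2, m1, m2, n1, n2, w1, w2, v1, v2, r1, r2``.
State vector layout: ``x1, x2, f1, f2, p, q``.
"""

import numpy as np
from numba import njit

# integrator status codes
OK = 0
STEP_UNDERFLOW = 1
NONFINITE = 2

_MIN_STEP = 1e-12


@njit(cache=True, fastmath=False)
def _rhs(x1, x2, f1, f2, p, q, Ft, HAt, P, out):
    y1 = x1 if x1 > 0.0 else 0.0
    y2 = x2 if x2 > 0.0 else 0.0
    pdot = P[14] * (Ft - p)
    qdot = P[15] * (HAt - q)
    s1 = P[6] * p + P[8] * pdot + P[10] * q + P[12] * qdot
    s2 = P[7] * p + P[9] * pdot + P[11] * q + P[13] * qdot
    out[0] = -x1 + P[0] * y1 + P[1] * y2 + s1 - P[2] * f1
    out[1] = -x2 + P[0] * y2 + P[1] * y1 + s2 - P[3] * f2
    out[2] = (y1 - f1) / P[4]
    out[3] = (y2 - f2) / P[5]
    out[4] = pdot
    out[5] = qdot


@njit(cache=True, fastmath=False)
def _interp(t, t0, dt, arr):
    # linear interpolation on a uniform timebase, clamped at the ends
    u = (t - t0) / dt
    n = arr.shape[0]
    if u <= 0.0:
        return arr[0]
    if u >= n - 1:
        return arr[n - 1]
    i = int(u)
    frac = u - i
    return arr[i] + (arr[i + 1] - arr[i]) * frac


@njit(cache=True, fastmath=False)
def _eval_rhs(t, y, P, F, HA, t0, dts, k):
    Ft = _interp(t, t0, dts, F)
    HAt = _interp(t, t0, dts, HA)
    _rhs(y[0], y[1], y[2], y[3], y[4], y[5], Ft, HAt, P, k)


@njit(cache=True, fastmath=False)
def integrate_dp54(P, timebase, F, HA, y0, rtol, atol):
    """Adaptive Dormand-Prince 5(4) integration of the oscillator.

    Integrates segment by segment between consecutive sample times, so the
    returned trajectory is evaluated exactly on ``timebase``.

    Returns ``(traj, status, t_reached)`` where ``traj`` has shape
    ``(len(timebase), 6)``.
    """
    n = timebase.shape[0]
    t0 = timebase[0]
    dts = timebase[1] - timebase[0]
    traj = np.empty((n, 6))
    y = y0.copy()
    traj[0] = y

    # Dormand-Prince tableau
    c2, c3, c4, c5 = 0.2, 0.3, 0.8, 8.0 / 9.0
    a21 = 0.2
    a31, a32 = 3.0 / 40.0, 9.0 / 40.0
    a41, a42, a43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
    a51, a52, a53, a54 = (
        19372.0 / 6561.0,
        -25360.0 / 2187.0,
        64448.0 / 6561.0,
        -212.0 / 729.0,
    )
    a61, a62, a63, a64, a65 = (
        9017.0 / 3168.0,
        -355.0 / 33.0,
        46732.0 / 5247.0,
        49.0 / 176.0,
        -5103.0 / 18656.0,
    )
    b1, b3, b4, b5, b6 = (
        35.0 / 384.0,
        500.0 / 1113.0,
        125.0 / 192.0,
        -2187.0 / 6784.0,
        11.0 / 84.0,
    )
    # error weights (5th order minus embedded 4th order)
    e1, e3, e4, e5, e6, e7 = (
        71.0 / 57600.0,
        -71.0 / 16695.0,
        71.0 / 1920.0,
        -17253.0 / 339200.0,
        22.0 / 525.0,
        -1.0 / 40.0,
    )

    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    k5 = np.empty(6)
    k6 = np.empty(6)
    k7 = np.empty(6)
    ytmp = np.empty(6)
    ynew = np.empty(6)

    h = dts  # initial step: one sample interval
    t = t0
    for seg in range(n - 1):
        t_end = timebase[seg + 1]
        while t < t_end - 1e-14:
            if h > t_end - t:
                h = t_end - t
            if h < _MIN_STEP:
                return traj, STEP_UNDERFLOW, t
            _eval_rhs(t, y, P, F, HA, t0, dts, k1)
            for i in range(6):
                ytmp[i] = y[i] + h * a21 * k1[i]
            _eval_rhs(t + c2 * h, ytmp, P, F, HA, t0, dts, k2)
            for i in range(6):
                ytmp[i] = y[i] + h * (a31 * k1[i] + a32 * k2[i])
            _eval_rhs(t + c3 * h, ytmp, P, F, HA, t0, dts, k3)
            for i in range(6):
                ytmp[i] = y[i] + h * (a41 * k1[i] + a42 * k2[i] + a43 * k3[i])
            _eval_rhs(t + c4 * h, ytmp, P, F, HA, t0, dts, k4)
            for i in range(6):
                ytmp[i] = y[i] + h * (
                    a51 * k1[i] + a52 * k2[i] + a53 * k3[i] + a54 * k4[i]
                )
            _eval_rhs(t + c5 * h, ytmp, P, F, HA, t0, dts, k5)
            for i in range(6):
                ytmp[i] = y[i] + h * (
                    a61 * k1[i]
                    + a62 * k2[i]
                    + a63 * k3[i]
                    + a64 * k4[i]
                    + a65 * k5[i]
                )
            _eval_rhs(t + h, ytmp, P, F, HA, t0, dts, k6)
            for i in range(6):
                ynew[i] = y[i] + h * (
                    b1 * k1[i] + b3 * k3[i] + b4 * k4[i] + b5 * k5[i] + b6 * k6[i]
                )
            _eval_rhs(t + h, ynew, P, F, HA, t0, dts, k7)

            # scaled RMS error estimate
            err = 0.0
            finite = True
            for i in range(6):
                if not np.isfinite(ynew[i]):
                    finite = False
                    break
                ei = h * (
                    e1 * k1[i]
                    + e3 * k3[i]
                    + e4 * k4[i]
                    + e5 * k5[i]
                    + e6 * k6[i]
                    + e7 * k7[i]
                )
                sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
                err += (ei / sc) ** 2
            if not finite:
                return traj, NONFINITE, t
            err = np.sqrt(err / 6.0)

            if err <= 1.0:
                t = t + h
                for i in range(6):
                    y[i] = ynew[i]
                fac = 5.0 if err == 0.0 else min(5.0, 0.9 * err ** (-0.2))
                h = h * fac
            else:
                h = h * max(0.2, 0.9 * err ** (-0.2))
        traj[seg + 1] = y
        t = t_end
    return traj, OK, t
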