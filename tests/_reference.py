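"""Independent reference implementations used as oracles in tests.

These deliberately share no code with the package: the oscillator
right-hand side is rewritten from the model definition and integrated with
a plain fixed-step classical Runge-Kutta scheme.
"""

import numpy as np


def reference_rhs(y, F_t, HA_t, p):
    """Model equations written out directly; p is a dict of parameters."""
    x1, x2, f1, f2, ps, qs = y
    y1 = x1 if x1 > 0 else 0.0
    y2 = x2 if x2 > 0 else 0.0
    p_dot = p["r1"] * (F_t - ps)
    q_dot = p["r2"] * (HA_t - qs)
    s1 = p["m1"] * ps + p["n1"] * p_dot + p["w1"] * qs + p["v1"] * q_dot
    s2 = p["m2"] * ps + p["n2"] * p_dot + p["w2"] * qs + p["v2"] * q_dot
    return np.array(
        [
            -x1 + p["a_self"] * y1 + p["a_mut"] * y2 + s1 - p["b1"] * f1,
            -x2 + p["a_self"] * y2 + p["a_mut"] * y1 + s2 - p["b2"] * f2,
            (y1 - f1) / p["T1"],
            (y2 - f2) / p["T2"],
            p_dot,
            q_dot,
        ]
    )


def rk4_fixed_step(params_dict, timebase, F, HA, y0, dt=1e-4):
    """Classical RK4 at fixed dt; drives linearly interpolated.

    Returns the state trajectory evaluated at ``timebase``.
    """
    t_grid = np.asarray(timebase, float)
    F = np.asarray(F, float)
    HA = np.asarray(HA, float)

    def drive(t):
        return (
            np.interp(t, t_grid, F),
            np.interp(t, t_grid, HA),
        )

    traj = np.empty((t_grid.size, 6))
    y = np.array(y0, dtype=float)
    traj[0] = y
    t = t_grid[0]
    for k in range(t_grid.size - 1):
        t_end = t_grid[k + 1]
        while t < t_end - 1e-12:
            h = min(dt, t_end - t)
            Ft, Ht = drive(t)
            k1 = reference_rhs(y, Ft, Ht, params_dict)
            Fm, Hm = drive(t + h / 2)
            k2 = reference_rhs(y + h / 2 * k1, Fm, Hm, params_dict)
            k3 = reference_rhs(y + h / 2 * k2, Fm, Hm, params_dict)
            Fe, He = drive(t + h)
            k4 = reference_rhs(y + h * k3, Fe, He, params_dict)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        traj[k + 1] = y
        t = t_end
    return traj
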