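"""Independent fixed-step integrators used as test oracles.

Deliberately minimal and self-contained (pure Python floats, classical
fourth-order Runge-Kutta): these must not share code with the package's
adaptive integration path.
"""

from __future__ import annotations

import math


def rk4_trajectory(params, t_grid, dt=1e-3):
    """Classical RK4 at fixed step ``dt``, landing exactly on each grid time.

    Returns (f1, f2, ifn) lists aligned with ``t_grid``.
    """
    fr, sr = params.fr, params.sr
    kon, koff, kf, dfr = params.kon, params.koff, params.kf, params.df
    T, H = params.T, params.H

    def rhs(f1, f2, ifn):
        h = ifn**H / (T**H + ifn**H) if ifn > 0.0 else 0.0
        return (
            kon * (fr - f1) - koff * f1,
            kon * h * (sr - f2) - koff * f2,
            kf * (f1 + f2) - dfr * ifn,
        )

    f1, f2, ifn = 0.0, 0.0, 0.0
    out = [(f1, f2, ifn)]
    for t0, t1 in zip(t_grid, t_grid[1:]):
        span = float(t1) - float(t0)
        n = max(1, math.ceil(span / dt))
        h = span / n
        for _ in range(n):
            k1 = rhs(f1, f2, ifn)
            k2 = rhs(f1 + 0.5 * h * k1[0], f2 + 0.5 * h * k1[1], ifn + 0.5 * h * k1[2])
            k3 = rhs(f1 + 0.5 * h * k2[0], f2 + 0.5 * h * k2[1], ifn + 0.5 * h * k2[2])
            k4 = rhs(f1 + h * k3[0], f2 + h * k3[1], ifn + h * k3[2])
            f1 += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            f2 += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            ifn += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        out.append((f1, f2, ifn))
    return (
        [s[0] for s in out],
        [s[1] for s in out],
        [s[2] for s in out],
    )


def f1_closed_form(params, t):
    """Analytic f1(t) from rest: valid for any kf (the f1 equation is linear)."""
    rate = params.kon + params.koff
    return params.kon * params.fr / rate * (1.0 - math.exp(-rate * t))
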