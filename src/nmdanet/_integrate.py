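"""Embedded Runge-Kutta-Fehlberg 4(5) stepping on lists of arrays.

The simulation engine advances membrane potentials (and, in the exact NMDA
backend, the per-source gating pairs) over one grid interval ``dt`` at a time;
spike thresholds are only inspected at grid points, so the integrator is free
to subdivide the interval adaptively.  States are lists of ndarrays so that
heterogeneous blocks (V, S, x) can be integrated together without copying into
a single flat vector.
"""

from __future__ import annotations

import numpy as np

# Fehlberg 4(5) tableau
_C = (0.0, 1.0 / 4.0, 3.0 / 8.0, 12.0 / 13.0, 1.0, 1.0 / 2.0)
_A = (
    (),
    (1.0 / 4.0,),
    (3.0 / 32.0, 9.0 / 32.0),
    (1932.0 / 2197.0, -7200.0 / 2197.0, 7296.0 / 2197.0),
    (439.0 / 216.0, -8.0, 3680.0 / 513.0, -845.0 / 4104.0),
    (-8.0 / 27.0, 2.0, -3544.0 / 2565.0, 1859.0 / 4104.0, -11.0 / 40.0),
)
_B5 = (16.0 / 135.0, 0.0, 6656.0 / 12825.0, 28561.0 / 56430.0, -9.0 / 50.0, 2.0 / 55.0)
_B4 = (25.0 / 216.0, 0.0, 1408.0 / 2565.0, 2197.0 / 4104.0, -1.0 / 5.0, 0.0)


class IntegrationError(RuntimeError):
    """Raised when the adaptive stepper cannot meet its tolerance."""


def rkf45_interval(rhs, y0, dt, h0, atol=1e-6, rtol=1e-6, max_substeps=10_000):
    """Advance ``y' = rhs(s, y)`` from s=0 to s=dt with adaptive RKF45.

    Parameters
    ----------
    rhs : callable ``(s, [arrays]) -> [arrays]``
        Vector field, expressed in the local interval time ``s`` in [0, dt].
    y0 : list of ndarrays
        Initial state; not modified.
    dt : float
        Interval length (ms).
    h0 : float
        First substep to attempt; subsequent runs should pass the value
        returned by the previous call so the step size persists across
        intervals.
    atol, rtol : float
        Per-component error tolerances (max-norm over all components).

    Returns
    -------
    (y_end, h_next) with ``y_end`` a new list of arrays and ``h_next`` the
    step size to try first on the next interval.
    """
    y = [np.array(a, dtype=float, copy=True) for a in y0]
    s = 0.0
    h = min(h0, dt)
    nsub = 0
    while s < dt - 1e-12 * dt:
        h = min(h, dt - s)
        k = []
        for i in range(6):
            if i == 0:
                yi = y
            else:
                ai = _A[i]
                yi = [
                    ya + h * sum(ai[j] * k[j][m] for j in range(i))
                    for m, ya in enumerate(y)
                ]
            k.append(rhs(s + _C[i] * h, yi))
        y5 = [
            ya + h * sum(_B5[i] * k[i][m] for i in range(6))
            for m, ya in enumerate(y)
        ]
        err = 0.0
        for m, ya in enumerate(y5):
            e4 = y[m] + h * sum(_B4[i] * k[i][m] for i in range(6) if _B4[i])
            scale = atol + rtol * np.abs(ya)
            err = max(err, float(np.max(np.abs(ya - e4) / scale)) if ya.size else 0.0)
        if err <= 1.0:
            y = y5
            s += h
            fac = 5.0 if err == 0.0 else min(5.0, max(0.2, 0.9 * err ** -0.2))
            h *= fac
        else:
            h *= max(0.1, 0.9 * err ** -0.2)
        nsub += 1
        if nsub > max_substeps:
            raise IntegrationError(
                f"RKF45 failed to cross interval of {dt} ms within "
                f"{max_substeps} substeps (err={err:.3g}, h={h:.3g})"
            )
    return y, h


def rk4_fixed(rhs, y0, t_end, step):
    """Classic fixed-step RK4 reference integrator (oracle for tests)."""
    y = [np.array(a, dtype=float, copy=True) for a in y0]
    n = int(round(t_end / step))
    t = 0.0
    for _ in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + step / 2, [ya + step / 2 * k1[m] for m, ya in enumerate(y)])
        k3 = rhs(t + step / 2, [ya + step / 2 * k2[m] for m, ya in enumerate(y)])
        k4 = rhs(t + step, [ya + step * k3[m] for m, ya in enumerate(y)])
        y = [
            ya + step / 6 * (k1[m] + 2 * k2[m] + 2 * k3[m] + k4[m])
            for m, ya in enumerate(y)
        ]
        t += step
    return y
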