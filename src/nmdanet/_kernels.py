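"""Compiled inner loop for the approximate-backend membrane step.

The aggregated-NMDA backend spends essentially all of its time advancing the
membrane potentials over one grid interval; this module provides a fused
RKF45 kernel for that step (numba-jitted when available, with a numpy
fallback).  The synaptic gating variables are known in closed form within the
interval, so the kernel only integrates V.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


_A = np.zeros((6, 5))
_A[1, 0] = 1 / 4
_A[2, :2] = (3 / 32, 9 / 32)
_A[3, :3] = (1932 / 2197, -7200 / 2197, 7296 / 2197)
_A[4, :4] = (439 / 216, -8.0, 3680 / 513, -845 / 4104)
_A[5, :5] = (-8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40)
_C = np.array([0.0, 1 / 4, 3 / 8, 12 / 13, 1.0, 1 / 2])
_B5 = np.array([16 / 135, 0.0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55])
_B4 = np.array([25 / 216, 0.0, 1408 / 2565, 2197 / 4104, -1 / 5, 0.0])


@njit(cache=True, fastmath=True)
def _step_v_numba(V, sx0, sg0, sn_ss, sn_dev, gL, EL, Cm, gN, VE, VI, Mg,
                  inv_tA, inv_tG, inv_tN, dt, h0, atol, rtol):
    """Advance V (flattened batch*N) by dt with embedded RKF45; returns h."""
    n = V.size
    N = gL.size
    k = np.empty((6, n))
    y5 = np.empty(n)
    s = 0.0
    h = h0 if h0 < dt else dt
    while s < dt - 1e-12 * dt:
        if h > dt - s:
            h = dt - s
        for st in range(6):
            cs = s + _C[st] * h
            eA = np.exp(-cs * inv_tA)
            eG = np.exp(-cs * inv_tG)
            eN = np.exp(-cs * inv_tN)
            for i in range(n):
                j = i % N
                if st == 0:
                    v = V[i]
                else:
                    acc = 0.0
                    for q in range(st):
                        acc += _A[st, q] * k[q, i]
                    v = V[i] + h * acc
                mg = 1.0 / (1.0 + Mg * np.exp(-0.062 * v) / 3.57)
                i_syn = (sx0[i] * eA * (v - VE)
                         + sg0[i] * eG * (v - VI)
                         + gN[j] * (sn_ss[j] + sn_dev[i] * eN) * mg * (v - VE))
                k[st, i] = (-gL[j] * (v - EL[j]) - i_syn) / Cm[j]
        err = 0.0
        for i in range(n):
            a5 = 0.0
            a4 = 0.0
            for st in range(6):
                a5 += _B5[st] * k[st, i]
                a4 += _B4[st] * k[st, i]
            yv = V[i] + h * a5
            y5[i] = yv
            sc = atol + rtol * abs(yv)
            e = abs(h * (a5 - a4)) / sc
            if e > err:
                err = e
        if err <= 1.0:
            for i in range(n):
                V[i] = y5[i]
            s += h
            fac = 5.0 if err == 0.0 else min(5.0, max(0.2, 0.9 * err ** -0.2))
            h *= fac
        else:
            h *= max(0.1, 0.9 * err ** -0.2)
    return h


@njit(cache=True)
def _post_step_numba(V, refrac, s_loc, Vres, Vthr, ref_steps, is_exc, pop_of,
                     decayN, k0, k1, clamp_active, clamp_mask, clamp_vals,
                     forced, counts, dS_pop, spk_b, spk_i, spk_dS):
    """Refractory clamp, grid-point threshold, jump-map update and population
    sums, fused over the flattened (batch, N) state.  Returns the number of
    spikes written into the spk_* buffers."""
    n = V.size
    N = Vres.size
    B = n // N
    for b in range(B):
        for p in range(counts.shape[1]):
            counts[b, p] = 0.0
            dS_pop[b, p] = 0.0
    ns = 0
    for i in range(n):
        j = i % N
        in_ref = refrac[i] > 0
        if in_ref:
            V[i] = Vres[j]
        spiked = (not in_ref and V[i] >= Vthr[j]) or forced[i] != 0
        if spiked:
            V[i] = Vres[j]
        s_loc[i] *= decayN
        if clamp_active and clamp_mask[j] != 0:
            s_loc[i] = clamp_vals[j]
        if spiked:
            b = i // N
            counts[b, pop_of[j]] += 1.0
            if is_exc[j] != 0 and not (clamp_active and clamp_mask[j] != 0):
                dS = k0 + k1 * s_loc[i]
                s_loc[i] += dS
                dS_pop[b, pop_of[j]] += dS
                spk_dS[ns] = dS
            else:
                spk_dS[ns] = 0.0
            spk_b[ns] = b
            spk_i[ns] = j
            ns += 1
            refrac[i] = ref_steps[j]
        elif in_ref:
            refrac[i] -= 1
    return ns


def step_v_approx(V, S_ext_g, S_gaba_g, sn_ss, sn_dev, params, dt, h, atol, rtol):
    """Advance the (batch, N) membrane array in place; returns next h.

    ``S_ext_g``/``S_gaba_g`` are the conductance-weighted gating values at the
    interval start; ``sn_ss`` (N,) and ``sn_dev`` (batch, N) describe the
    NMDA aggregate as ss + dev*exp(-s/tau_d) (ss nonzero only under clamp).
    """
    gL, EL, Cm, gN, VE, VI, Mg, inv_tA, inv_tG, inv_tN = params
    return _step_v_numba(V.ravel(), S_ext_g.ravel(), S_gaba_g.ravel(),
                         sn_ss, sn_dev.ravel(), gL, EL, Cm, gN, VE, VI, Mg,
                         inv_tA, inv_tG, inv_tN, dt, h, atol, rtol)
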