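"""NMDA gating-variable kinetics: exact two-ODE model and jump approximation.

The exact (Wang/Brunel) synapse keeps a pair ``(S, x)`` per presynaptic
neuron:

.. math::

    dS/dt = -S/\\tau_d + \\alpha x (1 - S), \\qquad
    dx/dt = -x/\\tau_r + \\sum_k \\delta(t - t_k)

The saturating term makes the sum over presynaptic gating variables
non-aggregable.  The approximation replaces the finite rise by an
instantaneous, history-dependent jump

.. math::

    \\Delta S = k_0 + k_1 S(t^-), \\qquad
    k_0 = (\\alpha\\tau_r)^{\\tau_r/\\tau_d}\\,
          \\gamma\\!\\left[1 - \\tau_r/\\tau_d,\\ \\alpha\\tau_r\\right], \\quad
    k_1 = e^{-\\alpha\\tau_r} - 1,

with :math:`\\gamma` the *unnormalized* lower incomplete gamma function, chosen
so that the post-spike exponential decay is asymptotically equal to the exact
solution.  Between events the approximate variable decays with
:math:`\\tau_d`, which makes weighted sums over synapses collapse into a
single per-neuron variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate as _sint
from scipy import special as _sp

from ._integrate import rkf45_interval

__all__ = [
    "GatingParams",
    "JumpConstants",
    "ExactGatingState",
    "ApproxGatingState",
    "compute_jump_constants",
    "exact_spike_update",
    "exact_gating_evolve",
    "exact_gating_closed_form",
    "asymptotic_decay",
    "approx_jump",
    "approx_gating_trajectory",
    "simulate_synapse_approx",
    "periodic_steady_state",
]


@dataclass(frozen=True)
class GatingParams:
    """NMDA kinetics parameters.

    alpha : gain of the rise term (1/ms); tau_r, tau_d : rise and decay time
    constants (ms).  The jump-constant derivation substitutes
    ``tau_tilde = (1/tau_d - 1/tau_r)^-1`` and evaluates a gamma function at
    ``1 - tau_r/tau_d``, both of which require ``tau_r < tau_d``.
    """

    alpha: float = 0.5
    tau_r: float = 2.0
    tau_d: float = 100.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not (0 < self.tau_r < self.tau_d):
            raise ValueError(
                f"need 0 < tau_r < tau_d, got tau_r={self.tau_r}, tau_d={self.tau_d}"
            )


@dataclass(frozen=True)
class JumpConstants:
    """Spike-jump constants of the approximate model (dimensionless)."""

    k0: float
    k1: float
    k1_prime: float

    @property
    def fixed_point(self) -> float:
        """Value at which the jump vanishes; the approximate ceiling k0/(-k1)."""
        if self.k1 == 0.0:
            return np.inf
        return self.k0 / (-self.k1)


@dataclass
class ExactGatingState:
    """Per-synapse state of the exact model: open fraction S and rise variable x."""

    S: float = 0.0
    x: float = 0.0


@dataclass
class ApproxGatingState:
    """Single (or aggregated) gating value of the approximate model."""

    S: float = 0.0


def compute_jump_constants(params: GatingParams) -> JumpConstants:
    """Derive (k0, k1, k1') from the synaptic parameters.

    ``k0 = (alpha tau_r)^(tau_r/tau_d) * gamma_lower(1 - tau_r/tau_d, alpha tau_r)``
    with the unnormalized lower incomplete gamma function, and
    ``k1' = exp(-alpha tau_r)``, ``k1 = k1' - 1``.
    """
    a = params.alpha * params.tau_r
    s = 1.0 - params.tau_r / params.tau_d
    k1_prime = float(np.exp(-a))
    if a == 0.0:
        k0 = 0.0
    else:
        # scipy's gammainc is regularized; multiply by Gamma(s) to undo.
        k0 = float(a ** (params.tau_r / params.tau_d) * _sp.gammainc(s, a) * _sp.gamma(s))
    return JumpConstants(k0=k0, k1=k1_prime - 1.0, k1_prime=k1_prime)


def exact_spike_update(state: ExactGatingState, n_spikes: int = 1) -> ExactGatingState:
    """Apply presynaptic spike(s): the delta pulse enters only the x equation."""
    return ExactGatingState(S=state.S, x=state.x + float(n_spikes))


def _exact_rhs(params: GatingParams):
    inv_td, inv_tr, alpha = 1.0 / params.tau_d, 1.0 / params.tau_r, params.alpha

    def rhs(_t, y):
        S, x = y
        return [-S * inv_td + alpha * x * (1.0 - S), -x * inv_tr]

    return rhs


def exact_gating_evolve(
    state: ExactGatingState,
    params: GatingParams,
    duration: float,
    step: float,
    atol: float = 1e-10,
    rtol: float = 1e-10,
):
    """Integrate the spike-free exact ODEs, sampling every ``step`` ms.

    Returns ``(times, S, x)`` arrays including t=0.  Adaptive RKF45 is used
    within each output step.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    n = int(round(duration / step))
    rhs = _exact_rhs(params)
    times = np.arange(n + 1) * step
    Ss = np.empty(n + 1)
    xs = np.empty(n + 1)
    y = [np.array([state.S]), np.array([state.x])]
    Ss[0], xs[0] = state.S, state.x
    h = step / 10
    for i in range(1, n + 1):
        y, h = rkf45_interval(rhs, y, step, h, atol=atol, rtol=rtol)
        Ss[i], xs[i] = y[0][0], y[1][0]
    return times, Ss, xs


def exact_gating_closed_form(state: ExactGatingState, params: GatingParams, t):
    """Closed-form spike-free solution via integrating factor.

    ``S(t) = exp(-t/tau_d - alpha x0 tau_r (1 - e^{-t/tau_r})) (S0 + alpha x0 J(t))``
    where J(t) has no elementary antiderivative and is evaluated by adaptive
    quadrature.  ``x(t) = x0 e^{-t/tau_r}``.
    """
    tr, td, alpha = params.tau_r, params.tau_d, params.alpha
    x0, S0 = state.x, state.S
    inv_tilde = 1.0 / td - 1.0 / tr  # 1/tau_tilde, negative for tau_r < tau_d

    def integrand(u):
        return np.exp(u * inv_tilde + alpha * x0 * tr * (1.0 - np.exp(-u / tr)))

    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        J, _ = _sint.quad(integrand, 0.0, ti, epsabs=1e-13, epsrel=1e-12, limit=500)
        pref = np.exp(-ti / td - alpha * x0 * tr * (1.0 - np.exp(-ti / tr)))
        out[i] = pref * (S0 + alpha * x0 * J)
    return out[0] if np.isscalar(t) else out


def asymptotic_decay(jc: JumpConstants, params: GatingParams, t):
    """Post-spike asymptote for a single spike from rest: ``k0 exp(-t/tau_d)``."""
    return jc.k0 * np.exp(-np.asarray(t, dtype=float) / params.tau_d)


def approx_jump(S_pre, jc: JumpConstants):
    """Jump transmitted at a presynaptic spike: ``dS = k0 + k1 S(t-)``."""
    return jc.k0 + jc.k1 * np.asarray(S_pre, dtype=float)


def approx_gating_trajectory(S0: float, params: GatingParams, events, t_eval):
    """Closed-form trajectory of ``dS/dt = -S/tau_d + sum dS_k delta(t - t_k)``.

    ``events`` is a sequence of ``(time_ms, delta_S)`` with sorted times.  The
    decay between events is the exact exponential propagator; no ODE solver is
    involved.  Events at exactly ``t`` are included in ``S(t)``.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    td = params.tau_d
    S = S0 * np.exp(-t_eval / td)
    prev = -np.inf
    running = None
    for tk, dS in events:
        if tk < prev:
            raise ValueError("event times must be sorted")
        prev = tk
        mask = t_eval >= tk
        S[mask] += dS * np.exp(-(t_eval[mask] - tk) / td)
        running = tk
    del running
    if np.any(S < -1e-12):
        raise ValueError("trajectory went negative: inconsistent negative jumps")
    return S


def simulate_synapse_approx(spike_times, params: GatingParams, jc: JumpConstants | None = None):
    """Self-consistent single-synapse approximation.

    Iterates decay + jump over the neuron's own ``spike_times`` and returns the
    list of ``(t_k, delta_S_k)`` it would transmit, plus the post-jump values.
    """
    if jc is None:
        jc = compute_jump_constants(params)
    S = 0.0
    t_prev = 0.0
    events = []
    post = []
    for tk in spike_times:
        S *= np.exp(-(tk - t_prev) / params.tau_d)
        dS = jc.k0 + jc.k1 * S
        S += dS
        events.append((float(tk), float(dS)))
        post.append(S)
        t_prev = tk
    return events, np.asarray(post)


def periodic_steady_state(jc: JumpConstants, params: GatingParams, interval: float) -> float:
    """Pre-spike fixed point of the jump-decay map under periodic firing.

    With decay factor ``q = exp(-interval/tau_d)`` the map is
    ``S -> (k0 + k1' S) q``, whose fixed point is ``k0 q / (1 - k1' q)``.
    """
    q = np.exp(-interval / params.tau_d)
    return float(jc.k0 * q / (1.0 - jc.k1_prime * q))
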