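"""Conductance-based leaky integrate-and-fire neuron with AMPA/GABA/NMDA input.

Units are fixed package-wide: ms, mV, nS, pF, pA, mM (consistent since
nS*mV = pA and pF/nS = ms).  Membrane dynamics

    C_m dV/dt = -g_L (V - E_L) - I_syn(t)

with I_syn the sum of AMPA (recurrent and external pools with separate
conductances), GABA, and magnesium-blocked NMDA currents.  Spikes are checked
only at grid intervals of dt; subthreshold integration uses adaptive RKF45
confined to each interval, with the aggregated synaptic gating variables
propagated by their exact exponentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._integrate import rkf45_interval
from .gating import GatingParams

__all__ = ["NeuronParams", "NeuronState", "mg_block_factor", "synaptic_current", "integrate_neuron"]


@dataclass(frozen=True)
class NeuronParams:
    """LIF and receptor parameters; defaults are the excitatory column.

    ``g_AMPA``/``g_GABA``/``g_NMDA`` are the recurrent conductances;
    ``g_AMPA_ext`` is the conductance of the external-drive AMPA pool
    (background and stimulus Poisson input, weight 1).
    """

    C_m: float = 500.0        # pF
    g_L: float = 25.0         # nS
    E_L: float = -70.0        # mV
    V_thr: float = -50.0      # mV
    V_reset: float = -55.0    # mV
    t_ref: float = 2.0        # ms
    g_AMPA: float = 0.05      # nS
    g_AMPA_ext: float = 2.1   # nS
    g_GABA: float = 1.3       # nS
    g_NMDA: float = 0.165     # nS
    V_E: float = 0.0          # mV
    V_I: float = -70.0        # mV
    Mg: float = 1.0           # mM
    tau_AMPA: float = 2.0     # ms
    tau_GABA: float = 5.0     # ms
    gating: GatingParams = field(default_factory=GatingParams)

    def __post_init__(self):
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError("C_m and g_L must be positive")
        if self.V_reset >= self.V_thr:
            raise ValueError("V_reset must be below V_thr")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")
        if self.tau_AMPA <= 0 or self.tau_GABA <= 0:
            raise ValueError("receptor time constants must be positive")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m/g_L (ms)."""
        return self.C_m / self.g_L

    @classmethod
    def excitatory(cls, **over) -> "NeuronParams":
        return cls(**over)

    @classmethod
    def inhibitory(cls, **over) -> "NeuronParams":
        base = dict(
            C_m=200.0, g_L=20.0, t_ref=1.0,
            g_AMPA=0.04, g_AMPA_ext=1.62, g_GABA=1.0, g_NMDA=0.13,
        )
        base.update(over)
        return cls(**base)


@dataclass
class NeuronState:
    """Membrane potential plus aggregated (weight-scaled) gating variables."""

    V: float = -70.0
    S_AMPA: float = 0.0       # recurrent AMPA pool
    S_AMPA_ext: float = 0.0   # external AMPA pool
    S_GABA: float = 0.0
    S_NMDA: float = 0.0
    refractory_until: float = -math.inf
    last_spike: float | None = None


def mg_block_factor(V, Mg: float = 1.0):
    """Voltage-dependent magnesium unblock: 1/(1 + Mg e^{-0.062 V}/3.57).

    Strictly increasing in V and in (0, 1] for Mg >= 0; V in mV.
    """
    return 1.0 / (1.0 + Mg * np.exp(-0.062 * np.asarray(V, dtype=float)) / 3.57)


def synaptic_current(state: NeuronState, params: NeuronParams) -> float:
    """Total synaptic current in pA (positive = hyperpolarizing in Eq. form).

    Presynaptic weights are already folded into the aggregated S variables.
    """
    V = state.V
    i_ampa = (params.g_AMPA * state.S_AMPA + params.g_AMPA_ext * state.S_AMPA_ext) * (V - params.V_E)
    i_gaba = params.g_GABA * state.S_GABA * (V - params.V_I)
    i_nmda = params.g_NMDA * state.S_NMDA * (V - params.V_E) * mg_block_factor(V, params.Mg)
    return float(i_ampa + i_gaba + i_nmda)


def integrate_neuron(
    state: NeuronState,
    params: NeuronParams,
    t0: float,
    dt: float,
    I_inj: float | None = None,
    atol: float = 1e-6,
    rtol: float = 1e-6,
    h0: float | None = None,
):
    """Advance one grid interval; returns ``(new_state, spiked)``.

    Gating variables decay by their exact exponentials over the interval
    (incoming spikes must already have been applied at the boundary).  The
    membrane potential is integrated with adaptive RKF45; the threshold is
    checked only at the end of the interval.  While refractory, V is clamped
    to V_reset but the gating variables keep evolving.  ``I_inj`` (pA)
    replaces the synaptic current entirely when given (current-clamp mode).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params
    sA0, sX0, sG0, sN0 = state.S_AMPA, state.S_AMPA_ext, state.S_GABA, state.S_NMDA
    t_end = t0 + dt

    decay = {
        "S_AMPA": sA0 * math.exp(-dt / p.tau_AMPA),
        "S_AMPA_ext": sX0 * math.exp(-dt / p.tau_AMPA),
        "S_GABA": sG0 * math.exp(-dt / p.tau_GABA),
        "S_NMDA": sN0 * math.exp(-dt / p.gating.tau_d),
    }

    if t_end <= state.refractory_until + 1e-9:
        new = replace(state, V=p.V_reset, **decay)
        return new, False

    def rhs(s, y):
        V = y[0]
        if I_inj is not None:
            i_syn = I_inj
        else:
            eA = math.exp(-s / p.tau_AMPA)
            i_syn = (
                (p.g_AMPA * sA0 + p.g_AMPA_ext * sX0) * eA * (V - p.V_E)
                + p.g_GABA * sG0 * math.exp(-s / p.tau_GABA) * (V - p.V_I)
                + p.g_NMDA * sN0 * math.exp(-s / p.gating.tau_d)
                * (V - p.V_E) * mg_block_factor(V, p.Mg)
            )
        return [(-p.g_L * (V - p.E_L) - i_syn) / p.C_m]

    y, _ = rkf45_interval(rhs, [np.array([state.V])], dt, h0 or dt / 10, atol=atol, rtol=rtol)
    V = float(y[0][0])
    spiked = V >= p.V_thr
    if spiked:
        n_ref = math.ceil(p.t_ref / dt)
        new = replace(
            state, V=p.V_reset, refractory_until=t_end + n_ref * dt,
            last_spike=t_end, **decay,
        )
    else:
        new = replace(state, V=V, **decay)
    return new, spiked
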