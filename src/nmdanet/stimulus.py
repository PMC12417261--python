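"""External drive: background Poisson input, coherence-biased stimulus, clamp.

Background input is an independent Poisson process per neuron at rate
``nu_ext`` delivered onto the external AMPA pool with weight 1.  During the
stimulus window the two selective populations additionally receive Poisson
spikes whose rates are redrawn every ``resample_interval`` ms from Gaussians
centered on

    mu_A = mu0 + rho_A * c',    mu_B = mu0 - rho_B * c'

(c' the coherence in percent), clipped at zero.  The clamp used in the
sparse-network experiments replaces NMDA transmission from the selective
populations by a constant drive on the targets' aggregated gating variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSpec",
    "ClampSpec",
    "poisson_train",
    "coherence_rates",
    "resampled_stimulus",
    "clamp_response",
]


@dataclass(frozen=True)
class StimulusSpec:
    nu_ext: float = 2400.0            # background rate per neuron, spikes/s
    mu0: float = 40.0                 # base selective rate, spikes/s
    rho_A: float = 0.4                # spikes/s per % coherence
    rho_B: float = 0.4
    coherence: float = 0.0            # c', percent
    resample_interval: float = 50.0   # ms
    rate_sd: float = 4.0              # Gaussian spread of segment rates, spikes/s
    window: tuple = (1000.0, 3000.0)  # ms

    def __post_init__(self):
        if self.nu_ext < 0 or self.mu0 < 0:
            raise ValueError("rates must be >= 0")
        if self.resample_interval <= 0:
            raise ValueError("resample_interval must be > 0")


@dataclass(frozen=True)
class ClampSpec:
    """Clamp outgoing NMDA gating of selected populations to fixed values.

    ``sources`` maps population name -> clamped gating value (the standard
    protocol pins selective population A to 1 and B to 0).  During the window
    event transmission from those populations is suppressed and every target's
    aggregated variable receives the constant drive whose steady state equals
    the weighted sum it would take at the clamped values.  With
    ``include_conductance`` the drive additionally carries the g_NMDA factor
    (variant form); the default is the conductance-free drive consistent with
    the dimensionless aggregated variable.
    """

    sources: dict = field(default_factory=lambda: {"EA": 1.0, "EB": 0.0})
    window: tuple = (0.0, 2000.0)
    include_conductance: bool = False

    def __post_init__(self):
        if any(v < 0 for v in self.sources.values()):
            raise ValueError("clamp values must be >= 0")
        if self.window[0] != 0.0:
            raise ValueError("clamp window must start at t=0")


def poisson_train(rate: float, T: float, dt: float, seed) -> np.ndarray:
    """Grid-binned Poisson spike train: Bernoulli per bin, p = rate*dt/1000.

    At most one spike per bin; returns spike times (end-of-bin convention,
    multiples of dt).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    p = rate * dt / 1000.0
    if p > 1:
        raise ValueError(f"rate {rate} too high for dt={dt} (p={p:.3f} > 1)")
    if rate == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n = int(round(T / dt))
    hits = rng.random(n) < p
    return (np.nonzero(hits)[0] + 1) * dt


def coherence_rates(spec: StimulusSpec) -> tuple[float, float]:
    """Mean stimulus rates (mu_A, mu_B) in spikes/s; clipped at zero."""
    mu_a = max(0.0, spec.mu0 + spec.rho_A * spec.coherence)
    mu_b = max(0.0, spec.mu0 - spec.rho_B * spec.coherence)
    return mu_a, mu_b


def resampled_stimulus(spec: StimulusSpec, T: float, seed):
    """Piecewise-constant stimulus rate traces for populations A and B.

    Returns ``(edges, rates_A, rates_B)`` where ``edges`` are the segment
    start times within the stimulus window and rates are clipped-Gaussian
    draws around the coherence-biased means.  Outside the window the added
    rate is zero (segments cover only the window).
    """
    t_on, t_off = spec.window
    if not (0 <= t_on <= t_off <= T):
        raise ValueError("stimulus window must lie within [0, T]")
    rng = np.random.default_rng(seed)
    mu_a, mu_b = coherence_rates(spec)
    edges = np.arange(t_on, t_off, spec.resample_interval)
    ra = np.clip(rng.normal(mu_a, spec.rate_sd, size=edges.size), 0.0, None)
    rb = np.clip(rng.normal(mu_b, spec.rate_sd, size=edges.size), 0.0, None)
    return edges, ra, rb


def clamp_response(drive: float, tau_d: float, t):
    """Closed form of dS/dt = -S/tau_d + drive from S(0)=0.

    ``S(t) = drive * tau_d * (1 - exp(-t/tau_d))``; steady state drive*tau_d.
    """
    t = np.asarray(t, dtype=float)
    return drive * tau_d * (1.0 - np.exp(-t / tau_d))
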