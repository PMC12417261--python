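# nmdanet

Spiking-network simulator for conductance-based leaky integrate-and-fire
neurons with NMDA-receptor-mediated currents — both the exact saturating
two-ODE gating model and its asymptotically matched **jump approximation**,
which lets the postsynaptic NMDA input be simulated as a single aggregated
variable per neuron under arbitrary connectivity and delay distributions.

It is written for computational neuroscientists who want to study
slow-reverberation (winner-take-all) dynamics — the classic binary
decision-making network — beyond the fully connected, identical-delay regime
to which the exact model is effectively restricted.

## The model in brief

Exact per-synapse NMDA gating (per presynaptic neuron *j*):

    dS_j/dt = -S_j/τ_d + α x_j (1 - S_j),     dx_j/dt = -x_j/τ_r + Σ_k δ(t - t_j^k)

The saturating term makes Σ_j w_j S_j non-aggregable.  The approximation
keeps the exponential decay and replaces the finite rise with a
history-dependent jump at each spike,

    ΔS_j = k₀ + k₁ S_j(t⁻),   k₀ = (ατ_r)^(τ_r/τ_d) γ[1 − τ_r/τ_d, ατ_r],   k₁ = e^(−ατ_r) − 1,

(γ the unnormalized lower incomplete gamma function), chosen so the
post-spike decay is asymptotically equal to the exact solution.  The
postsynaptic sum then obeys a single linear ODE per neuron,
dS/dt = −S/τ_d + Σ ΔS_j δ(t − t_j), which the engine propagates exactly
between events.  Membrane potentials follow
C_m dV/dt = −g_L(V − E_L) − I_syn with AMPA/GABA exponential synapses and the
magnesium-blocked NMDA current, integrated with adaptive RKF45 and
grid-point spike detection (dt = 0.1 ms).

See `docs/methods.md` for the full model description, parameter tables,
numerical choices and known limitations.

## Worked example

```python
from nmdanet import GatingParams, compute_jump_constants, run_decision_trial

jc = compute_jump_constants(GatingParams())   # α=0.5/ms, τ_r=2 ms, τ_d=100 ms
print(jc.k0, jc.k1_prime, jc.fixed_point)
# 0.648417 0.367879 1.0258

trial = run_decision_trial(coherence=40.0, seed=7, scale=0.25)
print(trial.winner, trial.rate_A, trial.rate_B)
# A 33.8 0.4
```

`k0 = 0.648417` is the gating jump a single spike produces from rest;
`1.0258` is the value at which further jumps vanish — slightly above one, the
price of the instantaneous rise.  The decision trial runs the quarter-scale
winner-take-all network (populations EA/EB/EN/I, background Poisson drive at
2400 sp/s, coherence-biased stimulus during 1000–3000 ms): at 40% coherence
population A receives 56 vs 24 sp/s extra drive, wins, and self-sustains at
~34 sp/s after stimulus offset while B is suppressed to ~0.4 sp/s.

The `examples/` directory holds one short script per capability: jump
constants (`jump_constants.py`), exact-vs-approximate error traces
(`single_neuron_error.py`), a decision trial, a small psychometric curve with
bootstrap intervals, and the sparse-network clamp protocol.  A thin CLI
exposes the same drivers:

```sh
nmdanet decision-trial --coherence 40 --seed 7 --out-dir out/
nmdanet psychometric --coherences 1,10,40 --n-trials 12
nmdanet sparse-clamp --fully-connected
```

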