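# Methods

## Model

`nmdanet` simulates networks of conductance-based leaky integrate-and-fire
neurons,

    C_m dV/dt = -g_L (V - E_L) - I_syn(t),

with synaptic input through four receptor pools: an external AMPA pool
(background and stimulus Poisson drive, weight 1), a recurrent AMPA pool, a
GABA pool, and an NMDA pool with the voltage-dependent magnesium unblock
factor 1/(1 + [Mg²⁺] e^(−0.062 V)/3.57) (V in mV, [Mg²⁺] in mM).  Currents
are g·(V − E_rev)·ΣwS in pA (units package-wide: ms, mV, nS, pF, pA).

### NMDA gating: exact model and jump approximation

The exact per-synapse gating is the saturating two-ODE system

    dS/dt = -S/tau_d + alpha x (1 - S),     dx/dt = -x/tau_r + Σ_k δ(t - t_k),

whose nonlinearity prevents aggregation of the postsynaptic sum Σ w_j S_j.
The approximation replaces the finite rise with an instantaneous jump
ΔS = k₀ + k₁ S(t⁻) at each presynaptic spike and a pure exponential decay
(tau_d) between spikes, with

    k₀ = (α τ_r)^(τ_r/τ_d) · γ[1 − τ_r/τ_d, α τ_r],     k₁ = e^(−α τ_r) − 1,

γ the **unnormalized** lower incomplete gamma function (scipy's regularized
`gammainc` multiplied by `gamma`).  The constants are chosen so that after a
spike the approximate decay is asymptotically equal to the exact solution;
with the default kinetics (α = 0.5/ms, τ_r = 2 ms, τ_d = 100 ms) k₀ ≈ 0.6484,
k₁ ≈ −0.6321, and the jump map's fixed point k₀/(−k₁) ≈ 1.026, so the
aggregated variable can marginally exceed one and is no longer interpretable
as a strict open-channel fraction.  Because the approximate dynamics are
linear between events, the weighted sum over presynaptic neurons collapses to
a single per-neuron ODE, dS/dt = −S/τ_d + Σ ΔS_j δ(t − t_j), which the engine
propagates with the exact exponential (no ODE solver error for this
variable).

### Integration and spike handling

Membrane potentials are integrated with an embedded Runge–Kutta–Fehlberg 4(5)
stepper (absolute and relative tolerance 1e−6, first substep dt/10, step size
persisted across intervals) confined to each grid interval of dt = 0.1 ms.
AMPA/GABA/NMDA gating decays are evaluated in closed form at the substage
times.  Thresholds are checked **only at grid points**; after a spike V is
clamped to V_reset for ceil(t_ref/dt) grid steps.  Spikes are delivered after
their connection delay through per-slot ring buffers (population-level for
all-to-all connections, per-neuron CSR for fixed in-degree connections), so
heterogeneous delay distributions are supported in the approximate backend.
The per-step order is: deliver arrivals → integrate → refractory clamp and
threshold → queue outgoing spikes at t + delay.  The membrane step and the
threshold/jump bookkeeping of the approximate backend run as compiled
(numba) kernels; a pure-numpy path with identical semantics is used for the
exact backends and as fallback.

### Backends

* `approximate` — one local gating variable per excitatory neuron (decay +
  jump at its own spikes); targets accumulate w·ΔS.  Arbitrary connectivity
  and delays.
* `exact` — one delayed (S, x) stream per presynaptic neuron co-integrated
  with the membrane potentials.  Since S_j depends only on neuron j's spike
  train, this equals per-synapse simulation whenever all NMDA delays are
  equal, which this backend requires (all-to-all only).  The exact model's x
  is uncapped and accumulates across spikes; the "x has decayed before the
  next spike" premise is an assumption of the approximation only.
* `exact_per_synapse` — literal per-(target, source) pairs, O(N²) state, used
  as a correctness oracle at small N (agrees with `exact` to machine
  precision).

## Network and parameters

The decision network has selective populations EA and EB (each f·N_E
neurons), nonselective EN, and inhibitory I, fully connected (autapses
included — the synapse count of the largest benchmark variant, ≈ 755 million,
is only reproduced with self-connections counted), with potentiated
intra-selective weight w₊ = 1.7 and depressed weight
w₋ = 1 − f(w₊ − 1)/(1 − f) ≈ 0.876 (the normalization that keeps the
spontaneous state balanced; the alternative product form 0.911 is available
via `w_minus_form="printed"`).  Defaults: N_E = 1600, N_I = 400, f = 0.15,
delay 0.5 ms, dt 0.1 ms.

Two receptor/membrane constant sets appear in the literature this package
replicates, and they are **not interchangeable**:

* **Decision-network constants (package defaults).**  τ_GABA = 5 ms and
  inhibitory C_m = 200 pF (τ_m = 10 ms), the Wang (2002) values.  Only in
  this regime does the network hold a stable low-rate spontaneous state
  (E ≈ 2–5 sp/s, I ≈ 8 sp/s) so that the coherence-biased stimulus, not
  background noise, determines the decision.  With τ_GABA = 2 ms the network
  runs away to a global high-activity state within ~200 ms; with
  C_m,I = 250 pF the symmetric state breaks spontaneously before stimulus
  onset and coherence has no effect.
* **Sparse-study constants (`sparse_study_params()`).**  τ_GABA = 2 ms,
  C_m,I = 250 pF.  In this regime a symmetric high-activity attractor
  coexists with the asymmetric one, and the connectivity-fragility
  phenomenon appears: the fully connected network retains a clamped-in
  asymmetric state (E[S_A] ≈ 0.8 vs E[S_B] ≈ 0.1), while a 5% dilution with
  1/0.95 conductance scaling tips it into the symmetric high state
  (E[S_A] ≈ E[S_B] ≈ 0.7).  At the reduced test scale the collapse is
  partial for some connectivity draws (the seed-averaged asymmetry drops
  several-fold rather than exactly to zero).  Under the decision-network constants the
  asymmetric attractor is much deeper and survives even 99% unscaled
  dilution, so the clamp experiments default to this variant.

The parameter table further omits an external AMPA conductance; the package
uses the Wang (2002) values g_ext = 2.1 nS (excitatory) / 1.62 nS
(inhibitory) — without a separate external conductance the 2400 sp/s
background cannot drive the network.

`scale_network(spec, f)` multiplies population sizes by f and divides the
recurrent conductances by f (external drive unchanged), preserving mean
recurrent input at the cost of ×1/√f larger finite-size fluctuations.  The
reduced test scale is 0.25 (N_E = 400, N_I = 100); all decision statistics in
the test suite are computed there.

## Stimulus and clamp

Background: independent per-neuron Bernoulli-per-bin Poisson drive at
ν_ext = 2400 sp/s (p = ν dt/1000 ≤ 1, at most one spike per bin), entering
the external AMPA pool with weight 1.  A shared train would induce
correlations absent from the asynchronous regime, hence independent
realizations.  Stimulus: during 1000–3000 ms the selective populations
receive extra Poisson input whose rates are redrawn every 50 ms from
N(μ_A, σ = 4 sp/s) and N(μ_B, σ = 4), clipped at zero, with
μ_A = μ₀ + ρ_A c′ and μ_B = μ₀ − ρ_B c′ (μ₀ = 40 sp/s, ρ = 0.4).  σ is
interpreted as a standard deviation (the replicated study's convention); a
variance-4 reading would give σ = 2.

The clamp replaces NMDA transmission from the selective populations by a
constant drive D_X = Σ_s v_s N_s ε_sX w_sX / τ_d on each target's aggregated
variable (v_A = 1, v_B = 0), whose steady state D·τ_d equals the weighted sum
the target would see if every S_j in population A were 1.  The variant
including the g_NMDA factor (dimensionally a conductance-scaled aggregate) is
available via `include_conductance=True`.  During the window the clamped
neurons' local gating is held at the clamp values and resumes free dynamics
at release.

## Decision rule and statistics

Winner = selective population with the higher mean 50-ms-binned rate over the
final 500 ms of the trial, with a 5 sp/s dead band ("none" below it).  The
psychometric function is P(correct) = fraction of trials won by A (undecided
counts as incorrect), fitted by Bernoulli maximum likelihood to
P(c′) = 1 − 0.5 exp(−(c′/α)^β) in log-parameter space from a fixed start
(α₀ = 10, β₀ = 1, Nelder–Mead; a least-squares option exists).  Zero
coherence carries no scale information and is excluded from fits; flat
curves are flagged non-identifiable.  Per-coherence confidence intervals are
90% percentile bootstrap with 5000 resamples.

## Randomness and batching

A master seed fans out through `numpy.random.SeedSequence` into independent
connectivity and noise streams (and named substreams via
`derive_seeds`).  Identical (spec, seed, backend) runs are bit-identical.
Statistical experiments run many trials as one vectorized batch sharing a
single noise stream derived from the seed list; a trial's realization then
depends on the batch composition, which is irrelevant for the aggregate
statistics reported.  Matched-pair designs (exact vs approximate on
bit-identical inputs) run both backends against the same stream so every
trial sees the same external and stimulus spikes.  Fully connected clamp
runs batch all seeds; sparse runs redraw connectivity per seed sequentially.

## Problem sizes in the test suite

Unit oracles run at tiny N against closed forms, fine-step RK4, quadrature
and series evaluations of the incomplete gamma function, and the per-synapse
backend.  The scientific end-to-end checks use: a 4×4 (w, n_pre) grid at
10 s per cell for the error characterization; 100 quarter-scale trials at
c′ = 0 and 50 per coherence in {1, 10, 40}; 8 seeds per connectivity
condition for the clamp protocol (6 s each).  The full published designs
(400 trials × 5 coherences at full scale; a 33×33 connectivity sweep × 8
seeds) are reachable through the same functions and the CLI but are
cluster-scale; the package's drivers default to the reduced sizes.

## Known limitations

* The exact backend requires all-to-all connectivity with a uniform NMDA
  delay; heterogeneous-delay exact simulation would need true per-synapse
  state (the cost the approximation exists to avoid).
* Spike detection at grid points (no within-step threshold interpolation)
  follows the stated method; rates carry an O(dt) discretization bias shared
  by both backends.
* The quarter-scale network has ×2 larger finite-size fluctuations;
  psychometric curves are shallower than at full scale, and spontaneous
  transitions during long waits are more common.
* Wall-clock benchmarking of the two backends is out of scope; only their
  dynamics are compared.
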