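"""Scripted experiments: error characterization, decision trials, sparse clamp.

Three reproductions are packaged here:

* single-neuron comparison of exact vs. jump-approximated NMDA input driven by
  identical presynaptic Poisson trains (current error traces and RMS of the
  membrane-potential difference across an input grid);
* the winner-take-all decision network: single trials, batches, psychometric
  curves over coherence;
* the sparse-network clamp protocol: pin the outgoing NMDA gating of selective
  population A to 1 (B to 0) for two seconds via an equivalent constant drive
  on the targets, release, and measure whether an asymmetric attractor
  persists, as a function of connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._integrate import rkf45_interval
from .gating import compute_jump_constants
from .neuron import NeuronParams, mg_block_factor
from .network import (
    NetworkSpec,
    SimResult,
    Simulator,
    decision_network_spec,
    scale_conductances,
    sparse_epsilons,
)
from .stimulus import ClampSpec, StimulusSpec

__all__ = [
    "ErrorExperimentSpec",
    "ErrorExperimentResult",
    "run_error_experiment",
    "run_error_grid",
    "TrialResult",
    "decide_winner",
    "run_decision_trial",
    "run_decision_batch",
    "run_psychometric",
    "run_matched_backend_trials",
    "SparseClampResult",
    "run_sparse_clamp",
    "run_connectivity_sweep",
]


# ---------------------------------------------------------------------------
# Single-neuron error characterization


@dataclass(frozen=True)
class ErrorExperimentSpec:
    """Identical-input comparison of exact and approximate NMDA dynamics."""

    n_pre: int = 1
    nu_pre: float = 20.0   # spikes/s per presynaptic neuron
    weight: float = 1.0
    T: float = 1000.0      # ms
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_pre < 1:
            raise ValueError("n_pre must be >= 1")


@dataclass
class ErrorExperimentResult:
    times: np.ndarray
    i_error: np.ndarray       # I_NMDA,exact - I_NMDA,approximate (pA)
    v_error: np.ndarray       # V_exact - V_approx (mV)
    rms: float                # RMS of the voltage difference (mV)
    i_exact: np.ndarray
    i_approx: np.ndarray
    v_exact: np.ndarray
    v_approx: np.ndarray
    n_spikes_exact: int
    n_spikes_approx: int
    spike_steps: np.ndarray   # input arrival steps (first cell only)


def _error_core(n_pres, weights, nu_pre, T, dt, seed, params, trains=None,
                record_traces=False):
    """Vectorized exact-vs-approximate comparison over a list of cells.

    Each cell is an independent postsynaptic neuron receiving NMDA input from
    ``n_pre`` Poisson sources with synaptic weight ``w``; both models of every
    cell see bit-identical input spikes.
    """
    n_pres = np.asarray(n_pres, dtype=int)
    weights = np.asarray(weights, dtype=float)
    C = n_pres.size
    M = int(n_pres.sum())
    cell_offsets = np.concatenate([[0], np.cumsum(n_pres)[:-1]])
    w_cell = weights
    p = params
    gat = p.gating
    jc = compute_jump_constants(gat)
    nsteps = int(round(T / dt))
    p_pre = np.full(M, nu_pre * dt / 1000.0)
    rng = np.random.default_rng(seed)

    train_hits = None
    if trains is not None:
        train_hits = np.zeros((nsteps, M), dtype=bool)
        for j, tr in enumerate(trains):
            idx = np.round(np.asarray(tr, dtype=float) / dt).astype(int)
            train_hits[idx[idx < nsteps], j] = True

    decayN = np.exp(-dt / gat.tau_d)
    inv_td, inv_tr, alpha = 1.0 / gat.tau_d, 1.0 / gat.tau_r, gat.alpha
    n_ref = int(np.ceil(p.t_ref / dt))

    V_ex = np.full(C, p.E_L); V_ap = np.full(C, p.E_L)
    S = np.zeros(M); x = np.zeros(M)       # exact per-source gating
    s_src = np.zeros(M)                    # approximate per-source gating
    Sn_ap = np.zeros(C)                    # aggregated approximate variable
    ref_ex = np.zeros(C, dtype=int); ref_ap = np.zeros(C, dtype=int)
    nspk_ex = np.zeros(C, dtype=int); nspk_ap = np.zeros(C, dtype=int)
    h_ex = dt / 10; h_ap = dt / 10

    sumsq = np.zeros(C)
    if record_traces:
        times = np.arange(1, nsteps + 1) * dt
        i_ex_tr = np.zeros((nsteps, C)); i_ap_tr = np.zeros((nsteps, C))
        v_ex_tr = np.zeros((nsteps, C)); v_ap_tr = np.zeros((nsteps, C))
    spike_steps = []

    def rhs_exact(s, y):
        Vc, Sc, xc = y
        wS = w_cell * np.add.reduceat(Sc, cell_offsets)
        mg = mg_block_factor(Vc, p.Mg)
        i_syn = p.g_NMDA * wS * mg * (Vc - p.V_E)
        return [(-p.g_L * (Vc - p.E_L) - i_syn) / p.C_m,
                -Sc * inv_td + alpha * xc * (1.0 - Sc),
                -xc * inv_tr]

    for t in range(nsteps):
        hits = train_hits[t] if train_hits is not None else rng.random(M) < p_pre
        if hits.any():
            x = x + hits
            dS = np.where(hits, jc.k0 + jc.k1 * s_src, 0.0)
            s_src = s_src + dS
            Sn_ap = Sn_ap + w_cell * np.add.reduceat(dS, cell_offsets)
            if record_traces:
                spike_steps.append(t)

        (V_ex, S, x), h_ex = rkf45_interval(rhs_exact, [V_ex, S, x], dt, h_ex)

        sn0 = Sn_ap.copy()

        def rhs_ap(s, y):
            Vc = y[0]
            sn = sn0 * np.exp(-s * inv_td)
            i_syn = p.g_NMDA * sn * mg_block_factor(Vc, p.Mg) * (Vc - p.V_E)
            return [(-p.g_L * (Vc - p.E_L) - i_syn) / p.C_m]

        (V_ap,), h_ap = rkf45_interval(rhs_ap, [V_ap], dt, h_ap)
        Sn_ap *= decayN
        s_src *= decayN

        # refractory clamp and grid-point threshold, both models alike
        V_ex[ref_ex > 0] = p.V_reset
        V_ap[ref_ap > 0] = p.V_reset
        if record_traces:
            wS = w_cell * np.add.reduceat(S, cell_offsets)
            mg_e = mg_block_factor(V_ex, p.Mg)
            i_ex_tr[t] = p.g_NMDA * wS * mg_e * (V_ex - p.V_E)
            i_ap_tr[t] = p.g_NMDA * Sn_ap * mg_block_factor(V_ap, p.Mg) * (V_ap - p.V_E)
        spk_e = (V_ex >= p.V_thr) & (ref_ex == 0)
        spk_a = (V_ap >= p.V_thr) & (ref_ap == 0)
        V_ex[spk_e] = p.V_reset; V_ap[spk_a] = p.V_reset
        ref_ex[ref_ex > 0] -= 1; ref_ap[ref_ap > 0] -= 1
        ref_ex[spk_e] = n_ref; ref_ap[spk_a] = n_ref
        nspk_ex += spk_e; nspk_ap += spk_a

        sumsq += (V_ex - V_ap) ** 2
        if record_traces:
            v_ex_tr[t] = V_ex; v_ap_tr[t] = V_ap

    rms = np.sqrt(sumsq / nsteps)
    out = {
        "rms": rms, "n_spikes_exact": nspk_ex, "n_spikes_approx": nspk_ap,
    }
    if record_traces:
        out.update(times=times, i_exact=i_ex_tr, i_approx=i_ap_tr,
                   v_exact=v_ex_tr, v_approx=v_ap_tr,
                   spike_steps=np.asarray(spike_steps, dtype=int))
    return out


def run_error_experiment(spec: ErrorExperimentSpec, spike_trains=None,
                         params: NeuronParams | None = None) -> ErrorExperimentResult:
    """Run one exact-vs-approximate cell; returns signed error traces and RMS.

    ``spike_trains`` (list of per-source spike-time arrays, ms) overrides the
    Poisson generator, e.g. for single-spike probes.
    """
    p = params or NeuronParams.excitatory()
    out = _error_core([spec.n_pre], [spec.weight], spec.nu_pre, spec.T, spec.dt,
                      spec.seed, p, trains=spike_trains, record_traces=True)
    return ErrorExperimentResult(
        times=out["times"],
        i_error=out["i_exact"][:, 0] - out["i_approx"][:, 0],
        v_error=out["v_exact"][:, 0] - out["v_approx"][:, 0],
        rms=float(out["rms"][0]),
        i_exact=out["i_exact"][:, 0], i_approx=out["i_approx"][:, 0],
        v_exact=out["v_exact"][:, 0], v_approx=out["v_approx"][:, 0],
        n_spikes_exact=int(out["n_spikes_exact"][0]),
        n_spikes_approx=int(out["n_spikes_approx"][0]),
        spike_steps=out["spike_steps"],
    )


def run_error_grid(weights=(0.1, 1.0, 10.0, 100.0), n_pres=(1, 10, 100, 800),
                   nu_pre: float = 20.0, T: float = 10_000.0, dt: float = 0.1,
                   seed: int = 0, params: NeuronParams | None = None) -> pd.DataFrame:
    """RMS voltage difference across a (weight, n_pre) grid, all cells at once.

    Returns one row per cell with the total input ``n_pre * nu_pre * w`` and
    whether the exact-model neuron fired.
    """
    grid = [(w, n) for w in weights for n in n_pres]
    ws = [g[0] for g in grid]; ns = [g[1] for g in grid]
    p = params or NeuronParams.excitatory()
    out = _error_core(ns, ws, nu_pre, T, dt, seed, p)
    return pd.DataFrame({
        "weight": ws, "n_pre": ns,
        "total_input": [w * n * nu_pre for w, n in grid],
        "rms": out["rms"],
        "n_spikes_exact": out["n_spikes_exact"],
        "n_spikes_approx": out["n_spikes_approx"],
        "spiking": out["n_spikes_exact"] > 0,
    })


# ---------------------------------------------------------------------------
# Decision trials


@dataclass
class TrialResult:
    winner: str                  # "A" | "B" | "none"
    rate_A: float                # mean post-stimulus rate, spikes/s
    rate_B: float
    result: SimResult = field(repr=False)
    trial: int = 0

    @property
    def s_trace_A(self):
        return self.result.s_traces[self.trial, :, self.result.pop_names.index("EA")]

    @property
    def s_trace_B(self):
        return self.result.s_traces[self.trial, :, self.result.pop_names.index("EB")]


def decide_winner(result: SimResult, trial: int = 0, window=(3500.0, 4000.0),
                  dead_band: float = 5.0):
    """Winner = selective population with the higher mean binned rate in
    ``window``; "none" when the rates differ by less than ``dead_band`` sp/s."""
    ra = result.mean_rate("EA", *window, trial=trial)
    rb = result.mean_rate("EB", *window, trial=trial)
    if abs(ra - rb) < dead_band:
        return "none", ra, rb
    return ("A" if ra > rb else "B"), ra, rb


def run_decision_trial(coherence: float, seed, backend: str = "approximate",
                       scale: float = 0.25, spec: NetworkSpec | None = None,
                       stimulus: StimulusSpec | None = None, T: float = 4000.0,
                       record_spikes: bool = True, **run_kwargs) -> TrialResult:
    """One full decision trial (background + coherence-biased stimulus)."""
    from .network import simulate

    spec = spec or decision_network_spec(scale=scale)
    stim = stimulus or StimulusSpec(coherence=coherence)
    res = simulate(spec, T, seed, backend=backend, stimulus=stim,
                   record_spikes=record_spikes, **run_kwargs)
    window = (stim.window[1] + (T - stim.window[1]) / 2.0, T)
    winner, ra, rb = decide_winner(res, 0, window=window)
    return TrialResult(winner=winner, rate_A=ra, rate_B=rb, result=res)


def run_decision_batch(coherence: float, seeds, backend: str = "approximate",
                       scale: float = 0.25, spec: NetworkSpec | None = None,
                       stimulus: StimulusSpec | None = None, T: float = 4000.0,
                       **run_kwargs) -> list[TrialResult]:
    """Vectorized batch of decision trials sharing connectivity and one noise
    stream derived from the seed list; trial i is NOT individually matched to
    seeds[i] (use run_decision_trial for matched-seed designs)."""
    seeds = list(seeds)
    spec = spec or decision_network_spec(scale=scale)
    stim = stimulus or StimulusSpec(coherence=coherence)
    ss = np.random.SeedSequence(seeds)
    conn_ss, noise_ss = ss.spawn(2)
    sim = Simulator(spec, conn_ss, backend)
    rng = np.random.default_rng(noise_ss)
    res = sim.run(T, rng, batch=len(seeds), stimulus=stim, record_spikes=False,
                  **run_kwargs)
    window = (stim.window[1] + (T - stim.window[1]) / 2.0, T)
    out = []
    for b in range(len(seeds)):
        winner, ra, rb = decide_winner(res, b, window=window)
        out.append(TrialResult(winner=winner, rate_A=ra, rate_B=rb, result=res, trial=b))
    return out


def run_psychometric(coherences, n_trials: int, master_seed: int = 0,
                     backend: str = "approximate", scale: float = 0.25,
                     spec: NetworkSpec | None = None, T: float = 4000.0,
                     n_resamples: int = 5000, level: float = 0.90,
                     **run_kwargs) -> pd.DataFrame:
    """P(correct) per coherence with bootstrap confidence intervals.

    Correct means selective population A wins (it receives the stronger
    stimulus for c' > 0); undecided trials count as incorrect.
    """
    from .analysis import bootstrap_ci

    rows = []
    ss = np.random.SeedSequence(master_seed)
    for c, child in zip(coherences, ss.spawn(len(coherences))):
        seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in child.spawn(n_trials)]
        trials = run_decision_batch(c, seeds, backend=backend, scale=scale,
                                    spec=spec, T=T, **run_kwargs)
        outcomes = np.array([t.winner == "A" for t in trials], dtype=float)
        lo, hi = bootstrap_ci(outcomes, n_resamples=n_resamples, level=level,
                              seed=child)
        rows.append({"coherence": c, "n_trials": n_trials,
                     "n_correct": int(outcomes.sum()),
                     "p_correct": float(outcomes.mean()),
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def run_matched_backend_trials(coherence: float, n_trials: int, master_seed: int = 0,
                               scale: float = 0.25, T: float = 2500.0,
                               stim_window=(500.0, 1500.0),
                               measure=(2000.0, 2500.0)) -> pd.DataFrame:
    """Matched exact-vs-approximate trials on bit-identical inputs.

    Both backends consume the same noise stream in the same order, so every
    trial sees the same external and stimulus spikes.  Returns the winning
    population (from the exact run) and its mean late activity under both
    backends, one row per trial.
    """
    spec = decision_network_spec(scale=scale)
    stim = StimulusSpec(coherence=coherence, window=stim_window)
    ss = np.random.SeedSequence(master_seed)
    conn_ss, noise_ss = ss.spawn(2)
    results = {}
    for backend in ("approximate", "exact"):
        sim = Simulator(spec, conn_ss, backend)
        rng = np.random.default_rng(noise_ss)
        results[backend] = sim.run(T, rng, batch=n_trials, stimulus=stim,
                                   record_spikes=False)
    rows = []
    for b in range(n_trials):
        row = {"trial": b}
        for backend, res in results.items():
            ra = res.mean_rate("EA", *measure, trial=b)
            rb = res.mean_rate("EB", *measure, trial=b)
            row[f"rate_A_{backend}"] = ra
            row[f"rate_B_{backend}"] = rb
            row[f"rate_win_{backend}"] = max(ra, rb)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sparse clamp protocol


def sparse_study_params():
    """Receptor/membrane constants for the sparse-connectivity study.

    The connectivity-fragility phenomenon — a fully connected network retains
    the clamped-in asymmetric state, while a 5% dilution (with 1/0.95
    conductance scaling) tips it into a symmetric high-activity state — occurs
    in the regime with fast GABA decay (2 ms) and slower interneurons
    (C_m = 250 pF).  With the decision-network constants (GABA 5 ms,
    C_m,I = 200 pF) the asymmetric attractor is much deeper and survives
    dilution, so the clamp experiments use this variant.
    """
    return (NeuronParams.excitatory(tau_GABA=2.0),
            NeuronParams.inhibitory(C_m=250.0, tau_GABA=2.0))


@dataclass
class SparseClampResult:
    trace_times: np.ndarray
    S_A: np.ndarray       # (n_seeds, n_rec)
    S_B: np.ndarray
    E_SA: np.ndarray      # per-seed expectation over the late window
    E_SB: np.ndarray
    diff: np.ndarray      # per-seed E[S_A - S_B]


def _clamp_run(spec, seed_like, T, clamp, background, record=(), batch=1):
    ss = np.random.SeedSequence(seed_like)
    conn_ss, noise_ss = ss.spawn(2)
    sim = Simulator(spec, conn_ss, "approximate")
    rng = np.random.default_rng(noise_ss)
    return sim.run(T, rng, batch=batch, stimulus=background, clamp=clamp,
                   record_spikes=False, snapshot_vars=record)


def run_sparse_clamp(seeds, eps_selective: float | None = None,
                     eps_inhibitory: float | None = None,
                     eps_base: float = 0.2, fully_connected: bool = False,
                     scale: float = 0.25, conductance_scale: float = 1.0,
                     T: float = 6000.0, t_release: float = 2000.0,
                     window=(4000.0, 6000.0),
                     background: StimulusSpec | None = None,
                     params: tuple | None = None) -> SparseClampResult:
    """Clamp protocol: S_A pinned to 1 and S_B to 0 until ``t_release``; after
    release the population-averaged gating traces reveal whether an asymmetric
    (decision) state is stable.  Fully connected networks share wiring, so all
    seeds run in one batch; sparse networks redraw connectivity per seed.
    Neuron parameters default to :func:`sparse_study_params`.
    """
    seeds = list(seeds)
    pe, pi = params if params is not None else sparse_study_params()
    kw = dict(scale=scale, exc_params=pe, inh_params=pi)
    if fully_connected:
        spec = decision_network_spec(**kw)
    else:
        eps = sparse_epsilons(eps_base,
                              eps_selective if eps_selective is not None else eps_base,
                              eps_inhibitory if eps_inhibitory is not None else eps_base)
        spec = decision_network_spec(epsilons=eps, **kw)
    if conductance_scale != 1.0:
        spec = scale_conductances(spec, conductance_scale)
    clamp = ClampSpec(window=(0.0, t_release))
    bg = background or StimulusSpec(window=(0.0, 0.0))

    iA = spec.pop_index("EA"); iB = spec.pop_index("EB")
    if fully_connected:
        res = _clamp_run(spec, seeds, T, clamp, bg, batch=len(seeds))
        tt = res.trace_times
        S_A = res.s_traces[:, :, iA]; S_B = res.s_traces[:, :, iB]
    else:
        tAs, tBs = [], []
        for s in seeds:
            res = _clamp_run(spec, s, T, clamp, bg)
            tAs.append(res.s_traces[0, :, iA]); tBs.append(res.s_traces[0, :, iB])
        tt = res.trace_times
        S_A = np.array(tAs); S_B = np.array(tBs)
    m = (tt >= window[0]) & (tt <= window[1])
    E_SA = S_A[:, m].mean(axis=1); E_SB = S_B[:, m].mean(axis=1)
    return SparseClampResult(trace_times=tt, S_A=S_A, S_B=S_B,
                             E_SA=E_SA, E_SB=E_SB, diff=E_SA - E_SB)


def run_connectivity_sweep(eps_selective_grid, eps_inhibitory_grid, seeds,
                           eps_base: float = 0.2, scale: float = 0.25,
                           T: float = 6000.0, window=(4000.0, 6000.0)) -> pd.DataFrame:
    """Reduced-resolution sweep over intra-selective and inhibitory-selective
    connectivity; synaptic conductances are kept at their table values.

    Returns one row per grid point with seed-averaged E[S_A] and E[S_A - S_B].
    """
    rows = []
    for es in eps_selective_grid:
        for ei in eps_inhibitory_grid:
            r = run_sparse_clamp(seeds, eps_selective=es, eps_inhibitory=ei,
                                 eps_base=eps_base, scale=scale, T=T,
                                 window=window)
            rows.append({"eps_selective": es, "eps_inhibitory": ei,
                         "E_SA": float(r.E_SA.mean()),
                         "E_SA_minus_SB": float(r.diff.mean())})
    return pd.DataFrame(rows)
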