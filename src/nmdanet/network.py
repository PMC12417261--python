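"""Population/connectivity construction and the time-driven network engine.

The engine advances on a fixed grid of width ``dt``.  Within one step the
order of operations is: deliver spike arrivals (ring buffers, one slot per
grid step of delay) -> integrate membrane potentials over the interval
(adaptive RKF45; synaptic gating propagated by exact exponentials) -> clamp
refractory neurons and check thresholds at the grid point -> queue outgoing
spikes at ``t + delay``.

Two NMDA backends are provided:

``approximate``
    Each excitatory neuron carries one local gating variable evolved by
    exponential decay plus the jump map at its own spikes; at each spike the
    scalar ``w * dS`` is delivered (after the connection delay) into every
    target's aggregated S_NMDA.  Arbitrary connectivity and per-connection
    delays are supported.

``exact``
    One delayed (S, x) stream per presynaptic excitatory neuron is
    co-integrated with the membrane potentials and targets sum ``w_j S_j``
    each step.  Because S_j depends only on the presynaptic spike train this
    is identical to per-synapse simulation whenever all NMDA delays are equal,
    which this backend requires (the restriction that motivates the
    approximation in the first place).

``exact_per_synapse``
    Literal per-synapse (S, x) pairs, one full copy per (target, source).
    O(N^2) state; intended as a correctness oracle at small N.

A batch dimension allows many independently seeded trials with shared
connectivity to be integrated in one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._integrate import rkf45_interval
from ._kernels import HAVE_NUMBA, _post_step_numba, step_v_approx
from .gating import compute_jump_constants
from .neuron import NeuronParams
from .stimulus import ClampSpec, StimulusSpec

__all__ = [
    "PopulationSpec",
    "ConnectivitySpec",
    "NetworkSpec",
    "SpikeRecord",
    "SimResult",
    "w_minus_value",
    "decision_network_spec",
    "benchmark_network_spec",
    "sparse_epsilons",
    "scale_network",
    "scale_conductances",
    "count_synapses",
    "build_connectivity",
    "simulate",
    "Simulator",
    "write_spikes",
    "read_spikes",
]

RECEPTORS = ("AMPA", "NMDA", "GABA")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    params: NeuronParams
    kind: str  # "excitatory" | "inhibitory"

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"population {self.name}: size must be >= 1")
        if self.kind not in ("excitatory", "inhibitory"):
            raise ValueError(f"population {self.name}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class ConnectivitySpec:
    source: str
    target: str
    rule: str = "all_to_all"  # or "fixed_indegree"
    epsilon: float = 1.0
    weight: float = 1.0
    delay: float = 0.5  # ms
    receptors: tuple = ("AMPA", "NMDA")

    def __post_init__(self):
        if self.rule not in ("all_to_all", "fixed_indegree"):
            raise ValueError(f"unknown connection rule {self.rule!r}")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        bad = set(self.receptors) - set(RECEPTORS)
        if bad:
            raise ValueError(f"unknown receptors {bad}")


@dataclass(frozen=True)
class NetworkSpec:
    populations: tuple
    connections: tuple
    dt: float = 0.1
    f: float | None = None
    w_plus: float | None = None
    w_minus: float | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for c in self.connections:
            if c.source not in names or c.target not in names:
                raise ValueError(f"connection {c.source}->{c.target}: unknown population")
            if c.delay < self.dt - 1e-12:
                raise ValueError(f"delay {c.delay} must be >= dt {self.dt}")
            if abs(round(c.delay / self.dt) - c.delay / self.dt) > 1e-9:
                raise ValueError(f"delay {c.delay} not a multiple of dt {self.dt}")

    @property
    def pop_names(self):
        return tuple(p.name for p in self.populations)

    def pop_index(self, name: str) -> int:
        return self.pop_names.index(name)

    def pop(self, name: str) -> PopulationSpec:
        return self.populations[self.pop_index(name)]

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    def slices(self):
        out, o = {}, 0
        for p in self.populations:
            out[p.name] = slice(o, o + p.size)
            o += p.size
        return out


@dataclass(frozen=True)
class SpikeRecord:
    neuron: int
    time: float


def w_minus_value(f: float, w_plus: float, form: str = "division") -> float:
    """Depressed weight balancing the potentiated one.

    ``division``: 1 - f(w+ - 1)/(1 - f)  (Wang 2002 normalization, default)
    ``printed``:  1 - f(w+ - 1)(1 - f)
    """
    if form == "division":
        return 1.0 - f * (w_plus - 1.0) / (1.0 - f)
    if form == "printed":
        return 1.0 - f * (w_plus - 1.0) * (1.0 - f)
    raise ValueError(f"unknown w_minus form {form!r}")


def decision_network_spec(
    scale: float = 1.0,
    f: float = 0.15,
    w_plus: float = 1.7,
    w_minus: float | None = None,
    w_minus_form: str = "division",
    delay: float = 0.5,
    dt: float = 0.1,
    N_E: int = 1600,
    N_I: int = 400,
    epsilons: dict | None = None,
    exc_params: NeuronParams | None = None,
    inh_params: NeuronParams | None = None,
) -> NetworkSpec:
    """Winner-take-all decision network: populations EA, EB, EN, I.

    ``epsilons`` maps (source, target) name pairs to connection probabilities;
    when given, all connections use the fixed in-degree rule (missing pairs
    default to 1.0).  When ``scale != 1`` population sizes are multiplied and
    recurrent conductances divided by it (external drive unchanged).
    """
    if w_minus is None:
        w_minus = w_minus_value(f, w_plus, w_minus_form)
    pe = exc_params or NeuronParams.excitatory()
    pi = inh_params or NeuronParams.inhibitory()
    nA = int(round(f * N_E))
    pops = (
        PopulationSpec("EA", nA, pe, "excitatory"),
        PopulationSpec("EB", nA, pe, "excitatory"),
        PopulationSpec("EN", N_E - 2 * nA, pe, "excitatory"),
        PopulationSpec("I", N_I, pi, "inhibitory"),
    )
    wmat = {
        ("EA", "EA"): w_plus, ("EA", "EB"): w_minus, ("EA", "EN"): 1.0, ("EA", "I"): 1.0,
        ("EB", "EB"): w_plus, ("EB", "EA"): w_minus, ("EB", "EN"): 1.0, ("EB", "I"): 1.0,
        ("EN", "EA"): w_minus, ("EN", "EB"): w_minus, ("EN", "EN"): 1.0, ("EN", "I"): 1.0,
    }
    conns = []
    for (src, tgt), w in wmat.items():
        conns.append(_conn(src, tgt, w, delay, ("AMPA", "NMDA"), epsilons))
    for tgt in ("EA", "EB", "EN", "I"):
        conns.append(_conn("I", tgt, 1.0, delay, ("GABA",), epsilons))
    spec = NetworkSpec(pops, tuple(conns), dt=dt, f=f, w_plus=w_plus, w_minus=w_minus)
    if scale != 1.0:
        spec = scale_network(spec, scale)
    return spec


def _conn(src, tgt, w, delay, receptors, epsilons):
    if epsilons is None:
        return ConnectivitySpec(src, tgt, "all_to_all", 1.0, w, delay, receptors)
    eps = epsilons.get((src, tgt), 1.0)
    return ConnectivitySpec(src, tgt, "fixed_indegree", eps, w, delay, receptors)


def sparse_epsilons(eps_base: float = 0.2, eps_selective: float = 0.2,
                    eps_inhibitory: float = 0.2) -> dict:
    """Connection-probability table for the sparse decision network.

    All pairs at ``eps_base`` except the intra-selective (EA->EA, EB->EB) and
    inhibitory-to-selective (I->EA, I->EB) probabilities, which are varied.
    """
    pairs = [(s, t) for s in ("EA", "EB", "EN", "I") for t in ("EA", "EB", "EN", "I")]
    eps = {p: eps_base for p in pairs}
    eps[("EA", "EA")] = eps_selective
    eps[("EB", "EB")] = eps_selective
    eps[("I", "EA")] = eps_inhibitory
    eps[("I", "EB")] = eps_inhibitory
    return eps


def benchmark_network_spec(scale: float = 1.0, delay: float = 0.5, dt: float = 0.1) -> NetworkSpec:
    """Steady-state benchmark variant (f=0): one excitatory, one inhibitory pop."""
    pops = (
        PopulationSpec("E", 1600, NeuronParams.excitatory(), "excitatory"),
        PopulationSpec("I", 400, NeuronParams.inhibitory(), "inhibitory"),
    )
    conns = (
        ConnectivitySpec("E", "E", "all_to_all", 1.0, 1.0, delay, ("AMPA", "NMDA")),
        ConnectivitySpec("E", "I", "all_to_all", 1.0, 1.0, delay, ("AMPA", "NMDA")),
        ConnectivitySpec("I", "E", "all_to_all", 1.0, 1.0, delay, ("GABA",)),
        ConnectivitySpec("I", "I", "all_to_all", 1.0, 1.0, delay, ("GABA",)),
    )
    spec = NetworkSpec(pops, conns, dt=dt, f=0.0)
    if scale != 1.0:
        spec = scale_network(spec, scale)
    return spec


def scale_network(spec: NetworkSpec, factor: float) -> NetworkSpec:
    """Resize populations by ``factor``; recurrent conductances scale as 1/factor.

    External-drive conductances are left unchanged so the mean drive per
    neuron from recurrent input is preserved.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    pops = []
    for p in spec.populations:
        ns = p.size * factor
        if abs(ns - round(ns)) > 1e-9:
            raise ValueError(f"factor {factor} gives non-integer size for {p.name}")
        q = replace(
            p.params,
            g_AMPA=p.params.g_AMPA / factor,
            g_GABA=p.params.g_GABA / factor,
            g_NMDA=p.params.g_NMDA / factor,
        )
        pops.append(replace(p, size=int(round(ns)), params=q))
    return replace(spec, populations=tuple(pops))


def scale_conductances(spec: NetworkSpec, factor: float) -> NetworkSpec:
    """Multiply all recurrent conductances by ``factor`` (sizes unchanged)."""
    pops = tuple(
        replace(p, params=replace(
            p.params,
            g_AMPA=p.params.g_AMPA * factor,
            g_GABA=p.params.g_GABA * factor,
            g_NMDA=p.params.g_NMDA * factor,
        ))
        for p in spec.populations
    )
    return replace(spec, populations=pops)


def count_synapses(spec: NetworkSpec) -> int:
    """One synapse per (connected pair, receptor).

    All-to-all includes autapses, so an excitatory population of size N
    contributes 2N (AMPA+NMDA paired) connections onto every target neuron.
    """
    total = 0
    sizes = {p.name: p.size for p in spec.populations}
    for c in spec.connections:
        ns, nt = sizes[c.source], sizes[c.target]
        if c.rule == "all_to_all":
            pairs = ns * nt
        else:
            pairs = nt * int(round(c.epsilon * ns))
        total += pairs * len(c.receptors)
    return total


# ---------------------------------------------------------------------------
# Compiled connectivity


@dataclass
class _PopEdge:
    src: int
    tgt: int
    weight: float
    delay_steps: int
    receptors: tuple


@dataclass
class _CSREdge:
    src: int
    tgt: int
    weight: float
    delay_steps: int
    receptors: tuple
    indptr: np.ndarray   # per source-local neuron
    targets: np.ndarray  # global target ids
    indegree: int


@dataclass
class Connectivity:
    pop_edges: list
    csr_edges: list
    max_delay_steps: int


def build_connectivity(spec: NetworkSpec, seed) -> Connectivity:
    """Compile connection specs; fixed in-degree draws are deterministic in seed.

    Each target under the fixed in-degree rule receives exactly
    ``round(epsilon * N_src)`` distinct presynaptic partners drawn uniformly
    without replacement (no multapses; autapses excluded within a population).
    All-to-all connections keep population-level weights (autapses included).
    """
    sl = spec.slices()
    names = spec.pop_names
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child = ss.spawn(len(spec.connections))
    pop_edges, csr_edges = [], []
    max_d = 1
    for c, cs in zip(spec.connections, child):
        d = int(round(c.delay / spec.dt))
        max_d = max(max_d, d)
        si, ti = names.index(c.source), names.index(c.target)
        if c.rule == "all_to_all":
            pop_edges.append(_PopEdge(si, ti, c.weight, d, c.receptors))
            continue
        ns = spec.populations[si].size
        nt = spec.populations[ti].size
        k = int(round(c.epsilon * ns))
        same = si == ti
        avail = ns - 1 if same else ns
        if same and k == ns:
            k = ns - 1  # epsilon = 1 within a population: all partners but self
        if k > avail:
            raise ValueError(
                f"{c.source}->{c.target}: in-degree {k} exceeds {avail} distinct sources"
            )
        if k < 1:
            raise ValueError(f"{c.source}->{c.target}: in-degree rounds to 0")
        rng = np.random.default_rng(cs)
        src_lists = [[] for _ in range(ns)]
        for t_loc in range(nt):
            draw = rng.choice(avail, size=k, replace=False)
            if same:
                draw = np.where(draw >= t_loc, draw + 1, draw)  # skip self
            for s_loc in draw:
                src_lists[s_loc].append(sl[c.target].start + t_loc)
        indptr = np.zeros(ns + 1, dtype=np.int64)
        indptr[1:] = np.cumsum([len(x) for x in src_lists])
        targets = np.concatenate([np.asarray(x, dtype=np.int64) for x in src_lists if x] or
                                 [np.empty(0, dtype=np.int64)])
        csr_edges.append(_CSREdge(si, ti, c.weight, d, c.receptors, indptr, targets, k))
    return Connectivity(pop_edges, csr_edges, max_d)


# ---------------------------------------------------------------------------
# Results


@dataclass
class SimResult:
    """Spikes, binned population activity and gating traces from one run."""

    pop_names: tuple
    pop_sizes: tuple
    T: float
    dt: float
    rate_bin: float
    pop_rates: np.ndarray          # (batch, n_bins, n_pops), spikes/s per neuron
    trace_times: np.ndarray        # ms
    s_traces: np.ndarray           # (batch, n_rec, n_pops) population-mean local S_NMDA
    spike_trial: np.ndarray | None = None
    spike_time: np.ndarray | None = None
    spike_neuron: np.ndarray | None = None
    snapshots: dict = field(default_factory=dict)

    @property
    def batch(self) -> int:
        return self.pop_rates.shape[0]

    def spikes_of(self, trial: int = 0):
        """(times, neuron ids) of one trial, sorted by (time, neuron)."""
        if self.spike_time is None:
            raise ValueError("spikes were not recorded")
        m = self.spike_trial == trial
        t, n = self.spike_time[m], self.spike_neuron[m]
        order = np.lexsort((n, t))
        return t[order], n[order]

    def rate_of(self, pop: str, trial: int = 0) -> np.ndarray:
        return self.pop_rates[trial, :, self.pop_names.index(pop)]

    def mean_rate(self, pop: str, t_from: float, t_to: float, trial: int = 0) -> float:
        """Mean binned population rate over [t_from, t_to) in spikes/s."""
        b0 = int(round(t_from / self.rate_bin))
        b1 = int(round(t_to / self.rate_bin))
        return float(self.pop_rates[trial, b0:b1, self.pop_names.index(pop)].mean())


def write_spikes(path, times, neurons):
    """Two-column delimited spike file, sorted by (time, neuron)."""
    order = np.lexsort((neurons, times))
    with open(path, "w") as fh:
        fh.write("neuron_id\ttime_ms\n")
        for t, n in zip(np.asarray(times)[order], np.asarray(neurons)[order]):
            fh.write(f"{int(n)}\t{t:.4f}\n")


def read_spikes(path):
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.size == 0:
        return np.empty(0), np.empty(0, dtype=int)
    return data[:, 1], data[:, 0].astype(int)


# ---------------------------------------------------------------------------
# Engine


class Simulator:
    """Compiled network ready to run; reusable across runs with fresh RNGs."""

    def __init__(self, spec: NetworkSpec, conn_seed, backend: str = "approximate"):
        if backend not in ("approximate", "exact", "exact_per_synapse"):
            raise ValueError(f"unknown backend {backend!r}")
        self.spec = spec
        self.backend = backend
        self.dt = spec.dt
        pops = spec.populations
        self.P = len(pops)
        self.N = spec.n_neurons
        self.slices = spec.slices()
        self.offsets = np.array([self.slices[p.name].start for p in pops], dtype=np.int64)
        self.pop_of = np.concatenate([np.full(p.size, i, dtype=np.int64)
                                      for i, p in enumerate(pops)])
        self.is_exc = np.concatenate([np.full(p.size, p.kind == "excitatory")
                                      for p in pops])

        def arr(get):
            return np.concatenate([np.full(p.size, get(p.params), dtype=float) for p in pops])

        self.Cm = arr(lambda q: q.C_m)
        self.gL = arr(lambda q: q.g_L)
        self.EL = arr(lambda q: q.E_L)
        self.Vthr = arr(lambda q: q.V_thr)
        self.Vres = arr(lambda q: q.V_reset)
        self.gA = arr(lambda q: q.g_AMPA)
        self.gAx = arr(lambda q: q.g_AMPA_ext)
        self.gG = arr(lambda q: q.g_GABA)
        self.gN = arr(lambda q: q.g_NMDA)
        self.ref_steps = np.concatenate([
            np.full(p.size, int(np.ceil(p.params.t_ref / self.dt)), dtype=np.int64)
            for p in pops
        ])
        # shared scalars (validated uniform across populations)
        q0 = pops[0].params
        for p in pops:
            q = p.params
            if (q.tau_AMPA, q.tau_GABA, q.Mg, q.V_E, q.V_I, q.gating) != (
                q0.tau_AMPA, q0.tau_GABA, q0.Mg, q0.V_E, q0.V_I, q0.gating
            ):
                raise ValueError("receptor time constants, Mg, reversals and gating "
                                 "parameters must be shared across populations")
        self.tauA, self.tauG = q0.tau_AMPA, q0.tau_GABA
        self.Mg, self.VE, self.VI = q0.Mg, q0.V_E, q0.V_I
        self.gating = q0.gating
        self.jc = compute_jump_constants(self.gating)

        self.conn = build_connectivity(spec, conn_seed)
        self.D = self.conn.max_delay_steps + 1

        # excitatory source bookkeeping (exact backends / jump bookkeeping)
        self.exc_idx = np.nonzero(self.is_exc)[0]
        self.nE = self.exc_idx.size
        self.exc_pops = [i for i, p in enumerate(pops) if p.kind == "excitatory"]
        # reduceat offsets of excitatory sources grouped by population
        self.exc_offsets = np.array(
            [np.searchsorted(self.pop_of[self.exc_idx], i) for i in self.exc_pops],
            dtype=np.int64,
        )
        # NMDA pop-level weight matrix (exact backends)
        self.Wn = np.zeros((len(self.exc_pops), self.P))
        for e in self.conn.pop_edges:
            if "NMDA" in e.receptors and e.src in self.exc_pops:
                self.Wn[self.exc_pops.index(e.src), e.tgt] += e.weight
        if backend in ("exact", "exact_per_synapse"):
            if self.conn.csr_edges:
                raise ValueError("exact backends support all-to-all connectivity only")
            dl = {e.delay_steps for e in self.conn.pop_edges if "NMDA" in e.receptors}
            if len(dl) > 1:
                raise ValueError("exact backends require a single uniform NMDA delay")
            self.nmda_delay = dl.pop() if dl else 1

    # -- helpers -----------------------------------------------------------

    def _clamp_drive(self, clamp: ClampSpec):
        """Per-neuron constant added to dS_NMDA/dt during the clamp window."""
        drive = np.zeros(self.N)
        src_pops = set()
        for name, value in clamp.sources.items():
            si = self.spec.pop_index(name)
            src_pops.add(si)
            ns = self.spec.populations[si].size
            for e in self.conn.pop_edges:
                if e.src == si and "NMDA" in e.receptors:
                    drive[self.slices[self.spec.pop_names[e.tgt]]] += (
                        value * ns * e.weight / self.gating.tau_d
                    )
            for e in self.conn.csr_edges:
                if e.src == si and "NMDA" in e.receptors:
                    drive[self.slices[self.spec.pop_names[e.tgt]]] += (
                        value * e.indegree * e.weight / self.gating.tau_d
                    )
        if clamp.include_conductance:
            drive = drive * self.gN
        return drive, src_pops

    # -- main loop ---------------------------------------------------------

    def run(
        self,
        T: float,
        rng: np.random.Generator,
        batch: int = 1,
        stimulus: StimulusSpec | None = None,
        clamp: ClampSpec | None = None,
        record_spikes: bool = True,
        rate_bin: float = 50.0,
        trace_interval: float = 1.0,
        snapshot_vars: tuple = (),
        forced_spikes: dict | None = None,
        atol: float = 1e-6,
        rtol: float = 1e-6,
    ) -> SimResult:
        dt, B, N, P = self.dt, batch, self.N, self.P
        nsteps = int(round(T / dt))
        if abs(nsteps * dt - T) > 1e-9:
            raise ValueError("T must be a multiple of dt")
        if clamp is not None and self.backend != "approximate":
            raise NotImplementedError("the clamp protocol requires the approximate backend")

        exact = self.backend in ("exact", "exact_per_synapse")
        per_syn = self.backend == "exact_per_synapse"
        jc, gat = self.jc, self.gating
        decayA = np.exp(-dt / self.tauA)
        decayG = np.exp(-dt / self.tauG)
        decayN = np.exp(-dt / gat.tau_d)

        V = np.broadcast_to(self.EL, (B, N)).copy()
        S_ext = np.zeros((B, N)); S_ampa = np.zeros((B, N))
        S_gaba = np.zeros((B, N)); S_nmda = np.zeros((B, N))
        s_loc = np.zeros((B, N))
        refrac = np.zeros((B, N), dtype=np.int64)
        Vres_b = np.broadcast_to(self.Vres, (B, N))

        if exact:
            shape = (B, N, self.nE) if per_syn else (B, self.nE)
            Sd = np.zeros(shape); xd = np.zeros(shape)
            ring_x = np.zeros((self.D, B, self.nE))
            if per_syn:
                # per-(target, source) weights from the population matrix
                pos = np.full(P, -1, dtype=np.int64)
                pos[self.exc_pops] = np.arange(len(self.exc_pops))
                srcpos = pos[self.pop_of[self.exc_idx]]
                self.wmat_ps = self.Wn[srcpos][:, self.pop_of].T  # (N, nE)

        D = self.D
        ring_pop = np.zeros((D, B, P, 3))
        ring_neu = {}
        for e in self.conn.csr_edges:
            for r in e.receptors:
                if r not in ring_neu:
                    ring_neu[r] = np.zeros((D, B, N))

        p_ext = 0.0
        do_stim = False
        if stimulus is not None:
            p_ext = stimulus.nu_ext * dt / 1000.0
            if p_ext > 1:
                raise ValueError("nu_ext too high for dt (bin probability > 1)")
            slA = self.slices.get("EA"); slB = self.slices.get("EB")
            mu_a = max(0.0, stimulus.mu0 + stimulus.rho_A * stimulus.coherence)
            mu_b = max(0.0, stimulus.mu0 - stimulus.rho_B * stimulus.coherence)
            stim_on = int(round(stimulus.window[0] / dt))
            stim_off = int(round(stimulus.window[1] / dt))
            seg_steps = int(round(stimulus.resample_interval / dt))
            do_stim = stim_off > stim_on
            if do_stim and (slA is None or slB is None):
                raise ValueError("selective stimulus requires populations EA and EB")
            pA = np.zeros(B); pB = np.zeros(B)

        clamp_steps = 0
        if clamp is not None:
            drive, clamp_src = self._clamp_drive(clamp)
            cN = drive * gat.tau_d                       # steady-state target
            clamp_steps = int(round(clamp.window[1] / dt))
            clamp_neurons = np.zeros(N, dtype=bool)
            clamp_vals = np.zeros(N)
            for name, value in clamp.sources.items():
                s = self.slices[name]
                clamp_neurons[s] = True
                clamp_vals[s] = value

        forced = {}
        if forced_spikes:
            for step, ids in forced_spikes.items():
                forced[int(step)] = np.asarray(ids, dtype=np.int64)

        # recording
        n_bins = int(np.ceil(nsteps * dt / rate_bin))
        counts_bins = np.zeros((B, n_bins, P))
        k_trace = max(1, int(round(trace_interval / dt)))
        n_rec = nsteps // k_trace
        s_traces = np.full((B, n_rec, P), np.nan)
        trace_times = (np.arange(1, n_rec + 1) * k_trace) * dt
        snapshots = {v: [] for v in snapshot_vars}
        sp_t, sp_n, sp_b = [], [], []

        inv_tauA, inv_tauG = 1.0 / self.tauA, 1.0 / self.tauG
        inv_tauN = 1.0 / gat.tau_d
        inv_tr = 1.0 / gat.tau_r
        alpha = gat.alpha
        gL, EL, Cm = self.gL, self.EL, self.Cm
        gA, gAx, gG, gN = self.gA, self.gAx, self.gG, self.gN
        VE, VI, Mg = self.VE, self.VI, self.Mg
        vparams = (gL, EL, Cm, gN, float(VE), float(VI), float(Mg),
                   inv_tauA, inv_tauG, inv_tauN)
        zero_ss = np.zeros(N)
        if not exact and HAVE_NUMBA:
            counts = np.zeros((B, P))
            dS_pop = np.zeros((B, P))
            spk_b_buf = np.empty(B * N, dtype=np.int64)
            spk_i_buf = np.empty(B * N, dtype=np.int64)
            spk_dS_buf = np.empty(B * N)
            is_exc_u8 = self.is_exc.astype(np.uint8)
            forced_flat = np.zeros(B * N, dtype=np.uint8)
            if clamp is not None:
                clamp_mask_u8 = clamp_neurons.astype(np.uint8)
                clamp_vals_arr = clamp_vals
            else:
                clamp_mask_u8 = np.zeros(N, dtype=np.uint8)
                clamp_vals_arr = np.zeros(N)
        h = dt / 10.0

        def nmda_sum_exact(Sd_cur):
            if per_syn:
                return np.einsum("bij,ij->bi", Sd_cur, self.wmat_ps)
            sums = np.add.reduceat(Sd_cur, self.exc_offsets, axis=1)
            return (sums @ self.Wn)[:, self.pop_of]

        for t in range(nsteps):
            slot = t % D
            clamp_active = clamp is not None and t < clamp_steps

            # 1 -- deliveries
            rp = ring_pop[slot]
            S_ampa += rp[:, self.pop_of, 0]
            S_nmda += rp[:, self.pop_of, 1]
            S_gaba += rp[:, self.pop_of, 2]
            rp[:] = 0.0
            if ring_neu:
                for r, ring in ring_neu.items():
                    tgt = {"AMPA": S_ampa, "NMDA": S_nmda, "GABA": S_gaba}[r]
                    tgt += ring[slot]
                    ring[slot] = 0.0
            if exact:
                if per_syn:
                    xd += ring_x[slot][:, None, :]
                else:
                    xd += ring_x[slot]
                ring_x[slot] = 0.0
            if stimulus is not None:
                if p_ext > 0:
                    S_ext += rng.random((B, N)) < p_ext
                if do_stim and stim_on <= t < stim_off:
                    if (t - stim_on) % seg_steps == 0:
                        ra = np.clip(rng.normal(mu_a, stimulus.rate_sd, B), 0, None)
                        rb = np.clip(rng.normal(mu_b, stimulus.rate_sd, B), 0, None)
                        pA = ra * dt / 1000.0
                        pB = rb * dt / 1000.0
                    S_ext[:, slA] += rng.random((B, slA.stop - slA.start)) < pA[:, None]
                    S_ext[:, slB] += rng.random((B, slB.stop - slB.start)) < pB[:, None]

            # 2 -- integrate membrane potentials over the interval
            sx0 = gAx * S_ext + gA * S_ampa
            sg0 = gG * S_gaba
            if not exact:
                if clamp_active:
                    sn_ss = cN
                    sn_dev = S_nmda - cN
                else:
                    sn_ss = zero_ss
                    sn_dev = S_nmda
                if HAVE_NUMBA:
                    h = step_v_approx(V, sx0, sg0, sn_ss, sn_dev, vparams,
                                      dt, h, atol, rtol)
                else:

                    def rhs(s, y):
                        Vc = y[0]
                        eA = np.exp(-s * inv_tauA)
                        eN = np.exp(-s * inv_tauN)
                        mg = 1.0 / (1.0 + Mg * np.exp(-0.062 * Vc) / 3.57)
                        i_syn = (
                            sx0 * eA * (Vc - VE)
                            + sg0 * np.exp(-s * inv_tauG) * (Vc - VI)
                            + gN * (sn_ss + sn_dev * eN) * mg * (Vc - VE)
                        )
                        return [(-gL * (Vc - EL) - i_syn) / Cm]

                    (V,), h = rkf45_interval(rhs, [V], dt, h, atol=atol, rtol=rtol)
            else:

                def rhs(s, y):
                    Vc, Sc, xc = y
                    eA = np.exp(-s * inv_tauA)
                    mg = 1.0 / (1.0 + Mg * np.exp(-0.062 * Vc) / 3.57)
                    sn = nmda_sum_exact(Sc)
                    i_syn = (
                        sx0 * eA * (Vc - VE)
                        + sg0 * np.exp(-s * inv_tauG) * (Vc - VI)
                        + gN * sn * mg * (Vc - VE)
                    )
                    dV = (-gL * (Vc - EL) - i_syn) / Cm
                    dS = -Sc * inv_tauN + alpha * xc * (1.0 - Sc)
                    dx = -xc * inv_tr
                    return [dV, dS, dx]

                (V, Sd, xd), h = rkf45_interval(rhs, [V, Sd, xd], dt, h, atol=atol, rtol=rtol)

            # 3 -- propagate aggregated gating to the end of the interval
            S_ext *= decayA
            S_ampa *= decayA
            S_gaba *= decayG
            if clamp_active:
                S_nmda -= cN
                S_nmda *= decayN
                S_nmda += cN
            else:
                S_nmda *= decayN

            # 4-7 -- refractoriness, threshold, jump map, delivery, recording
            if not exact and HAVE_NUMBA:
                if t in forced:
                    for b in range(B):
                        forced_flat[b * N + forced[t]] = 1
                ns = _post_step_numba(
                    V.ravel(), refrac.ravel(), s_loc.ravel(), self.Vres,
                    self.Vthr, self.ref_steps, is_exc_u8, self.pop_of,
                    decayN, jc.k0, jc.k1, clamp_active, clamp_mask_u8,
                    clamp_vals_arr, forced_flat, counts, dS_pop,
                    spk_b_buf, spk_i_buf, spk_dS_buf)
                if t in forced:
                    for b in range(B):
                        forced_flat[b * N + forced[t]] = 0
                if ns:
                    for e in self.conn.pop_edges:
                        ws = (slot + 1 + e.delay_steps) % D
                        if "AMPA" in e.receptors:
                            ring_pop[ws, :, e.tgt, 0] += e.weight * counts[:, e.src]
                        if "GABA" in e.receptors:
                            ring_pop[ws, :, e.tgt, 2] += e.weight * counts[:, e.src]
                        if "NMDA" in e.receptors:
                            if not (clamp_active and e.src in clamp_src):
                                ring_pop[ws, :, e.tgt, 1] += e.weight * dS_pop[:, e.src]
                    for e in self.conn.csr_edges:
                        s = self.slices[self.spec.pop_names[e.src]]
                        ws = (slot + 1 + e.delay_steps) % D
                        supp = clamp_active and e.src in clamp_src
                        for q in range(ns):
                            i = spk_i_buf[q]
                            if not (s.start <= i < s.stop):
                                continue
                            rel = i - s.start
                            tg = e.targets[e.indptr[rel]:e.indptr[rel + 1]]
                            if tg.size == 0:
                                continue
                            b = spk_b_buf[q]
                            if "AMPA" in e.receptors:
                                ring_neu["AMPA"][ws, b, tg] += e.weight
                            if "GABA" in e.receptors:
                                ring_neu["GABA"][ws, b, tg] += e.weight
                            if "NMDA" in e.receptors and not supp:
                                ring_neu["NMDA"][ws, b, tg] += e.weight * spk_dS_buf[q]
                    tb = min(n_bins - 1, int((t * dt) // rate_bin))
                    counts_bins[:, tb, :] += counts
                    if record_spikes:
                        sp_b.append(spk_b_buf[:ns].copy())
                        sp_n.append(spk_i_buf[:ns].copy())
                        sp_t.append(np.full(ns, (t + 1) * dt))
            else:
                in_ref = refrac > 0
                V[in_ref] = Vres_b[in_ref]
                spk = (V >= self.Vthr) & ~in_ref
                if t in forced:
                    spk[:, forced[t]] = True
                V[spk] = Vres_b[spk]

                spk_exc = spk & self.is_exc
                if not exact:
                    s_loc *= decayN
                    if clamp_active:
                        s_loc[:, clamp_neurons] = clamp_vals[clamp_neurons]
                    dS = np.where(spk_exc, jc.k0 + jc.k1 * s_loc, 0.0)
                    if clamp_active:
                        dS[:, clamp_neurons] = 0.0
                    s_loc += dS

                counts = np.add.reduceat(spk.astype(float), self.offsets, axis=1)
                if not exact:
                    dS_pop = np.add.reduceat(dS, self.offsets, axis=1)
                for e in self.conn.pop_edges:
                    ws = (slot + 1 + e.delay_steps) % D
                    if "AMPA" in e.receptors:
                        ring_pop[ws, :, e.tgt, 0] += e.weight * counts[:, e.src]
                    if "GABA" in e.receptors:
                        ring_pop[ws, :, e.tgt, 2] += e.weight * counts[:, e.src]
                    if "NMDA" in e.receptors and not exact:
                        if not (clamp_active and e.src in clamp_src):
                            ring_pop[ws, :, e.tgt, 1] += e.weight * dS_pop[:, e.src]
                if exact and np.any(spk_exc):
                    ws = (slot + 1 + self.nmda_delay) % D
                    ring_x[ws][spk[:, self.exc_idx]] += 1.0
                for e in self.conn.csr_edges:
                    s = self.slices[self.spec.pop_names[e.src]]
                    bs, isrc = np.nonzero(spk[:, s])
                    ws = (slot + 1 + e.delay_steps) % D
                    for b, i in zip(bs, isrc):
                        tg = e.targets[e.indptr[i]:e.indptr[i + 1]]
                        if tg.size == 0:
                            continue
                        if "AMPA" in e.receptors:
                            ring_neu["AMPA"][ws, b, tg] += e.weight
                        if "GABA" in e.receptors:
                            ring_neu["GABA"][ws, b, tg] += e.weight
                        if "NMDA" in e.receptors:
                            if not (clamp_active and e.src in clamp_src):
                                ring_neu["NMDA"][ws, b, tg] += e.weight * dS[b, s.start + i]

                refrac[in_ref] -= 1
                refrac[spk] = np.broadcast_to(self.ref_steps, (B, N))[spk]

                tb = min(n_bins - 1, int((t * dt) // rate_bin))
                counts_bins[:, tb, :] += counts
                if record_spikes and np.any(spk):
                    bs, ns_ = np.nonzero(spk)
                    sp_b.append(bs)
                    sp_n.append(ns_)
                    sp_t.append(np.full(bs.size, (t + 1) * dt))
            if (t + 1) % k_trace == 0:
                m = (t + 1) // k_trace - 1
                if exact:
                    src_s = Sd[:, 0, :] if per_syn else Sd
                    sums = np.add.reduceat(src_s, self.exc_offsets, axis=1)
                    for j, pi in enumerate(self.exc_pops):
                        s_traces[:, m, pi] = sums[:, j] / self.spec.populations[pi].size
                else:
                    mean_s = np.add.reduceat(s_loc, self.offsets, axis=1)
                    s_traces[:, m, :] = mean_s / np.array([p.size for p in self.spec.populations])
                for v in snapshot_vars:
                    if v == "S_NMDA" and exact:
                        snapshots[v].append(nmda_sum_exact(Sd))
                        continue
                    src = {"V": V, "S_NMDA": S_nmda, "S_AMPA": S_ampa,
                           "S_GABA": S_gaba, "s_loc": s_loc}[v]
                    snapshots[v].append(src.copy())

        sizes = np.array([p.size for p in self.spec.populations], dtype=float)
        pop_rates = counts_bins / (sizes[None, None, :] * rate_bin / 1000.0)
        result = SimResult(
            pop_names=self.spec.pop_names,
            pop_sizes=tuple(int(x) for x in sizes),
            T=T, dt=dt, rate_bin=rate_bin,
            pop_rates=pop_rates,
            trace_times=trace_times,
            s_traces=s_traces,
            snapshots={v: np.array(a) for v, a in snapshots.items()},
        )
        if record_spikes:
            if sp_t:
                result.spike_trial = np.concatenate(sp_b)
                result.spike_time = np.concatenate(sp_t)
                result.spike_neuron = np.concatenate(sp_n)
            else:
                result.spike_trial = np.empty(0, dtype=np.int64)
                result.spike_time = np.empty(0)
                result.spike_neuron = np.empty(0, dtype=np.int64)
        return result


def simulate(
    spec: NetworkSpec,
    T: float,
    seed,
    backend: str = "approximate",
    stimulus: StimulusSpec | None = None,
    clamp: ClampSpec | None = None,
    batch: int = 1,
    **run_kwargs,
) -> SimResult:
    """Build connectivity and run; deterministic in (spec, seed, backend).

    The seed fans out into independent connectivity and noise streams.  With
    ``batch > 1`` all trials share the connectivity draw and one noise stream
    (vectorized); run trials separately for per-trial matched-seed designs.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    conn_ss, noise_ss = ss.spawn(2)
    sim = Simulator(spec, conn_ss, backend)
    rng = np.random.default_rng(noise_ss)
    return sim.run(T, rng, batch=batch, stimulus=stimulus, clamp=clamp, **run_kwargs)
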