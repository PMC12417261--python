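"""Connectivity construction, spike delivery, backends, determinism."""

import numpy as np
import pytest

from nmdanet.neuron import NeuronParams
from nmdanet.network import (
    ConnectivitySpec,
    NetworkSpec,
    PopulationSpec,
    benchmark_network_spec,
    build_connectivity,
    count_synapses,
    decision_network_spec,
    scale_network,
    simulate,
    sparse_epsilons,
    w_minus_value,
)
from nmdanet.stimulus import StimulusSpec


def two_pop_spec(n_src=5, n_tgt=3, weight=0.7, delay=1.0, rule="all_to_all",
                 epsilon=1.0, dt=0.1):
    pe = NeuronParams.excitatory()
    return NetworkSpec(
        populations=(
            PopulationSpec("SRC", n_src, pe, "excitatory"),
            PopulationSpec("TGT", n_tgt, pe, "excitatory"),
        ),
        connections=(
            ConnectivitySpec("SRC", "TGT", rule, epsilon, weight, delay,
                             ("AMPA", "NMDA")),
        ),
        dt=dt,
    )


class TestConnectivity:
    def test_fixed_indegree_exact_and_distinct(self):
        spec = two_pop_spec(n_src=10, n_tgt=50, rule="fixed_indegree", epsilon=0.2)
        conn = build_connectivity(spec, 1)
        e = conn.csr_edges[0]
        assert e.indegree == 2
        # invert source->target lists back to per-target in-degrees
        indeg = np.zeros(50, dtype=int)
        for s in range(10):
            tg = e.targets[e.indptr[s]:e.indptr[s + 1]] - 10
            assert np.unique(tg).size == tg.size  # no multapses
            indeg[tg] += 1
        assert np.all(indeg == 2)

    def test_no_autapses_within_population(self):
        pe = NeuronParams.excitatory()
        spec = NetworkSpec(
            populations=(PopulationSpec("E", 20, pe, "excitatory"),),
            connections=(ConnectivitySpec("E", "E", "fixed_indegree", 0.5, 1.0,
                                          0.5, ("AMPA", "NMDA")),),
        )
        conn = build_connectivity(spec, 3)
        e = conn.csr_edges[0]
        for s in range(20):
            assert s not in e.targets[e.indptr[s]:e.indptr[s + 1]]

    def test_epsilon_one_recovers_all_to_all_between_populations(self):
        spec = two_pop_spec(n_src=8, n_tgt=6, rule="fixed_indegree", epsilon=1.0)
        conn = build_connectivity(spec, 0)
        e = conn.csr_edges[0]
        for s in range(8):
            assert e.indptr[s + 1] - e.indptr[s] == 6  # every source hits every target

    def test_out_degree_binomial_mean_over_seeds(self):
        spec = two_pop_spec(n_src=10, n_tgt=40, rule="fixed_indegree", epsilon=0.2)
        outdeg = []
        for seed in range(300):
            e = build_connectivity(spec, seed).csr_edges[0]
            outdeg.append(np.diff(e.indptr))
        outdeg = np.array(outdeg, dtype=float)
        # each target picks 2 of 10 sources: E[out-degree] = 0.2 * 40 = 8
        sd = outdeg.std() / np.sqrt(outdeg.size)
        assert abs(outdeg.mean() - 8.0) < 4 * sd + 1e-9

    def test_full_indegree_within_population_caps_at_all_but_self(self):
        pe = NeuronParams.excitatory()
        spec = NetworkSpec(
            populations=(PopulationSpec("E", 4, pe, "excitatory"),),
            connections=(ConnectivitySpec("E", "E", "fixed_indegree", 1.0, 1.0,
                                          0.5, ("AMPA",)),),
        )
        e = build_connectivity(spec, 0).csr_edges[0]
        assert e.indegree == 3  # every distinct partner, no autapse
        for s in range(4):
            tg = e.targets[e.indptr[s]:e.indptr[s + 1]]
            assert s not in tg
            assert tg.size == 3

    def test_tiny_indegree_rejected(self):
        spec = two_pop_spec(n_src=10, n_tgt=3, rule="fixed_indegree", epsilon=0.01)
        with pytest.raises(ValueError, match="rounds to 0"):
            build_connectivity(spec, 0)

    def test_misaligned_delay_rejected(self):
        with pytest.raises(ValueError):
            two_pop_spec(delay=0.25, dt=0.3)


class TestCounting:
    def test_base_network(self):
        assert count_synapses(benchmark_network_spec()) == 7_200_000
        assert count_synapses(decision_network_spec()) == 7_200_000

    def test_scaled_benchmark_network(self):
        spec = scale_network(benchmark_network_spec(), 10.24)
        assert spec.populations[0].size == 16_384
        assert spec.populations[1].size == 4_096
        assert count_synapses(spec) == 754_974_720

    def test_no_connections(self):
        pe = NeuronParams.excitatory()
        spec = NetworkSpec(populations=(PopulationSpec("E", 1, pe, "excitatory"),),
                           connections=())
        assert count_synapses(spec) == 0


class TestScaling:
    def test_identity(self):
        spec = decision_network_spec()
        s1 = scale_network(spec, 1.0)
        assert [p.size for p in s1.populations] == [p.size for p in spec.populations]

    def test_quarter_scale_conductances(self):
        spec = scale_network(benchmark_network_spec(), 0.25)
        assert [p.size for p in spec.populations] == [400, 100]
        assert spec.populations[0].params.g_NMDA == pytest.approx(0.165 * 4)
        assert spec.populations[0].params.g_AMPA_ext == pytest.approx(2.1)  # unchanged

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            scale_network(benchmark_network_spec(), 1 / 3)

    def test_w_minus_forms(self):
        assert w_minus_value(0.15, 1.7) == pytest.approx(1 - 0.15 * 0.7 / 0.85)
        assert w_minus_value(0.15, 1.7, "printed") == pytest.approx(
            1 - 0.15 * 0.7 * 0.85)
        assert decision_network_spec().w_minus == pytest.approx(0.876470588, abs=1e-8)


class TestDelivery:
    def test_single_spike_jump_after_delay(self, jc):
        # one forced source spike; each target's aggregated S jumps by w*k0
        # exactly one delay later, then decays with tau_d
        w, delay, dt = 0.7, 1.0, 0.1
        spec = two_pop_spec(n_src=1, n_tgt=2, weight=w, delay=delay, dt=dt)
        res = simulate(spec, 30.0, 0, forced_spikes={49: [0]},  # spike at t=5.0 ms
                       snapshot_vars=("S_NMDA",), trace_interval=0.1)
        snap = res.snapshots["S_NMDA"][:, 0, :]  # (n_steps, N)
        tgt = snap[:, 1]
        # spike time 5.0 ms (end of step 49); arrival at 6.0 ms = start of
        # step 60; first recorded sample is the end of that step (one decay)
        arrive_idx = 49 + 1 + int(delay / dt)
        assert np.all(tgt[:arrive_idx] == 0)
        decay = np.exp(-dt / 100.0)
        assert tgt[arrive_idx] == pytest.approx(w * jc.k0 * decay, rel=1e-12)
        t_rel = np.arange(40) * dt
        np.testing.assert_allclose(tgt[arrive_idx:arrive_idx + 40],
                                   tgt[arrive_idx] * np.exp(-t_rel / 100.0),
                                   rtol=1e-10)

    def test_aggregate_equals_weighted_local_sum(self, jc):
        # approximate backend bookkeeping: target S_NMDA(t) == w * sum_j s_j(t - d)
        w, delay = 0.6, 1.0
        spec = two_pop_spec(n_src=5, n_tgt=3, weight=w, delay=delay)
        forced = {30: [0, 2], 80: [1], 81: [1], 200: [0, 1, 2, 3, 4], 450: [3]}
        res = simulate(spec, 100.0, 0, forced_spikes=forced,
                       snapshot_vars=("S_NMDA", "s_loc"), trace_interval=1.0)
        s_nmda = res.snapshots["S_NMDA"][:, 0, :]
        s_loc = res.snapshots["s_loc"][:, 0, :]
        d_rec = int(delay / 1.0)
        lhs = s_nmda[d_rec:, 5]                      # any target neuron
        rhs = w * s_loc[:-d_rec, :5].sum(axis=1)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-15)

    def test_zero_weight_network_equals_isolated_neurons(self):
        eps = sparse_epsilons(0.5, 0.5, 0.5)
        spec = decision_network_spec(scale=0.1, N_E=400, N_I=100, epsilons=eps)
        zero = NetworkSpec(
            populations=spec.populations,
            connections=tuple(
                ConnectivitySpec(c.source, c.target, c.rule, c.epsilon, 0.0,
                                 c.delay, c.receptors) for c in spec.connections),
            dt=spec.dt,
        )
        isolated = NetworkSpec(populations=spec.populations, connections=(),
                               dt=spec.dt)
        stim = StimulusSpec(window=(0.0, 0.0))
        r0 = simulate(zero, 500.0, 4, stimulus=stim)
        r1 = simulate(isolated, 500.0, 4, stimulus=stim)
        t0, n0 = r0.spikes_of(0)
        t1, n1 = r1.spikes_of(0)
        assert np.array_equal(n0, n1)
        assert np.array_equal(t0, t1)

    def test_determinism(self):
        spec = decision_network_spec(scale=0.1, N_E=400, N_I=100)
        stim = StimulusSpec(window=(0.0, 0.0))
        r0 = simulate(spec, 300.0, 9, stimulus=stim)
        r1 = simulate(spec, 300.0, 9, stimulus=stim)
        assert np.array_equal(r0.spike_time, r1.spike_time)
        assert np.array_equal(r0.spike_neuron, r1.spike_neuron)
        assert np.array_equal(r0.pop_rates, r1.pop_rates)


class TestExactBackend:
    def test_exact_requires_uniform_nmda_delay(self):
        pe = NeuronParams.excitatory()
        spec = NetworkSpec(
            populations=(PopulationSpec("A", 2, pe, "excitatory"),
                         PopulationSpec("B", 2, pe, "excitatory")),
            connections=(
                ConnectivitySpec("A", "B", "all_to_all", 1.0, 1.0, 0.5),
                ConnectivitySpec("B", "A", "all_to_all", 1.0, 1.0, 1.0),
            ),
        )
        with pytest.raises(ValueError):
            simulate(spec, 10.0, 0, backend="exact")

    def test_backend_population_rates_agree_in_spontaneous_state(self):
        # reduced decision network, symmetric background-only state: rates of
        # the two backends agree within 10%
        spec = decision_network_spec(scale=0.25)
        stim = StimulusSpec(window=(0.0, 0.0))
        rates = {}
        sizes = np.array([p.size for p in spec.populations], dtype=float)
        for backend in ("approximate", "exact"):
            res = simulate(spec, 1500.0, 21, backend=backend, stimulus=stim,
                           batch=6, record_spikes=False)
            # discard the 500 ms transient; pool excitatory populations and
            # take the median over trials (robust to occasional spontaneous
            # transitions out of the symmetric state)
            r = res.pop_rates[:, 10:, :]
            e = np.average(r[..., :3].mean(axis=1), axis=1, weights=sizes[:3])
            rates[backend] = np.array([np.median(e), np.median(r[..., 3].mean(axis=1))])
        ex, ap = rates["exact"], rates["approximate"]
        assert np.all(np.abs(ap - ex) <= 0.10 * ex)
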