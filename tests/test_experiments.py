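"""Experiment drivers: error characterization, decisions, clamp protocol."""

import numpy as np
import pytest

from nmdanet.experiments import (
    ErrorExperimentSpec,
    decide_winner,
    run_decision_batch,
    run_error_experiment,
    run_matched_backend_trials,
    run_psychometric,
    run_connectivity_sweep,
)
from nmdanet.network import SimResult, Simulator, decision_network_spec, simulate
from nmdanet.stimulus import ClampSpec, StimulusSpec


class TestErrorExperiment:
    def test_zero_weight_zero_error(self):
        res = run_error_experiment(ErrorExperimentSpec(n_pre=3, weight=0.0,
                                                       nu_pre=40.0, T=500.0))
        assert res.rms == 0.0
        assert np.all(res.i_error == 0)
        assert np.all(res.v_error == 0)

    def test_single_spike_error_positive_and_fast_decaying(self):
        # the approximation overshoots the inward current right after a spike,
        # so the signed error I_exact - I_approx jumps positive, then decays
        # on the rise-time scale
        res = run_error_experiment(ErrorExperimentSpec(n_pre=1, weight=1.0,
                                                       T=200.0),
                                   spike_trains=[[50.0]])
        pre = res.times < 50.0
        assert np.all(res.i_error[pre] == 0)
        peak = np.max(res.i_error)
        assert peak > 0
        assert peak == np.max(np.abs(res.i_error))
        at20 = res.i_error[np.argmin(np.abs(res.times - 70.0))]
        assert abs(at20) < 0.05 * peak

    def test_identical_inputs_both_models(self):
        # subthreshold regime: V traces must start identical and diverge only
        # through the NMDA pathway
        res = run_error_experiment(ErrorExperimentSpec(n_pre=2, weight=0.5,
                                                       nu_pre=10.0, T=300.0, seed=3))
        assert res.v_exact[0] == res.v_approx[0]
        assert res.rms < 0.5  # weak input: subthreshold, small error
        assert res.n_spikes_exact == 0
        assert res.n_spikes_approx == 0


class TestWinnerRule:
    def _fake_result(self, ra, rb):
        rates = np.zeros((1, 80, 4))
        rates[0, :, 0] = ra
        rates[0, :, 1] = rb
        return SimResult(pop_names=("EA", "EB", "EN", "I"),
                         pop_sizes=(60, 60, 280, 100), T=4000.0, dt=0.1,
                         rate_bin=50.0, pop_rates=rates,
                         trace_times=np.array([]), s_traces=np.zeros((1, 0, 4)))

    def test_clear_winner(self):
        assert decide_winner(self._fake_result(40.0, 2.0))[0] == "A"
        assert decide_winner(self._fake_result(2.0, 40.0))[0] == "B"

    def test_dead_band(self):
        assert decide_winner(self._fake_result(10.0, 7.0))[0] == "none"
        assert decide_winner(self._fake_result(10.0, 4.0))[0] == "A"


class TestDecisionNetwork:
    def test_strong_coherence_selects_stimulated_population(self):
        # exchanging the roles of A and B via the stimulus sign exchanges the
        # winner: +c drives A, -c drives B
        seeds = list(range(8))
        up = run_decision_batch(80.0, seeds)
        down = run_decision_batch(-80.0, seeds)
        assert sum(t.winner == "A" for t in up) >= 7
        assert sum(t.winner == "B" for t in down) >= 7

    def test_unstructured_network_has_no_systematic_side(self):
        # with w+ = w- = 1 and no stimulus the two selective labels are
        # statistically exchangeable
        spec = decision_network_spec(scale=0.25, w_plus=1.0, w_minus=1.0)
        stim = StimulusSpec(window=(0.0, 0.0))
        res = simulate(spec, 1500.0, 31, stimulus=stim, batch=16,
                       record_spikes=False)
        d = np.array([res.mean_rate("EA", 1000.0, 1500.0, b)
                      - res.mean_rate("EB", 1000.0, 1500.0, b)
                      for b in range(16)])
        assert abs(d.mean()) <= 2.5 * d.std(ddof=1) / np.sqrt(d.size) + 0.5

    def test_single_trial_probability_is_binary(self):
        t = run_psychometric([40.0], 1, master_seed=3, n_resamples=100)
        assert t["p_correct"].iloc[0] in (0.0, 1.0)

    def test_approximation_bias_in_winning_population(self):
        # on bit-identical inputs the approximate model's winning population
        # shows slightly elevated activity relative to the exact model
        df = run_matched_backend_trials(40.0, 20, master_seed=5)
        d = df.rate_win_approximate - df.rate_win_exact
        assert d.mean() > 0.0
        assert (d > 0).sum() >= 12  # tendency, not a per-trial guarantee


class TestClamp:
    def test_steady_state_matches_closed_form(self, jc):
        # network with no external drive: every target's aggregated variable
        # is driven purely by the clamp and must hit the analytic value at
        # release to 1e-6 relative
        spec = decision_network_spec(scale=0.025)  # EA/EB of 6, EN 28, I 10
        # clamp every excitatory population (EN at 0) so no NMDA events mix
        # with the constant drive while AMPA/GABA activity continues freely
        clamp = ClampSpec(sources={"EA": 1.0, "EB": 0.0, "EN": 0.0},
                          window=(0.0, 2000.0))
        ss = np.random.SeedSequence(0)
        c1, c2 = ss.spawn(2)
        sim = Simulator(spec, c1)
        res = sim.run(2000.0, np.random.default_rng(c2), clamp=clamp,
                      snapshot_vars=("S_NMDA",), record_spikes=False)
        snap = res.snapshots["S_NMDA"][-1, 0, :]  # at t_release
        tau_d = spec.populations[0].params.gating.tau_d
        nA = spec.pop("EA").size
        sl = spec.slices()
        sat = 1.0 - np.exp(-2000.0 / tau_d)
        for name, w_ax in [("EA", spec.w_plus), ("EB", spec.w_minus),
                           ("EN", 1.0), ("I", 1.0)]:
            expected = nA * w_ax * sat  # only EA clamps to 1; EB clamps to 0
            got = snap[sl[name]]
            np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_release_restores_free_dynamics(self):
        # unreachable threshold: no spikes, so after release the aggregated
        # variable must follow a pure exponential decay
        from nmdanet.neuron import NeuronParams

        pe = NeuronParams.excitatory(V_thr=60.0)
        pi = NeuronParams.inhibitory(V_thr=60.0)
        spec = decision_network_spec(scale=0.025, exc_params=pe, inh_params=pi)
        clamp = ClampSpec(window=(0.0, 500.0))
        res = simulate(spec, 1000.0, 0, clamp=clamp, record_spikes=False,
                       snapshot_vars=("S_NMDA",))
        snap = res.snapshots["S_NMDA"][:, 0, 0]
        tau_d = spec.populations[0].params.gating.tau_d
        # after release with no drive the aggregate decays exponentially
        post = snap[500:]
        expect = post[0] * np.exp(-np.arange(post.size) * 1.0 / tau_d)
        np.testing.assert_allclose(post, expect, rtol=1e-9)

    def test_clamp_requires_approximate_backend(self):
        spec = decision_network_spec(scale=0.025)
        with pytest.raises(NotImplementedError):
            simulate(spec, 100.0, 0, backend="exact", clamp=ClampSpec())

    def test_sweep_driver_smoke(self):
        table = run_connectivity_sweep([0.6, 1.0], [0.2], [0],
                                       scale=0.1, T=1000.0,
                                       window=(500.0, 1000.0))
        assert len(table) == 2
        assert {"eps_selective", "eps_inhibitory", "E_SA",
                "E_SA_minus_SB"} <= set(table.columns)
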