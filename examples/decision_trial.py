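"""One winner-take-all decision trial on the quarter-scale network.

Background Poisson drive runs throughout; the coherence-biased stimulus is on
during 1000-3000 ms.  The winner is the selective population with the higher
mean activity in the final 500 ms.
"""

from nmdanet import run_decision_trial

trial = run_decision_trial(coherence=40.0, seed=7, scale=0.25)
print(f"winner = {trial.winner}")
print(f"post-stimulus mean rates: A = {trial.rate_A:.1f} sp/s, "
      f"B = {trial.rate_B:.1f} sp/s")
r = trial.result
print("\n50-ms binned activity (sp/s), population A then B:")
for pop in ("EA", "EB"):
    rates = r.pop_rates[0, ::4, r.pop_names.index(pop)]
    print(pop, " ".join(f"{x:5.1f}" for x in rates))
print("\nAt 40% coherence population A receives the stronger stimulus")
print("(56 vs 24 sp/s above baseline) and should win almost always,")
print("sustaining elevated activity after the stimulus ends at 3000 ms.")
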