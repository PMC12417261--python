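"""Small psychometric curve: P(correct) vs coherence with bootstrap CIs.

A desk-scale version of the published experiment (which used 400 trials per
coherence at full network size); here 12 quarter-scale trials per point.
"""

from nmdanet import run_psychometric

table = run_psychometric([1.0, 10.0, 40.0], n_trials=12, master_seed=0,
                         scale=0.25)
print(table.to_string(index=False))
print("\nP(correct) = fraction of trials in which population A (the more")
print("strongly stimulated one) wins; the interval is a 90% percentile")
print("bootstrap over trials.  P rises with coherence toward 1.")
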