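"""Clamp protocol on the sparse decision network.

For the first two seconds the outgoing NMDA gating of selective population A
is pinned to 1 (B to 0) through an equivalent constant drive on all targets.
After release the network either relaxes into a stable asymmetric (decision)
state or falls back to symmetry.  A 5% connectivity dilution (with 1/0.95
conductance scaling) is enough to destroy the asymmetric state.
"""

import numpy as np

from nmdanet import run_sparse_clamp

seeds = [0, 1, 2, 3]
fc = run_sparse_clamp(seeds, fully_connected=True)
dl = run_sparse_clamp(seeds, eps_base=0.95, eps_selective=0.95,
                      eps_inhibitory=0.95, conductance_scale=1 / 0.95)

print("late-window (4-6 s) population-averaged NMDA gating, per seed:")
print("fully connected : E[S_A] =", np.round(fc.E_SA, 3),
      " E[S_B] =", np.round(fc.E_SB, 3))
print("95% connectivity: E[S_A] =", np.round(dl.E_SA, 3),
      " E[S_B] =", np.round(dl.E_SB, 3))
print(f"\nmean asymmetry E[S_A - S_B]: fully connected {fc.diff.mean():.3f}, "
      f"95% diluted {dl.diff.mean():.3f}")
print("The fully connected network keeps A high and B suppressed; after the")
print("5% dilution both populations settle at similar gating levels.")
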