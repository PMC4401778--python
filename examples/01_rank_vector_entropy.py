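"""Rank vector entropy of ordered versus disordered signals.

Builds a pure 10 Hz oscillation and a white-noise signal, runs the RVE
transform (W = 5 samples at lag xi = 2, leaky integrator tau = 0.3 s) and
prints the post-burn-in mean entropy of each.  Ordered signals visit few
ordinal patterns, so their normalised entropy sits far below the white-noise
value, which approaches the theoretical maximum of 1.
"""

import numpy as np

import entropyscope as es

fs = 600.0
t = np.arange(0, 60, 1 / fs)
rng = np.random.default_rng(0)

cfg = es.RveConfig(W=5, xi=2, tau=0.3, f=fs)
tone = es.rve_timecourse(np.sin(2 * np.pi * 10 * t), cfg)
noise = es.rve_timecourse(rng.standard_normal(t.size), cfg)

print(f"pure 10 Hz oscillation : mean S = {tone.valid().mean():.3f}")
print(f"white noise            : mean S = {noise.valid().mean():.3f}")
print("S is normalised to [0, 1]; 1 means all 120 rank patterns equally likely.")

# the worked symbolisation example
rv = es.extract_rank_vector([3.3, 2.7, 2.8, 4.6, 6.0])
sym = es.symbolise(rv, es.SymbolTable(5))
print(f"window [3.3, 2.7, 2.8, 4.6, 6.0] -> rank vector {rv.tolist()} -> symbol {sym}")
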