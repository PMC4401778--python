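"""Multi-scale sample entropy of oscillation + noise mixtures.

Computes SampEn (m = 2, r = 0.2 SD) across coarse-graining scales 1-10 for a
white-noise signal and an alpha-dominated signal.  White noise loses
irregularity as averaging removes fast fluctuations; the oscillatory signal
stays orderly at every scale.
"""

import numpy as np

import entropyscope as es

rng = np.random.default_rng(0)
fs = 300.0
n = int(60 * fs)

white = rng.standard_normal(n)
alpha = np.sin(2 * np.pi * 10 * np.arange(n) / fs) + 0.2 * rng.standard_normal(n)

per_scale = es.SampEnConfig(m=2, r_frac=0.2, r_mode="per_scale")
fixed_r = es.SampEnConfig(m=2, r_frac=0.2, r_mode="global")
w_ps = es.mse_curve(white, per_scale, s_max=10).sampen_per_scale
w_fx = es.mse_curve(white, fixed_r, s_max=10).sampen_per_scale
a_ps = es.mse_curve(alpha, per_scale, s_max=10).sampen_per_scale

print(f"{'scale':>5} {'white (r/scale)':>16} {'white (r fixed)':>16} {'alpha (r/scale)':>16}")
for s in range(10):
    print(f"{s + 1:>5} {w_ps[s]:>16.3f} {w_fx[s]:>16.3f} {a_ps[s]:>16.3f}")
print("\nWith r recomputed per scale (the package default) Gaussian noise keeps")
print("its SampEn across scales; with r fixed from the original series (the")
print("classic convention) the white-noise curve decays as averaging removes")
print("fast fluctuations.  The oscillatory signal stays orderly either way.")
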