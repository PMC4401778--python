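"""Two-group parameter recovery on a simulated cohort.

Simulates 5 + 5 subjects with a doubled task broadband response in one of
four source regions for group 2, runs the source-level pipeline (entropy
transform, per-region task-induced entropy change, permutation + rank-sum
conjunction with Bonferroni correction) and prints the per-region decisions.
"""

import tempfile

import entropyscope as es

cfg = es.PipelineConfig(task="rm", n_blocks=2, sampling_rate=150.0,
                        n_per_group=8, n_sources=4, effect_region=2,
                        entropy_effect_size=3.0, s_max=4,
                        n_iter=10_000, seed=0, compute_spectra=False)
with tempfile.TemporaryDirectory() as tmp:
    res = es.run_pipeline(cfg, tmp)

print(f"{'region':<12} {'diff':>8} {'perm p':>9} {'ranksum p':>10}  significant")
for c in res["comparisons"]:
    print(f"{c['region']:<12} {c['observed_diff']:+8.4f} {c['perm_p']:9.4f} "
          f"{c['ranksum_p']:10.4f}  {c['significant']}")
print("\n'diff' is the group-2 minus group-1 mean task-induced entropy change;")
print("a region is significant only if BOTH tests pass the 0.05/12 threshold.")
print(f"flagged regions: {res['significant_regions']}")
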