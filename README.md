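# entropyscope

Spatio-temporal entropy mapping for multi-channel electrophysiology
(MEG/EEG).  Neural oscillations make cortical signals orderly; engaging a
brain region in a task breaks that synchrony and makes its signal
transiently more disordered.  `entropyscope` turns recordings into
time-resolved maps of that disorder and tests whether task-induced entropy
changes differ between groups — the analysis style used to characterise
altered cortical dynamics in clinical populations.

The pipeline:

1. **LCMV beamforming** — project sensor data onto a source grid:
   Q̂(t) = wᵀm(t) with wᵀ = [hᵀ(C+μΣ)⁻¹h]⁻¹ hᵀ(C+μΣ)⁻¹, lead fields h from
   the single-sphere dipole model, broadband (1–150 Hz) covariance C,
   Σ = η²I, μ = 4, tangential orientation maximising pseudo-Z.
2. **Rank vector entropy (RVE)** — a sliding window of W = 5 samples at lag
   ξ = 2 is reduced to its ordinal pattern (one of 5! = 120 symbols); a
   leaky integrator (τ = 0.3 s, α = e^(−1/fτ)) accumulates symbol
   frequencies and S(k) = (1/ln W!) Σ −pₙ ln pₙ is emitted per sample.
   S ∈ [0,1], amplitude-free, high for noise-like signals, low for
   oscillations.
3. **Temporal ICA parcellation** — 1 s down-sampled entropy from all voxels,
   subjects and tasks is concatenated (Λ = AS), whitened to 45 dimensions
   and decomposed into 40 temporally independent components; thresholded
   mixing columns reconstruct regional broadband timecourses.
4. **Spectral coupling** — 33-band Hilbert-envelope spectrograms, per-band
   entropy–envelope Pearson correlations, and a GLM (s = Gβ + ε, SVD-
   orthogonalised design) for the entropy variance oscillations explain.
5. **Multi-scale sample entropy** — SampEn(m = 2, r = 0.2·SD) on
   coarse-grained series (scales 1–20 / 1–10) cross-validates RVE effects
   across timescales.
6. **Group statistics** — per-region task-induced entropy change Δ compared
   between groups by a label-permutation test (500,000 iterations) AND a
   rank-sum test, Bonferroni-corrected over N = 12 regions; a region is
   reported only when both tests pass.

A synthetic-data module generates the two task paradigms (Sternberg working
memory; relevance modulation, "RM"), task-modulated sources, spherical-
conductor sensor projections and two-group cohorts with a planted
region-specific effect, so the whole pipeline is testable without any
recordings.

## Worked example

```bash
python examples/01_rank_vector_entropy.py
```

```
pure 10 Hz oscillation : mean S = 0.337
white noise            : mean S = 0.966
S is normalised to [0, 1]; 1 means all 120 rank patterns equally likely.
window [3.3, 2.7, 2.8, 4.6, 6.0] -> rank vector [2, 3, 1, 4, 5] -> symbol 31
```

A pure oscillation revisits few ordinal patterns, so its entropy sits far
below the white-noise value, which approaches the theoretical maximum of 1.
The last line shows the symbolisation itself: the window's samples are
ranked (2nd smallest first, …) and the resulting permutation indexed in the
lexicographic table of all 120 patterns.

The other examples each exercise one capability and print what they compute:

* `02_beamformer_round_trip.py` — one simulated dipole at SNR 10 is
  localised to `0.0 mm` grid error with reconstruction correlation `0.998`.
* `03_entropy_oscillation_coupling.py` — a simulated task with alpha/beta
  suppression and a broadband increase yields the biphasic coupling
  spectrum: `alpha r = −0.50`, `beta r = −0.36`, `high gamma r = +0.43`,
  with the envelope GLM explaining `62%` of entropy variance.
* `04_group_comparison.py` — an 8 + 8 cohort with a tripled broadband
  response in one of four regions: only that region passes the
  permutation + rank-sum conjunction (`perm p = 0.0002`,
  `ranksum p = 0.0002`).
* `05_multiscale_entropy.py` — MSE curves under both tolerance conventions.

There is also a thin CLI (`entropyscope simulate|rve|beamform|mse|compare|
pipeline`) over the same functions; `entropyscope pipeline` runs the full
chain from a YAML config and writes per-stage artifacts plus a reproducible
manifest.

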