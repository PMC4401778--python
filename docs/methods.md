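# Methods

`entropyscope` measures the spatio-temporal dynamics of signal "disorder" in
multi-channel electrophysiological recordings (MEG/EEG).  This note documents
the models it implements, the parameters that matter, the synthetic data it
tests itself against, and the numerical choices made where the design was
genuinely open.

## Rank vector entropy (RVE)

A timecourse x sampled at rate f is scanned by a sliding window of W samples
taken at lag ξ:

    W_k = [x_k, x_{k+ξ}, ..., x_{k+(W−1)ξ}]

Each window is reduced to its rank vector (the ordinal pattern: element j is
the index of the j-th smallest sample, ties broken by earlier index), which
indexes one of W! symbols through a lexicographic lookup table, so
[1,2,…,W] ↦ 1 and the reversed pattern ↦ W!.  A leaky integrator accumulates
symbol frequencies: before each increment every count decays by
α = exp(−1/(f·τ)).  The normalised Shannon entropy of the current
distribution is emitted at every sample:

    S(k) = (1/ln W!) · Σ_n −p_n(k) ln p_n(k),   p = F/ΣF

S ∈ [0,1]: 1 when all ordinal patterns are equally frequent (exchangeable
noise), near 0 for signals stuck in few patterns (oscillations).  Because
only ranks enter, S is invariant under any strictly increasing pointwise
transform of the input — in particular amplitude and offset.

Defaults: W = 5, ξ = 2, τ = 0.3 s.  τ trades temporal resolution against
histogram population: it must be long enough for the 120 states to fill
(hence a burn-in of 3τ is masked, not deleted) and short enough that S still
tracks task dynamics.  S(k) is timestamped at the window's first sample; the
output is (W−1)ξ samples shorter than the input.

Implementation: symbolisation is vectorised (stable argsort + Lehmer codes);
the recursion F_k = αF_{k−1} + e_{sym(k)} is evaluated per symbol with a
first-order IIR filter, algebraically identical to the sequential update
(the unit tests include an explicit sequential-update oracle).

## Single-sphere forward model and LCMV beamformer

Sources are current dipoles in a homogeneous conducting sphere; the sensor
response is the closed-form sphere solution (with the property, used as a
test oracle, that volume currents contribute nothing to the radial field
component).  The inverse is a linearly constrained minimum-variance
beamformer: per voxel θ,

    wᵀ = [hᵀ(C + μΣ)⁻¹h]⁻¹ hᵀ(C + μΣ)⁻¹,   Σ = η²I

with C the covariance of the 1–150 Hz band-passed recording over the whole
session, η² the smallest singular value of C (floored at machine ε × trace),
and μ = 4 by default.  Orientation is restricted to the tangential plane
(the sphere model is blind to radial moments) and selected by a bounded 1-D
search (coarse 16-point scan + golden refinement, tolerance 0.1°) maximising
the projected SNR (wᵀCw)/(wᵀΣw) — the pseudo-Z, also used as the
localisation map.  Unit gain wᵀh = 1 holds at the chosen orientation, making
downstream entropy (rank-based) invariant to overall sensor scaling.  The
voxel grid is axis-aligned at 8 mm spacing, masked to the sphere interior
with a 10 % margin from the surface and a 5 % exclusion around the centre
where tangential lead fields degenerate.  A fixed-orientation mode bypasses
the search when orientations are known.

The regularised inverse is computed by eigendecomposition with an
ε·trace floor; genuinely indefinite inputs raise with advice to increase μ.

## Temporal ICA parcellation

Per-voxel entropy timecourses are down-sampled to 1 s resolution
(non-overlapping block means, burn-in excluded), de-meaned per subject
segment and concatenated across subjects and tasks into a voxels × time
matrix Λ.  PCA whitens Λ to n_pca dimensions (default 45) and FastICA
extracts n_ica temporally independent signals (default 40): Λ = A·S.
Columns of A (spatial maps) are sign-fixed (largest-|weight| voxel positive)
and unit-normalised.  Convergence failures retry with fresh seeds and then
raise; the pipeline additionally halves the model order on failure, since
synthetic datasets often contain fewer non-Gaussian temporal components than
the requested order.  On desk-scale problems the pipeline caps
n_ica ≤ 0.85·n_pca.

Component selection (replacing visual inspection): components are ranked by
a task-modulation ratio — variance of the trial-averaged component signal
divided by the mean variance over trial-shuffled surrogates (noise
components score ≈ 1) — with a manual override list accepted.  Regional
broadband timecourses are reconstructed as weighted sums of the full-rate
beamformed voxel timecourses, weights taken from the mixing column,
thresholded at 2 SD of the column (configurable absolute threshold) and
renormalised to Σ|w| = 1.  Regional entropy and spectrograms are then
recomputed at full rate.

## Spectral coupling

Spectrograms: 33 overlapping bands spanning 1–150 Hz (centres log-spaced
1.5–140 Hz, bandwidth max(2 Hz, 0.5·centre), ≥ 50 % neighbour overlap — the
exact edges are a package choice, config-exposed).  Each band is filtered
with a zero-phase FIR (symmetric kernel applied by centred convolution;
transition width 10 % of the low edge) and the Hilbert envelope taken; one
filter length at each end is masked from correlations.  Trial averaging and
baseline referencing use the task's averaging window (0–12 s Sternberg,
0–2 s RM) and the rest windows.

Entropy–oscillation coupling is quantified two ways, both on unaveraged
data: per-band Pearson correlation (envelope linearly interpolated onto the
entropy time axis), and a GLM s = Gβ + ε regressing entropy on all band
envelopes jointly, the design orthogonalised through the SVD of G·Gᵀ with
null directions dropped; r² = 1 − var(ε)/var(s).

## Multi-scale sample entropy

SampEn(m, r) = −ln(A/B), where B counts template pairs matching over m
points and A those still matching at m+1, Chebyshev distance, self-matches
excluded, both counts over the same N−m templates (Richman–Moorman; the
paper-facing prose omits the sign, the standard sign convention is used).
Defaults m = 2, r = 0.2·SD.  Scale s replaces the series by means of
non-overlapping blocks of s points; scales 1–20 (Sternberg) or 1–10 (RM).

Tolerance convention: by default r is recomputed from each analysed segment
(each coarse-grained series, each trial) — under this convention
coarse-grained Gaussian noise keeps its SampEn, because it remains Gaussian
noise.  The classic fixed-r convention (r from the original series, under
which white-noise curves decay with scale) is available as
`r_mode="global"`.  This is a known sensitivity of MSE and the single
largest interpretive knob in the module.

Task–rest changes are computed per trial window and averaged; the rest
reference is cut into segments matched to the trial-window length before
SampEn, because SampEn is length-biased and a task/rest comparison at
unequal lengths would confound the contrast.  RM trials are split into
relevant/irrelevant; flagged target trials are excluded everywhere.

## Group statistics

Per subject and region, Δ = mean entropy over task windows − mean over rest
windows.  Sessions (tasks) are pooled as independent observations.  Two
tests per region: a label-permutation test on the difference of group means
(default 500,000 iterations; add-one two-sided p so p > 0; "sham" groups
preserve group sizes) and a two-sided rank-sum test (exact for small
tie-free samples).  Significance requires BOTH tests below 0.05/N with
N = 12 regions (conjunction + Bonferroni).  MSE changes are tested with the
same machinery independently per scale.  Hemispheric lateralisation of the
entropy response is tested by a paired two-sided signed-rank comparison of
per-subject variances of the trial-averaged entropy timecourse.
Sidedness and the permutation statistic are package conventions (two-sided,
difference of means); the tests document them.

## Synthetic data

The generators define the study conditions everything is tested under.

Paradigms (timing constants are the tasks' printed design):
* Sternberg: trials of two 600 ms example stimuli with onsets 1 s apart, 6 s
  maintenance, 3 s probe at +8 s (probe placement rounds the stated
  durations so the retrieval response falls near 8 s); probe matches with
  p = 0.5; 3 trials + 36 s rest per block; 15 blocks canonical; averaging
  window 0–12 s.
* Relevance modulation (RM): blocks of 40 alternating 800 ms stimuli,
  offset-to-onset gaps from a truncated normal (mean 1.92 s, SD 0.08 s,
  ±3 SD; the printed "±" is read as an SD, and the gap definition is a
  package choice recorded on the spec object); target probability 0.05,
  targets excluded from analysis; block order BF, LB, LB, BF, LB, BF, BF,
  LB, 120 s per block, the remainder after the last stimulus being rest;
  averaging window 0–2 s.

Sources: each simulated source is a sum of band-limited oscillations
(zero-phase band-passed white noise; pure-tone mode for invariance tests)
whose amplitude is multiplied by an event-keyed factor during stimuli, plus
broadband noise likewise modulated, plus a stationary floor.  The default
task signature — oscillatory factor 0.5, broadband factor 2.0 — produces
task-locked alpha/beta suppression with an entropy increase, the coupling
the analysis is designed to expose.  The broadband component is "white"
(flat to Nyquist) or "fast" (first difference of white noise, power rising
toward Nyquist): the fast mode confines the broadband effect to the shortest
coarse-graining scales, giving the scale-specific MSE signature.  Between-
subject heterogeneity enters as a log-normal multiplier (SD 0.2 in the
cohort defaults) on the task broadband factors.

Cohorts: two groups; group 2's task broadband factor at one designated
region is multiplied by the entropy effect size (1 = exchangeable null).
The parameter-recovery conditions are 11 subjects per group with effect
size 2, a Sternberg session (2 blocks) and an RM session (1 block) per
subject at 150 Hz — pooled as 22 sessions per group for the regional
conjunction test, with per-scale MSE decisions from the RM session.  These
sizes are the package's desk-scale defaults; sampling at 150 Hz keeps the
oscillations well below Nyquist while making the fast broadband component
genuinely fast relative to the coarse-graining scales.

What the generator does not emulate: environmental interference, cardiac
and ocular artefacts, realistic cortical geometry, head movement, and
session-level dependence between a subject's two tasks (sessions are
simulated independently, matching how the statistics treat them).  Passing
tests therefore validate the algorithms and their statistical calibration,
not performance on real recordings.

## Numerical and performance choices

* SampEn pair counting uses shifted boolean match matrices in row chunks:
  exact, O(N²) time, bounded memory; verified against an explicit-loop
  oracle on every tested series.
* Permutation tests vectorise relabellings in chunks (argsort of uniforms),
  seeded through `numpy.random.default_rng`; identical seeds give identical
  p-values.
* Filters: Butterworth `sosfiltfilt` for the covariance band and source
  synthesis; symmetric FIR via centred FFT convolution for spectrograms.
* Degenerate inputs: zero-variance SampEn input and all-zero histograms
  raise; undefined SampEn at long scales becomes NaN and is dropped from
  group tables; beamformer grids outside the sphere and sources at the
  sphere centre raise geometry errors.
* The pipeline persists stage artifacts (CSV/HDF5) plus a manifest with the
  config hash and seeds; re-running a completed configuration in the same
  directory is a no-op, and re-running in a fresh directory is bit-identical.

## Known limitations

* The sphere head model and radial-sensor cap are idealised; no synthetic
  gradiometers or realistic conductor models.
* Correlated sources violate the LCMV independence assumption; no remedy is
  implemented (out of scope).
* ICA component count on small synthetic datasets is limited by the true
  non-Gaussian rank; the pipeline's order-halving fallback trades model
  order for convergence.
* Treating two sessions per subject as independent observations (as the
  group tests do) is statistically debatable; a mixed-effects treatment is
  deliberately not implemented.
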