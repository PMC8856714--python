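# Methods

This note documents the models, parameter choices, and numerical conventions
behind `popdiff`, and what the synthetic-data tests do and do not establish
about real recordings.

## Spectral differentiation

A trial's ΔF/F slice (cells × samples, 30 Hz) is tiled into windows of
`window_length` s (default 1 s) with hop `window · (1 − overlap)`; a trailing
partial window is dropped (trial lengths in the supported designs are exact
multiples, so this only matters for ragged input).  Per cell and window a
taper is applied (rectangular by default; Tukey with fraction 0.25 at 12.5%
overlap and Kaiser β = 14 at 50% overlap are the supported alternatives for
sensitivity analysis) and the one-sided DFT magnitude is computed.  The state
vector concatenates per-cell spectra; the default spectrum is *power*
(squared magnitude) with the DC term retained.  Both choices are exposed
(`spectrum_kind`, `include_dc`) because neither is forced by the measure:
with power spectra ND scales as the square of signal amplitude, with
magnitude spectra linearly (both asserted exactly in tests).  Logarithmic
frequency binning sums power into geometric bins from the first nonzero
frequency to Nyquist, keeping DC as its own bin.

ND is the median of all pairwise distances between window states (Euclidean
default; Manhattan, cosine, and correlation supported for the sensitivity
grid), divided by √n_cells.  The median over an even number of distances is
the mean of the two central values.  Consequences worth keeping in mind:

* exactly window-periodic populations give ND = 0, and any operation that
  preserves per-window power spectra (e.g. per-window phase randomization)
  leaves ND unchanged;
* i.i.d. noise gives strictly positive ND (spectral estimation error);
* as a *median*, ND responds to spread among typical window pairs, not to a
  few extreme windows — this drove the design of the synthetic effect (below).

## Multivariate differentiation

Selected trials' samples are concatenated to an (m × n) matrix and embedded
to `n_components = 8` dimensions.  The default backend is UMAP with
`n_neighbors = 50`, `min_dist = 0.5`, Euclidean metric, and a fixed seed.
Because a nonlinear embedding is a cited tool rather than part of the
measure's contract, two deterministic alternatives exist for testing and fast
pipelines: a seeded orthonormalized Gaussian linear projection, and the
identity.  Per trial, ND is the mean Euclidean distance of that trial's
embedded points to their centroid; with the identity embedding this
dispersion is exactly rotation-invariant.  For event data, per-cell event
magnitudes are summed in 1-s bins and all-zero bins are dropped before
embedding (duplicate zero vectors would dilute the dispersion), with an index
map from retained bins back to trials.

## Phase scrambling

Temporal: per pixel and per contiguous 1-s window (30 frames), the DFT
magnitudes are kept and the phase is rebuilt as [original DC phase, 14 random
phases uniform on [0, 2π), original Nyquist phase, negated reversed random
phases] — the conjugate-symmetric construction for even N, generalized to
⌊N/2⌋−1 free phases (no Nyquist term for odd N).  Spatial: per window, a
single random 2-D phase field (the phase of the 2-D DFT of a random real
image) is added to the spatial dimensions of the window's 3-D spectrum,
broadcast across temporal frequencies; conjugate symmetry of the field makes
the inverse transform real to numerical precision.  Both scrambles preserve
per-window magnitude spectra exactly (tested to 1e-9).  Quantization back to
uint8 rounds half away from zero and clips to [0, 255]; the induced spectral
deviation is computed and reported (`quantization_spectrum_deviation`), since
clipped out-of-range excursions make quantized spectra closely matched but
not equal to their sources.

## Stimulus differentiation and statistics

SD applies the spectral measure to pixel-intensity timeseries after a
circular Gaussian blur with HWHM 8.92 visual degrees (the median L2/3 V1
receptive-field radius); σ_pixels = (HWHM/deg_per_px)/√(2 ln 2), truncated at
4σ.  `degrees_per_pixel` depends on screen geometry and defaults to 0.625
(a 192-px frame spanning ≈120° at 15 cm viewing distance); no quantitative
claim in the test suite depends on this value.  Stimulus statistics: mean
luminance (mean pixel intensity, raw), contrast (SD of pixel intensities,
raw), and spectral energy (sum over pixels of the DC-removed energy spectral
density of the blurred movie, normalized so it equals the energy of the
mean-removed traces by Parseval).

## Behavioral preprocessing

Locomotion: iterative prominence-based despiking with linear interpolation
(automated stand-in for the original per-session manual curation; prominence
is configurable because no principled universal default exists), then a
zero-phase low-pass Butterworth at 1 Hz — order 2 applied forward-backward,
i.e. effective order 4 with zero phase.  Running fraction binarizes the
preprocessed velocity at 2.5 cm/s (strict `>`; the boundary has measure
zero).  Pupil diameter is normalized by its maximum over the full extent of
the stimulus blocks (first trial start to last trial end), so gray gaps
inside the span count and pre-session samples may exceed 1.

Event detection is a pluggable interface; the built-in detector (smoothed
trace, raw first-difference thresholded at 3 robust SDs, one event per
contiguous suprathreshold run, 6-sample refractory) is a documented stand-in
for dedicated sparse-deconvolution methods and is validated only against the
generator's ground truth.  Transient removal replaces the 6 samples (200 ms)
after each event with linear interpolation between the nearest untouched
samples, merging overlapping spans and clamping at trace ends.

## Statistics

*Permutation test* (per session): observed statistic = mean(unscrambled ND) −
mean(scrambled ND); null from 20,000 seeded label shuffles, or exhaustive
enumeration on small designs; p = fraction of null draws strictly greater
than observed.  The strict inequality can give p = 0; an add-one-smoothed
estimator is available behind a flag when a guaranteed-positive p is needed.

*Mixed models*: ND is log-transformed (natural log; ND distributions are
approximately log-normal) and fitted by maximum likelihood with
`log ND ~ factor * category (+ covariates) + (1 | session)`.  Interaction
evidence is the LRT against the no-interaction model (df = levels − 1: 2 for
layer, 4 for area).  Optional arousal covariates (running fraction, mean
normalized pupil) enter as fixed effects.  Because single-optimizer fits of
variance-component models occasionally stop at poor local optima or report
degenerate infinite likelihoods — which would corrupt a likelihood *ratio* —
each model is fitted with several optimizers and the best finite
log-likelihood is kept.  Within-level one-sided contrasts (unscrambled −
scrambled) are adjusted with the single-step max-Z method using the contrast
correlation matrix (multivariate-normal equicoordinate probabilities); Holm
is the fallback when the covariance is unavailable, flagged in the output.
One-sided simultaneous confidence bounds are reported as [lower, ∞).
Pairwise stimulus contrasts use the same machinery two-sided (Tukey-style
simultaneous inference).  Cohen's d uses the pooled SD with n−1 variances.

*Decoding*: trials × (cells · samples) feature matrices; PCA retaining 99%
variance fitted on each training fold only (the leakage-safe reading — a
projection fitted on all trials would let test data shape the compression),
then LDA with the lsqr solver and automatic shrinkage, stratified fivefold
CV (stratification matters because the category design is 20/30 imbalanced),
scored by balanced accuracy (chance 0.5 for category, 1/12 for identity);
per-stimulus F1 for the five-continuous-stimuli target.

## Synthetic data generator

The generator is the package's study-design stand-in, not a biophysical
model.  Per session: 12 stimuli (2 unscrambled, 3 scrambled, 7 other) × 10
randomized blocks of 30-s trials with 4-s gray gaps at 30 Hz (≈68 min,
122,520 samples).  Per cell, events are a doubly-stochastic point process:
Poisson events at a baseline rate (default 0.5 Hz, lognormally varied across
cells) plus Poisson-triggered bursts (0.08 Hz triggers, 20 Hz for 0.3 s);
event magnitudes are exponential (mean 1 ΔF/F unit); the trace is the linear
superposition of a unit-peak difference-of-exponentials GCaMP6f kernel
(decay 0.6 s, rise 0.05 s) plus i.i.d. Gaussian noise (σ = 0.05).  Gray gaps
carry baseline activity and are excluded from all measures.

**Category effect.**  A shared latent modulator multiplies each cell's event
rate, burst-trigger rate, and event magnitudes by a gain that is constant
within each 1-s window and redrawn across windows.  Gains are mean-one
uniform on [1−a, 1+a] with a² / 3 = variance; in designated responsive
populations, unscrambled trials draw gains with variance exceeding the
scrambled trials' by `effect_delta` (so the total variance is capped at 1/3,
the maximum for a mean-one nonnegative uniform).  A broad bounded
distribution was chosen deliberately: the ND median responds to spread among
typical window pairs, and right-skewed mean-one alternatives concentrate
their variance in rare extreme windows that the median ignores.  A separate
`rate_effect_delta` knob adds a pure mean-rate component, since real
category effects contain both direct and rate-mediated parts.  With
`effect_delta = 0` the categories are statistically exchangeable by
construction, which the null-calibration tests exploit.

**Calibration.**  The documented operating point `EFFECT_DELTA_STAR = 0.29`
(base modulator variance 0.04, so boosted trials sit at the 1/3 cap) gives,
at the desk-scale session size used throughout the tests (12–16 cells),
within-session log-ND Cohen's d ≈ 0.9–1.3 and ≥80% per-session permutation
power — comparable to strong sessions in real recordings.  Arousal traces
(locomotion bouts at 1/60 s⁻¹, ≈12-s exponential durations, ≈10 cm/s speeds;
pupil positively coupled to a smoothed arousal state) are generated always
but gain-coupled to firing only when `arousal_gain_coupling` is set, keeping
measure-level tests arousal-free by default.

**What passing tests show — and don't.**  The generator produces linear
superposition of kernels; it has no calcium-buffering nonlinearity, no
spike-rate-dependent kernel saturation, no correlated noise across cells
beyond the shared modulator, and no stimulus-specific tuning (identity
decoding is at chance by design).  Tests passing on this data establish that
the *pipeline* is correct and calibrated — not that real cortical populations
behave like the model.  Conversely the null-calibration results are
distribution-light: they rely only on exchangeability, which holds for real
trial labels under the null as well.

## Problem sizes and determinism

All stochastic stages take explicit seeds; cohort generation fans a root
seed out through `numpy.random.SeedSequence`, and the end-to-end pipeline
reproduces numeric outputs byte-identically under a fixed config.  The test
suite and the acceptance script use scaled-down study conditions chosen as
the package's own desk-scale defaults: sessions of 6–16 cells (the full trial
structure is never scaled), 200 sessions for null calibration, 100 cohorts
of 45 sessions for specificity recovery, and 50 sessions for decoding-chance
calibration.

## Known limitations

* The built-in event detector is a simple threshold stand-in; serious event
  analysis should plug in a dedicated deconvolution method via the detector
  interface.
* The modulator variance cap (1/3) bounds the plantable variance effect; the
  mean-rate knob is unbounded.
* MixedLM variance components can legitimately hit zero on null cohorts;
  the LRT then behaves conservatively at the boundary.
* No reader for external acquisition-pipeline session formats; sessions
  enter through the documented directory dialect or in memory.
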