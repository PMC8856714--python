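# popdiff

Quantifying **stimulus-evoked neurophysiological differentiation (ND)** in
populations of neurons recorded with two-photon calcium imaging, and running
the statistical machinery that turns per-trial ND values into claims about
cortical layers and visual areas.

The scientific question: when a mouse watches a naturalistic movie versus a
phase-scrambled control with the same power spectrum, do some cell
populations visit a *richer repertoire of activity states*?  ND
operationalizes "richness of repertoire" without reference to the stimulus,
in contrast to decoding, which asks only whether stimulus information is
present.  The package is aimed at systems neuroscientists who want to apply
differentiation analysis to their own (or simulated) population recordings.

## The measures

**Spectral differentiation.**  For a population of $n$ cells responding to a
30-s stimulus at 30 Hz, each cell's ΔF/F trace is divided into 1-s windows
and the one-sided power spectrum of every window is estimated.  The
*population state* in window $w$ is the concatenation of the $n$ per-cell
spectra.  ND for the trial is

$$\mathrm{ND} = \frac{1}{\sqrt{n}}\,\mathrm{median}\big\{\lVert s_w - s_{w'}\rVert_2 : w < w'\big\},$$

the median pairwise Euclidean distance between the 30 states, divided by
$\sqrt{n}$ so that duplicating a population leaves the value unchanged.  A
trace set that is exactly 1-s periodic has ND = 0; i.i.d. noise has strictly
positive ND through finite-window estimation error.

**Multivariate differentiation.**  The (samples × cells) response matrix of
the selected trials is embedded into 8 dimensions (UMAP, `n_neighbors=50`,
`min_dist=0.5`); each trial's ND is the mean Euclidean distance of its
embedded samples to their centroid.

**Controls and statistics.**  Movie stimuli are phase-scrambled (temporally
per pixel, or spatially per 1-s window) with a conjugate-symmetric random
phase so the power spectrum is preserved exactly before uint8 quantization.
Inference uses one-sided trial-label permutation tests per session (20,000
shuffles, $p$ = fraction of permuted mean differences strictly greater than
observed), linear mixed models on log ND (`category * factor` fixed effects,
random intercept per session, likelihood-ratio tests of the interaction,
single-step-adjusted one-sided contrasts, Cohen's $d$ with the pooled SD),
and PCA + shrinkage-LDA decoding as the contrast analysis.

Because no recordings ship with the package, a first-class synthetic-data
generator produces cohorts with the full study structure (3 layers × 5
areas, 12 stimuli × 10 randomized blocks of 30-s trials with 4-s gray gaps,
GCaMP6f-kernel calcium dynamics, arousal covariates) and a tunable category
effect confined to designated populations — so every stage of the pipeline is
testable end to end.

## Worked example

```python
from popdiff.synth import CohortSpec, generate_session, EFFECT_DELTA_STAR
from popdiff.differentiation import SpectralParams, nd_per_trial
from popdiff.stats import PermutationParams, permutation_test

spec = CohortSpec(n_cells_range=(12, 12), effect_delta=EFFECT_DELTA_STAR)
session = generate_session(spec, "L2/3", "AL", seed=7)   # responsive population

table = nd_per_trial(session, SpectralParams(), categories=["unscrambled", "scrambled"])
res = permutation_test(table["nd_value"].to_numpy(), table["category"].to_numpy(),
                       PermutationParams(n_permutations=20000, seed=7))
print(table.groupby("category")["nd_value"].mean().round(1))
print(f"observed difference = {res.observed_diff:.1f}, one-sided p = {res.p:.4f}")
```

prints

```
category
scrambled      5047.7
unscrambled    7847.4
Name: nd_value, dtype: float64
observed difference = 2799.7, one-sided p = 0.0001
```

— the 20 unscrambled trials evoked visibly more differentiated responses than
the 30 scrambled trials (mean ND 7847 vs 5048, in ΔF/F² spectral-power
units), and only 2 of 20,000 label shuffles produce a difference that large,
so the session-level permutation test rejects.  Running the same session with
`effect_delta=0` gives a $p$ drawn uniformly from [0, 1].

The numbered scripts under `analysis/` run the full study on a demo cohort:
`01` simulates 15 sessions (effect planted only in L2/3 of AL and AM), `02`
phase-scrambles a movie and verifies spectrum preservation, `03` computes ND
and per-session permutation tests (the resulting fraction-significant table
isolates exactly the two responsive populations), `04` fits the mixed models
(layer interaction χ²(2) = 25.7, area interaction χ²(4) = 21.7 on the demo
cohort, with significant contrasts only in L2/3, AL, and AM), `05` runs the
decoding contrast, and `06` computes stimulus differentiation and low-level
stimulus statistics.  Tables land in `results/`, bulky arrays in `scratch/`.

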