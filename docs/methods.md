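# Methods

This note documents the models, conventions and numerical choices behind
`hsisort`, and what the synthetic study conditions do and do not show
about real acquisitions.

## The discrimination problem

Legume lots for gluten-free production (broad bean, chickpea, lentil)
must be cleared of gluten-bearing cereal kernels (wheat, oat). The
decision is per seed and binary — accept (legume) or eject — and the loss
is asymmetric: one admitted cereal kernel contaminates the lot, while an
ejected legume is only a small economic loss. Every design choice below
follows from that asymmetry: the headline operating point is *zero false
positives* with a false-negative rate well under 1%.

## Synthetic data generator

No public hyperspectral seed acquisitions accompany this problem, so the
generator is a first-class, tested component that defines the study
conditions for everything downstream.

**Wavelength axis.** One fused VNIR/SWIR axis, 400–1700 nm at a 5 nm
step: 261 bands. The physical sensor boundary near 1000 nm is not
modelled as a discontinuity; the downstream analysis treats the axis as
one candidate set.

**Endmembers.** All classes share one smooth random baseline (Gaussian
process–like, correlation length 80 nm, mean 0.5, amplitude 0.12
reflectance). Class contrast is planted per legume/contaminant pair at a
small set of wavelengths: at each planted band the pair differs by the
requested contrast (default 0.2 reflectance), with the first class of the
pair (the legume in all defaults) on the bright side. Off the planted
bands, paired classes coincide exactly. Each planted offset carries
shoulders one grid step away at a fifth of its height — absorption
features have finite spectral width, and a 15 nm broadband window should
retain most of the contrast rather than a third of it. The default
planted sets per pair follow the wavelength lists a real selection
campaign reported for these pairings (2–5 bands per pair).

When several pairs are requested at once, the per-band constraint system
(pairs planted at a band must differ; pairs not planted there must
coincide) is solved by union-find contraction and level assignment;
contradictory systems — a class forced both equal and different through a
chain of pairs — raise an explicit infeasibility error. The full 6-pair
system with the default band lists is infeasible in this sense, which is
why laboratory datasets are built pairwise (as the real campaign's
datasets were) and deployment libraries per legume.

**Per-seed variation.** Three components:

* *Brightness*: a multiplicative log-normal factor (σ = 0.05), modelling
  intact/non-intact units and illumination geometry.
* *Structured spectral fluctuation*: for each pair, per-seed Gaussian
  coefficients (base σ = 0.095) on an orthonormal basis of the
  planted-band subspace orthogonal to the class-contrast direction, each
  basis vector smoothly extended over the whole axis (Gaussian-bump
  interpolation, width 40 nm) so the fluctuation looks like broad
  spectral wiggle rather than isolated spikes. The amplitude scales with
  the planted-set size k as √(k(k−1)/2). This component is what makes
  the planted bands *jointly but not singly* sufficient: any proper
  subset of the planted bands retains enough fluctuation variance to
  blur the contrast (single-band accuracy ~70–90%), while the full set
  lets a linear model project the fluctuation out entirely. Without it,
  one 0.2-contrast band separates the classes essentially perfectly and
  a forward selection would stop after one pick — unlike the real
  campaign, whose per-pair selections needed all of their 2–5
  wavelengths. Because the fluctuation is orthogonal to the contrast,
  it never moves a seed along the discriminative direction itself.
* *Sensor noise*: additive Gaussian, σ = 0.01 reflectance per band on
  stream spectra; σ = 20 raw counts per pixel in rendered scenes (which
  averages to far less over a seed's ~100–300 pixels). Stream spectra
  are not clipped at zero — flat-field reflectance is not clipped either.

**Orientation degradation.** With probability `orientation_noise`
(default 0.005) a seed falls profile-on and under-exposes its surface:
its spectrum is attenuated to 10–45% of its clean level and mildly
flattened toward its own mean (0–30%). Degradation is deliberately
attenuation-dominant: a barely-exposed seed is dark, not recoloured.
This is the sole deployment degradation modelled, and it reproduces the
observed industrial pattern — a residual false-negative rate of a few
tenths of a percent with no false positives.

**Scenes.** Seeds are non-overlapping axis-aligned ellipses (size by
product: broad beans largest, lentils smallest) on a dark background;
raw counts are `dark + illumination(col) × reflectance × white_span +
noise`, and the reference frames are built from the same dark level and
illumination profile, so flat-field calibration of a noiseless scene
recovers the planted reflectance exactly (to < 1e-9). Disjointness uses
a conservative summed-axes ellipse test plus an exact raster check.

## Calibration

`Rc = (R − D)/(W − D)` per pixel and band. Cells where the white–dark
span is ≤ 1e-12 raw counts yield 0 and are counted in the output's
metadata (dead reference pixels are a practical nuisance the formula
does not address; zero is the conservative "no signal" choice). Negative
reflectance is kept by default and counted; clipping to [0, 1] is
opt-in. Single-line references broadcast across rows, matching
line-scanner practice. Supported ENVI dialects: BSQ/BIL/BIP, float32 /
float64 / uint16, little or big endian — the header is a plain-text
key/value block and is validated against the payload size.

## Segmentation

Foreground is thresholded on the band-averaged reflectance image —
Otsu's method by default (parameter-free and reproducible; the
acquisition background is dark and well separated), or a fixed
threshold. Connected components (8-connectivity default) of at least 20
pixels become objects; each object's spectrum is the per-band arithmetic
mean over its pixels, and object order is deterministic (row-major by
centroid). Touching-seed splitting is out of scope: the generator
guarantees disjoint seeds.

## Wavelength selection (mRMR)

Reflectances are discretised per band — equal-frequency, 8 bins by
default (robust to scale; equal-width is available) — and mutual
information is the plug-in estimate in bits. Relevance is `V(λ) =
I(λ; y)`; redundancy is the mean `W(λ) = (1/|S|) Σ_{z∈S} I(λ; z)`;
candidates are ranked by `MIQ = V / max(W, 1e-12)` (the quotient is
undefined at W = 0; the guard keeps a zero-redundancy informative band
first in line). The first step ranks by relevance alone, as W is
undefined for an empty set. Ties break toward the lower wavelength so
the procedure is fully deterministic.

After each addition a wrapper trains the linear classifier on the
training split and scores the *validation* split — never training data,
so the stopping rule cannot trivially reach 100%. The wrapper's score is
the overall correct-classification percentage across both classes: a
legume-rate-only score is degenerate under threshold shifts (accept
everything and the legume rate is 100%). Selection stops at the target
rate (default 99%), at the size cap (default 10; real selections here
have 2–5 bands), or when Ω is exhausted.

## Classification and metrics

The classifier is a linear support-vector machine (hinge loss, L2
penalty, C = 1 in the laboratory stage) on features standardized with
training-split statistics only. The data protocol: stratified 50/25/25
train/validation/test; the validation quarter drives the mRMR stopping
rule and the operating threshold; the test quarter is touched once.
5-fold stratified cross-validation inside the data checks model
stability.

Metrics follow the sorting convention: positives are legumes, `TPR` is
the percentage of legumes kept, `FNR = 100 − TPR` the legumes lost to
the reject stream, and `FPR` the percentage of contaminants wrongly
kept. The headline `CCR` equals the legume-class rate (CCR = TPR);
overall accuracy across both classes is reported alongside under its own
name, so the two notions are never silently conflated.

**Zero-FPR operating point.** After training, the decision threshold can
be shifted up so that every validation contaminant falls below it. With
no FNR budget the threshold bisects the gap between the highest
contaminant and the lowest legume above it. With a positive budget (a
fraction of legumes one accepts losing, set slightly above the expected
rate of badly exposed seeds) it moves to the midpoint between the
contaminant maximum and the legume score quantile at that budget — this
keeps a degraded legume from dragging the operating point down into the
ambiguous region.

A comparison harness ranks pluggable classifier families (trees,
discriminant analysis, logistic regression, naive Bayes, linear SVM,
nearest neighbour, random forest, a small neural network) by validation
accuracy; it exists to reproduce the *structure* of a preliminary
model-family survey, not anyone's numbers.

## Sorter simulation

**Broadband mode.** The sorter's optics integrate 15 nm, not 5: each
selected wavelength's feature becomes the mean over the window centred
on it ({λ−5, λ, λ+5} at 15 nm). Windows crossing the grid edge are
truncated with a logged warning. Bandwidth must be an odd multiple of
the grid step.

**Programmed wavelengths.** The deployment band list is the union of the
legume's pair-informative bands plus a few reference wavelengths placed
as far from the informative ones as the grid allows (default 4). The
references carry no class contrast; they let the linear rule cancel
common-mode brightness and the correlated fluctuation. Without them the
pooled two-contaminant task has no fluctuation-free linear direction
over the informative bands alone.

**Accept class.** The deployed model's accept class is *cleanly exposed
legume*: in the calibration stream (enriched to 5% profile-on seeds so
the reject side of the margin is well populated) degraded seeds of
either botanical class are labelled reject. This is the decisive choice
for the exact-zero-FPR behaviour. A model trained on botanical labels
places the degraded-seed score cloud around the decision boundary —
attenuation drags every score toward that of a dark spectrum, whose sign
under a brightness-cancelling rule is arbitrary — and some degraded
contaminant in a 10^5-seed campaign then crosses any midgap threshold.
Training dark/ambiguous appearance into the reject class pushes the
whole cloud to the reject side with margin; the threshold (FNR budget =
max(1%, 2 × orientation rate)) then sits in a wide gap. The cost is that
profile-on legumes are ejected, which is exactly the small industrial
FNR (~0.5% at the 0.5% default orientation rate) with FPR identically
zero — verified over tens of replicated 5000-seed runs and stress
streams with tenfold orientation rates. Deployment uses C = 10: the
margin against the reject cloud is the quantity of interest and the
training task is separable.

**Replicates and statistics.** A campaign runs the sorter n times
(default 5) on independently seeded streams. Because one scalar CCR per
run admits no within-group variance, the ANOVA response is the per-batch
legume-rate CCR (each run's stream divided into 10 contiguous batches),
with run as the one-way factor; Tukey's HSD compares run pairs at
α = 0.05. Runs that replay identical streams (or a response with no
variance at all) are flagged degenerate rather than tested. Under the
null (all runs from one distribution) the ANOVA p-values are
approximately uniform; this calibration is checked over 200 seeded
repetitions with a Kolmogorov–Smirnov test, using an elevated
orientation rate (5%) so batch error counts are large enough for the
F-approximation to hold.

Contaminant counts in a stream are binomial draws at the configured
doses, so realised stream sizes vary around the configured value; mass
conservation (accept + reject = stream) is asserted per realised stream.

## Problem sizes

Laboratory datasets use 400 seeds per pair (50/25/25 split ⇒ ~100
validation seeds, so the 99% stopping criterion means at most one
validation error). Sorter runs use 5000 seeds at 5% + 5% contamination,
five replicates per campaign. The planted-band recovery experiment runs
100 seeded replicates round-robin over the six pairs; the zero-FPR check
covers twenty 5000-seed runs across the three legume deployments.

## What passing tests do and do not show

The generator plants exactly the structure the selection is asked to
find: a few contrast-bearing wavelengths, class-independent correlated
fluctuation, multiplicative brightness, and attenuation-dominant
degradation. Real seed spectra differ in ways the generator does not
model: broad correlated absorption differences between classes (not a
handful of isolated features), heteroscedastic and spatially structured
sensor noise, touching seeds, specular highlights, moisture and variety
effects, and sensor-boundary artefacts near 1000 nm. Passing the
recovery and zero-FPR experiments therefore shows that the estimators,
the greedy selection, the threshold policy and the deployment logic are
implemented correctly and behave as designed under the stated
conditions — not that a physical sorter will reach these rates on any
particular product. The published campaign's own numbers come from
undeposited physical lots and are not reproduction targets.

## Known limitations

* The mutual-information estimator is the plug-in on discretised data;
  its positive bias on irrelevant bands is not corrected (the MIQ
  denominator largely cancels it here). Continuous estimators are out
  of scope.
* The MIQ criterion over-penalises strongly correlated informative
  bands; with only one informative band and pure-noise alternatives, an
  exact duplicate of it can outrank the noise. The duplicate-suppression
  guarantee holds in the generator's regime, where other informative
  bands exist.
* No ejector timing, seed kinematics or RGB-geometry grading; the
  sorter model is the spectral decision alone.
* Stone contaminants exist only as an optional flat-spectrum class in
  the generator and are untested beyond construction.
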