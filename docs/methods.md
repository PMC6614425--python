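# Methods

This note records the models implemented in `memcolor`, the assumptions and
parameter choices behind them, what the synthetic data generator does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## Color spaces and white points

All analysis happens in CIE 1976 L\*a\*b\*.  Monitor RGB settings are
linearized with a single per-channel exponent (default γ = 2.2 — the
calibration model is a power law, not a lookup table; the exponent is
configurable) and mapped to XYZ by the 3×3 primary matrix.  The default
calibration uses Rec.709-class primary chromaticities with primary
luminances solved so that full drive reproduces the monitor white,
XYZ = (87.4, 100, 57.7), exactly.

Two reference whites coexist and are never conflated:

* **monitor white** (87.4, 100, 57.7) — converts matches;
* **scene white** (27.9446, 25.0000, 10.5134), a white card under the
  room's broad-band illuminant — converts spectroradiometric measurements.

No chromatic-adaptation transform (von Kries, CAT02) is applied anywhere:
adaptation models are unreliable for strongly non-neutral illuminants, and
the analysis is designed to work in the space in which matches were made.

A deliberate design choice follows from that: **the hue-estimation
regression is fit with both sides in monitor-white L\*a\*b\***.  The
measured XYZ are rescaled to the monitor luminance scale (preserving Y/Yn —
relative colorimetry; spectroradiometric and monitor units are otherwise
incommensurate) and converted with the monitor white before entering the
model as predictors.  Comparing a hue angle computed against one white with
a hue angle computed against a different white conflates the white-point
change with the perceptual effect under study; placing predictors and
responses in one space makes the noise-free generative model an exact member
of the regression's function family, which in turn makes parameter-recovery
testing exact.  `measured.csv` still reports scene-white L\*a\*b\*, as a
measurement pipeline would.

Hue is reported in degrees counterclockwise from +a\* (0° red, 90° yellow,
180° green); chroma is the (a\*, b\*) norm.  At C\* = 0 the hue angle is
undefined and is reported as NaN — never silently 0° — and such records are
excluded from circular statistics.  Circular differences are wrapped to
(−180°, 180°].

## Synthetic study generator

The generator emulates the *structure* of the study — its factorial design
and the qualitative effects the analysis is built to detect — not any real
measurement values.  Its defaults define the simulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_participants` | 20 | observers; × 35 stimuli × 2 illuminants = 1400 matches |
| `lightness_hue_slope` | 0.2 °/L\* | darker objects matched subtly redder, lighter subtly yellower |
| `lps_chroma_compression` | 0.6 | matches under LPS under-estimate measured chroma |
| `delta_face` | 30° | greenward hue rotation for 3-D face-context stimuli under LPS |
| `photo_fraction` | 0.4 | fraction of `delta_face` applied to photographs |
| `race_lightness_shift` | ±5 L\* | matches lightened for Caucasian, darkened for African-American skin |
| `participant_sd` | 5° | per-observer hue bias, shared across all of an observer's matches |
| `match_noise_sd` | 12° | i.i.d. hue noise per match |
| `lightness_noise_sd` | 3 L\* | i.i.d. lightness noise per match |
| `lips_variance_inflation` | 3 | hue-noise variance multiplier for lips (a variance effect, not a mean shift) |

Magnitudes were chosen once as plausible for this kind of matching task: the
face effect (30°) sits between the observed face and body residual levels of
such experiments; the noise levels put the SD of a single hue match near
13°, which reproduces 99% CIs of a few degrees at n = 160; the slope is
small enough to be "subtle" yet recoverable.  The greenward shift is
injected as a hue *rotation* in degrees (not an a\* decrement) because the
analysis statistic is in hue-angle units; lips get variance inflation, not a
mean shift.

White-light measured colors sit at category-typical loci — saturated toys
and fruit, low-chroma orange skin whose lightness and chroma depend on race,
redder lips — defined in monitor-white L\*a\*b\* so the whole generative
model stays inside the monitor gamut.  **Under LPS the generator enforces
the physics of monochromatic light: every surface shares the illuminant's
chromaticity and only luminance varies.**  The LPS locus is hue 71°, chroma
27 at L\* = 70, luminance-scaled per stimulus, with only small
measurement-level jitter (0.3° hue, 0.5 chroma).  One consequence is that
Lab chroma shrinks with lightness under LPS; another is that measured hue
varies far less under LPS than under white light.  Gamut clipping of
simulated matches is logged, never silent; with default settings a handful
of the 1400 matches clip in the extreme noise tails.

What the generator does **not** emulate: spectral (per-wavelength)
rendering; inter-reflections and non-ideal LPS emission lines; actor- or
session-level variability beyond the per-stimulus loci; memory effects on
fruit (injected as exactly zero); demand characteristics.  Passing tests
therefore show that the *analysis chain* recovers known structure of the
assumed form — they are not evidence about real observers.

## Hue-estimation regression and residuals

The model estimates matched color from measured color using only stimuli
whose color carries no shape-specific expectation: the two Legos, the toy
phone, and the four masked foreheads.  The ping-pong ball, although
non-diagnostic, is excluded from training because its near-achromatic
matches have unstable hue.  To reconcile circular hue with linear lightness
and chroma, the model is linear in Cartesian coordinates: predictors
(1, a\*, b\*, L\*, C\*), responses matched (a\*, b\*) jointly; predicted
(a\*, b\*) are converted back to a hue angle.  C\* is retained as a
predictor alongside a\* and b\* (it is not a linear function of them), and
one fit is made per illuminant.  The reported fit correlation unwraps
matched hue onto the branch nearest its estimate so red-adjacent hues
(wrapping 360° → 0°) do not corrupt the Pearson r.

**Conditioning.**  Under a monochromatic illuminant the measured a\*, b\*
and C\* are mutually proportional, so the design matrix is intrinsically
near-rank-deficient (effectively a one-dimensional manifold parametrized by
lightness).  Ordinary unregularized least squares then assigns enormous
coefficients to near-null directions and amplifies measurement jitter into
tens of degrees of prediction error.  The fit therefore solves by truncated
SVD with a relative cutoff `rcond = 1e-4`: directions the data do not
populate are dropped and predictions stay on the populated manifold.
Exactly collinear predictors still raise an error.

Residual = circular_diff(matched hue, estimated hue); the sign convention
makes the face effect under LPS positive (greenward).

**Bootstrap.**  Three levels are provided.  (1) The default summary CI
resamples residual records with replacement (percentile bootstrap, 1000
resamples, 99% level) — the simplest reading of a record-level bootstrap and
the one used for the summary tables.  (2) A participant-level (clustered)
resampling mode for the same summaries.  (3) A *full-pipeline* bootstrap
(`pipeline_bootstrap_ci`) that resamples participants and refits the hue
model inside every replicate.  The third exists because the model-fit error
is shared across all records of a category: record resampling cannot see it,
so record-level CIs under-cover for parameter-recovery questions.  Recovery
experiments use the pipeline bootstrap; with the default study conditions
the injected face effect lies inside the 99% pipeline-bootstrap CI in ≈ 97%
of runs, and the white-light face CI contains 0 at a similar rate.

Whether lips and photo records enter the training diagnostics: they do not;
training is exactly the seven stimuli above.

## Hypothesis tests

* χ² on 2×2 tables is Pearson's statistic **without** Yates continuity
  correction — the uncorrected statistic is what reproduces the
  report-table values (8.57, 5.05); the corrected one does not.
* Welch *t* (Welch–Satterthwaite df), paired *t* (one-sample on
  differences), and a two-sided variance-ratio *F* (statistic =
  var(first)/var(second), two-sided p by doubling the smaller tail).
* p-values that underflow double precision are also reported as log10 p.
* Factorial ANOVA is restricted to *balanced* designs with 2-level factors,
  where the ±1 contrast coding makes every effect's sum of squares
  N·(contrast mean)² and Type I/II/III decompositions coincide; unbalanced
  input raises rather than silently approximating.  The face × 3-D contrast
  has unequal numbers of regions per cell, so residuals are first averaged
  to one value per participant × actor × cell, which restores balance.  The
  three-way ANOVA (lighting × skin type × race) uses match-level residuals
  as the error term.

## Representational-similarity analysis

Match RGB → XYZ → LMS via the Hunt–Pointer–Estévez (D65-normalized)
matrix — the transform is config-overridable; any standard fundamentals
preserve the L−M vs S dichotomy being tested — then lm = L/(L+M) and
s = S/(L+M), both invariant to luminance scaling.  Conditions are the five
skin regions, with the non-face regions (masked forehead, neck, hand) split
by actor race; cells average over actors within a condition, giving a
condition × participant matrix per component and illuminant.  The RDM is
the Euclidean distance between condition rows (correlation distance
available via the `rdm_metric` option); MDS is classical Torgerson
eigendecomposition (deterministic, no seed; the sign of each dimension is
fixed by making the largest-magnitude coordinate positive, and dimensions
with non-positive eigenvalues are zeroed); clustering is UPGMA with scipy's
lowest-index tie-breaking.  Lips and photographs do not enter the RSA.

## Health model and efficient-coding observer

Healthy and sick skin are Gaussian densities over a\*, one pair per
lighting.  Under LPS the healthy density is fit by moments from matches to
the masked forehead (skin without face context); the sick density is offset
−5 a\* units (sickness as a redness decrement).  The white-light parameters
(healthy μ = 12, σ = 2.5; sick μ = 7, σ = 3) are **illustrative synthetic
placeholders** in the style of clinical skin-color measurements, not
literature values; every quantitative claim about this module is
property-based, not value-based.  The sickness posterior is plain Bayes with
prior π = 0.5 (π only shifts the curve's midpoint).

The observer encodes the stimulus through the CDF of its prior — internal
coordinates are prior-uniform, so sensory resolution is allocated where
stimuli are common — adds Gaussian internal noise (SD `sigma_int`) in that
space with reflection at the (0, 1) boundaries, and decodes by posterior
mean (L2 loss).  The observer variable is a\* (the axis on which the
health densities live); hue-angle observers are possible by passing a
different prior.

**Noise regime.**  Repulsion versus attraction is regime-dependent: the
encoder resolves a stimulus only while its encoded value is farther from
the boundary than the internal noise, i.e. out to about
Φ⁻¹(`sigma_int`) prior SDs.  Beyond that the posterior collapses onto the
prior tail, the estimate saturates, and the bias turns attractive — this
saturation is intrinsic to posterior-mean decoding with a Gaussian prior
and occurs with or without boundary reflection.  The default
`sigma_int = 0.001` places the saturation boundary near 3.1 prior SDs, so
the bias is repulsive, and grows with the deviation, across the 1–3 SD
prediction errors of interest (quadrature-verified values ≈ 1.7 × 10⁻⁵,
6.9 × 10⁻⁴ and 4.6 × 10⁻² prior SDs at 1, 2 and 3 SDs).  Larger noise
moves the boundary inward: at `sigma_int = 0.05` the model attracts beyond
≈ 1.6 SDs.  Because the 1-SD bias is far below Monte-Carlo resolution at
reasonable sample counts, the package provides both the Monte-Carlo
`bias_curve` (with standard errors) and a deterministic `expected_bias`
quadrature.

**Numerics.**  Decoding substitutes the encoded coordinate u = F(a), which
absorbs the prior into a uniform measure; the posterior over u given a
measurement is then a (reflected) normal restricted to the encoded support,
and E[a|m] = ∫F⁻¹(u) p(m|u) du / ∫p(m|u) du over the measurement's 8σ
window.  This keeps the quadrature well conditioned at small noise, where
the stimulus-space likelihood near the prior mean is far narrower than the
stimulus grid.  Rows within ~24σ of a boundary use a 4×-denser quadrature
because F⁻¹ curves sharply there.  The decoder agrees with a 10×-resolution
refinement to better than 10⁻³ prior SDs everywhere on (0, 1).

## Pipeline determinism and problem sizes

The global seed is expanded through `numpy.random.SeedSequence` into
independent per-stage streams (simulation, bootstrap, observer), so adding
or re-running a stage never perturbs another's draws; two runs with equal
config and seed are byte-identical, which the manifest's per-file SHA-256
hashes make checkable.  The default run uses the full study conditions
(20 participants, 1000 bootstrap resamples, 2000 Monte-Carlo encodings per
observer stimulus) and completes in well under a minute on one CPU.  The
repeated-seed experiments use 40 runs at 400 bootstrap resamples for
recovery coverage and 20 runs for the RSA separation rates — sizes at which
the binomial checks are meaningful while the whole battery stays fast.

## Known limitations

* The regression's truncated-SVD cutoff is a fixed relative threshold; a
  design whose genuine small-variance directions fall below it would be
  over-regularized.  For the monochromatic-illuminant designs this pipeline
  targets, the gap between populated and jitter directions is several
  orders of magnitude, so the cutoff is not delicate.
* Record-level bootstrap CIs on category means do not include model-fit
  uncertainty; use `pipeline_bootstrap_ci` when the question is parameter
  recovery.
* The generator's effect structure is additive in hue angle; real
  memory-color effects may be chroma-dependent.
* The observer model is explanatory, not fitted to matches; its noise level
  is a regime choice, not an estimate.
* Balanced-only ANOVA is a deliberate restriction; unbalanced designs need
  a regression framework outside this package's scope.
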