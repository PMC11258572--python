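# Methods

This note documents the models, conventions and numerical choices behind
`natsc`, and what the synthetic-data experiments do and do not demonstrate.

## Signal model and phantom

The phantom is a nested-ellipsoid head defined in world millimetres:
an outer CSF envelope (subarachnoid rim), a cortical GM shell, a WM core
containing two ellipsoidal ventricles (CSF), and two 11 mm-radius vitreous
spheres outside the brain.  Boundaries are soft: each compartment has a
linear partial-volume ramp of width 2 mm, so fraction maps contain genuine
mixed voxels.  Per voxel, fractions satisfy 0 ≤ f ≤ 1 and
f_GM + f_WM + f_CSF ≤ 1, and the true concentration is the
fraction-weighted sum (defaults GM 35 mM, WM 30 mM, CSF and vitreous
140 mM).  The geometry is deliberately non-anatomical: the estimator only
ever sees fractions and intensities, so nested ellipsoids exercise the
same partial-volume structure as a segmented head.

The acquisition is simulated at image level (no k-space trajectory):

1. convolve the hi-res concentration volume with the PSF kernel;
2. block-average to the 6 mm nominal sodium grid (exact integer factors);
3. scale mM → arbitrary signal units with a fixed gain (10 units/mM), so
   calibration has real work to do;
4. add Rician magnitude noise (Gaussian optional), seeded.

**PSF.** The kernel is the inverse transform of a radially symmetric
k-space weighting exp(−t(k)/T₂) with t(k) linear from 0 at the k-space
centre to the readout duration (default 36.3 ms, a typical 3-hub FLORET
readout; the true value is sequence-dependent and config-exposed) at
k_max, taken as the Nyquist radius of the *nominal* 6 mm resolution.  With
T₂ = 56 ms the weighting at k_max is exp(−0.65) ≈ 0.52.  Two properties
matter:

* as T₂ → ∞ the kernel tends to a discrete delta (no decay, no blur);
* the kernel is heavy-tailed: measured numerically, ~14% of its mass lies
  beyond 11 mm.  This drives the calibration design below.

A Gaussian fallback mode matches the exponential kernel's main-lobe FWHM
(measured on an oversampled rendering) for users who prefer a compact,
non-negative kernel.

**Noise scale.**  Where a noise level is quoted as a percentage it means
σ = level × gain × (volume-weighted mean parenchymal concentration), a
closed-form quantity independent of any simulated image ("parenchymal" =
GM+WM).  At defaults, 5% gives σ ≈ 16.5 signal units ≈ 1.65 mM per voxel.

## Calibration

Signal is mapped to concentration by the unique line through
(noise SD ↦ 0 mM) and (vitreous reference ↦ 140 mM).  The noise SD is the
sample SD (n−1) over a declared 560-voxel background region.  On the
phantom's 32³ sodium grid a 560-pixel in-plane corner block cannot avoid
the head, so the default background is a 10×8×7 corner *box*; the shape is
config-exposed and an in-plane block is appropriate on larger real-data
grids.

**Eye reference.**  Two estimators are provided:

* *plain ROI statistic* (mean or median) over the declared eye voxels —
  the conventional choice on real heads, where the eyes are embedded in
  signal-bearing orbital tissue;
* *partial-volume-corrected reference*: least-squares regression of the
  measured signal on the PSF-blurred eye occupancy, with a pooled
  brain-occupancy column absorbing spill from the nearby head.  Because
  the PSF is heavy-tailed, an isolated synthetic eye's ROI mean is
  depressed by tens of percent (the phantom's eye ROI reads ~60% of the
  pure-eye signal); the corrected estimator recovers the pure-vitreous
  signal to ≪1% and is what the quantitative pipeline uses.

Negative calibrated values are clamped to 0 by default but preserved
behind a flag — the regression below needs unclamped values for unbiased
residuals.

**Known bias.**  Anchoring the background SD to 0 mM subtracts a small
offset from every voxel; at 5% noise this contributes a systematic
≈ −0.8 mM to tissue estimates, and it shrinks linearly with σ.  This is a
property of the two-anchor scheme itself, kept deliberately.

## Partial-volume regression

Tissue fractions are re-gridded to the sodium grid (volume-weighted block
averaging when the grids nest exactly, trilinear resampling otherwise) and
then convolved with the PSF kernel built at the sodium resolution with the
same k_max — this counteracts CSF spill-over by making the model voxels
mix exactly as the image voxels do.  The regrid-then-convolve order was
compared numerically against convolve-then-regrid: noiseless recovery
errors are 0.08 vs 0.008 mM — both negligible, so the simpler order is the
default and both are available.

Over brain voxels (default inclusion rule f_GM+f_WM+f_CSF ≥ 0.5 after
smoothing, which excludes background and eyes), ordinary least squares
solves

  c_v − f_CSF,v·140 = f_GM,v·aTSC_GM + f_WM,v·aTSC_WM.

CSF enters as a fixed 140 mM subtraction by default; a three-unknown mode
estimates it instead (sensitivity analysis).  The solver reports the
voxel count, residual RMS and design condition number, and rejects
rank-deficient designs (condition number > 1e8) — e.g. a single-tissue
image where the two unknowns are not separable.  No weighting is applied;
the estimator is plain OLS.

Measured performance at the default 2 mm phantom (20 seeds): noiseless
|error| ≈ 0.04 mM for both tissues; at 5% Rician noise the median |error|
is ≈ 0.76/0.77 mM (GM/WM), dominated by the calibration zero-anchor bias.
Doubling the ventricle volume moves recovered tissue aTSC by < 2%.

Normalized ventricular volume is (left+right)/eTIV, a dimensionless ratio
(typical control value ≈ 0.01).

## Outcome instruments

* **RPQ**: 16 items scored 0–4; total 0–64; three-factor split
  (somatic 9 / emotional 4 / cognitive 3 items) stored as an editable YAML
  table, with light sensitivity and double vision assigned to the somatic
  factor (their conventional placement).  Items > 1 qualify as
  post-concussive symptoms; qualification affects reporting only, totals
  always sum raw items.
* **BTACT**: subtest z = (raw − norm mean)/norm SD; composite = unweighted
  mean of the six subtest z-scores.  The shipped norms are *synthetic
  placeholders* (the authoritative population norms are not
  redistributable); they preserve the arithmetic, not the interpretation.
* **GOSE**: recovered ⇔ score 8.
* **Rates of change**: signed (late − early)/days-between; an
  absolute-value mode exists behind a flag.  Rates are computed only for
  subjects observed at both visits.

## Nonparametric toolkit

Mid-ranks everywhere.  Exact paths:

* Mann–Whitney U and Wilcoxon signed-rank use complete enumeration
  whenever n₁+n₂ ≤ 20 (resp. n ≤ 20 after dropping zero differences) and
  the data are tie-free; with ties, enumeration conditioned on the
  observed mid-ranks is available behind a flag (used by the battery,
  where integer scores guarantee ties).  Internally the null counts come
  from subset-sum dynamic programming over doubled mid-ranks, which is
  exact in float64 at these sizes; the test suite checks every p-value
  bit-for-bit against independent itertools enumeration.
* Two-sided p-values double the smaller one-sided tail, capped at 1 —
  stated explicitly because conventions differ for asymmetric exact
  distributions.
* Spearman's ρ is the Pearson correlation of mid-ranks; p-values come
  from the full n! permutation distribution for n ≤ 8 and otherwise from
  seeded Monte-Carlo permutation (default 10⁵ draws) with the observed
  permutation counted in numerator and denominator (so p ≥ 1/(B+1) and
  the test is never anti-conservative by construction).
* Wilcoxon drops zero differences (classic treatment, not Pratt).
* Cohen's d uses the pooled SD; patients first, controls second, so a
  patient deficit is negative.
* No multiple-comparison correction anywhere, by design.

Null calibration was measured at 2000 replicates (n = 20 per arm): each
test's rejection rate at α = 0.05 falls within [0.035, 0.065].

## Cohort generator

Defaults encode the study conditions: 27 patients / 21 controls at v1,
20 outcome returnees at v2 (17 with imaging), 15 at v3 (drawn from the v2
returnees; the true attrition mechanism is unknowable from the published
counts), visit times ≈ 22 ± 10 days, 16 ± 3 weeks, 60 ± 7 weeks.  Controls
contribute one visit and carry no GOSE or injury date.

Each patient has two independent latent traits — severity `u` and
recovery speed `r`.  Visit severity = baseline(visit) + u − gain(visit)·r;
RPQ items are Binomial(4, sigmoid(·)) in severity with fixed per-item
offsets, BTACT z-scores decline linearly in severity, GOSE bins severity.
GM/WM aTSC at v1 sit below the control mean by a configured deficit
(default 2.0 and 0.6 control-SDs — producing Cohen's d ≈ −2.0 and −0.6),
with the subject-level deviation mixing −u and independent noise at a
configurable coupling (default 0.5); aTSC then recovers linearly at a
per-day rate (default 0.04 ± 0.04 mM/day for GM, 0.01 ± 0.03 for WM) whose
deviation mixes `r` the same way.  Setting the coupling to 0 makes every
aTSC column independent of every outcome column by construction — the
basis of the null-calibration experiments.  Note that a *fully* null world
also requires the rate SDs at 0: between-subject recovery heterogeneity
inflates the v2 aTSC variance relative to controls, which the
Mann–Whitney test legitimately detects as a distributional difference.

What the generator does *not* emulate: anatomical geometry, regional
heterogeneity of aTSC, instrument floor/ceiling artefacts, non-random
attrition, and measurement error in the outcome instruments beyond their
generative noise.  Passing tests therefore demonstrate correctness of the
estimators and tests under the assumed generative model, not clinical
validity on real data.

## Battery and verdicts

H1/H2 use the signed-rank test on within-subject differences (serial
subjects only); H3 compares patients at v2 with controls (Mann–Whitney,
with Cohen's d); H4–H6 use Spearman correlations plus Mann–Whitney
comparisons over GOSE-defined subgroups ("matched controls" is implemented
as the full control group; the cohort generator owns any matching).
Verdicts: all comparisons significant → supported; some → partially
supported; none → rejected (α = 0.05, two-sided, uncorrected).
Degenerate comparisons (all-zero differences, constant variables, empty
subgroups) are recorded with an explanatory note and excluded from the
verdict count.

## Problem sizes and runtime choices

The default phantom is 96³ at 2 mm (sodium grid 32³); the end-to-end demo
uses 3 mm (64³) so that ~65 imaging sessions, scoring and the battery
complete in seconds — at 3 mm the noiseless recovery error grows to
≈ 0.5 mM, which is why accuracy claims are made at 2 mm.  The end-to-end
pipeline exploits linearity of blur + downsampling: the four compartment
basis images are blurred once and each subject's noiseless image is their
concentration-weighted sum, which is exactly equivalent to the full
forward model.  Replicated experiments (null calibration, power) pass
smaller Monte-Carlo permutation counts to the Spearman test; this is a
runtime choice that does not alter defaults, and permutation tests remain
valid at any resample count.

## Limitations

* Real k-space sampling, B₀/B₁ effects, relaxation weighting beyond the
  PSF model, and reconstruction artefacts are out of scope; the phantom
  starts at the image level.
* The calibration zero-anchor bias (≈ −0.05 mM per 1 mM of per-voxel noise
  SD) is inherent to the two-anchor scheme and not corrected.
* The plain eye-ROI reference is unusable on an isolated synthetic eye
  (heavy PSF tails); real acquisitions with tissue around the orbit are
  less affected, but users quantifying phantoms must use the
  partial-volume-corrected reference.
* BTACT norms are placeholders; scored composites are comparable within a
  synthetic cohort only.
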