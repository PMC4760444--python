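# Methods

This note documents the models implemented in `cvrpipe`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical decisions a maintainer would want written down.

## Signal model and GLM

The pipeline assumes the BOLD signal responds linearly to the end-tidal
CO₂ excursion over the protocol's ±10/−5/+15 mmHg range:

    S(v, t) = S₀(v) · (1 + CVR(v)/100 · ΔpetCO₂(t − δ(v))) + drift + ε,

with CVR in % per mmHg and δ a circulatory/sampling delay. A single
linear petCO₂ regressor spans all five steps; no per-step or sigmoidal
reactivity model is fitted (the linearity of the BOLD–petCO₂ relation
over this range is the model's premise, and it is what the z map tests).

Fitting is ordinary least squares per voxel with an intercept, the
mean-centred delay-corrected petCO₂ regressor, and a mean-centred SpO₂
nuisance computed from the delay-corrected petO₂ via the classic
single-equation Severinghaus form S = (23400/(P³+150P)+1)⁻¹. When the
petO₂ clamp makes SpO₂ constant, the nuisance column is dropped (the
intercept already spans it). No prewhitening is applied: the quantity of
interest is the beta (the CVR magnitude), and on the phantoms the noise
is white by construction; an autocorrelation-consistent variance would
change only real-data z values, not the CVR maps.

**Percent normalization.** CVR = 100·β/S̄ uses the voxel's temporal mean
S̄ as baseline. With the default protocol the mean excursion is 15/7 mmHg,
so S̄ sits about 0.6% of CVR above the true zero-excursion baseline —
a relative bias of ~0.6% of the CVR value (≤ 0.002 %·mmHg⁻¹ at cortical
reactivity levels), far below measurement noise. The temporal mean was
preferred over an extrapolated zero-excursion intercept because it is
robust to regressor misalignment and to drift in the first volumes.

## Preprocessing

- **Spatial smoothing**: Gaussian, FWHM 6 mm by default, σ = FWHM/√(8 ln 2)
  per axis in voxel units, renormalized inside the brain mask so edge
  voxels are not diluted by out-of-mask zeros.
- **Temporal high-pass**: a Gaussian-weighted running straight-line fit is
  subtracted and the voxel mean restored. Default σ = 50 s; values below
  2·TR are refused without an explicit override, since they fit noise.
  The *same* trend operator is applied to the design-matrix regressors and
  to every candidate lag during alignment — filtering the data alone would
  attenuate the beta and bias the lag search (both effects were observed
  and are covered by tests).
- **Delay correction**: the end-tidal series is shifted by the integer
  volume lag (0 … max_lag, default 20 s) that maximizes Pearson
  correlation with the whole-brain mean signal, ties to the smallest lag.
  Only non-negative lags are searched because the BOLD response trails the
  stimulus. The recovered lag is the *combined* sample + circulation
  delay: breath-quantization of the regressor (a detected onset falls just
  after the true zero crossing) can shift it by one breath relative to
  the physiological delay, which is exactly what the correction absorbs.
- Motion correction, slice timing and registration are identity no-op
  hooks: phantoms are motion-free and share one grid.

## Multiple comparisons

Residual smoothness is estimated from the lag-1 spatial autocorrelation ρ
of the standardized GLM residuals along each axis,
FWHM = √(4 ln 2 / (−2 ln ρ)), floored at one voxel; the resel count is
V/∏FWHM. Two thresholding rules are provided:

- `grf` (default): solve resels · ρ₃(z) = α for the 3-D Euler-
  characteristic density ρ₃(z) = (4 ln 2)^{3/2}(2π)⁻²(z²−1)e^{−z²/2}
  (doubled for two-sided tests), then cap at the voxelwise Bonferroni
  threshold (always a valid bound, and the sharper one for barely-smooth
  fields) and floor at the single-comparison quantile.
- `resel_bonferroni`: treat the resels as independent samples and solve
  resels · P(|Z| > z*) = α.

The default is `grf` because treating resels as independent tests is
markedly anticonservative for smooth fields: the expected number of
suprathreshold excursions exceeds the per-resel tail probability by a
factor ≈ 0.29·z(z²−1) (about 18× near z = 4). Simulation with smoothed
white noise (FWHM 2–4 voxels, 20³ grids, 200 replicates) gives a
family-wise error of 0.25–0.37 for the resel-Bonferroni rule versus
0.015–0.03 for the expected-EC rule; the packaged null-phantom check
(50 seeded runs through the full pipeline) reproduces the controlled
rate. Two-sided thresholding is the default because negative reactivity
is a first-class finding, not an artifact to ignore.

## Regional analysis

Tissue-level CVR is extracted from gray/white masks eroded by one voxel
(configurable). With 6 mm smoothing on 3 mm voxels, interface voxels mix
gray, white and CSF signal; on the default phantom the full-mask
gray:white ratio reads ≈1.79 for a true 2.0 while the eroded-mask ratio
reads ≈1.95. Partial-volume-avoiding erosion is the standard convention
for tissue-level CVR and is applied symmetrically at both sessions.

Dichotomization keeps, per structure, the baseline-significant voxels
with CVR > 0 and CVR < 0 as two frozen masks (CVR exactly 0 — a
measure-zero event under noise — belongs to neither). The same masks are
reapplied at follow-up, so a compartment's change is measured on fixed
tissue. Structures with an empty compartment at baseline are excluded
listwise from the 2×2 ANOVA. Fractional CVR distributions use 0.025
%·mmHg⁻¹ bins over [−1, 1], with out-of-range voxels clipped into the end
bins so fractions always sum to one.

## Volumetry

Segmentation is a three-class Gaussian mixture on the masked intensities,
classes identified by ascending mean (CSF < GM < WM for T1-like
contrast), partial volumes = posterior probabilities. Component means are
initialized at the 10th/50th/90th percentiles for determinism, and the
covariance is **tied** across classes: with equal variances the posterior
decision boundaries sit at the class-mean midpoints, so the linear
partial-volume ramps at tissue interfaces integrate to (nearly) their
true volumes — with free variances the broadest class annexes the
interface voxels and tissue volumes shift by several percent. On the
default structural phantom with 1% intensity noise, recovered tissue
volumes are within 0.3% of truth.

PBVC follows the edge-displacement principle: the brain/nonbrain edge of
the baseline image is triangulated (marching cubes at the half level
between the CSF and GM class means — sub-voxel accurate and with unbiased
mesh surface area, unlike boundary-voxel counting, which overestimates a
sphere's area by ≈1.5×); at each triangle centroid the intensity profile
along the outward normal is sampled in both volumes and the half-level
crossing located by linear interpolation; then

    PBVC = 100 · Σᵢ dᵢ aᵢ / V,

the area-weighted perpendicular displacement over the surface. On a 60 mm
sphere eroded by 1.5 mm this recovers −7.5% against the analytic −7.31%
(the residual is the first-order flat-surface approximation versus the
exact curved-shell volume), is antisymmetric under swapping the time
points within 5%, and reads ≈0 for a pure translation. Lesions are
counted as 26-connected components above 5 mm³.

## Group statistics

The 2×2 repeated-measures ANOVA (session × hemisphere, or session ×
compartment sign) is computed from within-subject sums of squares; each
effect is tested against its own effect-by-subject interaction with
(1, n−1) degrees of freedom, verified against an independent
repeated-measures implementation on randomized instances. Tukey's HSD
compares the four cell means using the highest-order interaction mean
square and the studentized-range distribution with n−1 error df (the
error term is a genuine choice in a repeated-measures context; the
highest-order term is the conservative one matching the interaction
test). All p values are two-sided. Skewed lesion counts are summarized as
median ± IQR with inclusive (Tukey-hinge) quartiles, under which the
example cohort's counts give pre 3 ± 2 and post 4 ± 5.

## What the phantoms do and do not emulate

The generators impose: the stepped protocol with square expired plateaus
(only the end-tidal value matters downstream); prescribed ventilation
with no chemoreflex feedback; a pure 6 s delay as the default
hemodynamic/sampling lag (no dispersed response function); white Gaussian
noise at 1% of the gray-matter baseline signal; optional linear drift;
gray reactivity twice white (0.30 vs 0.15 %·mmHg⁻¹) with scattered
negative foci at −0.20; and, structurally, spherical geometry with
analytic signed distances so imposed atrophy is sub-voxel exact (default
gray/white volumes ≈ 668/615 mL). Negative foci default to 9 mm radius:
foci at or below the 6 mm smoothing kernel are physically unrecoverable
by any method, and focal steal regions of interest are of this larger
scale.

Passing tests on these phantoms therefore demonstrates correct recovery
under the stated linear model — they do not probe motion, spin-history or
physiological noise, dispersed hemodynamic responses, registration error,
field distortions, or non-spherical anatomy. Real-data use would add
motion correction and registration in the provided hook points.

## Numerical details and degenerate inputs

- All generators are reproducible from integer seeds; fixed seed ⇒
  bit-identical outputs.
- z values are clipped at ±38 (beyond double-precision tail resolution);
  zero-residual-variance voxels receive the clipped value with a log
  note; voxels with non-positive baseline are removed from the analysis
  mask rather than producing infinities.
- Cross-correlation ties break toward the smallest lag; constant inputs
  raise rather than return an arbitrary lag.
- Breaths with no expiratory samples are excluded and flagged; traces
  with constant flow raise "no breaths detected".
- Edge profiles without a clean inside-to-outside crossing are dropped
  and counted; the crossing interpolation is clamped to its bracketing
  interval.
- The paired t test with zero-variance nonzero differences reports an
  infinite statistic with a `degenerate` flag instead of dividing by zero.
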