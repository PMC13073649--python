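# Methods

This note documents the models, conventions, and numerical choices behind
`petstab`, and what the synthetic experiments can and cannot say about
real clinical data.

## Image model and conventions

Volumes are 3-D SUV grids with axis order (x, y, z), z cranio-caudal,
0-based voxel indices and the voxel-center mapping
`coord = origin + index · spacing` (mm). SUV is activity concentration
(kBq/mL) divided by injected activity per body weight (kBq/g); inputs are
assumed decay-corrected. Values are finite and non-negative; spacing is
strictly positive. The default grid spacing, 2.73 × 2.73 × 2.79 mm,
matches a modern digital PET reconstruction matrix.

Isotropic resampling (default 2 × 2 × 2 mm³) uses cubic B-spline
interpolation, output grid anchored at the input origin and sized to cover
the input field of view; out-of-support samples use nearest-edge
extension and negative interpolation overshoot is clamped to zero.
Cubic prefiltering has edge effects that decay geometrically away from
the support boundary, which is why identity/affine reproduction is only
exact in the interior. Masks are never interpolated: VOIs on resampled
images are regenerated by re-running segmentation, so each imaging
condition gets an independent delineation.

## Lesion phantoms

A phantom is an ellipsoidal (optionally lobulated) lesion of uptake
`lesion_suv` on a low background (default 0.5 SUV), with three intensity
components:

- an eccentric **Gaussian hotspot** (offset, width, peak increment) that
  defines a ground-truth hotspot displacement;
- **spatially correlated heterogeneity**: a Gaussian-filtered random
  field (correlation length `texture_corr_mm`, default 8 mm) scaled by
  `texture_sd` and added inside the lesion. Without this component all
  lesions of a batch would have nearly identical entropy and texture,
  which removes the between-lesion variance that reliability statistics
  measure; real tumors are heterogeneous at exactly this scale;
- **PSF smoothing**: an isotropic Gaussian (FWHM `psf_fwhm_mm`; the study
  batch uses 5 mm, typical of current scanners) applied to the composed
  image, emulating reconstruction resolution;
- i.i.d. **Gaussian noise** in SUV, clamped at zero — a post-
  reconstruction, image-space approximation rather than Poisson counting
  noise.

All randomness is driven by the spec's integer seed; a fixed seed gives
bit-identical phantoms.

## Respiratory motion and gating

Motion is a rigid cranio-caudal translation
`z(u) = A · cos(πu)^{2p}` over cycle phase `u ∈ [0, 1)`, with
peak-to-peak amplitude `A`, exponent `p = 2` (end-expiration dwell:
the lesion spends most of the cycle near z = 0), period 4 s, and 40
frames per cycle. The **non-gated** image is the mean of all frames,
each a cubic-B-spline translation of the static phantom; the **gated**
image averages only frames whose phase falls in
`[offset, offset + window)`, default offset 0.30 and window 0.50 — the
default quiescent-window settings of commercial data-driven gating. With
these defaults the mean displacement of the retained frames is a fraction
of a voxel, so the gated image closely approximates the static one while
the non-gated image is visibly smeared (the mean displacement over the
full cycle is 3A/8).

Fidelity limits: real respiratory motion includes elastic deformation,
hysteresis and cycle-to-cycle variability; gated reconstructions use
fewer counts and are noisier than non-gated ones. None of these are
modeled — both conditions receive independent noise of equal sd — so the
synthetic experiment isolates *blur-induced* feature instability only.

## Segmentation

VOIs are produced by thresholding at 40% of the SUVmax inside a seed box
(threshold inclusive, ≥), reduced to the 26-connected component
containing the max voxel. Segmentation is idempotent and anti-monotone in
the threshold fraction. Lesions with fewer than 64 voxels are excluded
from analysis; survival analyses keep only the largest-MTV lesion per
patient (ties to the lowest lesion index).

## Hotspot-displacement features

`r_eq = (3·MTV/4π)^{1/3}` normalizes both distances; it is the only
normalizer under which the continuous ball identity NHOC + NHOP = 1
holds, and is adopted as the definition.

- **NHOC**: Euclidean distance from the hotspot to the unweighted
  centroid of the VOI voxel centers, over `r_eq`.
- **NHOP**: exhaustive minimum distance from the hotspot to the exposed
  voxel-face centers of the VOI (faces between a foreground voxel and an
  in-grid background neighbor), over `r_eq`. Face centers — not
  boundary-voxel centers — are used because voxel centers sit half a
  voxel inside the true surface, which biases the ball identity low
  (measured 0.92 at the center of a radius-12 ball, vs 0.97–1.06 across
  interior hotspots with face centers). The set of face centers is still
  finite and exactly enumerable, so the brute-force oracle tests remain
  exact.
- **SUVmax hotspot**: arg-max voxel over the VOI, ties broken by lowest
  (z, y, x) index.
- **SUVpeak hotspot**: the 1 mL sphere (radius ≈ 6.2035 mm) whose mean
  SUV over all grid voxels is maximal, centered on a VOI voxel (the
  default "search" mode; a "max" mode centers it on the SUVmax voxel
  instead). Search mode makes the peak hotspot genuinely distinct from
  the max hotspot, which is why NHOCpeak ≠ NHOCmax in general. Lesions
  under 1 mL return missing values (never zeros) for all peak-based
  features; a sphere that would extend past the image grid raises an
  error naming the clipped axis.

## Reference texture features

Gray levels use fixed-bin-width discretization,
`level = floor(SUV / 0.25) + 1`, anchored at absolute 0 SUV. Texture
matrices are 3-D with the 13 unique distance-1 directions, counts merged
over directions before normalization (the common single-number
aggregation), and the gray-level axis restricted to the occupied range
(min..max occupied level), which makes all matrix features invariant
under constant SUV shifts of whole bins. All entropies are log-base-2.

- first-order entropy of the occupied-level histogram;
- GLCM joint entropy, sum entropy, IDN `Σ p(i,j)/(1+|i−j|/N_g)` and
  IDMN `Σ p(i,j)/(1+(i−j)²/N_g²)` with `N_g` the occupied-range size;
- GLRLM run entropy of the direction-merged run-length matrix;
- sphericity `(36π V²)^{1/3}/A` with `A` the total exposed voxel-face
  area. Face-area surfaces make the digital cube exactly
  `(36π)^{1/3}/6 ≈ 0.8060`, but overestimate smooth surfaces: the
  exposed-face area of a ball converges to `6πR²` (twice the projected
  disc area per axis), so digitized-sphere sphericity converges to 2/3
  rather than 1. Absolute values are therefore not comparable to
  mesh-based sphericity; paired gated/non-gated comparisons, which is all
  this package uses them for, are unaffected. A mesh-based surface is a
  possible extension.

Reported IDN/IDMN are stored unscaled; report code may multiply by 1000
for display.

## Stability statistics

Per lesion and feature, the paired CoV is `100·sd(a,b)/mean(a,b)` with
the sample (n−1) sd, i.e. `100·|a−b|/(√2·mean)`; per-feature CoV is the
arithmetic mean of per-lesion CoVs (median available). ICC(2,1) —
single-measure, two-way random effects, absolute agreement — comes from
the ANOVA decomposition `(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)`
with the McGraw–Wong F-based 95% CI. Identical columns define ICC = 1;
negative estimates are reported as computed and classify as "poor".
Benchmarks: CoV < 5 / ≤ 10 / ≤ 20 / > 20 % → excellent / good / moderate
/ poor; ICC > 0.90 / ≥ 0.75 / ≥ 0.50 / < 0.50 → excellent / good /
moderate / poor (boundary values to the band whose printed range includes
them). Lesions missing a feature (sub-mL peak features) drop out of that
feature's analysis only. Reports cover the full batch and MTV < 3 mL vs
≥ 3 mL strata.

## Survival statistics

The cohort generator draws feature vectors (standard normal by default),
event times exponential with rate `λ₀·exp(βᵀx)` and censoring times
exponential with rate `λ_c`. Defaults `λ₀ = ln 2 / 45.4` per month and
`λ_c = 0.015` per month emulate a cohort with median survival ≈ 45 months
and roughly half the patients reaching the event.

Cox models maximize the partial likelihood with the Breslow convention
for tied event times (statsmodels `PHReg` behind the module surface);
hazard ratios carry Wald 95% CIs and p-values, and a monotone likelihood
(perfect separation) is flagged as non-convergence rather than raised.
Exactly collinear designs are rejected with the offending columns named.
Harrell's c-index counts pairs whose shorter observed time is an event
(tied-time event/censored pairs count, tied-time event/event pairs do
not), credits tied risks 0.5, and is invariant under strictly increasing
transforms of the risk score. The bootstrap c-index comparison resamples
patients with replacement (default 1000 replicates), computes both
c-indices per resample, takes the 2.5/97.5 percentile CI of the
difference, and inverts the percentile position of zero for a two-sided
p; degenerate resamples are redrawn and counted. M_eff is the number of
connected components of the feature graph joining |r| ≥ 0.8 pairs
(pairwise-complete Pearson), and the Bonferroni threshold is
`α / M_eff` — with the four entropy features mutually collinear and the
IDN/IDMN pair among 12 features this gives M_eff = 8 and α = 0.00625.
The 0.8 threshold is a configurable choice.

## The synthetic stability study

`simulate_stability_study` draws a batch (default 60 lesions) from a
population with radii 8–18 mm (spheres and mildly anisotropic
ellipsoids, lobulation up to 0.12), lesion SUV 3–10, hotspot offsets
0.3–0.7 of the minor axis in random directions, hotspot increments
0.3–0.8 of the lesion SUV, heterogeneity sd 10–25% of lesion SUV, PSF
5 mm, on 32 × 32 × 40 grids at scanner spacing. Each lesion is imaged
gated and non-gated (15 mm amplitude by default), receives independent
0.2 SUV noise per condition, and is segmented and featurized
independently per condition. This problem size keeps the full experiment
around a minute while leaving ≈60 analyzable lesions.

What passing shows: under pure rigid-translation blur, entropy-family
features remain reproducible (CoV < 5%, good-to-excellent ICC) while
hotspot-displacement features degrade strongly (CoV ≫ 10%, poor-to-
moderate ICC) — the direction reported for patient data. What it does not
show: magnitudes comparable to any particular clinical cohort (motion
amplitudes, lesion populations and scanner chains differ), behavior under
non-rigid deformation, or count-statistics effects of gating.

## Degenerate inputs and tie-breaks

Empty masks, zero-signal seed regions, sub-3-subject ICC tables,
no-comparable-pair c-indices and empty gating windows raise errors;
sub-mL SUVpeak returns missing, not an error. Arg-max ties (SUVmax,
SUVpeak search) resolve to the lowest (z, y, x) index; largest-lesion
ties to the lowest lesion index. GLCM/GLRLM probability matrices must sum
to 1 within 1e-9.
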