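# petstab

Respiratory-motion stability and prognostic analysis of PET
hotspot-displacement radiomic features, on digital lesion phantoms with
known ground truth.

## The problem

Thoracic ¹⁸F-FDG PET lesions move with breathing. Because a PET bed
position integrates minutes of emission data, respiratory motion blurs
tumor boundaries and smears the uptake distribution, which can silently
change radiomic features. A recently proposed family of *hotspot
displacement* features quantifies where the metabolic hotspot sits inside
the lesion:

- **NHOC** — normalized hotspot-to-centroid distance:
  `NHOC = ‖x_hot − x_centroid‖ / r_eq`
- **NHOP** — normalized hotspot-to-perimeter distance:
  `NHOP = min_{s ∈ surface} ‖x_hot − s‖ / r_eq`

with `r_eq = (3·MTV / 4π)^{1/3}` the lesion's equivalent-sphere radius, so
that on an ideal ball `NHOC + NHOP = 1` for any interior hotspot. The
hotspot is located either by the hottest voxel (SUVmax) or by the SUVpeak
sphere (mean SUV in a 1 mL sphere), giving NHOCmax/NHOCpeak and
NHOPmax/NHOPpeak. This package asks: are these features reproducible
between respiratory-gated (quiescent-window) and non-gated acquisitions,
and do they carry prognostic value — compared with reference features
(sphericity, first-order entropy, GLCM joint/sum entropy, IDN, IDMN, GLRLM
run entropy) that are known to be robust to motion?

Clinical scans are not required: a phantom module generates lesions of
configurable shape with eccentric Gaussian hotspots, spatially correlated
intra-tumoral heterogeneity, scanner-like PSF smoothing and noise, then
emulates a breathing acquisition by averaging rigid cranio-caudal
displacements over the respiratory cycle (non-gated analog) or over a
quiescent phase window (gated analog, default offset 30%, window 50% of
the cycle). A companion generator simulates survival cohorts whose hazard
depends on known feature coefficients.

## What the pipeline does

1. **Image model** (`image_core`) — SUV volumes with physical geometry,
   NIfTI I/O, SUV normalization (activity / (injected activity / body
   weight)), MTV, and isotropic 2×2×2 mm³ cubic-B-spline resampling.
2. **Segmentation** (`segmentation`) — 40%-of-SUVmax threshold VOIs
   (26-connected component containing the max voxel), the ≥64-voxel
   inclusion rule, and largest-lesion-per-patient selection. VOIs are
   segmented independently per condition; masks are never interpolated.
3. **Features** (`hotspot`, `texture`) — SUVmax/SUVpeak localization,
   NHOC/NHOP, and the seven reference features on a fixed-bin-width
   (0.25 SUV) discretization with 13-direction merged texture matrices.
4. **Stability statistics** (`stability`) — per-lesion paired CoV
   (`100·|a−b| / (√2·mean)`, averaged per feature), ICC(2,1) (two-way
   random effects, absolute agreement) with F-based 95% CI, benchmark
   bands, and MTV < 3 mL vs ≥ 3 mL stratification.
5. **Survival statistics** (`survival`) — univariable/multivariable Cox
   (Breslow ties), Harrell's c-index, bootstrap CIs for c-index
   differences (1000 resamples), feature correlation, and the
   effective-number-of-tests Bonferroni correction (M_eff = number of
   collinear-cluster components at |r| ≥ 0.8).

## Worked example

One lesion phantom (eccentric hotspot 8 mm off-center along the breathing
axis), 15 mm cranio-caudal motion, gated vs non-gated imaging, independent
segmentation and feature extraction:

```python
import numpy as np
from petstab import (PhantomSpec, MotionModel, GatingSpec, SeedRegion,
                     generate_static_phantom, simulate_gating_pair, add_noise,
                     threshold_segment, extract_features)

spec = PhantomSpec(hotspot_offset_mm=(0.0, 0.0, 8.0), texture_sd=0.8,
                   psf_fwhm_mm=5.0, seed=7)
static, truth = generate_static_phantom(spec)
gated, nongated = simulate_gating_pair(static, MotionModel(amplitude_mm=15.0),
                                       GatingSpec(0.30, 0.50))
gated = add_noise(gated, 0.2, seed=8)
nongated = add_noise(nongated, 0.2, seed=9)

for name, img in (("gated", gated), ("nongated", nongated)):
    voi = threshold_segment(img, SeedRegion.whole_grid(img.shape), fraction=0.40)
    feats = extract_features(img, voi)
    print(name, {k: round(v, 3) for k, v in feats.items()
                 if k in ("suv_max", "mtv_ml", "nhoc_max", "nhop_max",
                          "entropy", "sphericity")})
```

prints

```
gated    {'suv_max': 7.5,   'mtv_ml': 6.841, 'nhoc_max': 0.482, 'nhop_max': 0.424, 'sphericity': 0.655, 'entropy': 4.079}
nongated {'suv_max': 7.016, 'mtv_ml': 6.945, 'nhoc_max': 0.181, 'nhop_max': 0.664, 'sphericity': 0.646, 'entropy': 3.824}
```

Motion blur pulls the apparent hotspot toward the lesion centroid: NHOCmax
collapses from 0.48 to 0.18 between the gated and non-gated image of the
*same* lesion, while entropy (4.08 → 3.82, ~3% paired CoV) and sphericity
barely move. Run `simulate_stability_study(n_lesions=60, ...)` followed by
`stability_report(...)` to see the cohort-level version: entropy-family
features come out with CoV < 5% and good-to-excellent ICC, while the
hotspot-displacement family shows CoV > 20% and poor-to-moderate ICC.

A thin CLI mirrors the stages: `petstab simulate`, `petstab segment`,
`petstab resample`, `petstab cohort`, `petstab stability`,
`petstab survival` (see `--help`).

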