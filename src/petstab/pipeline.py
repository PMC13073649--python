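"""End-to-end feature extraction and the phantom motion-stability study.

``extract_features`` computes the full per-lesion feature record (SUVmax,
SUVpeak, MTV, the four hotspot-displacement features, sphericity, and the
six texture features) from a volume and VOI. ``simulate_stability_study``
runs the whole synthetic experiment: a batch of lesion phantoms with
eccentric hotspots is blurred by respiratory motion, imaged under a
quiescent-window gated analog and a non-gated (cycle-averaged) analog,
segmented independently per condition, and scored feature by feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hotspot import compute_hotspot_features
from .image_core import LesionMask, PetVolume, resample_bspline
from .phantom import (
    GatingSpec,
    MotionModel,
    PhantomSpec,
    add_noise,
    generate_static_phantom,
    simulate_gating_pair,
)
from .segmentation import SeedRegion, passes_inclusion, threshold_segment
from .texture import (
    DEFAULT_BIN_WIDTH,
    discretize_fbw,
    first_order_entropy,
    glcm,
    glcm_features,
    glrlm_run_entropy,
    sphericity,
)

__all__ = [
    "FEATURE_COLUMNS",
    "extract_features",
    "features_long_to_paired",
    "simulate_stability_study",
]

#: the eleven study features plus SUVmax, in report order
FEATURE_COLUMNS = [
    "suv_max",
    "suv_peak",
    "mtv_ml",
    "nhoc_max",
    "nhoc_peak",
    "nhop_max",
    "nhop_peak",
    "sphericity",
    "entropy",
    "joint_entropy",
    "sum_entropy",
    "run_entropy",
    "idn",
    "idmn",
]


def extract_features(
    volume: PetVolume,
    mask: LesionMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
    peak_mode: str = "search",
) -> dict[str, float]:
    """Full feature record for one lesion VOI (missing values as NaN)."""
    hot = compute_hotspot_features(volume, mask, peak_mode=peak_mode)
    disc = discretize_fbw(volume, mask, bin_width=bin_width)
    tex = glcm_features(glcm(disc))
    nan = float("nan")
    return {
        "suv_max": hot.suv_max,
        "suv_peak": hot.suv_peak if hot.suv_peak is not None else nan,
        "mtv_ml": hot.mtv_ml,
        "nhoc_max": hot.nhoc_max,
        "nhoc_peak": hot.nhoc_peak if hot.nhoc_peak is not None else nan,
        "nhop_max": hot.nhop_max,
        "nhop_peak": hot.nhop_peak if hot.nhop_peak is not None else nan,
        "sphericity": sphericity(mask),
        "entropy": first_order_entropy(disc),
        "joint_entropy": tex["joint_entropy"],
        "sum_entropy": tex["sum_entropy"],
        "run_entropy": glrlm_run_entropy(disc),
        "idn": tex["idn"],
        "idmn": tex["idmn"],
    }


def features_long_to_paired(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long feature table (lesion_id, condition, features...) into
    the wide paired layout used by the stability report.

    The stratification MTV is the gated (motion-corrected) lesion volume.
    """
    required = {"lesion_id", "condition"}
    if not required.issubset(long.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    feats = [c for c in FEATURE_COLUMNS if c in long.columns]
    wide = long.pivot(index="lesion_id", columns="condition", values=feats)
    out = pd.DataFrame(index=wide.index)
    for f in feats:
        for cond in ("gated", "nongated"):
            out[f"{f}_{cond}"] = wide[(f, cond)]
    out["mtv_ml"] = wide[("mtv_ml", "gated")]
    return out.reset_index()


def _random_phantom_spec(rng: np.random.Generator, seed: int) -> PhantomSpec:
    """One lesion drawn from the study's phantom population: variable size
    and shape, moderate lobulation, and an eccentric hotspot."""
    radius = float(rng.uniform(8.0, 18.0))
    if rng.random() < 0.5:
        semi_axes = tuple(radius * rng.uniform(0.8, 1.2) for _ in range(3))
        lesion_geom = {"radius_mm": None, "semi_axes_mm": semi_axes}
        min_axis = min(semi_axes)
    else:
        lesion_geom = {"radius_mm": radius, "semi_axes_mm": None}
        min_axis = radius
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    offset = direction * rng.uniform(0.3, 0.7) * min_axis
    lesion_suv = float(rng.uniform(3.0, 10.0))
    return PhantomSpec(
        shape=(32, 32, 40),
        spacing=(2.73, 2.73, 2.79),
        background_suv=0.5,
        lesion_suv=lesion_suv,
        lobulation_amplitude=float(rng.uniform(0.0, 0.12)),
        hotspot_offset_mm=tuple(float(v) for v in offset),
        hotspot_width_mm=float(rng.uniform(4.0, 8.0)),
        hotspot_peak_suv=float(rng.uniform(0.3, 0.8)) * lesion_suv,
        texture_sd=float(rng.uniform(0.10, 0.25)) * lesion_suv,
        texture_corr_mm=float(rng.uniform(6.0, 12.0)),
        psf_fwhm_mm=5.0,
        seed=seed,
        **lesion_geom,
    )


def simulate_stability_study(
    n_lesions: int = 60,
    amplitude_mm: float = 15.0,
    noise_sd: float = 0.2,
    gating: GatingSpec = GatingSpec(),
    motion_kwargs: dict | None = None,
    resample: bool = False,
    seed: int = 0,
    segmentation_fraction: float = 0.40,
) -> pd.DataFrame:
    """Run the synthetic gated-vs-non-gated stability experiment.

    Returns a long feature table with one row per lesion x condition
    (x resampling arm when ``resample=True``): columns lesion_id,
    patient_id, condition in {gated, nongated}, resampled in {0, 1}, and
    the feature columns. Lesions whose VOI fails the 64-voxel inclusion
    rule in either condition are dropped.
    """
    rng = np.random.default_rng(seed)
    motion = MotionModel(amplitude_mm=amplitude_mm, **(motion_kwargs or {}))
    rows = []
    for i in range(n_lesions):
        lesion_seed = int(rng.integers(0, 2**31 - 1))
        spec = _random_phantom_spec(rng, seed=lesion_seed)
        static, _truth = generate_static_phantom(spec)
        gated, nongated = simulate_gating_pair(static, motion, gating)
        images = {
            "gated": add_noise(gated, noise_sd, seed=lesion_seed + 1),
            "nongated": add_noise(nongated, noise_sd, seed=lesion_seed + 2),
        }
        arms: list[tuple[int, dict[str, PetVolume]]] = [(0, images)]
        if resample:
            arms.append(
                (1, {c: resample_bspline(v) for c, v in images.items()})
            )
        lesion_rows = []
        ok = True
        for resampled, arm_images in arms:
            for condition, image in arm_images.items():
                voi = threshold_segment(
                    image,
                    SeedRegion.whole_grid(image.shape),
                    fraction=segmentation_fraction,
                )
                if not passes_inclusion(voi):
                    ok = False
                    break
                lesion_rows.append(
                    {
                        "lesion_id": f"L{i:03d}",
                        "patient_id": f"P{i:03d}",
                        "condition": condition,
                        "resampled": resampled,
                    }
                    | extract_features(image, voi)
                )
            if not ok:
                break
        if ok:
            rows.extend(lesion_rows)
    return pd.DataFrame(rows)
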