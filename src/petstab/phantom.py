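"""Digital lesion phantoms, respiratory motion/gating emulation, and a
survival-cohort generator with known ground truth.

The phantom emulates what matters for hotspot-displacement feature
stability: a blob-like lesion of configurable shape on a low-uptake
background, an eccentric metabolic hotspot, rigid cranio-caudal breathing
displacement averaged over an acquisition (non-gated analog) versus a
quiescent phase window (gated analog), and additive image-space noise.
Reconstruction physics, attenuation, and list-mode gating signal
extraction are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_core import AXIS_NAMES, LesionMask, PetVolume

__all__ = [
    "PhantomSpec",
    "MotionModel",
    "GatingSpec",
    "SurvivalRecord",
    "generate_static_phantom",
    "simulate_nongated",
    "simulate_gated",
    "add_noise",
    "generate_survival_cohort",
    "cohort_to_frame",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a static lesion phantom.

    The lesion is a sphere (``radius_mm``) or ellipsoid (``semi_axes_mm``),
    optionally lobulated, of uptake ``lesion_suv`` on a ``background_suv``
    background, with a Gaussian metabolic hotspot displaced from the lesion
    center by ``hotspot_offset_mm``.
    """

    shape: tuple[int, int, int] = (32, 32, 40)
    spacing: tuple[float, float, float] = (2.73, 2.73, 2.79)
    background_suv: float = 0.5
    lesion_suv: float = 5.0
    radius_mm: float | None = 12.0
    semi_axes_mm: tuple[float, float, float] | None = None
    lobulation_amplitude: float = 0.0
    hotspot_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hotspot_width_mm: float = 6.0
    hotspot_peak_suv: float = 4.0
    texture_sd: float = 0.0
    texture_corr_mm: float = 8.0
    psf_fwhm_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.radius_mm is None) == (self.semi_axes_mm is None):
            raise ValueError("specify exactly one of radius_mm or semi_axes_mm")
        if self.lesion_suv + self.hotspot_peak_suv <= self.background_suv:
            raise ValueError("peak lesion SUV must exceed the background SUV")

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        if self.semi_axes_mm is not None:
            return tuple(float(a) for a in self.semi_axes_mm)
        return (float(self.radius_mm),) * 3

    @property
    def center_mm(self) -> np.ndarray:
        """Lesion center: the physical center of the grid."""
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)


@dataclass(frozen=True)
class MotionModel:
    """Rigid cranio-caudal respiratory displacement.

    Displacement along z at cycle phase u in [0, 1) is
    ``z(u) = A * cos(pi*u)**(2p)`` with peak-to-peak amplitude ``A`` (mm).
    The exponent ``p`` controls the end-expiration dwell: for p >= 1 the
    trajectory spends most of the cycle near z = 0 (the quiescent phase).
    """

    amplitude_mm: float = 15.0
    period_s: float = 4.0
    exponent: int = 2
    n_frames: int = 40

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames per cycle")
        if self.exponent < 1:
            raise ValueError("waveform exponent must be >= 1")

    def displacement_mm(self, phase: np.ndarray) -> np.ndarray:
        """Cranio-caudal displacement (mm) at cycle phase(s) in [0, 1)."""
        phase = np.asarray(phase, dtype=float)
        return self.amplitude_mm * np.cos(np.pi * phase) ** (2 * self.exponent)

    def frame_phases(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.n_frames


@dataclass(frozen=True)
class GatingSpec:
    """Quiescent-window gating: keep frames whose phase lies in
    [phase_offset, phase_offset + phase_window) modulo 1."""

    phase_offset: float = 0.30
    phase_window: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_offset < 1.0:
            raise ValueError("phase_offset must lie in [0, 1)")
        if not 0.0 < self.phase_window <= 1.0:
            raise ValueError("phase_window must lie in (0, 1]")

    def selects(self, phase: np.ndarray) -> np.ndarray:
        rel = np.mod(np.asarray(phase, dtype=float) - self.phase_offset, 1.0)
        return rel < self.phase_window - 1e-12


def _lesion_indicator(spec: PhantomSpec) -> np.ndarray:
    """Analytic lesion geometry sampled at voxel centers."""
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)),
        indexing="ij",
    )
    rel = [g - c for g, c in zip(grids, spec.center_mm)]
    a = spec.semi_axes
    rho = np.sqrt(sum((r / ax) ** 2 for r, ax in zip(rel, a)))
    if spec.lobulation_amplitude > 0:
        # deterministic angular modulation of the boundary radius
        theta = np.arctan2(np.sqrt(rel[0] ** 2 + rel[1] ** 2), rel[2])
        phi = np.arctan2(rel[1], rel[0])
        boundary = 1.0 + spec.lobulation_amplitude * np.sin(3 * theta) * np.cos(2 * phi)
    else:
        boundary = 1.0
    return rho <= boundary


def generate_static_phantom(spec: PhantomSpec) -> tuple[PetVolume, LesionMask]:
    """Build the motion-free phantom and its analytic ground-truth mask."""
    max_axis = max(spec.semi_axes) * (1.0 + spec.lobulation_amplitude)
    center = spec.center_mm
    for a in range(3):
        extent = (spec.shape[a] - 1) * spec.spacing[a]
        if center[a] - max_axis < 2 * spec.spacing[a] or center[a] + max_axis > extent - 2 * spec.spacing[a]:
            raise ValueError(
                f"lesion does not fit inside the grid with a 2-voxel margin "
                f"along axis {AXIS_NAMES[a]!r}"
            )
    inside = _lesion_indicator(spec)
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)),
        indexing="ij",
    )
    hot_center = center + np.asarray(spec.hotspot_offset_mm)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, hot_center))
    hotspot = spec.hotspot_peak_suv * np.exp(-d2 / (2.0 * spec.hotspot_width_mm**2))
    values = np.full(spec.shape, spec.background_suv, dtype=np.float64)
    values[inside] = spec.lesion_suv + hotspot[inside]
    if spec.texture_sd > 0:
        # spatially correlated intra-lesion heterogeneity: a Gaussian-filtered
        # random field normalized to unit sd, scaled and added inside the lesion
        rng = np.random.default_rng(spec.seed)
        sigma_vox = [spec.texture_corr_mm / (2.355 * s) for s in spec.spacing]
        field = ndimage.gaussian_filter(
            rng.standard_normal(spec.shape), sigma=sigma_vox
        )
        field /= field.std()
        values[inside] = np.clip(
            values[inside] + spec.texture_sd * field[inside],
            0.25 * spec.lesion_suv,
            None,
        )
    if spec.psf_fwhm_mm > 0:
        # scanner point-spread function: isotropic Gaussian in physical space
        sigma_vox = [spec.psf_fwhm_mm / (2.355 * s) for s in spec.spacing]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    volume = PetVolume(values=np.clip(values, 0.0, None), spacing=spec.spacing)
    if spec.noise_sd > 0:
        volume = add_noise(volume, spec.noise_sd, seed=spec.seed)
    mask = LesionMask(indicator=inside, spacing=spec.spacing)
    return volume, mask


def _translated_z(volume: PetVolume, dz_mm: float) -> np.ndarray:
    """Volume values rigidly translated by dz_mm toward +z (cubic B-spline)."""
    shift_voxels = dz_mm / volume.spacing[2]
    out = ndimage.shift(
        volume.values, (0.0, 0.0, shift_voxels), order=3, mode="nearest"
    )
    return np.clip(out, 0.0, None)


def _frame_average(volume: PetVolume, motion: MotionModel, keep: np.ndarray) -> PetVolume:
    phases = motion.frame_phases()[keep]
    if phases.size == 0:
        raise ValueError("gating window selects no frames")
    acc = np.zeros_like(volume.values)
    for dz in motion.displacement_mm(phases):
        acc += _translated_z(volume, float(dz))
    return PetVolume(
        values=acc / phases.size, spacing=volume.spacing, origin=volume.origin
    )


def simulate_nongated(volume: PetVolume, motion: MotionModel) -> PetVolume:
    """Acquisition-averaged (motion-blurred) image: mean over all frames of
    one breathing cycle, each a rigid z-translation of the input."""
    keep = np.ones(motion.n_frames, dtype=bool)
    return _frame_average(volume, motion, keep)


def simulate_gated(
    volume: PetVolume, motion: MotionModel, gating: GatingSpec = GatingSpec()
) -> PetVolume:
    """Quiescent-window (gated) analog: mean over the frames whose phase
    falls inside the gating window."""
    keep = gating.selects(motion.frame_phases())
    if not keep.any():
        raise ValueError(
            "gating window smaller than one frame: no frames selected"
        )
    return _frame_average(volume, motion, keep)


def simulate_gating_pair(
    volume: PetVolume, motion: MotionModel, gating: GatingSpec = GatingSpec()
) -> tuple[PetVolume, PetVolume]:
    """(gated, non-gated) pair sharing one set of translated frames.

    Equivalent to calling :func:`simulate_gated` and
    :func:`simulate_nongated` separately, but each frame is translated once.
    """
    phases = motion.frame_phases()
    keep = gating.selects(phases)
    if not keep.any():
        raise ValueError("gating window smaller than one frame: no frames selected")
    frames = [_translated_z(volume, float(dz)) for dz in motion.displacement_mm(phases)]
    stack = np.stack(frames)
    gated = PetVolume(
        values=stack[keep].mean(axis=0), spacing=volume.spacing, origin=volume.origin
    )
    nongated = PetVolume(
        values=stack.mean(axis=0), spacing=volume.spacing, origin=volume.origin
    )
    return gated, nongated


def add_noise(volume: PetVolume, sd: float, seed: int) -> PetVolume:
    """Add i.i.d. Gaussian noise (SUV units), clamped at zero."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return volume
    rng = np.random.default_rng(seed)
    noisy = volume.values + rng.normal(0.0, sd, size=volume.shape)
    return PetVolume(
        values=np.clip(noisy, 0.0, None),
        spacing=volume.spacing,
        origin=volume.origin,
    )


# ---------------------------------------------------------------------------
# Survival cohort with known ground truth


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time (months), event flag, feature vector."""

    patient_id: str
    time_months: float
    event: int
    features: dict[str, float] = field(default_factory=dict)


def generate_survival_cohort(
    n: int,
    betas: dict[str, float],
    baseline_rate: float = np.log(2) / 45.4,
    censor_rate: float = 0.015,
    feature_distribution=None,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Simulate a cohort whose hazard depends on known feature coefficients.

    Event times are exponential with rate ``baseline_rate * exp(beta @ x)``;
    censoring times are exponential with rate ``censor_rate`` (0 disables
    censoring). Feature vectors default to i.i.d. standard normal; pass
    ``feature_distribution(rng, n, names)`` returning an (n, p) array to
    override. Default rates emulate a cohort with a median survival of
    about 45 months and roughly half the patients reaching the event.
    """
    if n < 2:
        raise ValueError("need at least 2 patients")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be non-negative")
    rng = np.random.default_rng(seed)
    names = list(betas)
    beta = np.array([betas[k] for k in names], dtype=float)
    if feature_distribution is None:
        x = rng.standard_normal((n, len(names)))
    else:
        x = np.asarray(feature_distribution(rng, n, names), dtype=float)
        if x.shape != (n, len(names)):
            raise ValueError(f"feature_distribution returned shape {x.shape}")
    rate = baseline_rate * np.exp(x @ beta if names else np.zeros(n))
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return [
        SurvivalRecord(
            patient_id=f"P{i:04d}",
            time_months=float(time[i]),
            event=int(event[i]),
            features={k: float(x[i, j]) for j, k in enumerate(names)},
        )
        for i in range(n)
    ]


def cohort_to_frame(records: list[SurvivalRecord]):
    """Cohort as a DataFrame: patient_id, time_months, event, feature columns."""
    import pandas as pd

    rows = [
        {"patient_id": r.patient_id, "time_months": r.time_months, "event": r.event}
        | r.features
        for r in records
    ]
    return pd.DataFrame(rows)
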