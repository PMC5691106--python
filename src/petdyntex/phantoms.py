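"""Synthetic paired dual-time-point PET tumor phantoms.

Each phantom is an ellipsoidal lesion on a uniform background, with
lesion-scale heterogeneity modeled as a smoothed Gaussian random field
(correlation length in mm) so that texture survives at PET-like
resolution, an optional enclosed necrotic core, additive Gaussian noise
followed by a reconstruction-like Gaussian point-spread smoothing (FWHM
in mm), and programmed standard-to-delayed dynamics: at the delayed
acquisition the uptake is raised by a multiplicative gain and the radial
profile is sharpened by an exponent > 1, so SUV-based variables rise
while the fixed-fraction (40% of SUVmax) threshold volume shrinks.
Noise and smoothing are applied in a generous neighborhood of the lesion
(the far background stays at its nominal value, which no analysis box
reaches), keeping generation cost independent of the grid size.

Default geometry follows a whole-body PET protocol: 128 x 128 in-plane
matrix, 5.47 x 5.47 x 3.27 mm voxels, lesions at least 2 cm across,
uptake times of 60 min (PET-1) and ~187 min (PET-2).  Default dynamics
(gain 1.18, profile sharpening 1.12, the latter calibrated against the
point-spread smoothing that partly blunts it) land near +15% SUVmax and
-10% MTV — tunable knobs, not ground truth.  All randomness flows through one seeded
generator; identical spec and seed reproduce volumes bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import PairedCohort
from .io import AcquisitionMeta, PETVolume
from .segmentation import BoundingBox, segment_lesion
from .texture import extract_features

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "make_cohort",
    "default_spec_sampler",
    "extract_pair",
]

#: 18F half-life in seconds
F18_HALF_LIFE_S = 6588.0

#: programmed PET-1 -> PET-2 effect directions under the default dynamics
EFFECT_DIRECTIONS = {
    "suv_max": "up",
    "suv_mean": "up",
    "suv_peak": "up",
    "mtv_cm3": "down",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one paired phantom.

    Lengths are mm, uptake values SUV.  ``pet2_gain`` multiplies the lesion
    uptake at the delayed acquisition; ``pet2_contrast`` (> 1) sharpens the
    radial profile so a fixed-fraction threshold volume shrinks.
    ``noise_sd`` is the amplitude of the voxel noise *before* the
    point-spread smoothing (``psf_fwhm_mm``; 0 disables smoothing), so the
    apparent noise in the image is a few times smaller.
    """

    shape: tuple[int, int, int] = (128, 128, 48)
    spacing: tuple[float, float, float] = (5.47, 5.47, 3.27)
    lesion_axes_mm: tuple[float, float, float] = (40.0, 40.0, 36.0)
    base_uptake: float = 9.0
    background_uptake: float = 1.0
    texture_amplitude: float = 0.3
    texture_corr_mm: float = 15.0
    necrotic_radius_mm: float = 0.0
    pet2_gain: float = 1.18
    pet2_contrast: float = 1.12
    noise_sd: float = 0.8
    psf_fwhm_mm: float = 7.0
    uptake_time_pet1_min: float = 60.0
    uptake_time_pet2_min: float = 187.0
    seed: int = 0

    def __post_init__(self):
        if min(self.lesion_axes_mm) < 20.0:
            raise ValueError("lesion axes must be at least 20 mm (lesions >= 2 cm)")
        if self.pet2_gain <= 0 or self.pet2_contrast <= 0:
            raise ValueError("gain and contrast must be > 0")
        if self.base_uptake <= self.background_uptake:
            raise ValueError("lesion uptake must exceed background")
        for ax, n, sp in zip(self.lesion_axes_mm, self.shape, self.spacing):
            if ax >= (n - 4) * sp:
                raise ValueError("lesion does not fit in the grid")


@dataclass
class GroundTruth:
    """What the generator actually drew."""

    lesion_mask: np.ndarray
    necrotic_mask: np.ndarray
    spec: PhantomSpec
    effect_directions: dict = field(default_factory=dict)


def _meta(spec: PhantomSpec, timepoint: str, uptake_min: float) -> AcquisitionMeta:
    return AcquisitionMeta(
        patient_weight_g=70000.0,
        injected_dose_bq=3.7e8,
        half_life_s=F18_HALF_LIFE_S,
        decay_factor=1.0,
        elapsed_time_s=uptake_min * 60.0,
        rescale_slope=1.0,
        timepoint=timepoint,
        uptake_time_min=uptake_min,
    )


def make_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[PETVolume, PETVolume, GroundTruth]:
    """Generate one (PET-1, PET-2, ground truth) triple.

    The tumor texture field is drawn once and shared by both timepoints
    (it is a property of the lesion); the acquisition noise is independent
    between timepoints.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing)
    center = (np.asarray(spec.shape) - 1) / 2.0
    semi = np.asarray(spec.lesion_axes_mm) / 2.0 / spacing  # semi-axes in voxels

    psf_sigma_vox = (spec.psf_fwhm_mm / 2.3548) / spacing if spec.psf_fwhm_mm > 0 else None
    # noise and PSF smoothing are applied in this neighborhood of the lesion;
    # the analysis box never reaches the noiseless far background
    pad = (np.ceil(4 * psf_sigma_vox).astype(int) if psf_sigma_vox is not None else 0) + 4
    lo = np.maximum(0, np.floor(center - semi - pad).astype(int))
    hi = np.minimum(spec.shape, np.ceil(center + semi + pad + 1).astype(int))
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    xs = [np.arange(lo[k], hi[k]) - center[k] for k in range(3)]
    grids = np.meshgrid(*xs, indexing="ij")
    r2 = sum((g / s) ** 2 for g, s in zip(grids, semi))
    profile = np.clip(1.0 - r2, 0.0, None)
    support = profile > 0

    # shared lesion texture: white noise smoothed to the correlation length
    white = rng.standard_normal(profile.shape)
    sigma_vox = spec.texture_corr_mm / spacing
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    sd = smooth.std()
    texture = spec.texture_amplitude * (smooth / sd if sd > 0 else smooth)

    # physical radius from the lesion center, for the necrotic core
    r_mm = np.sqrt(sum((g * s) ** 2 for g, s in zip(grids, spacing)))
    necro_local = support & (r_mm < spec.necrotic_radius_mm)

    bg = spec.background_uptake
    amp = spec.base_uptake - bg

    def build(gain: float, contrast: float, timepoint: str, uptake_min: float) -> PETVolume:
        lesion = amp * gain * profile**contrast * (1.0 + texture)
        lesion[necro_local] = 0.0  # necrotic core falls back to background
        region = bg + np.clip(lesion, 0.0, None)
        region += spec.noise_sd * rng.standard_normal(region.shape)
        if psf_sigma_vox is not None:
            region = ndimage.gaussian_filter(region, sigma=psf_sigma_vox)
        vol = np.full(spec.shape, bg, dtype=np.float64)
        vol[box] = np.clip(region, 0.0, None)
        return PETVolume(vol, spec.spacing, _meta(spec, timepoint, uptake_min))

    pet1 = build(1.0, 1.0, "PET1", spec.uptake_time_pet1_min)
    pet2 = build(spec.pet2_gain, spec.pet2_contrast, "PET2", spec.uptake_time_pet2_min)

    lesion_mask = np.zeros(spec.shape, dtype=bool)
    lesion_mask[box] = support & ~necro_local
    necrotic_mask = np.zeros(spec.shape, dtype=bool)
    necrotic_mask[box] = necro_local
    directions = (
        dict(EFFECT_DIRECTIONS)
        if spec.pet2_gain > 1.0 and spec.pet2_contrast > 1.0
        else {}
    )
    return pet1, pet2, GroundTruth(lesion_mask, necrotic_mask, spec, directions)


def extract_pair(
    pet1: PETVolume,
    pet2: PETVolume,
    truth: GroundTruth,
    patient_id,
    fraction: float = 0.40,
    n_levels: int = 16,
    box_margin: int = 2,
) -> list[dict]:
    """Segment each timepoint independently and extract both feature rows."""
    box = BoundingBox.from_mask(truth.lesion_mask | truth.necrotic_mask,
                                margin=box_margin, volume_shape=pet1.shape)
    rows = []
    for vol in (pet1, pet2):
        mask = segment_lesion(vol, box, fraction=fraction)
        feats = extract_features(vol, mask, n_levels=n_levels)
        row = {"patient_id": patient_id, "timepoint": vol.meta.timepoint}
        row.update(feats.to_dict())
        rows.append(row)
    return rows


def default_spec_sampler(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """Draw a patient-level PhantomSpec spanning both MTV strata.

    Lesion diameters are uniform on 24-56 mm with mild anisotropy, so the
    40%-threshold volumes straddle the 10 cm^3 cutoff; lesion uptake,
    heterogeneity amplitude, delayed-acquisition gain/sharpening and the
    inter-scan delay vary per patient.  Keyword overrides pin any field
    (e.g. ``pet2_gain=1.0, pet2_contrast=1.0`` for a null cohort).
    """
    d = float(rng.uniform(24.0, 56.0))
    axes = tuple(float(np.clip(d * rng.uniform(0.85, 1.15), 20.0, None)) for _ in range(3))
    fields = {
        "lesion_axes_mm": axes,
        "base_uptake": float(rng.uniform(6.0, 14.0)),
        "texture_amplitude": float(rng.uniform(0.15, 0.35)),
        "pet2_gain": float(rng.uniform(1.10, 1.26)),
        "pet2_contrast": float(rng.uniform(1.06, 1.18)),
        "necrotic_radius_mm": float(rng.uniform(4.0, 10.0)) if rng.random() < 0.2 else 0.0,
        "uptake_time_pet2_min": 60.0 + float(rng.uniform(112.0, 138.0)),
    }
    fields.update(overrides)
    return PhantomSpec(**fields)


def make_cohort(
    n: int,
    seed: int = 0,
    spec_sampler=None,
    fraction: float = 0.40,
    n_levels: int = 16,
    **sampler_overrides,
) -> tuple[PairedCohort, list[GroundTruth]]:
    """Generate n independent paired phantoms and their feature table.

    ``spec_sampler(rng) -> PhantomSpec`` customizes the population;
    keyword overrides are forwarded to :func:`default_spec_sampler` when
    no sampler is given.  Fully reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    truths: list[GroundTruth] = []
    for k in range(n):
        if spec_sampler is None:
            spec = default_spec_sampler(rng, **sampler_overrides)
        else:
            spec = spec_sampler(rng)
        spec = replace(spec, seed=int(rng.integers(2**31)))
        pet1, pet2, truth = make_phantom(spec)
        rows.extend(extract_pair(pet1, pet2, truth, patient_id=f"P{k:03d}",
                                 fraction=fraction, n_levels=n_levels))
        truths.append(truth)
    if not rows:
        return PairedCohort.empty(), []
    return PairedCohort(pd.DataFrame(rows)), truths
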