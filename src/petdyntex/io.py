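"""Reading and writing PET volumes, SUV conversion, and feature tables.

The standardized uptake value (SUV, g/ml) of a voxel with stored scanner
value ``SV`` is computed with the decay-corrected body-weight formula

    SUV = SV * RS * W / ((RTD * DF) * exp(-ln2 * Et / HF))

where ``RS`` is the rescale slope, ``W`` the patient weight in grams,
``RTD`` the injected radiotracer dose in Bq, ``DF`` an optional decay
factor already applied by the scanner export (1 when none), ``Et`` the
elapsed time from injection to acquisition of the slice in seconds, and
``HF`` the radionuclide half-life in seconds.  Dividing by the decaying
exponential corrects the measured activity back to injection time, which
makes standard (~60 min) and delayed (~3 h) acquisitions of the same
patient directly comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMeta",
    "PETVolume",
    "InvalidMetadataError",
    "LoadError",
    "PairedCompletenessWarning",
    "decay_corrected_suv",
    "load_nifti_volume",
    "save_nifti_volume",
    "save_mask_nifti",
    "load_dicom_series",
    "save_feature_table",
    "load_feature_table",
    "METABOLIC_COLUMNS",
    "TEXTURE_COLUMNS",
    "FEATURE_COLUMNS",
]

#: the five SUV/volume metrics reported per scan
METABOLIC_COLUMNS = ["suv_max", "suv_mean", "suv_peak", "mtv_cm3", "tlg"]

#: the 18 three-dimensional textural features, in conventional order:
#: 5 co-occurrence features, 11 run-length features, 2 gradient energies
TEXTURE_COLUMNS = [
    "ENT", "HOM", "CON", "DIS", "UNI",
    "SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
    "GLNU", "RLNU", "RPC",
    "SE", "TE",
]

FEATURE_COLUMNS = METABOLIC_COLUMNS + TEXTURE_COLUMNS

TIMEPOINTS = ("PET1", "PET2")


class InvalidMetadataError(ValueError):
    """Acquisition metadata violates a physical constraint."""


class LoadError(ValueError):
    """A volume could not be loaded (missing metadata, inconsistent series...)."""


class PairedCompletenessWarning(UserWarning):
    """A patient is missing one of the two timepoints in a feature table."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Metadata needed to convert stored pixel values to SUV.

    Parameters
    ----------
    patient_weight_g : float
        Patient weight in grams (> 0).
    injected_dose_bq : float
        Injected radiotracer dose in Bq (> 0).
    half_life_s : float
        Radionuclide half-life in seconds (> 0); 6588 s for 18F.
    decay_factor : float
        Decay factor already applied by the scanner export.  Defaults to 1
        (no pre-applied correction).  If the export pre-applies decay,
        supply it here and do NOT also encode it in ``elapsed_time_s``:
        avoiding double correction is the caller's responsibility.
    elapsed_time_s : float
        Elapsed time from injection to acquisition (per slice when known,
        otherwise scan-level), in seconds (>= 0).
    rescale_slope : float
        DICOM rescale slope mapping stored integers to activity units.
    timepoint : str
        ``"PET1"`` (standard, ~60 min) or ``"PET2"`` (delayed, ~3 h).
    uptake_time_min : float
        Nominal injection-to-scan uptake time in minutes (bookkeeping).
    """

    patient_weight_g: float
    injected_dose_bq: float
    half_life_s: float
    decay_factor: float = 1.0
    elapsed_time_s: float = 0.0
    rescale_slope: float = 1.0
    timepoint: str = "PET1"
    uptake_time_min: float = 60.0

    def __post_init__(self) -> None:
        if not self.patient_weight_g > 0:
            raise InvalidMetadataError("patient_weight_g must be > 0")
        if not self.injected_dose_bq > 0:
            raise InvalidMetadataError("injected_dose_bq must be > 0")
        if not self.half_life_s > 0:
            raise InvalidMetadataError("half_life_s must be > 0")
        if not self.decay_factor > 0:
            raise InvalidMetadataError("decay_factor must be > 0")
        if self.elapsed_time_s < 0:
            raise InvalidMetadataError("elapsed_time_s must be >= 0")
        if self.timepoint not in TIMEPOINTS:
            raise InvalidMetadataError(f"timepoint must be one of {TIMEPOINTS}")


def decay_corrected_suv(stored_value, meta: AcquisitionMeta, elapsed_time_s: float | None = None):
    """Convert stored pixel value(s) to SUV with decay correction.

    Parameters
    ----------
    stored_value : scalar or ndarray
        Raw stored value(s) ``SV``.
    meta : AcquisitionMeta
        Validated acquisition metadata.
    elapsed_time_s : float, optional
        Per-slice elapsed time overriding ``meta.elapsed_time_s``.

    Returns
    -------
    scalar or ndarray, same shape as ``stored_value``, in SUV (g/ml).
    """
    et = meta.elapsed_time_s if elapsed_time_s is None else float(elapsed_time_s)
    if et < 0:
        raise InvalidMetadataError("elapsed time must be >= 0")
    decay = math.exp(-math.log(2.0) * et / meta.half_life_s)
    denom = meta.injected_dose_bq * meta.decay_factor * decay
    return stored_value * meta.rescale_slope * meta.patient_weight_g / denom


@dataclass
class PETVolume:
    """A 3D SUV field with voxel spacing and acquisition metadata.

    ``suv`` is indexed ``(x, y, z)`` with 0-based voxel indices; ``spacing``
    is ``(dx, dy, dz)`` in mm.  SUV is non-negative everywhere.
    """

    suv: np.ndarray
    spacing: tuple[float, float, float]
    meta: AcquisitionMeta | None = None

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=np.float64)
        if self.suv.ndim != 3:
            raise ValueError("suv field must be 3-dimensional")
        if any(s < 2 for s in self.suv.shape):
            raise ValueError("suv field must have extent >= 2 along every axis")
        if np.any(self.suv < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.suv.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_nifti_volume(volume: PETVolume, path) -> None:
    """Write a PETVolume to a NIfTI-1 file (SUV units, spacing in the affine)."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.suv, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_nifti_volume(
    path,
    meta: AcquisitionMeta | None = None,
    suv_precomputed: bool = True,
) -> PETVolume:
    """Load a NIfTI volume as a PETVolume.

    With ``suv_precomputed=True`` (default) the stored field is taken to be
    SUV already and passed through unchanged.  Otherwise ``meta`` is
    required and the stored values are converted with
    :func:`decay_corrected_suv` using the scan-level elapsed time.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if suv_precomputed:
        return PETVolume(data, spacing, meta)
    if meta is None:
        raise LoadError("metadata required to convert stored values to SUV (missing field: meta)")
    return PETVolume(decay_corrected_suv(data, meta), spacing, meta)


def save_mask_nifti(mask: np.ndarray, spacing, path) -> None:
    """Write a boolean mask as uint8 NIfTI."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = {
    "PatientWeight": "patient weight",
    "RescaleSlope": "rescale slope",
    "PixelSpacing": "pixel spacing",
    "ImagePositionPatient": "image position",
    "ImageOrientationPatient": "image orientation",
    "AcquisitionTime": "acquisition time",
}


def _parse_dicom_time(value: str) -> float:
    """HHMMSS(.ffffff) -> seconds since midnight."""
    s = str(value)
    hh, mm = int(s[0:2]), int(s[2:4])
    ss = float(s[4:]) if len(s) > 4 else 0.0
    return hh * 3600 + mm * 60 + ss


def load_dicom_series(directory, timepoint: str = "PET1", uptake_time_min: float = 60.0) -> PETVolume:
    """Load a single-frame PET DICOM series as a PETVolume.

    Slices are sorted by position along the scan axis; each slice is
    converted to SUV with its own elapsed time (acquisition time minus
    radiopharmaceutical start time).  All slices must share in-plane
    spacing and orientation.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise LoadError(f"no DICOM files found in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    for ds in slices:
        for tag, label in _REQUIRED_TAGS.items():
            if getattr(ds, tag, None) is None:
                raise LoadError(f"missing field: {label} ({tag})")
        if getattr(ds, "RadiopharmaceuticalInformationSequence", None) is None:
            raise LoadError("missing field: radiopharmaceutical information "
                            "(RadiopharmaceuticalInformationSequence)")
        rp = ds.RadiopharmaceuticalInformationSequence[0]
        for tag, label in {
            "RadionuclideTotalDose": "injected dose",
            "RadionuclideHalfLife": "half-life",
            "RadiopharmaceuticalStartTime": "injection time",
        }.items():
            if getattr(rp, tag, None) is None:
                raise LoadError(f"missing field: {label} ({tag})")

    ref = slices[0]
    orient = [float(v) for v in ref.ImageOrientationPatient]
    pixsp = [float(v) for v in ref.PixelSpacing]
    for ds in slices[1:]:
        if [float(v) for v in ds.ImageOrientationPatient] != orient:
            raise LoadError("mixed slice orientations in series")
        if [float(v) for v in ds.PixelSpacing] != pixsp:
            raise LoadError("mixed in-plane pixel spacing in series")

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = [float(ds.ImagePositionPatient[2]) for ds in slices]
    dz = abs(zs[1] - zs[0]) if len(zs) > 1 else float(getattr(ref, "SliceThickness", 1.0) or 1.0)

    rp = ref.RadiopharmaceuticalInformationSequence[0]
    inj_t = _parse_dicom_time(rp.RadiopharmaceuticalStartTime)
    meta = AcquisitionMeta(
        patient_weight_g=float(ref.PatientWeight) * 1000.0,
        injected_dose_bq=float(rp.RadionuclideTotalDose),
        half_life_s=float(rp.RadionuclideHalfLife),
        decay_factor=1.0,
        elapsed_time_s=max(0.0, _parse_dicom_time(ref.AcquisitionTime) - inj_t),
        rescale_slope=float(ref.RescaleSlope),
        timepoint=timepoint,
        uptake_time_min=uptake_time_min,
    )

    planes = []
    for ds in slices:
        et = _parse_dicom_time(ds.AcquisitionTime) - inj_t
        if et < 0:
            raise LoadError("acquisition time precedes injection time")
        m = replace(meta, elapsed_time_s=et, rescale_slope=float(ds.RescaleSlope))
        planes.append(decay_corrected_suv(ds.pixel_array.astype(np.float64), m))
    # stack rows/cols as (x, y) then slices along z
    suv = np.stack(planes, axis=-1)
    spacing = (pixsp[0], pixsp[1], dz)
    return PETVolume(suv, spacing, meta)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def save_feature_table(cohort, path) -> None:
    """Write a paired cohort to CSV, one row per (patient, timepoint)."""
    frame = cohort.frame if hasattr(cohort, "frame") else pd.DataFrame(cohort)
    frame.to_csv(path, index=False, float_format="%.17g")


def load_feature_table(path):
    """Load a feature CSV into a :class:`~petdyntex.cohort.PairedCohort`.

    Patients missing one of the two timepoints trigger a
    :class:`PairedCompletenessWarning` naming them and are dropped.
    """
    from .cohort import PairedCohort

    frame = pd.read_csv(path)
    required = ["patient_id", "timepoint"] + FEATURE_COLUMNS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise LoadError(f"feature table is missing columns: {missing}")
    keys = frame[["patient_id", "timepoint"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].to_records(index=False).tolist()
        raise LoadError(f"duplicated (patient, timepoint) keys: {dup}")
    counts = frame.groupby("patient_id")["timepoint"].nunique()
    incomplete = sorted(counts.index[counts < 2].tolist())
    if incomplete:
        warnings.warn(
            f"patients missing a timepoint, excluded: {incomplete}",
            PairedCompletenessWarning,
            stacklevel=2,
        )
        frame = frame[~frame["patient_id"].isin(incomplete)]
    return PairedCohort(frame.reset_index(drop=True))
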