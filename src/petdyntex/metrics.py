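"""SUV and volume metrics of the segmented tumor.

SUVmax and SUVmean are the maximum and arithmetic mean SUV over the VOI.
SUVpeak is the maximum, over 3x3x3-voxel cubes centered on VOI voxels, of
the cube's mean SUV.  MTV (metabolic tumor volume) is the physical volume
of the VOI in cm^3, and TLG (total lesion glycolysis) is SUVmean * MTV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import PETVolume
from .segmentation import BoundingBox, EmptySegmentationError, TumorMask

__all__ = ["MetabolicMetrics", "suv_stats", "suv_peak", "mtv", "tlg", "metabolic_metrics"]


@dataclass(frozen=True)
class MetabolicMetrics:
    suv_max: float
    suv_mean: float
    suv_peak: float
    mtv_cm3: float
    tlg: float

    def __post_init__(self):
        # peak <= max and mean <= max always; mean <= peak is NOT guaranteed
        if self.suv_peak > self.suv_max + 1e-9:
            raise ValueError("suv_peak cannot exceed suv_max")
        if self.suv_mean > self.suv_max + 1e-9:
            raise ValueError("suv_mean cannot exceed suv_max")


def _mask_array(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)


def suv_stats(volume: PETVolume, mask) -> tuple[float, float]:
    """(SUVmax, SUVmean) over the masked voxels."""
    m = _mask_array(mask)
    if not m.any():
        raise EmptySegmentationError("mask is empty")
    vals = volume.suv[m]
    return float(vals.max()), float(vals.mean())


def suv_peak(volume: PETVolume, mask, masked_only: bool = False) -> float:
    """Maximum 3x3x3-cube mean SUV over cubes centered on masked voxels.

    By default the cube averages every image voxel it covers (also those
    outside the VOI); voxels falling outside the image are excluded from
    the mean.  With ``masked_only=True`` the mean runs over in-VOI cube
    voxels only.
    """
    m = _mask_array(mask)
    if not m.any():
        raise EmptySegmentationError("mask is empty")
    # restrict to the mask's neighborhood for speed; cubes see 1 voxel beyond
    if isinstance(mask, TumorMask):
        box = mask.box.expand(1, volume.shape)
    else:
        box = BoundingBox.from_mask(m, margin=1, volume_shape=volume.shape)
    sub = volume.suv[box.slices]
    sub_m = m[box.slices]
    if masked_only:
        values = np.where(sub_m, sub, 0.0)
        weights = sub_m.astype(np.float64)
    else:
        values = sub
        weights = np.ones_like(sub)
    sums = ndimage.uniform_filter(values, size=3, mode="constant") * 27.0
    counts = ndimage.uniform_filter(weights, size=3, mode="constant") * 27.0
    # interior cubes straddling the subvolume edge must still see image voxels
    # beyond it: the 1-voxel margin guarantees correctness at masked centers
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return float(means[sub_m].max())


def mtv(mask, spacing) -> float:
    """Metabolic tumor volume: voxel count x voxel volume, in cm^3."""
    m = _mask_array(mask)
    n = int(m.sum())
    if n == 0:
        raise EmptySegmentationError("MTV of an empty mask is undefined")
    dx, dy, dz = spacing
    return n * dx * dy * dz / 1000.0


def tlg(suv_mean: float, mtv_cm3: float) -> float:
    """Total lesion glycolysis: SUVmean x MTV (SUV.cm^3)."""
    return suv_mean * mtv_cm3


def metabolic_metrics(volume: PETVolume, mask, peak_masked_only: bool = False) -> MetabolicMetrics:
    smax, smean = suv_stats(volume, mask)
    speak = suv_peak(volume, mask, masked_only=peak_masked_only)
    vol = mtv(mask, volume.spacing)
    return MetabolicMetrics(smax, smean, speak, vol, tlg(smean, vol))
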