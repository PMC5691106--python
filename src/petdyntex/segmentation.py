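"""Semi-automatic tumor delineation.

The lesion is first located manually in a 3D bounding box; the volume of
interest (VOI) is then every voxel in the box whose SUV is equal to or
above a fixed fraction (default 40%) of the maximum SUV inside the box.
Central sub-threshold regions fully enclosed by the VOI are treated as
necrosis: they stay excluded from the volume and are counted for
provenance (no hole filling is applied).  When the thresholded region has
several 26-connected components (multifocal disease), the component with
the highest uptake is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import PETVolume

__all__ = [
    "BoundingBox",
    "TumorMask",
    "EmptySegmentationError",
    "threshold_voi",
    "exclude_necrotic_core",
    "pick_hottest_component",
    "segment_lesion",
]

#: 26-neighborhood structuring element, used for components and flood fill
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


class EmptySegmentationError(ValueError):
    """Segmentation produced (or was given) an empty mask."""


@dataclass(frozen=True)
class BoundingBox:
    """Half-open, 0-based voxel index ranges ``[x0, x1) x [y0, y1) x [z0, z1)``."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1 and self.z0 < self.z1):
            raise ValueError("bounding box must be nonempty")
        if min(self.x0, self.y0, self.z0) < 0:
            raise ValueError("bounding box indices must be >= 0")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.x0, self.x1), slice(self.y0, self.y1), slice(self.z0, self.z1))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x1 - self.x0, self.y1 - self.y0, self.z1 - self.z0)

    def check_within(self, volume_shape) -> None:
        if self.x1 > volume_shape[0] or self.y1 > volume_shape[1] or self.z1 > volume_shape[2]:
            raise ValueError(f"bounding box {self} exceeds volume shape {tuple(volume_shape)}")

    def expand(self, margin: int, volume_shape) -> "BoundingBox":
        """Grow by ``margin`` voxels on every side, clipped to the volume."""
        return BoundingBox(
            max(0, self.x0 - margin), min(volume_shape[0], self.x1 + margin),
            max(0, self.y0 - margin), min(volume_shape[1], self.y1 + margin),
            max(0, self.z0 - margin), min(volume_shape[2], self.z1 + margin),
        )

    @classmethod
    def from_mask(cls, mask: np.ndarray, margin: int = 0, volume_shape=None) -> "BoundingBox":
        """Tight box around the True voxels of ``mask``, optionally padded."""
        if not mask.any():
            raise EmptySegmentationError("cannot build a bounding box around an empty mask")
        shape = volume_shape if volume_shape is not None else mask.shape
        idx = np.nonzero(mask)
        lo = [int(a.min()) for a in idx]
        hi = [int(a.max()) + 1 for a in idx]
        box = cls(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
        return box.expand(margin, shape) if margin else box


@dataclass
class TumorMask:
    """Boolean VOI on a PETVolume grid, with segmentation provenance."""

    mask: np.ndarray
    box: BoundingBox
    fraction: float
    threshold: float
    necrotic_voxels: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def threshold_voi(volume: PETVolume, box: BoundingBox, fraction: float = 0.40) -> TumorMask:
    """Fixed-fraction threshold segmentation inside a manual box.

    Selects every voxel in ``box`` with SUV equal to or above
    ``fraction * max(SUV in box)`` (inclusive comparison).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    box.check_within(volume.shape)
    sub = volume.suv[box.slices]
    suv_max = float(sub.max())
    if suv_max <= 0:
        raise EmptySegmentationError("no uptake inside the bounding box (max SUV is 0)")
    threshold = fraction * suv_max
    mask = np.zeros(volume.shape, dtype=bool)
    mask[box.slices] = sub >= threshold
    return TumorMask(mask=mask, box=box, fraction=fraction, threshold=threshold)


def exclude_necrotic_core(tmask: TumorMask, volume: PETVolume) -> TumorMask:
    """Account for enclosed sub-threshold cavities (imaging necrosis).

    Sub-threshold 26-connected components inside the box that touch no box
    face are necrosis: they remain excluded from the mask (thresholding
    already removed them — this guarantees no hole filling) and their voxel
    count is recorded in ``necrotic_voxels``.  Cold regions open to a box
    face are background, not necrosis.
    """
    sub_mask = tmask.mask[tmask.box.slices]
    below = ~sub_mask
    labels, n = ndimage.label(below, structure=STRUCTURE_26)
    if n == 0:
        return replace(tmask, necrotic_voxels=0)
    # labels present on any face of the box are open to the outside
    open_labels = set()
    for axis in range(3):
        for face in (0, -1):
            face_lab = np.take(labels, face, axis=axis)
            open_labels.update(np.unique(face_lab[face_lab > 0]).tolist())
    enclosed = ~np.isin(np.arange(1, n + 1), sorted(open_labels))
    count = int(np.isin(labels, np.arange(1, n + 1)[enclosed]).sum()) if enclosed.any() else 0
    return replace(tmask, necrotic_voxels=count)


def pick_hottest_component(tmask: TumorMask, volume: PETVolume) -> TumorMask:
    """Keep only the 26-connected component with the highest uptake.

    The component containing the voxel of maximum SUV is returned.  If the
    maximum is attained in several components, the larger component wins;
    remaining ties go to the component containing the lowest linear voxel
    index (deterministic).
    """
    if not tmask.mask.any():
        raise EmptySegmentationError("mask is empty")
    sub = tmask.mask[tmask.box.slices]  # mask lives inside the box
    labels, n = ndimage.label(sub, structure=STRUCTURE_26)
    if n <= 1:
        return tmask
    suv = volume.suv[tmask.box.slices]
    masked_max = suv[sub].max()
    at_max = sub & (suv == masked_max)
    candidates = np.unique(labels[at_max])
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, candidates)

    def sort_key(k):
        lab = candidates[k]
        first_index = int(np.flatnonzero((labels == lab).ravel())[0])
        return (-sizes[k], first_index)

    best = candidates[min(range(len(candidates)), key=sort_key)]
    new_mask = np.zeros(tmask.mask.shape, dtype=bool)
    new_mask[tmask.box.slices] = labels == best
    return replace(tmask, mask=new_mask)


def segment_lesion(
    volume: PETVolume,
    box: BoundingBox,
    fraction: float = 0.40,
    select_hottest: bool = True,
) -> TumorMask:
    """Full delineation: threshold, necrosis accounting, hottest component."""
    tmask = threshold_voi(volume, box, fraction)
    tmask = exclude_necrotic_core(tmask, volume)
    if select_hottest:
        tmask = pick_hottest_component(tmask, volume)
    return tmask
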