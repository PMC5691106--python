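"""3D textural features of the segmented tumor.

Two matrix families are computed on a gray-level-discretized VOI and one
gradient family on the raw SUV field:

* **Co-occurrence matrix (CM)** — counts of pairs of adjacent masked
  voxels by gray level, over all 26 neighbours of every voxel (the 13
  distinct 3D directions and their opposites), normalized to sum 1.
  Features: entropy (ENT), homogeneity (HOM), contrast (CON),
  dissimilarity (DIS), uniformity (UNI).
* **Run-length matrix (RLM)** — ``RLM(i, j)`` is the number of maximal
  collinear runs of length ``j`` of masked voxels with gray level ``i``,
  accumulated over the 13 directions.  Out-of-mask voxels terminate runs.
  Features: SRE, LRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU,
  RLNU, RPC.
* **Energies** — from the raw (undiscretized) SUV field ``u``:
  specific energy ``SE = sqrt(int |grad u|^2 dV) / sqrt(int |u|^2 dV)``
  (intensive: variation per unit volume and SUV) and total energy
  ``TE = sqrt(int |grad u|^2 dV) / max(u)`` (extensive: grows with the
  domain).  Gradients use central differences in physical units (mm),
  falling back to one-sided differences at the VOI boundary.

Gray levels are integers ``1..N`` (default ``N = 16``) from equal-width
binning between the VOI minimum and maximum.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FEATURE_COLUMNS, PETVolume
from .metrics import metabolic_metrics
from .segmentation import BoundingBox, EmptySegmentationError, TumorMask

__all__ = [
    "DIRECTIONS_13",
    "DiscretizedVOI",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "discretize_voi",
    "build_cm",
    "cm_features",
    "build_rlm",
    "rlm_features",
    "energy_features",
    "extract_features",
]

#: the 13 distinct direction vectors of the 26-neighborhood (one per
#: opposite pair), lexicographically positive
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class DiscretizedVOI:
    """Integer gray levels ``1..n_levels`` on masked voxels of a cropped grid.

    ``levels`` is a 3D int array over the mask's bounding box with 0
    outside the mask; ``histogram[k]`` counts voxels at level ``k + 1``.
    """

    levels: np.ndarray
    n_levels: int
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.levels = np.asarray(self.levels)
        inside = self.levels[self.levels > 0]
        if inside.size and int(inside.max()) > self.n_levels:
            raise ValueError("gray levels exceed n_levels")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())

    @property
    def histogram(self) -> np.ndarray:
        return np.bincount(self.levels[self.levels > 0], minlength=self.n_levels + 1)[1:]


@dataclass
class CooccurrenceMatrix:
    """N x N symmetric probability matrix of adjacent gray-level pairs."""

    matrix: np.ndarray
    pair_count: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if np.any(self.matrix < 0):
            raise ValueError("co-occurrence entries must be non-negative")


@dataclass
class RunLengthMatrix:
    """N x M run-count matrix; column ``j`` holds runs of length ``j + 1``."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("run-length matrix must be 2-dimensional")
        if np.any(self.matrix < 0):
            raise ValueError("run counts must be non-negative")

    @property
    def n_runs(self) -> int:
        return int(self.matrix.sum())

    @property
    def n_voxel_direction(self) -> int:
        """Sum of RLM(i, j) * j — equals 13 x masked voxel count."""
        j = np.arange(1, self.matrix.shape[1] + 1)
        return int((self.matrix * j).sum())


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_voi(
    volume: PETVolume,
    mask,
    n_levels: int = 16,
    bounds: tuple[float, float] | None = None,
) -> DiscretizedVOI:
    """Equal-width gray-level binning of the masked SUVs.

    With the default relative binning, level = ``min(N, floor(N * (s - min)
    / (max - min)) + 1)`` using the VOI's own minimum and maximum; a
    constant VOI maps to level 1.  Fixed bounds can be supplied instead.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptySegmentationError("mask is empty")
    box = mask.box if isinstance(mask, TumorMask) else BoundingBox.from_mask(m)
    sub = volume.suv[box.slices]
    sub_m = m[box.slices]
    vals = sub[sub_m]
    lo, hi = (float(vals.min()), float(vals.max())) if bounds is None else map(float, bounds)
    levels = np.zeros(sub.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor(n_levels * (vals - lo) / (hi - lo)).astype(np.int32) + 1
        np.clip(lv, 1, n_levels, out=lv)
    else:
        lv = np.ones(vals.shape, dtype=np.int32)  # degenerate range -> lowest bin
    levels[sub_m] = lv
    return DiscretizedVOI(levels=levels, n_levels=n_levels, spacing=volume.spacing)


# ---------------------------------------------------------------------------
# Co-occurrence matrix
# ---------------------------------------------------------------------------

def build_cm(d: DiscretizedVOI) -> CooccurrenceMatrix:
    """Accumulate ordered pairs of 26-adjacent masked voxels into one matrix.

    Every distance-1 offset (13 directions and their opposites) contributes;
    pairs with either voxel outside the mask are ignored.  The result is
    symmetric by construction and normalized to sum 1.
    """
    L = d.levels
    n = d.n_levels
    flat: list[np.ndarray] = []
    for dx, dy, dz in DIRECTIONS_13:
        sa = tuple(slice(max(0, o), L.shape[k] + min(0, o)) for k, o in enumerate((dx, dy, dz)))
        sb = tuple(slice(max(0, -o), L.shape[k] + min(0, -o)) for k, o in enumerate((dx, dy, dz)))
        a, b = L[sa], L[sb]
        valid = (a > 0) & (b > 0)
        av, bv = a[valid] - 1, b[valid] - 1
        flat.append(av * n + bv)
        flat.append(bv * n + av)  # the opposite offset
    idx = np.concatenate(flat)
    counts = np.bincount(idx, minlength=n * n).reshape(n, n)
    total = int(counts.sum())
    if total == 0:
        raise EmptySegmentationError("no adjacent in-mask voxel pairs; texture undefined")
    return CooccurrenceMatrix(matrix=counts / total, pair_count=total)


def cm_features(cm: CooccurrenceMatrix) -> dict[str, float]:
    """Entropy, homogeneity, contrast, dissimilarity, uniformity of a CM.

    Entropy uses the natural logarithm with the convention 0*ln(0) = 0.
    """
    p = cm.matrix
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    diff = i - j
    pos = p > 0
    ent = float(-(p[pos] * np.log(p[pos])).sum())
    return {
        "ENT": ent,
        "HOM": float((p / (1.0 + diff**2)).sum()),
        "CON": float((p * diff**2).sum()),
        "DIS": float((p * np.abs(diff)).sum()),
        "UNI": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# Run-length matrix
# ---------------------------------------------------------------------------

def _shift(a: np.ndarray, d) -> np.ndarray:
    """``out[v] = a[v + d]``, zero/False where ``v + d`` leaves the grid."""
    out = np.zeros_like(a)
    src = tuple(slice(max(0, o), a.shape[k] + min(0, o)) for k, o in enumerate(d))
    dst = tuple(slice(max(0, -o), a.shape[k] + min(0, -o)) for k, o in enumerate(d))
    out[dst] = a[src]
    return out


def build_rlm(d: DiscretizedVOI) -> RunLengthMatrix:
    """Count maximal equal-level in-mask runs along the 13 directions.

    Out-of-mask voxels break runs (runs live strictly inside the tumor, no
    bridging); an isolated masked voxel is a run of length 1 in every
    direction, so each masked voxel belongs to exactly one run per
    direction.

    Per direction the runs are counted without walking lines: a voxel
    *starts* a run if its predecessor does not continue into it, and a run
    starting at ``v`` has length >= k+1 iff the level repeats along the
    next k steps — tracked with a shifted-AND recurrence, so the cost is a
    handful of vectorized passes per direction.
    """
    L = d.levels
    if not (L > 0).any():
        raise EmptySegmentationError("mask is empty")
    mask = L > 0
    n = d.n_levels
    per_length: dict[int, np.ndarray] = defaultdict(lambda: np.zeros(n, dtype=np.int64))
    for dvec in DIRECTIONS_13:
        cont = mask & (_shift(L, dvec) == L)  # run continues one step along dvec
        back = tuple(-o for o in dvec)
        starts = mask & ~_shift(cont, back)  # predecessor does not continue into v
        # ge[k] = per-level counts of runs of length >= k
        ge: list[np.ndarray] = []
        cur = starts
        reach = None  # reach[v]: the run level repeats for len(ge) steps from v
        while cur.any():
            ge.append(np.bincount(L[cur], minlength=n + 1)[1:])
            reach = cont if reach is None else (cont & _shift(reach, dvec))
            cur = starts & reach
        for k, counts in enumerate(ge):
            exact = counts - (ge[k + 1] if k + 1 < len(ge) else 0)
            per_length[k + 1] += exact
    m_max = max(per_length)
    matrix = np.zeros((n, m_max), dtype=np.int64)
    for length, counts in per_length.items():
        matrix[:, length - 1] = counts
    return RunLengthMatrix(matrix=matrix)


def rlm_features(r: RunLengthMatrix) -> dict[str, float]:
    """The eleven run-length features.

    ``i`` indexes gray level (1..N), ``j`` run length (1..M), ``n_r`` is
    the total number of runs.  RPC's denominator is ``sum RLM(i,j) * j``,
    the voxel-direction count.
    """
    R = r.matrix.astype(np.float64)
    n_r = R.sum()
    if n_r <= 0:
        raise EmptySegmentationError("run-length matrix is empty")
    n, m = R.shape
    i = np.arange(1, n + 1)[:, None].astype(np.float64)
    j = np.arange(1, m + 1)[None, :].astype(np.float64)
    row = R.sum(axis=1)  # runs per gray level
    col = R.sum(axis=0)  # runs per length
    return {
        "SRE": float((R / j**2).sum() / n_r),
        "LRE": float((R * j**2).sum() / n_r),
        "LGRE": float((R / i**2).sum() / n_r),
        "HGRE": float((R * i**2).sum() / n_r),
        "SRLGE": float((R / (i**2 * j**2)).sum() / n_r),
        "SRHGE": float((R * i**2 / j**2).sum() / n_r),
        "LRLGE": float((R * j**2 / i**2).sum() / n_r),
        "LRHGE": float((R * i**2 * j**2).sum() / n_r),
        "GLNU": float((row**2).sum() / n_r),
        "RLNU": float((col**2).sum() / n_r),
        "RPC": float(n_r / (R * j).sum()),
    }


# ---------------------------------------------------------------------------
# Gradient energies
# ---------------------------------------------------------------------------

def energy_features(volume: PETVolume, mask) -> dict[str, float]:
    """Specific and total energy from the raw SUV field.

    The SUV gradient is evaluated per masked voxel with central differences
    in mm, using a one-sided difference when one axis neighbor leaves the
    mask and 0 for that axis when both do.  Integrals are voxel sums times
    the voxel volume.
    """
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptySegmentationError("mask is empty")
    box = mask.box if isinstance(mask, TumorMask) else BoundingBox.from_mask(m)
    u = np.pad(volume.suv[box.slices], 1)
    msk = np.pad(m[box.slices], 1)
    suv_max = float(u[msk].max())
    if suv_max <= 0:
        raise ValueError("SUVmax is 0; energies undefined")

    grad_sq = np.zeros_like(u)
    for axis, h in enumerate(volume.spacing):
        fwd_m = np.roll(msk, -1, axis=axis)
        bwd_m = np.roll(msk, 1, axis=axis)
        fwd_u = np.roll(u, -1, axis=axis)
        bwd_u = np.roll(u, 1, axis=axis)
        g = np.where(
            fwd_m & bwd_m,
            (fwd_u - bwd_u) / (2.0 * h),
            np.where(fwd_m, (fwd_u - u) / h, np.where(bwd_m, (u - bwd_u) / h, 0.0)),
        )
        grad_sq += g**2

    dv = volume.voxel_volume_mm3
    grad_energy = float(np.sqrt((grad_sq[msk]).sum() * dv))
    u_norm = float(np.sqrt((u[msk] ** 2).sum() * dv))
    return {
        "SE": grad_energy / u_norm,
        "TE": grad_energy / suv_max,
    }


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

def extract_features(
    volume: PETVolume,
    mask: TumorMask,
    n_levels: int = 16,
    peak_masked_only: bool = False,
    discretization_bounds: tuple[float, float] | None = None,
) -> pd.Series:
    """All 23 per-scan variables: 5 SUV/volume metrics + 18 texture features.

    Energies are computed on the raw SUV field; CM/RLM features on the
    discretized VOI.  Deterministic: identical inputs give identical
    outputs.
    """
    met = metabolic_metrics(volume, mask, peak_masked_only=peak_masked_only)
    d = discretize_voi(volume, mask, n_levels=n_levels, bounds=discretization_bounds)
    feats: dict[str, float] = {
        "suv_max": met.suv_max,
        "suv_mean": met.suv_mean,
        "suv_peak": met.suv_peak,
        "mtv_cm3": met.mtv_cm3,
        "tlg": met.tlg,
    }
    feats.update(cm_features(build_cm(d)))
    feats.update(rlm_features(build_rlm(d)))
    feats.update(energy_features(volume, mask))
    return pd.Series({k: feats[k] for k in FEATURE_COLUMNS})
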