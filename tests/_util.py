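"""Shared helpers and independent brute-force oracles for the test suite.

The oracles here are deliberately written as plain enumeration loops
(voxel-by-voxel, line-by-line with itertools.groupby, breadth-first flood
fill), structurally unrelated to the package's vectorized implementations.
"""

from __future__ import annotations

from collections import defaultdict, deque
from itertools import groupby, product

import numpy as np
import pandas as pd

from petdyntex.cohort import PairedCohort
from petdyntex.io import FEATURE_COLUMNS, PETVolume

OFFSETS_26 = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
DIRS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]  # one per opposite pair


def make_volume(arr, spacing=(1.0, 1.0, 1.0), meta=None) -> PETVolume:
    return PETVolume(np.asarray(arr, dtype=float), spacing, meta)


def in_grid(p, shape) -> bool:
    return all(0 <= p[k] < shape[k] for k in range(3))


# ---------------------------------------------------------------------------
# texture oracles
# ---------------------------------------------------------------------------

def discretize_bruteforce(values, n_levels):
    """Per-value equal-width binning between min and max."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    out = []
    for s in values:
        if hi == lo:
            out.append(1)
        else:
            out.append(min(n_levels, int(np.floor(n_levels * (s - lo) / (hi - lo))) + 1))
    return np.array(out)


def cm_bruteforce(levels, n_levels):
    """Ordered-pair counts over all 26 offsets, then normalized."""
    levels = np.asarray(levels)
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for pos in product(*map(range, shape)):
        a = int(levels[pos])
        if a == 0:
            continue
        for off in OFFSETS_26:
            q = tuple(pos[k] + off[k] for k in range(3))
            if in_grid(q, shape):
                b = int(levels[q])
                if b > 0:
                    counts[a - 1, b - 1] += 1
    total = counts.sum()
    if total == 0:
        return counts.astype(float), 0
    return counts / total, int(total)


def rlm_bruteforce(levels, n_levels):
    """Line extraction + groupby run counting over the 13 directions."""
    levels = np.asarray(levels)
    shape = levels.shape
    runs: dict[tuple[int, int], int] = defaultdict(int)
    for d in DIRS_13:
        for start in product(*map(range, shape)):
            prev = tuple(start[k] - d[k] for k in range(3))
            if in_grid(prev, shape):
                continue  # not the first voxel of its line
            seq = []
            p = start
            while in_grid(p, shape):
                seq.append(int(levels[p]))
                p = tuple(p[k] + d[k] for k in range(3))
            for val, grp in groupby(seq):
                if val > 0:
                    runs[(val, len(list(grp)))] += 1
    m = max((length for _, length in runs), default=1)
    mat = np.zeros((n_levels, m), dtype=np.int64)
    for (val, length), c in runs.items():
        mat[val - 1, length - 1] = c
    return mat


def cm_features_bruteforce(p):
    """Independent double-loop evaluation of the five CM features."""
    n = p.shape[0]
    ent = hom = con = dis = uni = 0.0
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            if v > 0:
                ent -= v * np.log(v)
            hom += v / (1 + (i - j) ** 2)
            con += v * (i - j) ** 2
            dis += v * abs(i - j)
            uni += v**2
    return {"ENT": ent, "HOM": hom, "CON": con, "DIS": dis, "UNI": uni}


def rlm_features_bruteforce(mat):
    """Independent double-loop evaluation of the eleven RLM features."""
    n, m = mat.shape
    n_r = mat.sum()
    acc = dict.fromkeys(
        ["SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE", "RPC"], 0.0
    )
    denom_rpc = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            r = mat[i - 1, j - 1]
            acc["SRE"] += r / j**2
            acc["LRE"] += r * j**2
            acc["LGRE"] += r / i**2
            acc["HGRE"] += r * i**2
            acc["SRLGE"] += r / (i**2 * j**2)
            acc["SRHGE"] += r * i**2 / j**2
            acc["LRLGE"] += r * j**2 / i**2
            acc["LRHGE"] += r * i**2 * j**2
            denom_rpc += r * j
    out = {k: v / n_r for k, v in acc.items() if k != "RPC"}
    out["GLNU"] = sum(mat[i, :].sum() ** 2 for i in range(n)) / n_r
    out["RLNU"] = sum(mat[:, j].sum() ** 2 for j in range(m)) / n_r
    out["RPC"] = n_r / denom_rpc
    return out


def random_discrete_voi(rng, max_side=6, n_levels=16):
    """A random small DiscretizedVOI-style (levels, mask) pair."""
    shape = tuple(int(rng.integers(1, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    levels = np.where(mask, rng.integers(1, n_levels + 1, size=shape), 0)
    return levels.astype(np.int32)


# ---------------------------------------------------------------------------
# segmentation / metrics oracles
# ---------------------------------------------------------------------------

def threshold_bruteforce(suv, box_slices, fraction):
    """Per-voxel comparison loop against fraction * box max."""
    mask = np.zeros(suv.shape, dtype=bool)
    sub = suv[box_slices]
    thr = fraction * sub.max()
    offs = tuple(s.start for s in box_slices)
    for pos in product(*(range(s.stop - s.start) for s in box_slices)):
        g = tuple(offs[k] + pos[k] for k in range(3))
        if suv[g] >= thr:
            mask[g] = True
    return mask


def flood_fill_open_region(below, shape):
    """BFS from all box faces over sub-threshold voxels, 26-connectivity.

    Returns the set of reachable (open) voxels; enclosed = below & ~open.
    """
    below = np.asarray(below)
    seen = np.zeros(shape, dtype=bool)
    q = deque()
    for pos in product(*map(range, shape)):
        if any(pos[k] in (0, shape[k] - 1) for k in range(3)) and below[pos]:
            seen[pos] = True
            q.append(pos)
    while q:
        p = q.popleft()
        for off in OFFSETS_26:
            r = tuple(p[k] + off[k] for k in range(3))
            if in_grid(r, shape) and below[r] and not seen[r]:
                seen[r] = True
                q.append(r)
    return seen


def components_bruteforce(mask):
    """26-connected components by BFS; list of voxel-index-set frozensets."""
    mask = np.asarray(mask)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for pos in product(*map(range, mask.shape)):
        if mask[pos] and not seen[pos]:
            comp = []
            seen[pos] = True
            q = deque([pos])
            while q:
                p = q.popleft()
                comp.append(p)
                for off in OFFSETS_26:
                    r = tuple(p[k] + off[k] for k in range(3))
                    if in_grid(r, mask.shape) and mask[r] and not seen[r]:
                        seen[r] = True
                        q.append(r)
            comps.append(frozenset(comp))
    return comps


def suv_peak_bruteforce(suv, mask, masked_only=False):
    """Exhaustive sliding 3x3x3 cube means centered on masked voxels."""
    best = -np.inf
    shape = suv.shape
    for pos in product(*map(range, shape)):
        if not mask[pos]:
            continue
        vals = []
        for off in product((-1, 0, 1), repeat=3):
            q = tuple(pos[k] + off[k] for k in range(3))
            if in_grid(q, shape) and (mask[q] if masked_only else True):
                vals.append(suv[q])
        best = max(best, float(np.mean(vals)))
    return best


# ---------------------------------------------------------------------------
# cohort helper
# ---------------------------------------------------------------------------

def random_cohort(n, rng, jitter=0.0):
    """A feature-table cohort with random positive entries.

    ``jitter`` adds independent noise to PET2 relative to PET1 (0 gives
    identical timepoints).
    """
    rows = []
    for k in range(n):
        base = {c: float(rng.uniform(0.5, 10.0)) for c in FEATURE_COLUMNS}
        for tp in ("PET1", "PET2"):
            row = {"patient_id": f"P{k:03d}", "timepoint": tp}
            row.update(
                {
                    c: v + (float(rng.normal(0, jitter)) if tp == "PET2" and jitter else 0.0)
                    for c, v in base.items()
                }
            )
            rows.append(row)
    return PairedCohort(pd.DataFrame(rows))
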