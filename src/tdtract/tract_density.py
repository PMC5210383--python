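"""Tract-density (TD) maps and tendon segmentation.

TD is the number of distinct streamlines crossing each voxel under dense
whole-volume seeding, normalized to the mean TD over the foreground
(tissue) region so that muscle sits at TD ~ 1.  Voxels whose normalized TD
exceeds a threshold (default 1.5) are tendinous: streamlines from both
sides of an aponeurosis funnel into it and run along it, so its tract
count is well above the muscle plateau.

Counting is per streamline, not per point: each streamline increments a
voxel at most once, however many of its points fall inside, and the voxels
a segment crosses are found with an exact Amanatides-Woo 3D line walk, so
the map is independent of the tracking step length.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from tdtract.dwi_data import ScalarMap
from tdtract.tracking import Tractogram


@dataclasses.dataclass
class TractDensityMap:
    """Normalized tract-density map plus the raw counts behind it."""

    normalized: ScalarMap
    raw_counts: np.ndarray
    normalization_constant: float  # mean raw TD over the reference region
    reference_mask: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.normalized.values


@njit(cache=True)
def _accumulate_counts(points, offsets, Minv, t, shape, counts, stamp):  # pragma: no cover
    nx, ny, nz = shape[0], shape[1], shape[2]
    n_stream = offsets.shape[0] - 1
    for s in range(n_stream):
        lo, hi = offsets[s], offsets[s + 1]
        if hi - lo == 0:
            continue
        sid = s + 1
        # first point
        px, py, pz = points[lo, 0] - t[0], points[lo, 1] - t[1], points[lo, 2] - t[2]
        v0x = Minv[0, 0] * px + Minv[0, 1] * py + Minv[0, 2] * pz
        v0y = Minv[1, 0] * px + Minv[1, 1] * py + Minv[1, 2] * pz
        v0z = Minv[2, 0] * px + Minv[2, 1] * py + Minv[2, 2] * pz
        ix = int(np.floor(v0x + 0.5))
        iy = int(np.floor(v0y + 0.5))
        iz = int(np.floor(v0z + 0.5))
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz and stamp[ix, iy, iz] != sid:
            stamp[ix, iy, iz] = sid
            counts[ix, iy, iz] += 1
        for k in range(lo, hi - 1):
            qx = points[k + 1, 0] - t[0]
            qy = points[k + 1, 1] - t[1]
            qz = points[k + 1, 2] - t[2]
            v1x = Minv[0, 0] * qx + Minv[0, 1] * qy + Minv[0, 2] * qz
            v1y = Minv[1, 0] * qx + Minv[1, 1] * qy + Minv[1, 2] * qz
            v1z = Minv[2, 0] * qx + Minv[2, 1] * qy + Minv[2, 2] * qz
            dx, dy, dz = v1x - v0x, v1y - v0y, v1z - v0z
            jx = int(np.floor(v1x + 0.5))
            jy = int(np.floor(v1y + 0.5))
            jz = int(np.floor(v1z + 0.5))
            # Amanatides-Woo walk from (ix,iy,iz) to (jx,jy,jz); voxel i
            # spans [i - 0.5, i + 0.5) in continuous voxel coordinates
            sx = 1 if dx > 0 else -1
            sy = 1 if dy > 0 else -1
            sz = 1 if dz > 0 else -1
            big = 1e30
            tmx = ((ix + 0.5 * sx) - v0x) / dx if dx != 0.0 else big
            tmy = ((iy + 0.5 * sy) - v0y) / dy if dy != 0.0 else big
            tmz = ((iz + 0.5 * sz) - v0z) / dz if dz != 0.0 else big
            tdx = abs(1.0 / dx) if dx != 0.0 else big
            tdy = abs(1.0 / dy) if dy != 0.0 else big
            tdz = abs(1.0 / dz) if dz != 0.0 else big
            guard = 0
            max_guard = abs(jx - ix) + abs(jy - iy) + abs(jz - iz) + 3
            while (ix != jx or iy != jy or iz != jz) and guard < max_guard:
                guard += 1
                if tmx <= tmy and tmx <= tmz:
                    ix += sx
                    tmx += tdx
                elif tmy <= tmz:
                    iy += sy
                    tmy += tdy
                else:
                    iz += sz
                    tmz += tdz
                if (
                    0 <= ix < nx
                    and 0 <= iy < ny
                    and 0 <= iz < nz
                    and stamp[ix, iy, iz] != sid
                ):
                    stamp[ix, iy, iz] = sid
                    counts[ix, iy, iz] += 1
            ix, iy, iz = jx, jy, jz
            v0x, v0y, v0z = v1x, v1y, v1z


def compute_td(
    tractogram: Tractogram,
    reference_mask: np.ndarray,
    affine: np.ndarray,
) -> TractDensityMap:
    """Raw per-voxel streamline counts and the normalized TD map.

    ``reference_mask`` is the foreground region (e.g. voxels with nonzero
    b=0 signal): normalization divides by the mean raw count over it, and
    the map's mean over it is exactly 1.
    """
    if len(tractogram) == 0:
        raise ValueError("empty tractogram: TD normalization is undefined")
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    shape = reference_mask.shape
    A = np.asarray(affine, dtype=float)
    Minv = np.ascontiguousarray(np.linalg.inv(A[:3, :3]))
    t = np.ascontiguousarray(A[:3, 3])
    counts = np.zeros(shape, dtype=np.int64)
    stamp = np.zeros(shape, dtype=np.int64)
    _accumulate_counts(
        np.ascontiguousarray(tractogram.points),
        np.ascontiguousarray(tractogram.offsets),
        Minv,
        t,
        np.asarray(shape, dtype=np.int64),
        counts,
        stamp,
    )
    norm = float(counts[reference_mask].mean())
    if norm == 0:
        raise ValueError("no streamline crosses the reference region")
    normalized = ScalarMap(counts / norm, A, "TD")
    return TractDensityMap(normalized, counts, norm, reference_mask)


def tendon_mask(td: TractDensityMap, threshold: float = 1.5) -> np.ndarray:
    """Boolean mask of tendinous voxels: normalized TD strictly above
    ``threshold``."""
    return td.values > threshold
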