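"""Deterministic streamline tractography with pluggable stopping criteria.

Propagation is fixed-step Euler along the principal eigenvector of the
trilinearly interpolated diffusion tensor; the eigenvector sign is aligned
with the previous step direction (the tensor field itself is antipodally
symmetric).  Stopping criteria: FA window, maximum angle change per step,
tract-density threshold (nearest-voxel lookup), muscle-boundary mask,
volume edge, and a safety length cap.  Tracks are seeded bidirectionally
and the two half-tracks concatenated.

All positions are world mm; the tensor grid's affine maps voxel indices to
world coordinates.  The tracker is batch-vectorized: every seed propagates
simultaneously, which keeps whole-volume runs (~1e5-1e6 seeds) tractable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from tdtract.dwi_data import ScalarMap
from tdtract.tensor_fit import TensorVolume, components_to_matrices

#: termination reason codes (index into this tuple is what gets stored)
REASONS = (
    "in_progress",
    "fa_out_of_range",
    "angle_exceeded",
    "td_exceeded",
    "left_mask",
    "left_volume",
    "max_length",
    "seed_invalid",
)
_REASON_CODE = {name: i for i, name in enumerate(REASONS)}


@dataclasses.dataclass
class StoppingConfig:
    """Stopping criteria and integration parameters for one tracking pass.

    Defaults are the whole-volume first-pass settings: FA window 0.1-0.7,
    20 degrees per step, 1 mm steps, 2 mm minimum length.  The per-muscle
    second pass uses 10 degrees, 20 mm minimum length, a finer step and the
    TD threshold of 1.5.
    """

    fa_range: tuple[float, float] = (0.1, 0.7)
    max_angle_per_step: float = 20.0  # degrees
    step_length: float = 1.0  # mm
    min_length: float = 2.0  # mm
    max_length: float = 500.0  # mm, safety cap against runaway loops
    td_threshold: float | None = None  # normalized TD above which tracking halts
    td_map: ScalarMap | None = None
    boundary_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo, hi = self.fa_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("fa_range must satisfy 0 <= low < high <= 1")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.min_length < 0:
            raise ValueError("min_length must be nonnegative")
        if self.max_length <= 0:
            raise ValueError("max_length must be positive")
        if self.td_threshold is not None and self.td_threshold <= 1.0:
            raise ValueError(
                "td_threshold must exceed 1 (normalized muscle TD is ~1)"
            )
        if (self.td_threshold is None) != (self.td_map is None):
            raise ValueError("td_map must be given exactly when td_threshold is set")

    def to_dict(self) -> dict:
        return {
            "fa_range": list(self.fa_range),
            "max_angle_per_step": self.max_angle_per_step,
            "step_length": self.step_length,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "td_threshold": self.td_threshold,
            "boundary_mask": self.boundary_mask is not None,
        }


@dataclasses.dataclass
class Streamline:
    """One streamline: ordered world-space points plus per-end termination."""

    points: np.ndarray  # (n, 3) mm
    reason_start: str
    reason_end: str

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


class Tractogram:
    """Streamline collection stored as one flat point array plus offsets.

    ``points[offsets[i]:offsets[i + 1]]`` are the points of streamline i.
    ``reasons`` is an (n, 2) uint8 array of termination codes (start end),
    indices into :data:`REASONS`.
    """

    def __init__(
        self,
        points: np.ndarray,
        offsets: np.ndarray,
        reasons: np.ndarray,
        config: StoppingConfig | None = None,
        seeding: dict | None = None,
        diagnostics: dict | None = None,
    ) -> None:
        points = np.asarray(points)
        if points.dtype not in (np.float32, np.float64):
            points = points.astype(np.float64)
        self.points = points.reshape(-1, 3)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.reasons = np.asarray(reasons, dtype=np.uint8).reshape(-1, 2)
        self.config = config
        self.seeding = seeding or {}
        self.diagnostics = diagnostics or {}
        if self.offsets[0] != 0 or self.offsets[-1] != len(self.points):
            raise ValueError("offsets do not span the point array")
        if len(self.reasons) != len(self):
            raise ValueError("reasons length does not match streamline count")

    def __len__(self) -> int:
        return len(self.offsets) - 1

    def __getitem__(self, i: int) -> Streamline:
        sl = self.points[self.offsets[i] : self.offsets[i + 1]]
        return Streamline(sl, REASONS[self.reasons[i, 0]], REASONS[self.reasons[i, 1]])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def lengths(self) -> np.ndarray:
        """Streamline lengths in mm (sum of segment norms, vectorized)."""
        if len(self) == 0 or len(self.points) == 0:
            return np.zeros(len(self))
        # chunked so large float32 tractograms do not allocate big transients
        P = len(self.points)
        seg = np.empty(P - 1, dtype=np.float64)
        step = 4_000_000
        for lo in range(0, P - 1, step):
            hi = min(lo + step, P - 1)
            d = (
                self.points[lo + 1 : hi + 1].astype(np.float64)
                - self.points[lo:hi].astype(np.float64)
            )
            seg[lo:hi] = np.linalg.norm(d, axis=1)
        padded = np.append(seg, 0.0)
        sums = np.add.reduceat(padded, self.offsets[:-1])
        # subtract the spurious segment bridging consecutive streamlines
        return sums - padded[self.offsets[1:] - 1]

    def select(self, keep: np.ndarray) -> "Tractogram":
        """Sub-tractogram of the streamlines flagged in the boolean ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        counts = np.diff(self.offsets)[keep]
        point_mask = np.repeat(keep, np.diff(self.offsets))
        return Tractogram(
            self.points[point_mask],
            np.concatenate([[0], np.cumsum(counts)]),
            self.reasons[keep],
            self.config,
            dict(self.seeding),
            dict(self.diagnostics),
        )


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def seed_grid(mask: np.ndarray, affine: np.ndarray, spacing) -> np.ndarray:
    """Regular world-space seed lattice clipped to a voxel mask.

    The lattice is anchored at the volume's outer corner (voxel index -0.5)
    plus half a spacing, i.e. seeds sit at corner + (k + 1/2) * spacing.
    A seed is kept when its nearest voxel is inside the mask.  Ordering is
    lexicographic in the lattice indices, hence deterministic.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(spacing <= 0):
        raise ValueError("seed spacing must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("seed mask is empty; no seeds generated", stacklevel=2)
        return np.zeros((0, 3))
    A = np.asarray(affine, dtype=float)
    M, t = A[:3, :3], A[:3, 3]
    shape = np.array(mask.shape)
    corner = M @ (-0.5 * np.ones(3)) + t
    far = M @ (shape - 0.5) + t
    lo, hi = np.minimum(corner, far), np.maximum(corner, far)
    axes = []
    for d in range(3):
        n_d = int(np.floor((hi[d] - lo[d]) / spacing[d]))
        if n_d >= 1:
            axes.append(lo[d] + (np.arange(n_d) + 0.5) * spacing[d])
        else:  # spacing exceeds the extent: one seed at the volume center
            axes.append(np.array([(lo[d] + hi[d]) / 2.0]))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    vox = np.linalg.solve(M, (pts - t).T).T
    idx = np.round(vox).astype(int)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    keep = np.zeros(len(pts), dtype=bool)
    keep[inside] = mask[tuple(idx[inside].T)]
    return pts[keep]


def erode_to_fraction(mask: np.ndarray, fraction: float) -> np.ndarray:
    """Repeated one-voxel 6-connected erosion until the voxel count first
    drops to at most ``fraction`` of the original; never returns empty."""
    from scipy.ndimage import binary_erosion, generate_binary_structure

    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    n0 = int(mask.sum())
    if n0 == 0:
        raise ValueError("cannot erode an empty mask")
    structure = generate_binary_structure(3, 1)
    current = mask
    target = fraction * n0
    while current.sum() > target:
        nxt = binary_erosion(current, structure=structure)
        if not nxt.any():
            warnings.warn(
                "erosion would empty the mask before reaching the target "
                "fraction; returning the last nonempty mask",
                stacklevel=2,
            )
            break
        current = nxt
    return current


# ---------------------------------------------------------------------------
# interpolation helpers
# ---------------------------------------------------------------------------

class _FieldSampler:
    """Trilinear / nearest sampling of grids in world coordinates."""

    def __init__(self, affine: np.ndarray, shape: tuple[int, int, int]) -> None:
        A = np.asarray(affine, dtype=float)
        self.Minv = np.linalg.inv(A[:3, :3])
        self.t = A[:3, 3]
        self.shape = np.asarray(shape)

    def to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return (self.Minv @ (pts - self.t).T).T

    def inside(self, pts: np.ndarray) -> np.ndarray:
        """Inside the trilinear-interpolation domain (between edge centers)."""
        v = self.to_voxel(pts)
        return np.all((v >= 0.0) & (v <= self.shape - 1), axis=1)

    def trilinear(self, field: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """Sample ``field`` (3D or 4D multi-channel) at world points; points
        must be inside the domain (clipped defensively)."""
        v = self.to_voxel(pts)
        v = np.clip(v, 0.0, self.shape - 1.0)
        i0 = np.minimum(v.astype(int), self.shape - 2)
        i0 = np.maximum(i0, 0)
        frac = v - i0
        out = None
        for dx in (0, 1):
            wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
            for dy in (0, 1):
                wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
                for dz in (0, 1):
                    wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                    w = wx * wy * wz
                    vals = field[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                    term = vals * (w[:, None] if vals.ndim == 2 else w)
                    out = term if out is None else out + term
        return out

    def nearest(self, field: np.ndarray, pts: np.ndarray, fill=0):
        v = np.round(self.to_voxel(pts)).astype(int)
        ok = np.all((v >= 0) & (v < self.shape), axis=1)
        out = np.full(len(pts), fill, dtype=field.dtype)
        vv = v[ok]
        out[ok] = field[vv[:, 0], vv[:, 1], vv[:, 2]]
        return out


def _principal_dirs(components: np.ndarray) -> np.ndarray:
    """Principal eigenvectors of (N, 6) tensor components, batched.

    Closed-form trigonometric eigensolver for symmetric 3x3 matrices
    (an order of magnitude faster than LAPACK at this size); near-degenerate
    rows fall back to ``np.linalg.eigh``.
    """
    c = np.asarray(components, dtype=float)
    a00, a11, a22, a01, a02, a12 = (c[:, i] for i in range(6))
    p1 = a01**2 + a02**2 + a12**2
    q = (a00 + a11 + a22) / 3.0
    p2 = (a00 - q) ** 2 + (a11 - q) ** 2 + (a22 - q) ** 2 + 2.0 * p1
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    safe_p = np.where(p > 0, p, 1.0)
    b00, b11, b22 = (a00 - q) / safe_p, (a11 - q) / safe_p, (a22 - q) / safe_p
    b01, b02, b12 = a01 / safe_p, a02 / safe_p, a12 / safe_p
    detb = (
        b00 * (b11 * b22 - b12**2)
        - b01 * (b01 * b22 - b12 * b02)
        + b02 * (b01 * b12 - b11 * b02)
    )
    phi = np.arccos(np.clip(detb / 2.0, -1.0, 1.0)) / 3.0
    lam1 = q + 2.0 * p * np.cos(phi)

    # eigenvector from the two largest-norm cross products of (A - lam1 I)
    m00, m11, m22 = a00 - lam1, a11 - lam1, a22 - lam1
    r0 = np.stack([m00, a01, a02], axis=1)
    r1 = np.stack([a01, m11, a12], axis=1)
    r2 = np.stack([a02, a12, m22], axis=1)
    cands = np.stack(
        [np.cross(r0, r1), np.cross(r0, r2), np.cross(r1, r2)], axis=1
    )  # (N, 3, 3)
    norms = np.linalg.norm(cands, axis=2)
    best = norms.argmax(axis=1)
    rows = np.arange(len(c))
    v = cands[rows, best]
    n = norms[rows, best]

    scale = np.abs(c).max(axis=1) + 1e-300
    bad = (n < 1e-9 * scale**2) | (p <= 0)
    ok = ~bad
    out = np.empty((len(c), 3))
    out[ok] = v[ok] / n[ok, None]
    if bad.any():
        mats = components_to_matrices(c[bad])
        _, vecs = np.linalg.eigh(mats)
        out[bad] = vecs[..., :, 2]
    return out


# ---------------------------------------------------------------------------
# the tracker
# ---------------------------------------------------------------------------

def track(
    seeds: np.ndarray,
    tensors: TensorVolume,
    fa: ScalarMap,
    config: StoppingConfig,
    seeding: dict | None = None,
    chunk_size: int = 120_000,
) -> Tractogram:
    """Propagate every seed bidirectionally and assemble a tractogram.

    A step from p to p + h * d is accepted only if (a) FA at the new point
    is inside ``fa_range``, (b) the angle between d and the previous step
    direction is at most ``max_angle_per_step``, (c) normalized TD at the
    new point does not exceed ``td_threshold`` (when active, nearest-voxel
    lookup), (d) the new point lies inside ``boundary_mask`` (when active)
    and inside the volume, and (e) the total length stays within
    ``max_length``.  Streamlines shorter than ``min_length`` are discarded
    (counted in ``diagnostics``).

    Seeds are processed in chunks of ``chunk_size`` to bound memory on
    whole-volume runs; chunking does not change the result.
    """
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 3)
    if fa.values.shape != tensors.shape:
        raise ValueError("FA map grid does not match tensor grid")
    n = len(seeds)
    parts = []
    diagnostics = {"n_seeds": n, "n_rejected_seeds": 0, "n_below_min_length": 0}
    for lo in range(0, max(n, 1), chunk_size):
        chunk = seeds[lo : lo + chunk_size]
        if len(chunk) == 0:
            break
        pts, offs, reas, diag = _track_chunk(chunk, tensors, fa, config)
        parts.append((pts, offs, reas))
        diagnostics["n_rejected_seeds"] += diag["n_rejected_seeds"]
        diagnostics["n_below_min_length"] += diag["n_below_min_length"]

    if parts:
        points = np.concatenate([p for p, _, _ in parts])
        counts = np.concatenate([np.diff(o) for _, o, _ in parts])
        offsets = np.concatenate([[0], np.cumsum(counts)])
        reasons = np.concatenate([r for _, _, r in parts])
    else:
        points = np.zeros((0, 3), dtype=np.float32)
        offsets = np.zeros(1, dtype=np.int64)
        reasons = np.zeros((0, 2), dtype=np.uint8)
    return Tractogram(
        points, offsets, reasons, config=config,
        seeding=seeding or {}, diagnostics=diagnostics,
    )


def _track_chunk(
    seeds: np.ndarray,
    tensors: TensorVolume,
    fa: ScalarMap,
    config: StoppingConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    sampler = _FieldSampler(tensors.affine, tensors.shape)
    n = len(seeds)
    cos_limit = np.cos(np.deg2rad(config.max_angle_per_step))
    h = config.step_length
    max_steps = int(np.ceil(config.max_length / (2 * h))) + 1  # per half-track
    tensor_field = tensors.components

    td_values = config.td_map.values if config.td_map is not None else None
    bmask = (
        np.asarray(config.boundary_mask, dtype=bool)
        if config.boundary_mask is not None
        else None
    )

    def point_ok(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(acceptable, reason_code) for candidate points."""
        ok = sampler.inside(pts)
        reason = np.where(ok, 0, _REASON_CODE["left_volume"]).astype(np.uint8)
        fa_vals = np.zeros(len(pts))
        fa_vals[ok] = sampler.trilinear(fa.values, pts[ok])
        fa_bad = ok & ~(
            (fa_vals >= config.fa_range[0]) & (fa_vals <= config.fa_range[1])
        )
        reason[fa_bad] = _REASON_CODE["fa_out_of_range"]
        ok &= ~fa_bad
        if td_values is not None:
            td = sampler.nearest(td_values, pts, fill=np.inf)
            td_bad = ok & (td > config.td_threshold)
            reason[td_bad] = _REASON_CODE["td_exceeded"]
            ok &= ~td_bad
        if bmask is not None:
            inmask = sampler.nearest(bmask, pts, fill=False)
            m_bad = ok & ~inmask.astype(bool)
            reason[m_bad] = _REASON_CODE["left_mask"]
            ok &= ~m_bad
        return ok, reason

    # --- seed validation and initial directions -----------------------------
    seed_ok, _ = point_ok(seeds)
    init_dir = np.zeros((n, 3))
    if seed_ok.any():
        comp = sampler.trilinear(tensor_field, seeds[seed_ok])
        init_dir[seed_ok] = _principal_dirs(comp)
    n_rejected_seeds = int((~seed_ok).sum())

    def propagate(direction_sign: float) -> tuple[list, np.ndarray, np.ndarray]:
        """One half-track per seed; returns (step_records, counts, reasons)."""
        records: list[tuple[np.ndarray, np.ndarray]] = []
        counts = np.zeros(n, dtype=np.int64)
        reasons = np.full(n, _REASON_CODE["seed_invalid"], dtype=np.uint8)
        active = np.flatnonzero(seed_ok)
        if len(active) == 0:
            return records, counts, reasons
        reasons[active] = _REASON_CODE["in_progress"]
        pos = seeds[active].copy()
        prev_dir = direction_sign * init_dir[active]
        cur_dir = prev_dir.copy()
        for step in range(max_steps):
            if step > 0:
                comp = sampler.trilinear(tensor_field, pos)
                d = _principal_dirs(comp)
                dots = np.einsum("ij,ij->i", d, prev_dir)
                d *= np.where(dots < 0, -1.0, 1.0)[:, None]
                cosang = np.abs(dots)
                # exact 90 degrees between consecutive directions: terminate
                angle_ok = cosang >= cos_limit
                cur_dir = d
            else:
                angle_ok = np.ones(len(active), dtype=bool)

            cand = pos + h * cur_dir
            ok, reason = point_ok(cand)
            # length cap applies to the full (bidirectional) track
            too_long = (step + 1) * h > config.max_length / 2.0
            if too_long:
                reason[:] = _REASON_CODE["max_length"]
                ok[:] = False
            reason[~angle_ok] = _REASON_CODE["angle_exceeded"]
            ok &= angle_ok

            stopped = ~ok
            reasons[active[stopped]] = reason[stopped]
            if ok.any():
                records.append(
                    (active[ok].astype(np.int32), cand[ok].astype(np.float32))
                )
                counts[active[ok]] += 1
            active = active[ok]
            if len(active) == 0:
                break
            pos = cand[ok]
            prev_dir = cur_dir[ok]
        else:
            reasons[active] = _REASON_CODE["max_length"]
        return records, counts, reasons

    rec_b, counts_b, reasons_b = propagate(-1.0)  # backward half
    rec_f, counts_f, reasons_f = propagate(+1.0)  # forward half

    # --- assemble kept streamlines only: reversed backward + seed + forward --
    total = np.where(seed_ok, counts_b + counts_f + 1, 0)
    keep = (total > 0) & ((total - 1) * h >= config.min_length)
    n_below = int(((total > 0) & ~keep).sum())

    kept_total = total[keep]
    offsets = np.concatenate([[0], np.cumsum(kept_total)])
    # per-original-seed start index into the kept flat array (or -1)
    start = np.full(n, -1, dtype=np.int64)
    start[keep] = offsets[:-1]
    flat = np.empty((offsets[-1], 3), dtype=np.float32)
    kept_idx = np.flatnonzero(keep)
    flat[start[kept_idx] + counts_b[kept_idx]] = seeds[kept_idx]
    for k, (ids, pts) in enumerate(rec_b):
        sel = keep[ids]
        flat[start[ids[sel]] + counts_b[ids[sel]] - 1 - k] = pts[sel]
    for k, (ids, pts) in enumerate(rec_f):
        sel = keep[ids]
        flat[start[ids[sel]] + counts_b[ids[sel]] + 1 + k] = pts[sel]
    reasons = np.stack([reasons_b[keep], reasons_f[keep]], axis=1)
    diag = {"n_rejected_seeds": n_rejected_seeds, "n_below_min_length": n_below}
    return flat, offsets, reasons, diag


def fa_only_track(
    seeds: np.ndarray,
    tensors: TensorVolume,
    fa: ScalarMap,
    config: StoppingConfig | None = None,
    fa_range: tuple[float, float] = (0.15, 0.65),
) -> Tractogram:
    """Comparison method 1: FA window as the sole tissue criterion
    (0.15-0.65 by default); no TD threshold, no boundary mask."""
    base = config or StoppingConfig()
    cfg = dataclasses.replace(
        base, fa_range=fa_range, td_threshold=None, td_map=None, boundary_mask=None
    )
    return track(seeds, tensors, fa, cfg, seeding={"mode": "fa_only"})


def boundary_track(
    seeds: np.ndarray,
    tensors: TensorVolume,
    fa: ScalarMap,
    muscle_mask: np.ndarray,
    config: StoppingConfig | None = None,
) -> Tractogram:
    """Comparison method 2: halt at the segmented muscle boundary."""
    base = config or StoppingConfig()
    cfg = dataclasses.replace(
        base, td_threshold=None, td_map=None, boundary_mask=np.asarray(muscle_mask)
    )
    return track(seeds, tensors, fa, cfg, seeding={"mode": "boundary"})


# ---------------------------------------------------------------------------
# I/O: TrackVis .trk plus a JSON provenance sidecar
# ---------------------------------------------------------------------------

def write_trk(tractogram: Tractogram, reference_affine: np.ndarray, shape, path) -> None:
    import nibabel as nib

    streams = [
        tractogram.points[tractogram.offsets[i] : tractogram.offsets[i + 1]]
        for i in range(len(tractogram))
    ]
    nt = nib.streamlines.Tractogram(streams, affine_to_rasmm=np.eye(4))
    header = {
        "voxel_to_rasmm": np.asarray(reference_affine, dtype=np.float32),
        "voxel_sizes": np.linalg.norm(reference_affine[:3, :3], axis=0),
        "dimensions": np.asarray(shape, dtype=np.int16),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(nt, str(path), header=header)
    sidecar = {
        "config": tractogram.config.to_dict() if tractogram.config else None,
        "seeding": tractogram.seeding,
        "diagnostics": tractogram.diagnostics,
        "reasons": tractogram.reasons.tolist(),
        "reason_names": list(REASONS),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_trk(path) -> Tractogram:
    import nibabel as nib

    trk = nib.streamlines.load(str(path))
    streams = [np.asarray(s) for s in trk.tractogram.streamlines]
    counts = np.array([len(s) for s in streams], dtype=np.int64)
    points = (
        np.concatenate(streams, axis=0) if streams else np.zeros((0, 3))
    )
    offsets = np.concatenate([[0], np.cumsum(counts)])
    sidecar_path = Path(str(path) + ".json")
    reasons = np.zeros((len(streams), 2), dtype=np.uint8)
    seeding, diagnostics = {}, {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        if meta.get("reasons"):
            reasons = np.asarray(meta["reasons"], dtype=np.uint8)
        seeding = meta.get("seeding", {})
        diagnostics = meta.get("diagnostics", {})
    return Tractogram(points, offsets, reasons, None, seeding, diagnostics)
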