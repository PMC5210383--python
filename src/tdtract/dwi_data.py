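"""Data model and I/O for diffusion volumes, gradient tables, labels and SNR.

Conventions
-----------
* Voxel indices are 0-based.  World coordinates are millimetres, obtained
  from voxel indices through the NIfTI affine (``world = A @ [i, j, k, 1]``).
* Gradient tables use the FSL dialect: ``bvec`` is 3 rows x N columns in the
  image coordinate frame, ``bval`` is a single row of N values in s/mm^2.
* b-values below ``B0_THRESHOLD`` (50 s/mm^2) are treated as b = 0.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

B0_THRESHOLD = 50.0  # s/mm^2; anything below counts as an unweighted volume


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GradientTable:
    """Diffusion sensitization directions and b-values.

    Parameters
    ----------
    directions : (N, 3) float array
        Unit gradient directions; rows with b = 0 may be zero vectors.
    bvalues : (N,) float array
        b-values in s/mm^2.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self) -> None:
        directions = np.asarray(self.directions, dtype=float)
        bvalues = np.asarray(self.bvalues, dtype=float)
        if directions.ndim != 2 or directions.shape[1] != 3:
            raise ValueError(f"directions must be (N, 3), got {directions.shape}")
        if bvalues.shape != (directions.shape[0],):
            raise ValueError("bvalues length must match number of directions")
        b0 = bvalues < B0_THRESHOLD
        if not b0.any():
            raise ValueError("gradient table needs at least one b=0 entry")
        dwi = ~b0
        norms = np.linalg.norm(directions[dwi], axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero gradient vector on a diffusion-weighted row")
        if np.any(np.abs(norms - 1.0) > 1e-4):
            # re-normalize silently; scanners export with limited precision
            directions = directions.copy()
            directions[dwi] /= norms[:, None]
        # distinct non-b0 directions up to sign
        uniq = _count_distinct_directions(directions[dwi])
        if uniq < 6:
            raise ValueError(
                f"tensor fitting needs >=6 distinct gradient directions, got {uniq}"
            )
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "bvalues", bvalues)

    def __len__(self) -> int:
        return self.directions.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues < B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask


def _count_distinct_directions(dirs: np.ndarray, tol: float = 1e-6) -> int:
    """Count directions distinct up to antipodal symmetry."""
    seen: list[np.ndarray] = []
    for d in dirs:
        if not any(
            min(np.linalg.norm(d - s), np.linalg.norm(d + s)) < tol for s in seen
        ):
            seen.append(d)
    return len(seen)


@dataclasses.dataclass
class DWIStack:
    """4D diffusion-weighted image with voxel geometry.

    ``intensities`` is indexed (x, y, z, volume); ``affine`` maps 0-based
    voxel indices to world mm.
    """

    intensities: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be 4D (x, y, z, volume)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.intensities.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def b0_volume(self, table: GradientTable) -> np.ndarray:
        """Mean of the unweighted volumes."""
        if self.n_volumes != len(table):
            raise ValueError("gradient table does not match volume count")
        return self.intensities[..., table.b0_mask].mean(axis=3)


@dataclasses.dataclass
class LabelVolume:
    """Integer muscle-label volume; 0 = background, k > 0 = muscle k."""

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.affine = np.asarray(self.affine, dtype=float)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def present_labels(self) -> list[int]:
        return sorted(int(k) for k in np.unique(self.labels) if k > 0)


@dataclasses.dataclass
class ScalarMap:
    """3D scalar field (FA | MD | TD | SNR) sharing a parent grid/affine."""

    values: np.ndarray
    affine: np.ndarray
    quantity: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("scalar map must be 3D")
        if self.quantity == "FA" and (
            np.nanmin(self.values) < -1e-9 or np.nanmax(self.values) > 1 + 1e-9
        ):
            raise ValueError("FA values must lie in [0, 1]")
        if self.quantity in ("TD", "SNR") and np.nanmin(self.values) < -1e-9:
            raise ValueError(f"{self.quantity} values must be nonnegative")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dwi(path, bvec_path, bval_path) -> tuple[DWIStack, GradientTable]:
    """Read a 4D NIfTI plus FSL-style bvec/bval files.

    The volume count must match the gradient-table length; directions are
    re-normalized on load.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    bvecs = np.loadtxt(bvec_path)
    bvals = np.atleast_1d(np.loadtxt(bval_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T  # FSL: 3 rows x N columns
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError("bvec/bval row counts disagree")
    if data.shape[3] != bvals.shape[0]:
        raise ValueError(
            f"volume count {data.shape[3]} does not match gradient table "
            f"length {bvals.shape[0]}"
        )
    table = GradientTable(bvecs, bvals)
    return DWIStack(data, img.affine), table


def write_dwi(stack: DWIStack, table: GradientTable, path, bvec_path, bval_path) -> None:
    nib.save(nib.Nifti1Image(stack.intensities, stack.affine), str(path))
    np.savetxt(bvec_path, table.directions.T, fmt="%.12f")
    np.savetxt(bval_path, table.bvalues[None, :], fmt="%.1f")


def read_scalar(path, quantity: str) -> ScalarMap:
    img = nib.load(str(path))
    return ScalarMap(np.asarray(img.get_fdata(), dtype=float), img.affine, quantity)


def write_scalar(smap: ScalarMap, path) -> None:
    nib.save(nib.Nifti1Image(smap.values, smap.affine), str(path))


def read_labels(path, names_path=None) -> LabelVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata()).round().astype(np.int32)
    names: dict[int, str] = {}
    if names_path is not None and Path(names_path).exists():
        names = {int(k): v for k, v in json.loads(Path(names_path).read_text()).items()}
    return LabelVolume(labels, img.affine, names)


def write_labels(labels: LabelVolume, path, names_path=None) -> None:
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine), str(path))
    if names_path is not None:
        Path(names_path).write_text(
            json.dumps({str(k): v for k, v in labels.names.items()}, indent=2)
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def resample(stack: DWIStack, target_voxel_size) -> DWIStack:
    """Trilinear resample onto a grid with the requested voxel size.

    The world-space extent (outer voxel edges) is preserved within one
    voxel; the new grid is aligned to the old grid's corner edge.
    """
    from scipy.ndimage import map_coordinates

    target = np.asarray(target_voxel_size, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target voxel sizes must be positive")
    old_vox = stack.voxel_size
    if np.allclose(target, old_vox):
        return DWIStack(stack.intensities.copy(), stack.affine.copy())

    zoom = target / old_vox
    old_shape = np.array(stack.shape)
    new_shape = np.maximum(np.round(old_shape / zoom).astype(int), 1)

    M_old = stack.affine[:3, :3]
    t_old = stack.affine[:3, 3]
    M_new = M_old * zoom[None, :]
    # align outer voxel edges: world of index -0.5 is shared
    t_new = t_old - 0.5 * M_old.sum(axis=1) + 0.5 * M_new.sum(axis=1)
    new_affine = np.eye(4)
    new_affine[:3, :3] = M_new
    new_affine[:3, 3] = t_new

    # voxel coords of the new grid expressed in the old grid
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in new_shape), indexing="ij")
    idx_new = np.stack([ii, jj, kk], axis=0).reshape(3, -1).astype(float)
    world = M_new @ idx_new + t_new[:, None]
    idx_old = np.linalg.solve(M_old, world - t_old[:, None])

    out = np.empty(tuple(new_shape) + (stack.n_volumes,), dtype=float)
    for v in range(stack.n_volumes):
        out[..., v] = map_coordinates(
            stack.intensities[..., v], idx_old, order=1, mode="nearest"
        ).reshape(tuple(new_shape))
    return DWIStack(out, new_affine)


def estimate_noise_sigma(noise_volume: np.ndarray) -> float:
    """Gaussian noise SD from a pure-noise magnitude (Rician) image.

    For a magnitude image of pure complex Gaussian noise the second moment
    is ``E[m^2] = 2 sigma^2``, so ``sigma = sqrt(mean(m^2) / 2)``.
    """
    m = np.asarray(noise_volume, dtype=float)
    return float(np.sqrt(np.mean(m**2) / 2.0))


def snr_map(
    stack: DWIStack,
    table: GradientTable,
    noise_volume: np.ndarray,
    muscle_mask: np.ndarray,
) -> tuple[ScalarMap, float]:
    """Per-voxel SNR map and whole-mask summary SNR.

    The summary is the mean b=0 intensity over the muscle mask divided by
    the Gaussian noise standard deviation estimated from the noise scan.
    """
    mask = np.asarray(muscle_mask, dtype=bool)
    if not mask.any():
        raise ValueError("SNR mask is empty")
    if noise_volume.shape != stack.shape:
        raise ValueError("noise volume grid does not match the DWI stack")
    b0 = stack.b0_volume(table)
    sigma = estimate_noise_sigma(noise_volume)
    if sigma == 0:
        warnings.warn("noise volume is identically zero; SNR is infinite", stacklevel=2)
        return ScalarMap(np.where(b0 > 0, np.inf, 0.0), stack.affine, "SNR"), float("inf")
    values = b0 / sigma
    summary = float(b0[mask].mean() / sigma)
    return ScalarMap(values, stack.affine, "SNR"), summary
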