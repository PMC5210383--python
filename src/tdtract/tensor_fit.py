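"""Weighted linear least-squares diffusion-tensor estimation and scalar maps.

The log-linearized signal model is ``ln S = ln S0 - b g^T D g``.  Fitting is
one ordinary least-squares pass followed by one reweighted pass with weights
equal to the squared model-predicted signals — the standard WLLS scheme in
which the weights undo the log-transform's noise distortion.
"""

from __future__ import annotations

import dataclasses

import nibabel as nib
import numpy as np

from tdtract.dwi_data import DWIStack, GradientTable, ScalarMap

#: order of the unique tensor components throughout the package
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclasses.dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor.

    ``components`` holds the six unique elements (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz) in mm^2/s as a 4D (x, y, z, 6) array; ``mask`` marks voxels with a
    valid fit.
    """

    components: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    s0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 4 or self.components.shape[3] != 6:
            raise ValueError("tensor components must be (x, y, z, 6)")
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.components.shape[:3]:
            raise ValueError("mask grid does not match tensor grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Full 3x3 tensor per voxel, shape (x, y, z, 3, 3)."""
        return components_to_matrices(self.components)


def components_to_matrices(components: np.ndarray) -> np.ndarray:
    """Expand (..., 6) unique components into (..., 3, 3) symmetric tensors."""
    c = np.asarray(components, dtype=float)
    out = np.empty(c.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = c[..., 0]
    out[..., 1, 1] = c[..., 1]
    out[..., 2, 2] = c[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
    return out


def matrices_to_components(matrices: np.ndarray) -> np.ndarray:
    """Collapse (..., 3, 3) symmetric tensors into (..., 6) components."""
    m = np.asarray(matrices, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


def design_matrix(table: GradientTable) -> np.ndarray:
    """(N, 7) design for the log-linear model; columns: ln S0 then -b * (gx^2,
    gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)."""
    g = table.directions
    b = table.bvalues
    X = np.empty((len(table), 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2.0 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2.0 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2.0 * b * g[:, 1] * g[:, 2]
    return X


def fit_wlls(
    stack: DWIStack, table: GradientTable, mask: np.ndarray | None = None
) -> TensorVolume:
    """Fit the diffusion tensor per voxel by WLLS.

    Voxels with any nonpositive signal are excluded from the validity mask
    (the log model is undefined there).  Raises if the gradient scheme is
    rank-deficient (e.g. coplanar directions).
    """
    if stack.n_volumes != len(table):
        raise ValueError("gradient table does not match volume count")
    X = design_matrix(table)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "gradient scheme is rank-deficient (coplanar directions?); "
            "cannot fit a tensor"
        )

    shape = stack.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)

    signals = stack.intensities.reshape(-1, stack.n_volumes)
    flat_mask = mask.reshape(-1) & np.all(signals > 0, axis=1)

    components = np.zeros(shape + (6,), dtype=float).reshape(-1, 6)
    s0 = np.zeros(np.prod(shape), dtype=float)

    S = signals[flat_mask]
    if S.shape[0] > 0:
        y = np.log(S)  # (V, N)
        # OLS pass
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (7, V)
        # one reweighted pass, weights = squared predicted signals
        pred = X @ beta  # log-predicted, (N, V)
        w = np.exp(2.0 * pred)  # squared predicted signals
        # per-voxel weighted normal equations, batched
        Xw = X[None, :, :] * w.T[:, :, None]  # (V, N, 7)
        lhs = np.einsum("vni,nj->vij", Xw, X)
        rhs = np.einsum("vni,vn->vi", Xw, y)
        beta_w = np.linalg.solve(lhs, rhs[..., None])[..., 0]  # (V, 7)
        components[flat_mask] = beta_w[:, 1:]
        s0[flat_mask] = np.exp(beta_w[:, 0])

    return TensorVolume(
        components.reshape(shape + (6,)),
        stack.affine,
        flat_mask.reshape(shape),
        s0=s0.reshape(shape),
    )


def eigensystem(tensors: TensorVolume) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and principal-direction field.

    Returns ``(eigenvalues, principal)`` with shapes (x, y, z, 3) each.  The
    principal direction is the unit eigenvector of the largest eigenvalue;
    its sign is arbitrary (antipodal pairs are equivalent).
    """
    mats = tensors.as_matrices()
    w, v = np.linalg.eigh(mats)  # ascending
    eigvals = w[..., ::-1]
    principal = v[..., :, 2]
    return eigvals, principal


def _fa_from_eigvals(eigvals: np.ndarray) -> np.ndarray:
    md = eigvals.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(eigvals - md, axis=-1)
    den = np.linalg.norm(eigvals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)  # zero tensor -> FA := 0
    return np.clip(fa, 0.0, 1.0)


def fa_map(tensors: TensorVolume) -> ScalarMap:
    """Fractional anisotropy: sqrt(3/2) * ||lambda - mean|| / ||lambda||."""
    eigvals, _ = eigensystem(tensors)
    fa = _fa_from_eigvals(eigvals)
    fa[~tensors.mask] = 0.0
    return ScalarMap(fa, tensors.affine, "FA")


def md_map(tensors: TensorVolume) -> ScalarMap:
    """Mean diffusivity: mean of the eigenvalues (= trace / 3)."""
    md = tensors.components[..., :3].mean(axis=-1)
    md = md.copy()
    md[~tensors.mask] = 0.0
    return ScalarMap(md, tensors.affine, "MD")


def write_tensor(tensors: TensorVolume, path) -> None:
    """Write the six tensor components as a 4D NIfTI (order Dxx..Dyz)."""
    nib.save(nib.Nifti1Image(tensors.components, tensors.affine), str(path))
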