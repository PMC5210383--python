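"""Synthetic DT-MRI phantom of a unipennate muscle with an internal aponeurosis.

The phantom emulates a lower-leg-style acquisition (12 gradient directions,
b = 400 s/mm^2, SNR 30-70, working voxel size 1.5 x 1.5 x 3.0 mm) on a
simplified unipennate geometry: a planar internal aponeurosis (normal along
x, tendon fibers along z) flanked by two muscle compartments whose fibers
lie in the x-z plane at +/- the pennation angle, attaching to the
aponeurosis on one side and a bounding fascia on the other.  Voxels
straddling a muscle/tendon interface receive a partial tendinous volume
fraction, which is the mechanism that makes tractography continue along
tendinous sheets: the volume-averaged tensor in such voxels points along
the tendon.

Ground truth is known exactly: every fascicle spans the muscle half-width
``w`` at pennation angle ``theta``, so its length is ``L = w / sin(theta)``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from tdtract.dwi_data import (
    DWIStack,
    GradientTable,
    LabelVolume,
    write_dwi,
    write_labels,
)
from tdtract.tensor_fit import TensorVolume, matrices_to_components


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic acquisition and geometry.

    Defaults reproduce the study conditions: a 40 x 40 x 60 grid at the
    1.5 x 1.5 x 3.0 mm working resolution, 12 diffusion directions at
    b = 400 s/mm^2, SNR 40.  Diffusivities are in mm^2/s; the defaults give
    muscle FA ~ 0.21 (inside the 0.1-0.7 tracking window) and tendon
    FA ~ 0.74 (outside it).
    """

    grid_shape: tuple[int, int, int] = (40, 40, 60)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 3.0)
    pennation_angle: float = 30.0  # degrees between fibers and the aponeurosis plane
    muscle_half_width: float = 22.0  # mm, aponeurosis to fascia
    aponeurosis_thickness: float = 4.0  # mm, incl. its connective-tissue shell
    fascia_thickness: float = 3.0  # mm
    muscle_eigenvalues: tuple[float, float, float] = (2.2e-3, 1.5e-3, 1.3e-3)
    tendon_eigenvalues: tuple[float, float, float] = (1.8e-3, 0.4e-3, 0.4e-3)
    s0: float = 100.0  # baseline (b=0) signal, arbitrary units
    tendon_signal_fraction: float = 0.5  # tendon s0 relative to muscle (hypointense)
    snr: float = 40.0  # acquisition SNR: s0 / Gaussian noise SD of the noise scan
    # residual-noise reduction of the upstream denoising step the image
    # volumes have been through before reaching this pipeline; the noise
    # scan (hence the measured SNR) reflects the raw acquisition
    denoising_gain: float = 2.0
    b_value: float = 400.0  # s/mm^2
    n_directions: int = 12
    # optional spatial correlation (FWHM, mm) of the noise fields, to
    # emulate interpolation from a coarser acquired grid; off by default
    # because the matching signal-side smoothing is not modelled
    noise_correlation_fwhm_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    segmentation_error_mm: float = 2.0  # SD of the label-boundary displacement
    segmentation_error_corr_mm: float = 20.0  # its in-plane correlation length
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("muscle_eigenvalues", "tendon_eigenvalues"):
            ev = np.asarray(getattr(self, name))
            if np.any(ev <= 0) or np.any(np.diff(ev) > 0):
                raise ValueError(f"{name} must be strictly positive and non-increasing")
        if not (0.0 < self.pennation_angle <= 90.0):
            raise ValueError("pennation_angle must lie in (0, 90] degrees")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.muscle_half_width <= 0 or self.aponeurosis_thickness < 0:
            raise ValueError("geometry lengths must be positive")
        if self.n_directions < 6:
            raise ValueError("need at least 6 gradient directions for a tensor fit")
        if not (0.0 < self.tendon_signal_fraction <= 1.0):
            raise ValueError("tendon_signal_fraction must lie in (0, 1]")
        if self.denoising_gain < 1.0:
            raise ValueError("denoising_gain must be >= 1")
        if not np.isfinite(self.true_fascicle_length):
            raise ValueError("fascicle length is not finite")

    @property
    def true_fascicle_length(self) -> float:
        """Ground-truth fascicle length L = w / sin(theta), mm."""
        return self.muscle_half_width / np.sin(np.deg2rad(self.pennation_angle))

    @property
    def extent(self) -> np.ndarray:
        """World extent of the grid per axis, mm."""
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_size)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        return aff

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_fascicle_length"] = self.true_fascicle_length
        return d


@dataclasses.dataclass
class PhantomTruth:
    """Ground-truth fields of a generated phantom.

    ``tissue_fraction`` is the tendinous volume fraction per voxel (exact,
    from the planar geometry); ``aponeurosis_fraction`` and
    ``fascia_fraction`` split it by structure.  ``support_fraction`` is the
    fraction of each voxel inside the muscle-tendon complex (s0 scales with
    it; the rest is signal-free background).  ``muscle_labels`` is the
    emulated manual segmentation (label 1 = left compartment, 2 = right),
    including its boundary error; ``exact_labels`` is the error-free version.
    """

    orientation_field: np.ndarray  # (x, y, z, 3) unit fiber directions
    tissue_fraction: np.ndarray  # (x, y, z) in [0, 1]
    aponeurosis_fraction: np.ndarray
    fascia_fraction: np.ndarray
    support_fraction: np.ndarray
    muscle_labels: LabelVolume
    exact_labels: LabelVolume
    true_fascicle_length: float  # mm
    affine: np.ndarray

    def muscle_core_mask(self, margin_voxels: int = 2) -> np.ndarray:
        """Pure-muscle voxels at least ``margin_voxels`` from any interface."""
        from scipy.ndimage import binary_erosion

        pure = (self.tissue_fraction == 0) & (self.support_fraction >= 1.0)
        return binary_erosion(pure, iterations=margin_voxels)


# ---------------------------------------------------------------------------
# gradient scheme
# ---------------------------------------------------------------------------

def electrostatic_directions(n: int, seed: int = 0, n_iter: int = 2000) -> np.ndarray:
    """n approximately uniformly spread unit vectors (antipodally symmetric
    electrostatic repulsion, deterministic given the seed)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    lr = 0.005
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        anti = x[:, None, :] + x[None, :, :]
        d3 = np.linalg.norm(diff, axis=-1) ** 3
        a3 = np.linalg.norm(anti, axis=-1) ** 3
        np.fill_diagonal(d3, np.inf)
        np.fill_diagonal(a3, np.inf)
        force = (diff / d3[..., None]).sum(axis=1) + (anti / a3[..., None]).sum(axis=1)
        # project onto the tangent plane and step
        force -= (force * x).sum(axis=1, keepdims=True) * x
        x += lr * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def make_gradient_table(spec: PhantomSpec) -> GradientTable:
    """One b=0 volume followed by the diffusion-weighted directions."""
    dirs = electrostatic_directions(spec.n_directions, seed=spec.seed + 101)
    directions = np.vstack([np.zeros(3), dirs])
    bvalues = np.concatenate([[0.0], np.full(spec.n_directions, spec.b_value)])
    return GradientTable(directions, bvalues)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _slab_overlap_fraction(edges: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-voxel fraction of the x-interval [edges[i], edges[i+1]) inside
    [lo, hi]."""
    x0, x1 = edges[:-1], edges[1:]
    overlap = np.clip(np.minimum(x1, hi) - np.maximum(x0, lo), 0.0, None)
    return overlap / (x1 - x0)


def _smooth_displacement(
    shape_yz: tuple[int, int],
    voxel_yz: tuple[float, float],
    amplitude: float,
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean smooth random field over (y, z) with SD ``amplitude`` mm."""
    if amplitude <= 0:
        return np.zeros(shape_yz)
    noise = rng.normal(size=shape_yz)
    sigma = tuple(corr_mm / v for v in voxel_yz)
    field = gaussian_filter(noise, sigma=sigma, mode="wrap")
    sd = field.std()
    if sd < 1e-12:
        return np.zeros(shape_yz)
    return field * (amplitude / sd)


def build_geometry(spec: PhantomSpec) -> PhantomTruth:
    """Construct the unipennate geometry and its ground-truth fields.

    The aponeurosis is a slab of thickness ``aponeurosis_thickness``
    centered on the mid-x plane; fasciae are slabs of thickness
    ``fascia_thickness`` at distance ``muscle_half_width`` on either side.
    Tendinous fractions are exact 1D slab/voxel overlaps (the slabs are
    planes normal to x).
    """
    L = spec.true_fascicle_length
    extent = spec.extent
    theta = np.deg2rad(spec.pennation_angle)
    half_span_x = (
        spec.muscle_half_width
        + spec.aponeurosis_thickness / 2.0
        + spec.fascia_thickness
    )
    fiber_dz = spec.muscle_half_width / np.tan(theta) if spec.pennation_angle < 90 else 0.0
    if 2 * half_span_x > extent[0] or fiber_dz > extent[2] or L > extent.max():
        raise ValueError(
            f"grid extent {tuple(extent)} mm is too small to contain one full "
            f"fascicle (L = {L:.1f} mm, complex width = {2 * half_span_x:.1f} mm)"
        )

    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel_size
    cx = extent[0] / 2.0
    x_edges = np.arange(nx + 1) * vx
    x_centers = (x_edges[:-1] + x_edges[1:]) / 2.0

    a2 = spec.aponeurosis_thickness / 2.0
    w = spec.muscle_half_width
    f = spec.fascia_thickness

    apo_col = _slab_overlap_fraction(x_edges, cx - a2, cx + a2)
    fascia_col = _slab_overlap_fraction(
        x_edges, cx - a2 - w - f, cx - a2 - w
    ) + _slab_overlap_fraction(x_edges, cx + a2 + w, cx + a2 + w + f)
    support_col = _slab_overlap_fraction(x_edges, cx - half_span_x, cx + half_span_x)

    ones_yz = np.ones((ny, nz))
    aponeurosis_fraction = apo_col[:, None, None] * ones_yz
    fascia_fraction = fascia_col[:, None, None] * ones_yz
    tissue_fraction = aponeurosis_fraction + fascia_fraction
    support_fraction = support_col[:, None, None] * ones_yz

    # fiber directions: x-z plane, +/- theta from z, pointing away from the
    # aponeurosis with increasing z
    u_right = np.array([np.sin(theta), 0.0, np.cos(theta)])
    u_left = np.array([-np.sin(theta), 0.0, np.cos(theta)])
    orientation = np.empty((nx, ny, nz, 3))
    right = x_centers > cx
    orientation[right] = u_right
    orientation[~right] = u_left
    # the muscle contribution inside an aponeurosis-dominated voxel is the
    # average of both compartments (the x-z cross terms cancel): axis z;
    # fascia-dominated voxels keep the adjacent compartment's fiber axis
    apo_major = aponeurosis_fraction > 0.5
    orientation[apo_major] = np.array([0.0, 0.0, 1.0])

    # exact labels: voxel centers inside a muscle compartment
    in_left = (x_centers > cx - a2 - w) & (x_centers < cx - a2)
    in_right = (x_centers > cx + a2) & (x_centers < cx + a2 + w)
    exact = np.zeros((nx, ny, nz), dtype=np.int32)
    exact[in_left] = 1
    exact[in_right] = 2

    # emulated manual segmentation: smooth random displacement of each of
    # the four compartment boundaries along x
    rng = np.random.default_rng(spec.seed + 202)
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    disp = [
        _smooth_displacement(
            (ny, nz), (vy, vz), spec.segmentation_error_mm,
            spec.segmentation_error_corr_mm, rng,
        )
        for _ in range(4)
    ]
    xc3 = x_centers[:, None, None]
    left_mask = (xc3 > cx - a2 - w + disp[0][None]) & (xc3 < cx - a2 + disp[1][None])
    right_mask = (xc3 > cx + a2 + disp[2][None]) & (xc3 < cx + a2 + w + disp[3][None])
    labels[left_mask] = 1
    labels[right_mask] = 2
    # segmentation cannot include signal-free background
    labels[support_fraction < 0.5] = 0

    names = {1: "muscle_left", 2: "muscle_right"}
    return PhantomTruth(
        orientation_field=orientation,
        tissue_fraction=tissue_fraction,
        aponeurosis_fraction=aponeurosis_fraction,
        fascia_fraction=fascia_fraction,
        support_fraction=support_fraction,
        muscle_labels=LabelVolume(labels, spec.affine, names),
        exact_labels=LabelVolume(exact, spec.affine, dict(names)),
        true_fascicle_length=L,
        affine=spec.affine,
    )


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _tensor_from_axis(axis: np.ndarray, eigenvalues) -> np.ndarray:
    """Axially symmetric-ish tensor with principal axis ``axis``: lambda_1
    along the axis, lambda_2 along y x axis, lambda_3 along the remaining
    direction.  ``axis`` may be (..., 3)."""
    lam1, lam2, lam3 = eigenvalues
    axis = np.asarray(axis, dtype=float)
    ref = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(ref, axis)
    n2 = np.linalg.norm(e2, axis=-1, keepdims=True)
    # axis parallel to y: fall back to x as second axis
    fallback = np.broadcast_to(np.array([1.0, 0.0, 0.0]), axis.shape)
    e2 = np.where(n2 > 1e-12, e2 / np.where(n2 > 0, n2, 1.0), fallback)
    e3 = np.cross(axis, e2)
    outer = lambda v: v[..., :, None] * v[..., None, :]
    return lam1 * outer(axis) + lam2 * outer(e2) + lam3 * outer(e3)


def tensor_field(truth: PhantomTruth, spec: PhantomSpec) -> TensorVolume:
    """Ground-truth tensor volume: signal-weighted tensor-level mixture of
    the muscle and tendon tensors.

    Tendinous tissue is hypointense relative to muscle (its transverse
    relaxation is much faster), so a tendinous volume fraction ``f``
    contributes only ``f * w`` of the voxel signal, with
    ``w = tendon_signal_fraction``.  The voxel tensor is the mixture
    ``(1 - f_eff) D_muscle + f_eff D_tendon`` with the signal-effective
    fraction ``f_eff = f w / (m + f w)`` (``m`` = muscle fraction), and the
    voxel baseline signal is ``s0 (m + f w)``.  Mixing at the tensor level
    reproduces the partial-volume mechanism: the principal axis of an
    interface voxel rotates toward the tendon direction (z) as the
    tendinous fraction grows.
    """
    f = truth.tissue_fraction
    support = truth.support_fraction
    muscle = np.clip(support - f, 0.0, None)
    w = spec.tendon_signal_fraction
    weight = muscle + f * w  # voxel signal relative to pure muscle
    with np.errstate(invalid="ignore", divide="ignore"):
        f_eff = np.where(weight > 0, f * w / np.where(weight > 0, weight, 1.0), 0.0)
    f_eff = f_eff[..., None, None]

    D_muscle = _tensor_from_axis(truth.orientation_field, spec.muscle_eigenvalues)
    z_axis = np.broadcast_to(
        np.array([0.0, 0.0, 1.0]), truth.orientation_field.shape
    )
    D_tendon = _tensor_from_axis(z_axis, spec.tendon_eigenvalues)
    D = (1.0 - f_eff) * D_muscle + f_eff * D_tendon
    mask = support >= 0.5
    return TensorVolume(
        matrices_to_components(D), truth.affine, mask, s0=spec.s0 * weight
    )


def simulate_dwi(
    tensors: TensorVolume, spec: PhantomSpec, table: GradientTable | None = None
) -> tuple[DWIStack, GradientTable, np.ndarray]:
    """Simulate the acquisition: mono-exponential signals S = S0 exp(-b g^T D g)
    with Rician noise, plus a matching pure-noise magnitude volume.

    S0 scales with the in-complex volume fraction encoded in the tensor
    mask's parent truth (signal-free background outside).  Deterministic
    given ``spec.seed``.
    """
    if spec.snr <= 0:
        raise ValueError("snr must be positive")
    if table is None:
        table = make_gradient_table(spec)
    g = table.directions
    b = table.bvalues
    D = tensors.as_matrices()  # (x, y, z, 3, 3)
    # g^T D g for all voxels and directions
    quad = np.einsum("ni,xyzij,nj->xyzn", g, D, g)
    s0_map = (
        tensors.s0 if tensors.s0 is not None else spec.s0 * tensors.mask.astype(float)
    )
    clean = s0_map[..., None] * np.exp(-b[None, None, None, :] * quad)

    sigma = spec.s0 / spec.snr
    rng = np.random.default_rng(spec.seed)
    shape = clean.shape

    # the working grid interpolates data acquired at a coarser voxel size,
    # so the complex noise is spatially correlated at roughly that scale;
    # emulate with a variance-preserving Gaussian-filtered field
    voxel = np.linalg.norm(np.asarray(tensors.affine)[:3, :3], axis=0)
    fwhm_vox = np.asarray(spec.noise_correlation_fwhm_mm) / voxel
    sigma_vox = np.maximum(fwhm_vox / 2.355, 0.0)

    def noise_field(sz) -> np.ndarray:
        white = rng.standard_normal(sz)
        if np.all(sigma_vox < 1e-6):
            return white
        sig = tuple(sigma_vox) + ((0,) if len(sz) == 4 else ())
        field = gaussian_filter(white, sigma=sig, mode="nearest")
        # restore unit variance (use interior to avoid edge effects)
        sd = field.std()
        return field / max(sd, 1e-12)

    # image volumes carry the residual noise left after upstream denoising;
    # the noise scan keeps the raw acquisition noise level
    sigma_img = sigma / spec.denoising_gain
    noisy = np.sqrt(
        (clean + sigma_img * noise_field(shape)) ** 2
        + (sigma_img * noise_field(shape)) ** 2
    )
    noise_volume = np.sqrt(
        (sigma * noise_field(shape[:3])) ** 2
        + (sigma * noise_field(shape[:3])) ** 2
    )
    return DWIStack(noisy, tensors.affine), table, noise_volume


@dataclasses.dataclass
class PhantomDataset:
    """Bundle of everything a phantom run produces."""

    spec: PhantomSpec
    truth: PhantomTruth
    tensors: TensorVolume
    dwi: DWIStack
    table: GradientTable
    noise_volume: np.ndarray


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomDataset:
    """Build geometry, ground-truth tensors, and a noisy acquisition."""
    spec = spec or PhantomSpec()
    truth = build_geometry(spec)
    tensors = tensor_field(truth, spec)
    dwi, table, noise = simulate_dwi(tensors, spec)
    return PhantomDataset(spec, truth, tensors, dwi, table, noise)


def write_phantom(dataset: PhantomDataset, outdir) -> dict[str, str]:
    """Write DWI + bvec/bval, labels, truth volumes and a JSON sidecar."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = dataset.truth.affine
    paths = {
        "dwi": "dwi.nii.gz",
        "bvec": "dwi.bvec",
        "bval": "dwi.bval",
        "labels": "labels.nii.gz",
        "label_names": "labels.json",
        "noise": "noise.nii.gz",
        "tissue_fraction": "truth_tissue_fraction.nii.gz",
        "orientation": "truth_orientation.nii.gz",
        "sidecar": "phantom.json",
    }
    paths = {k: str(outdir / v) for k, v in paths.items()}
    write_dwi(dataset.dwi, dataset.table, paths["dwi"], paths["bvec"], paths["bval"])
    write_labels(dataset.truth.muscle_labels, paths["labels"], paths["label_names"])
    nib.save(nib.Nifti1Image(dataset.noise_volume, aff), paths["noise"])
    nib.save(nib.Nifti1Image(dataset.truth.tissue_fraction, aff), paths["tissue_fraction"])
    nib.save(nib.Nifti1Image(dataset.truth.orientation_field, aff), paths["orientation"])
    Path(paths["sidecar"]).write_text(json.dumps(dataset.spec.to_dict(), indent=2))
    return paths
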