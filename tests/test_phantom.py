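import dataclasses

import numpy as np
import pytest

from tdtract.dwi_data import estimate_noise_sigma, snr_map
from tdtract.phantom import (
    PhantomSpec,
    build_geometry,
    electrostatic_directions,
    generate_phantom,
    make_gradient_table,
    simulate_dwi,
    tensor_field,
)
from tdtract.tensor_fit import components_to_matrices


class TestSpecValidation:
    def test_ground_truth_length_follows_pennation_geometry(self):
        # L = w / sin(theta)
        assert PhantomSpec(
            pennation_angle=90.0, muscle_half_width=30.0, grid_shape=(50, 20, 24)
        ).true_fascicle_length == pytest.approx(30.0)
        assert PhantomSpec(
            pennation_angle=30.0, muscle_half_width=25.0, grid_shape=(44, 20, 40)
        ).true_fascicle_length == pytest.approx(50.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"muscle_eigenvalues": (1.0e-3, 2.0e-3, 0.5e-3)},  # not sorted
            {"tendon_eigenvalues": (1.8e-3, -1e-4, -1e-4)},  # negative
            {"pennation_angle": 0.0},
            {"pennation_angle": 95.0},
            {"snr": -1.0},
            {"tendon_signal_fraction": 0.0},
            {"denoising_gain": 0.5},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)

    def test_grid_too_small_for_fascicle_rejected(self):
        spec = PhantomSpec(grid_shape=(10, 10, 10))
        with pytest.raises(ValueError, match="too small"):
            build_geometry(spec)


class TestGeometry:
    def test_partial_volume_count_matches_supersampling_oracle(self, small_spec):
        truth = build_geometry(small_spec)
        n_partial = int(
            np.sum((truth.tissue_fraction > 0) & (truth.tissue_fraction < 1))
        )
        # independent oracle: voxelize the tendon slabs on a 10x supersampled
        # x-axis and count voxels that are neither empty nor full
        nx = small_spec.grid_shape[0]
        vx = small_spec.voxel_size[0]
        cx = nx * vx / 2.0
        a2 = small_spec.aponeurosis_thickness / 2.0
        w = small_spec.muscle_half_width
        ft = small_spec.fascia_thickness
        slabs = [
            (cx - a2, cx + a2),
            (cx - a2 - w - ft, cx - a2 - w),
            (cx + a2 + w, cx + a2 + w + ft),
        ]
        sub = 10
        fine = (np.arange(nx * sub) + 0.5) * (vx / sub)
        inside = np.zeros(nx * sub, dtype=bool)
        for lo, hi in slabs:
            inside |= (fine >= lo) & (fine <= hi)
        frac = inside.reshape(nx, sub).mean(axis=1)
        n_cols = int(np.sum((frac > 0) & (frac < 1)))
        ny, nz = small_spec.grid_shape[1:]
        assert n_partial == n_cols * ny * nz

    def test_orientations_unit_norm_and_in_xz_plane(self, small_phantom):
        truth = small_phantom.truth
        norms = np.linalg.norm(truth.orientation_field, axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        assert np.all(truth.orientation_field[..., 1] == 0)

    def test_tissue_fraction_bounds_and_label_consistency(self, small_phantom):
        truth = small_phantom.truth
        assert truth.tissue_fraction.min() >= 0
        assert truth.tissue_fraction.max() <= 1
        # labels only inside the complex and never on tendon-majority voxels
        labels = truth.exact_labels.labels
        assert set(np.unique(labels)) <= {0, 1, 2}
        assert np.all(truth.tissue_fraction[labels > 0] <= 0.5)

    def test_compartments_mirror_each_other(self, small_spec):
        truth = build_geometry(small_spec)
        lab = truth.exact_labels.labels
        assert (lab == 1).sum() == (lab == 2).sum()
        left_dir = truth.orientation_field[lab == 1][0]
        right_dir = truth.orientation_field[lab == 2][0]
        np.testing.assert_allclose(left_dir * [-1, 1, 1], right_dir)


class TestTensorField:
    def test_pure_muscle_voxel_has_muscle_eigenvalues(self, small_phantom):
        spec, truth = small_phantom.spec, small_phantom.truth
        tensors = small_phantom.tensors
        sel = (truth.tissue_fraction == 0) & (truth.support_fraction >= 1)
        mats = components_to_matrices(tensors.components[sel])
        eigvals = np.linalg.eigvalsh(mats)[..., ::-1]
        np.testing.assert_allclose(
            eigvals, np.broadcast_to(spec.muscle_eigenvalues, eigvals.shape),
            rtol=1e-10,
        )

    def test_pure_tendon_voxel_principal_axis_is_z(self, small_phantom):
        truth, tensors = small_phantom.truth, small_phantom.tensors
        sel = truth.tissue_fraction >= 1.0
        assert sel.any()
        mats = components_to_matrices(tensors.components[sel])
        _, vecs = np.linalg.eigh(mats)
        principal = vecs[..., :, 2]
        np.testing.assert_allclose(np.abs(principal[:, 2]), 1.0, atol=1e-10)

    def test_interface_voxel_rotates_toward_tendon(self):
        # a 50/50 voxel at 20 degrees pennation: the mixture's principal
        # axis lies closer to z than the muscle fiber does
        spec = PhantomSpec(
            pennation_angle=20.0, grid_shape=(40, 8, 30), tendon_signal_fraction=1.0
        )
        truth = build_geometry(spec)
        theta = np.deg2rad(20.0)
        u = np.array([np.sin(theta), 0, np.cos(theta)])
        f = 0.5
        # build the mixture directly from the same primitives
        truth.tissue_fraction[:] = 0
        truth.tissue_fraction[0, 0, 0] = f
        truth.orientation_field[0, 0, 0] = u
        tensors = tensor_field(truth, spec)
        mat = components_to_matrices(tensors.components[0, 0, 0])
        _, vecs = np.linalg.eigh(mat)
        e1 = vecs[:, 2]
        cos_mix = abs(e1[2])
        cos_muscle = abs(u[2])
        assert cos_mix > cos_muscle


class TestSignalModel:
    def test_b0_noise_free_signal_is_s0(self, noisefree_phantom):
        ds = noisefree_phantom
        b0 = ds.dwi.intensities[..., ds.table.b0_mask].mean(axis=-1)
        core = ds.truth.muscle_core_mask()
        np.testing.assert_allclose(b0[core], ds.spec.s0, rtol=1e-6)

    def test_isotropic_tensor_attenuates_all_directions_equally(self):
        from tdtract.tensor_fit import TensorVolume

        spec = PhantomSpec(snr=1e12, seed=3)
        iso = np.zeros((4, 4, 4, 6))
        iso[..., :3] = 1.5e-3
        tensors = TensorVolume(iso, np.eye(4), np.ones((4, 4, 4), bool))
        stack, table, _ = simulate_dwi(tensors, spec)
        dwi = stack.intensities[..., table.dwi_mask]
        np.testing.assert_allclose(
            dwi, np.broadcast_to(dwi[..., :1], dwi.shape), rtol=1e-6
        )

    def test_parallel_vs_perpendicular_attenuation_ratio(self, noisefree_phantom):
        # closed forms: S_parallel / S_perp-in-plane = exp(-b (l1 - l2)),
        # S_parallel / S_y = exp(-b (l1 - l3)) (y is the minor axis here)
        ds = noisefree_phantom
        spec = ds.spec
        lam1, lam2, lam3 = spec.muscle_eigenvalues
        theta = np.deg2rad(spec.pennation_angle)
        u = np.array([np.sin(theta), 0, np.cos(theta)])
        perp = np.array([np.cos(theta), 0, -np.sin(theta)])
        from tdtract.dwi_data import GradientTable

        extra = np.array([[1, 1, 1], [1, -1, 0]]) / np.array([[np.sqrt(3)], [np.sqrt(2)]])
        table = GradientTable(
            np.vstack([np.zeros(3), u, perp, np.eye(3), extra]),
            np.array([0.0] + [spec.b_value] * 7),
        )
        stack, _, _ = simulate_dwi(ds.tensors, spec, table=table)
        core = ds.truth.muscle_core_mask() & (
            ds.truth.orientation_field[..., 0] > 0
        )
        s_par = stack.intensities[core][:, 1]
        s_perp = stack.intensities[core][:, 2]
        s_y = stack.intensities[core][:, 4]
        np.testing.assert_allclose(
            s_par / s_perp, np.exp(-spec.b_value * (lam1 - lam2)), rtol=1e-9
        )
        np.testing.assert_allclose(
            s_par / s_y, np.exp(-spec.b_value * (lam1 - lam3)), rtol=1e-9
        )

    def test_snr_of_simulated_data_matches_spec(self):
        spec = PhantomSpec(seed=11)  # 40^3+ grid per the noise invariant
        ds = generate_phantom(spec)
        _, summary = snr_map(
            ds.dwi, ds.table, ds.noise_volume, ds.truth.muscle_core_mask()
        )
        assert summary == pytest.approx(spec.snr, rel=0.05)

    def test_noise_scan_sigma_estimator(self, small_phantom):
        ds = small_phantom
        sigma_true = ds.spec.s0 / ds.spec.snr
        assert estimate_noise_sigma(ds.noise_volume) == pytest.approx(
            sigma_true, rel=0.05
        )

    def test_determinism_identical_seeds(self, small_spec):
        a = generate_phantom(small_spec)
        b = generate_phantom(small_spec)
        np.testing.assert_array_equal(a.dwi.intensities, b.dwi.intensities)
        np.testing.assert_array_equal(a.noise_volume, b.noise_volume)
        np.testing.assert_array_equal(
            a.truth.muscle_labels.labels, b.truth.muscle_labels.labels
        )
        c = generate_phantom(dataclasses.replace(small_spec, seed=8))
        assert not np.array_equal(a.dwi.intensities, c.dwi.intensities)


class TestGradientScheme:
    def test_directions_unit_norm_and_spread(self):
        dirs = electrostatic_directions(12, seed=0)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9)
        # antipodally distinct: no two directions closer than ~20 degrees
        gram = np.abs(dirs @ dirs.T)
        np.fill_diagonal(gram, 0)
        assert gram.max() < np.cos(np.deg2rad(20))

    def test_gradient_table_has_b0_and_12_directions(self):
        table = make_gradient_table(PhantomSpec())
        assert len(table) == 13
        assert table.b0_mask.sum() == 1
        assert np.all(table.bvalues[table.dwi_mask] == 400.0)
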