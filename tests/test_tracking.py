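import numpy as np
import pytest

from tdtract.dwi_data import ScalarMap
from tdtract.tensor_fit import TensorVolume, matrices_to_components
from tdtract.tracking import (
    StoppingConfig,
    Tractogram,
    _principal_dirs,
    boundary_track,
    erode_to_fraction,
    fa_only_track,
    read_trk,
    seed_grid,
    track,
    write_trk,
)

LAM = np.array([2.0e-3, 1.0e-3, 1.0e-3])


def _axis_tensor(axis):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 1.0, 0.0]) if abs(axis[1]) < 0.9 else np.array([1.0, 0, 0])
    e2 = np.cross(ref, axis)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis, e2)
    return (
        LAM[0] * np.outer(axis, axis)
        + LAM[1] * np.outer(e2, e2)
        + LAM[2] * np.outer(e3, e3)
    )


def _uniform_volume(shape=(15, 15, 40), axis=(0, 0, 1), fa_value=None):
    D = _axis_tensor(axis)
    comp = np.broadcast_to(matrices_to_components(D), shape + (6,)).copy()
    tv = TensorVolume(comp, np.eye(4), np.ones(shape, bool))
    if fa_value is None:
        lam = LAM
        fa_value = np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / np.linalg.norm(lam)
    fa = ScalarMap(np.full(shape, fa_value), np.eye(4), "FA")
    return tv, fa


class TestSeedGrid:
    def test_unit_cube_lattice_count(self):
        # 10 mm cube at 1 mm spacing: 10^3 seeds at corner + half-spacing
        mask = np.ones((10, 10, 10), bool)
        seeds = seed_grid(mask, np.eye(4), 1.0)
        assert len(seeds) == 1000
        np.testing.assert_allclose(seeds[0], [0.0, 0.0, 0.0])  # -0.5 + 0.5

    def test_spacing_larger_than_volume_yields_center_seed(self):
        mask = np.ones((4, 4, 4), bool)
        seeds = seed_grid(mask, np.eye(4), 50.0)
        assert len(seeds) == 1
        np.testing.assert_allclose(seeds[0], [1.5, 1.5, 1.5])

    def test_count_tracks_mask_volume(self, small_phantom):
        labels = small_phantom.truth.muscle_labels
        mask = labels.mask(1)
        voxel_volume = np.prod(small_phantom.spec.voxel_size)
        seeds = seed_grid(mask, labels.affine, 1.0)
        volume = mask.sum() * voxel_volume
        # seed count equals the mask volume in mm^3 up to one lattice shell
        from scipy.ndimage import binary_dilation

        shell = (binary_dilation(mask) ^ mask).sum() * voxel_volume
        assert abs(len(seeds) - volume) < shell

    def test_empty_mask_warns_and_returns_no_seeds(self):
        with pytest.warns(UserWarning, match="empty"):
            seeds = seed_grid(np.zeros((5, 5, 5), bool), np.eye(4), 1.0)
        assert len(seeds) == 0

    def test_deterministic_lexicographic_order(self):
        mask = np.ones((6, 6, 6), bool)
        a = seed_grid(mask, np.eye(4), 2.0)
        b = seed_grid(mask, np.eye(4), 2.0)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.diff(a[:, 0]) >= 0)  # x slowest axis


class TestErodeToFraction:
    def test_first_crossing_rule(self):
        # a slab that a single erosion takes well below 90%
        mask = np.zeros((10, 10, 10), bool)
        mask[1:9, 1:9, 1:9] = True
        out = erode_to_fraction(mask, 0.9)
        assert out.sum() == 6**3  # exactly one 6-connected erosion

    def test_degenerate_mask_returns_nonempty_with_warning(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2:4] = True
        with pytest.warns(UserWarning, match="empty"):
            out = erode_to_fraction(mask, 0.9)
        assert out.sum() == 2  # original returned

    def test_ball_erodes_into_band(self):
        x, y, z = np.mgrid[:31, :31, :31]
        ball = (x - 15) ** 2 + (y - 15) ** 2 + (z - 15) ** 2 <= 12**2
        out = erode_to_fraction(ball, 0.9)
        ratio = out.sum() / ball.sum()
        assert 0.6 < ratio <= 0.9  # one voxel shell of a ball is sizeable

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            erode_to_fraction(np.ones((3, 3, 3), bool), 1.5)


class TestPrincipalDirs:
    def test_matches_lapack_on_random_tensors(self, rng):
        comp = rng.normal(size=(500, 6))
        from tdtract.tensor_fit import components_to_matrices

        mats = components_to_matrices(comp)
        _, vecs = np.linalg.eigh(mats)
        ref = vecs[:, :, 2]
        got = _principal_dirs(comp)
        align = np.abs(np.einsum("ij,ij->i", ref, got))
        np.testing.assert_allclose(align, 1.0, atol=1e-9)

    def test_handles_degenerate_tensors(self):
        comp = np.zeros((3, 6))
        comp[0, :3] = 1.0  # isotropic
        comp[1] = 0.0  # zero tensor
        comp[2, :3] = [2.0, 1.0, 1.0]  # axial, ambiguous minor plane
        out = _principal_dirs(comp)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)
        assert abs(out[2, 0]) == pytest.approx(1.0)


class TestTracker:
    def test_straight_field_spans_fa_valid_extent(self):
        shape = (15, 15, 40)
        tv, fa = _uniform_volume(shape)
        # FA valid only inside a z-slab
        fa.values[:, :, :8] = 0.05
        fa.values[:, :, 32:] = 0.05
        config = StoppingConfig(step_length=1.0, min_length=2.0)
        seed = np.array([[7.0, 7.0, 20.0]])
        tg = track(seed, tv, fa, config)
        assert len(tg) == 1
        pts = tg[0].points
        # independent oracle: extent of trilinear FA >= 0.1 along the line
        zs = np.linspace(0, 39, 4000)
        import scipy.ndimage as ndi

        vals = ndi.map_coordinates(
            fa.values, [np.full_like(zs, 7.0), np.full_like(zs, 7.0), zs], order=1
        )
        ok = zs[(vals >= 0.1) & (vals <= 0.7)]
        extent = ok.max() - ok.min()
        assert tg[0].length == pytest.approx(extent, abs=2 * config.step_length)
        # bidirectional symmetry: seed is the midpoint within one step
        mid = pts[len(pts) // 2]
        assert np.linalg.norm(mid - seed[0]) <= config.step_length
        # straightness: all points on the seed line
        np.testing.assert_allclose(pts[:, :2], 7.0, atol=1e-9)

    def test_consecutive_points_step_length_apart(self):
        tv, fa = _uniform_volume()
        tg = track(np.array([[7.0, 7.0, 20.0]]), tv, fa, StoppingConfig())
        seg = np.linalg.norm(np.diff(tg[0].points, axis=0), axis=1)
        np.testing.assert_allclose(seg, 1.0, atol=1e-6)
        assert tg[0].length == pytest.approx(seg.sum(), abs=1e-9)
        np.testing.assert_allclose(tg.lengths[0], tg[0].length, atol=1e-9)

    def test_rotating_field_halts_on_angle_criterion(self):
        # direction rotates 25 degrees per mm of z: every 1 mm step turns
        # more than the 20 degree limit
        shape = (20, 20, 30)
        comp = np.empty(shape + (6,))
        for z in range(shape[2]):
            theta = np.deg2rad(25.0 * z)
            D = _axis_tensor([np.sin(theta), 0, np.cos(theta)])
            comp[:, :, z] = matrices_to_components(D)
        tv = TensorVolume(comp, np.eye(4), np.ones(shape, bool))
        fa = ScalarMap(np.full(shape, 0.4), np.eye(4), "FA")
        seed = np.array([[10.0, 10.0, 0.5]])  # ~12 degrees tilt; next step +25
        tg = track(
            seed, tv, fa, StoppingConfig(max_angle_per_step=20.0, min_length=0.0)
        )
        assert len(tg) == 1
        assert tg[0].length <= 3.0
        assert "angle_exceeded" in (tg[0].reason_start, tg[0].reason_end)
        # a permissive angle limit propagates much further in the same field
        tg_loose = track(
            seed, tv, fa, StoppingConfig(max_angle_per_step=45.0, min_length=0.0)
        )
        assert tg_loose[0].length > tg[0].length

    def test_low_fa_everywhere_gives_no_streamlines(self):
        tv, fa = _uniform_volume(fa_value=0.05)
        seeds = seed_grid(np.ones(tv.shape, bool), np.eye(4), 3.0)
        tg = track(seeds, tv, fa, StoppingConfig())
        assert len(tg) == 0
        assert tg.diagnostics["n_rejected_seeds"] == len(seeds)

    def test_antipodal_invariance(self):
        # flipping the tensor field's eigenvector signs changes nothing;
        # equivalently tracking is invariant to the seed-direction sign
        tv, fa = _uniform_volume(axis=(0.3, 0.1, 0.9))
        seeds = np.array([[7.0, 7.0, 20.0], [5.0, 9.0, 15.0]])
        a = track(seeds, tv, fa, StoppingConfig())
        tv_flip, _ = _uniform_volume(axis=(-0.3, -0.1, -0.9))
        b = track(seeds, tv_flip, fa, StoppingConfig())
        np.testing.assert_allclose(a.points, b.points, atol=1e-9)

    def test_td_threshold_halts_at_ridge(self):
        tv, fa = _uniform_volume()
        td_vals = np.zeros(tv.shape)
        td_vals[:, :, 28:] = 2.0  # ridge above threshold
        td = ScalarMap(td_vals, np.eye(4), "TD")
        cfg = StoppingConfig(td_threshold=1.5, td_map=td, min_length=0.0)
        tg = track(np.array([[7.0, 7.0, 20.0]]), tv, fa, cfg)
        assert tg[0].reason_end == "td_exceeded"
        # nearest-voxel semantics: no accepted point in a ridge voxel
        assert tg[0].points[:, 2].max() < 27.5
        assert tg[0].points[:, 2].max() > 26.0

    def test_boundary_mask_halts_with_left_mask(self):
        tv, fa = _uniform_volume()
        mask = np.zeros(tv.shape, bool)
        mask[:, :, 5:30] = True
        tg = boundary_track(
            np.array([[7.0, 7.0, 20.0]]), tv, fa, mask,
            StoppingConfig(min_length=0.0),
        )
        assert tg[0].reason_end == "left_mask"
        assert tg[0].reason_start == "left_mask"
        inside = (tg[0].points[:, 2] >= 4.5) & (tg[0].points[:, 2] < 29.5)
        assert inside.all()

    def test_boundary_mask_whole_volume_equals_plain_track(self):
        tv, fa = _uniform_volume()
        seeds = np.array([[7.0, 7.0, 20.0], [3.0, 3.0, 10.0]])
        plain = track(seeds, tv, fa, StoppingConfig())
        masked = boundary_track(seeds, tv, fa, np.ones(tv.shape, bool))
        np.testing.assert_allclose(plain.points, masked.points, atol=1e-9)

    def test_max_length_cap(self):
        tv, fa = _uniform_volume()
        cfg = StoppingConfig(max_length=10.0, min_length=0.0)
        tg = track(np.array([[7.0, 7.0, 20.0]]), tv, fa, cfg)
        assert tg[0].length <= 10.0 + 1e-9
        assert tg[0].reason_end == "max_length"

    def test_min_length_filter_counted(self):
        tv, fa = _uniform_volume(shape=(15, 15, 8))
        cfg = StoppingConfig(min_length=100.0)
        tg = track(np.array([[7.0, 7.0, 4.0]]), tv, fa, cfg)
        assert len(tg) == 0
        assert tg.diagnostics["n_below_min_length"] == 1

    def test_determinism_and_chunking_equivalence(self):
        tv, fa = _uniform_volume(axis=(0.4, 0.2, 0.89))
        seeds = seed_grid(np.ones(tv.shape, bool), np.eye(4), 2.5)
        a = track(seeds, tv, fa, StoppingConfig())
        b = track(seeds, tv, fa, StoppingConfig())
        np.testing.assert_array_equal(a.points, b.points)
        c = track(seeds, tv, fa, StoppingConfig(), chunk_size=17)
        np.testing.assert_array_equal(a.points, c.points)
        np.testing.assert_array_equal(a.reasons, c.reasons)


class TestFaOnlyMode:
    def test_tendon_free_phantom_matches_plain_track(self, small_spec):
        import dataclasses

        from tdtract.phantom import generate_phantom
        from tdtract.tensor_fit import fa_map, fit_wlls

        spec = dataclasses.replace(
            small_spec, aponeurosis_thickness=0.0, fascia_thickness=0.0,
            segmentation_error_mm=0.0,
        )
        ds = generate_phantom(spec)
        tensors = fit_wlls(ds.dwi, ds.table)
        fa = fa_map(tensors)
        seeds = seed_grid(
            ds.truth.muscle_labels.mask(2), ds.truth.affine, 3.0
        )
        cfg = StoppingConfig(fa_range=(0.15, 0.65))
        plain = track(seeds, tensors, fa, cfg)
        faonly = fa_only_track(seeds, tensors, fa, cfg, fa_range=(0.15, 0.65))
        np.testing.assert_array_equal(plain.points, faonly.points)

    def test_uniform_isotropic_field_gives_nothing(self):
        comp = np.zeros((8, 8, 8, 6))
        comp[..., :3] = 1.5e-3
        tv = TensorVolume(comp, np.eye(4), np.ones((8, 8, 8), bool))
        fa = ScalarMap(np.zeros((8, 8, 8)), np.eye(4), "FA")
        tg = fa_only_track(np.array([[4.0, 4.0, 4.0]]), tv, fa)
        assert len(tg) == 0


class TestTractogramIO:
    def test_trk_roundtrip(self, tmp_path):
        tv, fa = _uniform_volume()
        seeds = np.array([[7.0, 7.0, 20.0], [5.0, 5.0, 15.0]])
        tg = track(seeds, tv, fa, StoppingConfig())
        path = tmp_path / "tracks.trk"
        write_trk(tg, np.eye(4), tv.shape, path)
        back = read_trk(path)
        assert len(back) == len(tg)
        np.testing.assert_allclose(back.points, tg.points, atol=1e-4)
        np.testing.assert_array_equal(back.reasons, tg.reasons)

    def test_select_preserves_point_alignment(self):
        tv, fa = _uniform_volume()
        seeds = np.array([[7.0, 7.0, 10.0], [7.0, 7.0, 20.0], [7.0, 7.0, 30.0]])
        tg = track(seeds, tv, fa, StoppingConfig())
        sub = tg.select(np.array([True, False, True]))
        assert len(sub) == 2
        np.testing.assert_allclose(sub[1].points, tg[2].points)


class TestStoppingConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fa_range": (0.7, 0.1)},
            {"step_length": 0.0},
            {"min_length": -1.0},
            {"td_threshold": 0.9, "td_map": "placeholder"},
            {"td_threshold": 2.0},  # threshold without map
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StoppingConfig(**kwargs)
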