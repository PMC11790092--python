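"""Differentiable view synthesis: warping, photometric error, smoothness."""

import numpy as np
import pytest

from berry3d.autodiff import Tensor
from berry3d.camera import default_synthetic_camera, fov_mask, uocm_project
from berry3d.scene import covisibility_mask
from berry3d.transforms import RigidTransform
from berry3d.viewsynth import (
    LossWeights,
    NoOverlapError,
    bilinear_resample,
    compute_sampling_grid,
    euler_rotation_t,
    normalized_inverse_depth,
    photometric_error,
    pose_vector_to_rt,
    reprojection_loss,
    reprojection_loss_t,
    smoothness_loss,
    total_loss_t,
)


class TestSamplingGrid:
    def test_identity_pose_gives_identity_grid(self):
        cam = default_synthetic_camera(64)
        depth = np.full((64, 64), 3.0)
        grid = compute_sampling_grid(depth, RigidTransform.identity(), cam)
        uu, vv = np.meshgrid(np.arange(64.0), np.arange(64.0))
        m = grid.valid
        assert m.any()
        assert np.allclose(grid.u[m], uu[m], atol=1e-9)
        assert np.allclose(grid.v[m], vv[m], atol=1e-9)

    def test_forward_translation_moves_points_radially_outward(self):
        # a source camera that moved toward the fronto-parallel plane sees it
        # magnified: warped coordinates move outward from the principal point.
        # T_{t->t'} for a source 1 unit forward subtracts 1 from z.
        cam = default_synthetic_camera(64)
        depth = np.full((64, 64), 5.0)
        pose = RigidTransform(translation=np.array([0.0, 0.0, -1.0]))
        grid = compute_sampling_grid(depth, pose, cam)
        c = 31.5
        for (v, u) in [(31, 20), (31, 45), (20, 31), (45, 31), (40, 40)]:
            assert grid.valid[v, u]
            r_before = np.hypot(u - c, v - c)
            r_after = np.hypot(grid.u[v, u] - c, grid.v[v, u] - c)
            assert r_after > r_before

    def test_matches_renderer_correspondence(self, orbit_small):
        fx = orbit_small
        va, vb = fx.views[0], fx.views[1]
        grid = compute_sampling_grid(va.depth, fx.trajectory.relative_pose(0, 1),
                                     fx.camera)
        m = grid.valid
        w2cb = fx.trajectory.world_to_cam(1)
        uv = uocm_project(w2cb.apply(va.points[m]), fx.camera)
        err = np.abs(uv - np.stack([grid.u[m], grid.v[m]], axis=1))
        assert err.max() < 0.05

    def test_shape_mismatch_rejected(self):
        cam = default_synthetic_camera(64)
        with pytest.raises(ValueError):
            compute_sampling_grid(np.ones((32, 32)), RigidTransform.identity(), cam)


class TestBilinearResample:
    def test_identity_grid_reproduces_source(self):
        cam = default_synthetic_camera(32)
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(32, 32, 3))
        grid = compute_sampling_grid(np.full((32, 32), 2.0),
                                     RigidTransform.identity(), cam)
        out = bilinear_resample(img, grid)
        m = grid.valid
        assert np.allclose(out[m], img[m], atol=1e-12)
        assert np.isnan(out[~m]).all()

    def test_constant_image_stays_constant(self):
        from berry3d.viewsynth import SamplingGrid
        img = np.full((8, 8, 3), 0.37)
        rng = np.random.default_rng(1)
        grid = SamplingGrid(u=rng.uniform(0, 7, (8, 8)), v=rng.uniform(0, 7, (8, 8)),
                            valid=np.ones((8, 8), bool))
        assert np.allclose(bilinear_resample(img, grid), 0.37, atol=1e-12)

    def test_half_pixel_shift_on_linear_ramp(self):
        from berry3d.viewsynth import SamplingGrid
        ramp = np.tile(np.arange(8.0)[None, :, None], (8, 1, 3)) / 7.0
        uu, vv = np.meshgrid(np.arange(8.0), np.arange(8.0))
        grid = SamplingGrid(u=uu + 0.5, v=vv, valid=uu + 0.5 <= 7)
        out = bilinear_resample(ramp, grid)
        m = grid.valid
        assert np.allclose(out[m], ramp[m] + 0.5 / 7.0, atol=1e-12)


class TestPhotometricError:
    def test_identical_images_have_zero_error(self, rng):
        img = rng.uniform(size=(16, 16, 3))
        pe_map, scalar = photometric_error(img, img)
        assert scalar == pytest.approx(0.0, abs=1e-12)
        assert np.nanmax(np.abs(pe_map)) < 1e-12

    def test_pure_l1_on_constant_offset(self):
        a = np.full((10, 10, 3), 0.4)
        b = np.full((10, 10, 3), 0.4 + 0.07)
        _, scalar = photometric_error(a, b, LossWeights(alpha_pe=0.0))
        assert scalar == pytest.approx(0.07, abs=1e-12)

    def test_ssim_matches_skimage_reference(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.uniform(size=(8, 8))
        b = np.clip(a + rng.normal(0, 0.1, size=(8, 8)), 0, 1)
        _, scalar = photometric_error(a, b, LossWeights(alpha_pe=1.0))
        _, smap = structural_similarity(
            a, b, win_size=3, gaussian_weights=False, use_sample_covariance=False,
            data_range=1.0, full=True)
        ref = (1 - smap[1:-1, 1:-1].mean()) / 2  # interior: identical padding
        assert scalar == pytest.approx(ref, abs=1e-6)

    def test_empty_mask_signals_no_overlap(self, rng):
        img = rng.uniform(size=(8, 8, 3))
        with pytest.raises(NoOverlapError):
            photometric_error(img, img, valid=np.zeros((8, 8), bool))

    def test_sentinel_pixels_never_read(self, rng):
        # NaN-poisoning: invalid cells must not influence the scalar loss
        img = rng.uniform(size=(16, 16, 3))
        other = rng.uniform(size=(16, 16, 3))
        valid = np.ones((16, 16), bool)
        valid[:4] = False
        poisoned = other.copy()
        poisoned[~valid] = np.nan
        _, s_poisoned = photometric_error(img, poisoned, valid=valid)
        clean = other.copy()
        clean[~valid] = 0.123
        _, s_clean = photometric_error(img, clean, valid=valid)
        assert np.isfinite(s_poisoned)
        assert s_poisoned == pytest.approx(s_clean, abs=1e-12)


class TestReprojectionLoss:
    def test_zero_for_identical_frames_identity_pose(self, rng):
        cam = default_synthetic_camera(32)
        img = rng.uniform(size=(32, 32, 3))
        loss = reprojection_loss(img, [img, img],
                                 np.full((32, 32), 3.0),
                                 [RigidTransform.identity()] * 2, cam,
                                 LossWeights(lambda_smooth=0.0))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_single_source_equals_its_pe_term(self, rng):
        cam = default_synthetic_camera(32)
        a = rng.uniform(size=(32, 32, 3))
        b = rng.uniform(size=(32, 32, 3))
        w = LossWeights(lambda_smooth=0.0)
        single = reprojection_loss(a, [b], np.full((32, 32), 3.0),
                                   [RigidTransform.identity()], cam, w)
        double = reprojection_loss(a, [b, b], np.full((32, 32), 3.0),
                                   [RigidTransform.identity()] * 2, cam, w)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_ground_truth_warp_loss_is_small(self, orbit_small):
        fx = orbit_small
        t = 1
        target = np.nan_to_num(fx.views[t].image)
        sources = [np.nan_to_num(fx.views[t - 1].image), np.nan_to_num(fx.views[t + 1].image)]
        poses = [fx.trajectory.relative_pose(t, t - 1), fx.trajectory.relative_pose(t, t + 1)]
        loss = reprojection_loss(target, sources, fx.views[t].depth, poses, fx.camera,
                                 LossWeights(alpha_pe=0.0, lambda_smooth=0.0))
        # two L1 terms, each bounded by interpolation + occlusion error
        assert loss < 0.02

    def test_mismatched_lengths_rejected(self, rng):
        cam = default_synthetic_camera(32)
        img = rng.uniform(size=(32, 32, 3))
        with pytest.raises(ValueError):
            reprojection_loss(img, [img], np.full((32, 32), 3.0),
                              [RigidTransform.identity()] * 2, cam)


class TestSmoothnessLoss:
    def test_constant_depth_is_zero(self, rng):
        img = rng.uniform(size=(16, 16, 3))
        assert smoothness_loss(np.full((16, 16), 4.0), img) == pytest.approx(0.0, abs=1e-12)

    def test_linear_inverse_depth_ramp_closed_form(self):
        # inverse depth 1..2 across 17 columns; normalized by its mean
        inv = np.tile(np.linspace(1.0, 2.0, 17)[None, :], (17, 1))
        depth = 1.0 / inv
        img = np.full((17, 17, 3), 0.5)
        slope = (inv[0, 1] - inv[0, 0]) / inv.mean()
        assert smoothness_loss(depth, img) == pytest.approx(slope, rel=1e-9)

    def test_image_edges_downweight_depth_gradients(self, rng):
        inv = np.tile(np.linspace(1.0, 2.0, 17)[None, :], (17, 1))
        depth = 1.0 / inv
        flat = np.full((17, 17, 3), 0.5)
        contrast = rng.uniform(size=(17, 17, 3))
        assert smoothness_loss(depth, contrast) < smoothness_loss(depth, flat)

    def test_normalized_inverse_depth_mean_is_one(self, rng):
        depth = rng.uniform(1.0, 9.0, size=(20, 20))
        valid = rng.uniform(size=(20, 20)) > 0.3
        d_star = normalized_inverse_depth(depth, valid)
        assert np.nanmean(d_star[valid]) == pytest.approx(1.0, abs=1e-6)


class TestDifferentiability:
    def test_pose_gradients_match_finite_differences(self, orbit_small):
        fx = orbit_small
        t = 1
        target = np.nan_to_num(fx.views[t].image)
        source = np.nan_to_num(fx.views[t + 1].image)
        depth = Tensor(np.nan_to_num(fx.views[t].depth, nan=1.0))
        w = LossWeights(alpha_pe=0.85, lambda_smooth=0.0)

        # a generic evaluation point: at e.g. zero vertical motion every
        # warped v-coordinate sits exactly on a bilinear-interpolation knot,
        # where the loss is not differentiable
        vec0 = np.array([0.01, -0.02, 0.005, 0.05, 0.03, -0.02])

        # the loss is piecewise-smooth in the pose: pixels at the mask border
        # flip validity under perturbation.  Restrict the comparison to a
        # region whose warps stay strictly interior so FD is well-posed.
        from berry3d.viewsynth import compute_sampling_grid as _grid

        pose0 = RigidTransform.from_euler_translation(vec0[:3], vec0[3:])
        g0 = _grid(np.nan_to_num(fx.views[t].depth, nan=1.0), pose0, fx.camera,
                   fx.views[t].valid)
        interior = (g0.valid & (g0.u > 4) & (g0.u < fx.camera.width - 5)
                    & (g0.v > 4) & (g0.v < fx.camera.height - 5))
        # also keep warped coordinates away from the bilinear knots (integer
        # grid lines), where the interpolant is not differentiable
        off_knots = ((np.abs(g0.u - np.round(g0.u)) > 0.05)
                     & (np.abs(g0.v - np.round(g0.v)) > 0.05))
        valid = fx.views[t].valid & interior & off_knots

        def loss_of(vec_arr):
            vec = Tensor(np.asarray(vec_arr, float), requires_grad=True)
            pose = pose_vector_to_rt(vec)
            loss = reprojection_loss_t(target, [source], depth, [pose], fx.camera, w, valid)
            return vec, loss

        vec, loss = loss_of(vec0)
        loss.backward()
        ana = vec.grad.copy()
        eps = 1e-6
        for i in range(6):
            vp = vec0.copy(); vp[i] += eps
            vm = vec0.copy(); vm[i] -= eps
            num = (loss_of(vp)[1].item() - loss_of(vm)[1].item()) / (2 * eps)
            assert ana[i] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_perturbing_true_pose_increases_loss(self, orbit_small, rng):
        fx = orbit_small
        t = 1
        target = np.nan_to_num(fx.views[t].image)
        source = np.nan_to_num(fx.views[t + 1].image)
        depth = fx.views[t].depth
        true_pose = fx.trajectory.relative_pose(t, t + 1)
        w = LossWeights(alpha_pe=0.85, lambda_smooth=0.0)
        base = reprojection_loss(target, [source], depth, [true_pose], fx.camera, w)
        worse = 0
        total = 0
        for mag in (0.01, 0.03, 0.1):
            for _ in range(7):
                d = rng.normal(size=6)
                d = mag * d / np.linalg.norm(d)
                pert = RigidTransform.from_rotvec_translation(
                    d[:3], true_pose.translation + d[3:]).compose(
                        RigidTransform(rotation=true_pose.rotation))
                loss = reprojection_loss(target, [source], depth, [pert], fx.camera, w)
                total += 1
                worse += loss > base
        assert worse == total

    def test_euler_rotation_tensor_matches_scipy(self, rng):
        from scipy.spatial.transform import Rotation

        ang = rng.normal(0, 0.5, size=3)
        R = euler_rotation_t(Tensor(ang)).value
        assert np.allclose(R, Rotation.from_euler("XYZ", ang).as_matrix(), atol=1e-12)

    def test_zero_pose_vector_is_identity(self):
        r, t = pose_vector_to_rt(Tensor(np.zeros(6)))
        assert np.allclose(r.value, np.eye(3), atol=1e-15)
        assert np.allclose(t.value, 0.0)
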