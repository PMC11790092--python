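"""Pose chaining, 3D lifting, mutual-NN matching, track building."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from berry3d.camera import default_synthetic_camera, uocm_project
from berry3d.tracking import (
    BerryObservation,
    BerryTrack,
    build_tracks,
    chain_poses,
    lift_centers,
    load_centers_csv,
    match_mutual_nn,
    save_tracks_csv,
)
from berry3d.transforms import RigidTransform


def obs_at(point, frame=0):
    point = np.asarray(point, float)
    return BerryObservation(frame=frame, center=(0.0, 0.0), depth=1.0,
                            cam_point=point, world_point=point)


class TestChainPoses:
    def test_identities_chain_to_identity(self):
        chain = chain_poses([RigidTransform.identity()] * 4)
        for cum in chain.cumulative:
            assert cum.almost_equal(RigidTransform.identity())

    def test_commuting_translations_add(self):
        rels = [RigidTransform(translation=np.array([0, 0, 1.0])),
                RigidTransform(translation=np.array([0, 0, 2.5]))]
        chain = chain_poses(rels)
        assert np.allclose(chain.cumulative[2].translation, [0, 0, 3.5])

    def test_matches_homogeneous_product_oracle(self):
        rng = np.random.default_rng(0)
        rels = [RigidTransform(rotation=Rotation.random(random_state=rng).as_matrix(),
                               translation=rng.normal(size=3)) for _ in range(10)]
        chain = chain_poses(rels)
        mat = np.eye(4)
        for rel in rels:
            mat = rel.as_matrix() @ mat
        assert np.allclose(chain.cumulative[10].as_matrix(), mat, atol=1e-10)

    def test_inverse_maps_camera_to_world(self):
        rel = RigidTransform.from_euler_translation([0.1, 0.2, -0.1], [1.0, 0, 0])
        chain = chain_poses([rel])
        x_cam = np.array([0.5, -0.5, 2.0])
        w = chain.cam_to_world(1).apply(x_cam)
        assert np.allclose(chain.world_to_cam(1).apply(w), x_cam, atol=1e-12)

    def test_non_rigid_input_rejected(self):
        with pytest.raises(TypeError):
            chain_poses([np.eye(4)])


class TestLiftCenters:
    def test_principal_point_identity_chain(self):
        cam = default_synthetic_camera(64)
        chain = chain_poses([])
        depth = np.full((64, 64), 4.2)
        obs = lift_centers(np.array([[cam.intrinsics.cx, cam.intrinsics.cy]]),
                           depth, cam, chain, 0)
        assert len(obs) == 1
        assert np.allclose(obs[0].world_point, [0, 0, 4.2], atol=1e-9)

    def test_pure_translation_chain_applies_inverse(self):
        cam = default_synthetic_camera(64)
        tau = np.array([0.3, -0.2, 0.1])
        chain = chain_poses([RigidTransform(translation=tau)])
        depth = np.full((64, 64), 5.0)
        obs = lift_centers(np.array([[31.5, 31.5]]), depth, cam, chain, 1)
        assert np.allclose(obs[0].world_point, obs[0].cam_point - tau, atol=1e-12)

    def test_world_point_consistency_invariant(self):
        cam = default_synthetic_camera(64)
        rng = np.random.default_rng(1)
        rels = [RigidTransform(rotation=Rotation.random(random_state=rng).as_matrix(),
                               translation=rng.normal(size=3) * 0.1) for _ in range(3)]
        chain = chain_poses(rels)
        depth = np.full((64, 64), 3.0)
        obs = lift_centers(rng.uniform(20, 44, size=(5, 2)), depth, cam, chain, 3)
        for o in obs:
            assert np.allclose(o.world_point,
                               chain.cam_to_world(3).apply(o.cam_point), atol=1e-9)

    def test_center_outside_fov_dropped(self, caplog):
        cam = default_synthetic_camera(64)  # inscribed circle: corners invalid
        chain = chain_poses([])
        depth = np.full((64, 64), 3.0)
        obs = lift_centers(np.array([[1.0, 1.0], [31.5, 31.5]]), depth, cam, chain, 0)
        assert len(obs) == 1

    def test_lifted_fixture_centers_match_true_berry_centers(self, orbit_small):
        # depth at the 2D center is the berry's front surface, so the lifted
        # point sits within one radius of the true center — well under 2% of
        # the bunch diameter from the surface-adjusted position
        fx = orbit_small
        chain = chain_poses(fx.trajectory.relative_chain())
        c2w_0 = fx.trajectory.poses_c2w[0]
        diam = 2 * np.linalg.norm(
            fx.scene.centers - fx.scene.centers.mean(0), axis=1).mean()
        for t in (0, 5):
            view = fx.views[t]
            centers = view.centers2d[["x", "y"]].to_numpy()
            obs = lift_centers(centers, view.depth, fx.camera, chain, t)
            errs = []
            for o, (_, row) in zip(obs, view.centers2d.iterrows()):
                true_center = c2w_0.inverse().apply(fx.scene.centers[int(row.berry_id)])
                r = fx.scene.radii[int(row.berry_id)]
                errs.append(np.linalg.norm(o.world_point - true_center) - r)
            # a few centers near occlusion edges sample contaminated depth;
            # the bulk must sit within 2% of the bunch diameter of the
            # surface-adjusted position
            errs = np.array(errs)
            assert np.median(errs) < 0.02 * diam
            assert np.mean(errs < 0.02 * diam) >= 0.8


class TestMutualNN:
    def test_identical_sets_pair_identically(self):
        pts = [obs_at([i, 0, 0]) for i in range(5)]
        assert match_mutual_nn(pts, pts) == [(i, i) for i in range(5)]

    def test_brute_force_two_point_case(self):
        a = [obs_at([0, 0, 0]), obs_at([10, 0, 0])]
        b = [obs_at([0.1, 0, 0]), obs_at([9.8, 0, 0])]
        assert match_mutual_nn(a, b) == [(0, 0), (1, 1)]

    def test_non_mutual_candidate_excluded(self):
        # b's lone right-side point prefers a[2]; a[1]'s NN is that same point
        # but the preference is not mutual, so a[1] stays unmatched
        a = [obs_at([0, 0, 0]), obs_at([5, 0, 0]), obs_at([6, 0, 0])]
        b = [obs_at([0.1, 0, 0]), obs_at([6.1, 0, 0])]
        pairs = match_mutual_nn(a, b)
        assert (2, 1) in pairs
        assert all(i != 1 for i, _ in pairs)

    def test_matches_brute_force_oracle(self, rng):
        a = [obs_at(p) for p in rng.normal(size=(15, 3))]
        b = [obs_at(p) for p in rng.normal(size=(12, 3))]
        pa = np.array([o.world_point for o in a])
        pb = np.array([o.world_point for o in b])
        d = np.linalg.norm(pa[:, None] - pb[None], axis=-1)
        expected = sorted((i, j) for i in range(15) for j in range(12)
                          if d[i].argmin() == j and d[:, j].argmin() == i)
        assert sorted(match_mutual_nn(a, b, max_dist=np.inf)) == expected

    def test_symmetry(self, rng):
        a = [obs_at(p) for p in rng.normal(size=(10, 3))]
        b = [obs_at(p) for p in rng.normal(size=(8, 3))]
        ab = set(match_mutual_nn(a, b, max_dist=np.inf))
        ba = set((j, i) for i, j in match_mutual_nn(b, a, max_dist=np.inf))
        assert ab == ba

    def test_invariance_under_common_rigid_transform(self, rng):
        tf = RigidTransform.from_euler_translation([0.5, -0.3, 1.0], [2.0, 1.0, -1.0])
        a = [obs_at(p) for p in rng.normal(size=(10, 3))]
        b = [obs_at(p) for p in rng.normal(size=(10, 3))]
        a2 = [obs_at(tf.apply(o.world_point)) for o in a]
        b2 = [obs_at(tf.apply(o.world_point)) for o in b]
        assert match_mutual_nn(a, b) == match_mutual_nn(a2, b2)

    def test_distance_gate(self):
        a = [obs_at([0, 0, 0]), obs_at([1, 0, 0])]
        b = [obs_at([0, 0, 0]), obs_at([50, 0, 0])]
        pairs = match_mutual_nn(a, b)  # default gate: 1.5x median NN spacing
        assert pairs == [(0, 0)]

    def test_empty_inputs(self):
        assert match_mutual_nn([], [obs_at([0, 0, 0])]) == []


class TestBuildTracks:
    @staticmethod
    def per_frame_from_paths(paths, n_frames):
        """paths: dict name -> (start, positions list); build per-frame lists."""
        frames = [[] for _ in range(n_frames)]
        for start, positions in paths.values():
            for k, p in enumerate(positions):
                frames[start + k].append(obs_at(p, frame=start + k))
        return frames

    def test_six_frame_chain_kept(self):
        frames = self.per_frame_from_paths(
            {"a": (0, [[0, 0, 0]] * 6)}, 6)
        tracks = build_tracks(frames, min_track_len=5)
        assert len(tracks) == 1
        assert len(tracks[0]) == 6

    def test_four_frame_chain_discarded(self):
        frames = self.per_frame_from_paths({"a": (0, [[0, 0, 0]] * 4)}, 5)
        assert build_tracks(frames, min_track_len=5) == []

    def test_partition_property(self, rng):
        # several wandering berries: no observation may enter two tracks
        n_frames, n_berries = 8, 6
        base = rng.normal(size=(n_berries, 3)) * 3
        frames = []
        for t in range(n_frames):
            frames.append([obs_at(base[j] + 0.01 * rng.normal(size=3), frame=t)
                           for j in range(n_berries)])
        tracks = build_tracks(frames, min_track_len=5)
        seen = set()
        for tr in tracks:
            for o in tr.observations:
                key = (o.frame, tuple(o.world_point))
                assert key not in seen
                seen.add(key)
        assert len(tracks) == n_berries

    def test_track_mean_inside_convex_hull(self, rng):
        pts = rng.normal(size=(6, 3))
        track = BerryTrack(observations=tuple(obs_at(p, frame=i)
                                              for i, p in enumerate(pts)))
        mean = track.mean_world_point
        assert np.all(mean >= pts.min(axis=0) - 1e-12)
        assert np.all(mean <= pts.max(axis=0) + 1e-12)

    def test_gap_breaks_track(self):
        with pytest.raises(ValueError):
            BerryTrack(observations=(obs_at([0, 0, 0], frame=0),
                                     obs_at([0, 0, 0], frame=2)))

    def test_fixture_links_are_correct(self, orbit_small):
        # ground-truth lifting: >= 95% of kept track links join the same berry
        fx = orbit_small
        chain = chain_poses(fx.trajectory.relative_chain())
        per_frame, ids = [], []
        for t, view in enumerate(fx.views):
            centers = view.centers2d[["x", "y"]].to_numpy()
            obs = lift_centers(centers, view.depth, fx.camera, chain, t)
            per_frame.append(obs)
            ids.append({(o.frame, tuple(np.round(o.center, 6))): bid
                        for o, bid in zip(obs, view.centers2d.berry_id)})
        tracks = build_tracks(per_frame, min_track_len=5)
        assert tracks
        good = total = 0
        for tr in tracks:
            bids = [ids[o.frame][(o.frame, tuple(np.round(o.center, 6)))]
                    for o in tr.observations]
            good += sum(b1 == b2 for b1, b2 in zip(bids, bids[1:]))
            total += len(bids) - 1
        assert total > 0
        assert good / total >= 0.95


class TestCsvIO:
    def test_centers_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"frame": [0, 0, 1], "x": [1.0, 2.0, 3.0],
                           "y": [4.0, 5.0, 6.0]})
        path = tmp_path / "centers.csv"
        df.to_csv(path, index=False)
        centers = load_centers_csv(path)
        assert np.allclose(centers[0], [[1, 4], [2, 5]])
        assert np.allclose(centers[1], [[3, 6]])

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,u,v\n0,1,2\n")
        with pytest.raises(ValueError):
            load_centers_csv(path)

    def test_tracks_csv_schema(self, tmp_path):
        import pandas as pd

        track = BerryTrack(observations=tuple(
            obs_at([i, 0.0, 1.0], frame=i) for i in range(5)))
        path = tmp_path / "tracks.csv"
        save_tracks_csv([track], path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["track_id", "frame", "x", "y", "X", "Y", "Z"]
        assert len(df) == 5
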