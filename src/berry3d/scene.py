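"""Synthetic grape-bunch scenes with exact ground truth.

Real input videos show a crowded cluster of young, textureless, quasi-spherical
berries filmed by a ~180° omnidirectional camera orbiting the bunch at close
range.  This module emulates exactly those conditions with an analytic CPU ray
caster: spheres in a downward-tapering cluster, a seeded orbit trajectory, and
per-pixel ground-truth depth, world hit points and berry identities.  Every
quantity is exact (closed-form ray/sphere intersection), which makes the
renderer the oracle for the warp, matching, and bundle-adjustment stages.

A mild 3D value-noise modulation is attached to the sphere surfaces; perfectly
constant colors would give the photometric losses degenerate flat minima,
while surface-attached noise keeps the rendering photometrically consistent
across views.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd

from .camera import UOCMCamera, default_synthetic_camera, pixel_grid, save_calibration, unproject_mask, uocm_project
from .transforms import RigidTransform

__all__ = [
    "SyntheticScene",
    "CameraTrajectory",
    "RenderedView",
    "generate_bunch",
    "orbit_trajectory",
    "render_view",
    "covisibility_mask",
    "make_fixture",
    "load_fixture",
    "FIXTURE_PRESETS",
]


# -- scene ---------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticScene:
    """Sphere-cluster bunch plus an enclosing textured background sphere."""

    centers: np.ndarray        # (N, 3) world coordinates, y pointing down
    radii: np.ndarray          # (N,)
    colors: np.ndarray         # (N, 3) base albedo in [0, 1]
    background_radius: float
    background_color: tuple = (0.45, 0.42, 0.38)
    texture_amplitude: float = 0.25
    texture_frequency: float = 6.0
    texture_seed: int = 0

    @property
    def n_berries(self) -> int:
        return len(self.centers)


def generate_bunch(n_berries: int = 30, berry_radius: float = 0.35,
                   spacing: float = 0.65, seed: int = 0,
                   allowed_overlap: float = 0.15,
                   max_retries: int = 400) -> SyntheticScene:
    """Sample a reproducible, downward-tapering cluster of berry spheres.

    Berries are placed inside an inverted-cone envelope (wide at the top,
    narrow at the bottom, as pruned table-grape bunches are shaped), with all
    pairwise center distances >= spacing * (1 - allowed_overlap).
    """
    if n_berries < 1:
        raise ValueError("n_berries must be >= 1")
    rng = np.random.default_rng(seed)
    height = spacing * max(1.0, 1.0 * np.sqrt(n_berries))
    r_top = spacing * max(0.8, 0.4 * np.sqrt(n_berries))
    r_bottom = 0.3 * r_top
    min_sep = spacing * (1.0 - allowed_overlap)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_berries:
        attempts += 1
        if attempts > max_retries * n_berries:
            raise RuntimeError(
                f"could not pack {n_berries} berries with spacing {spacing} "
                f"after {attempts} attempts")
        y = rng.uniform(0.0, height)
        r_max = r_top + (r_bottom - r_top) * y / height
        rad = np.sqrt(rng.uniform()) * r_max
        ang = rng.uniform(0, 2 * np.pi)
        cand = np.array([rad * np.cos(ang), y, rad * np.sin(ang)])
        if centers and np.min(np.linalg.norm(np.array(centers) - cand, axis=1)) < min_sep:
            continue
        centers.append(cand)
    centers_arr = np.array(centers)
    centers_arr -= centers_arr.mean(axis=0)
    base = np.array([0.35, 0.55, 0.30])
    colors = np.clip(base + rng.normal(0, 0.04, size=(n_berries, 3)), 0.05, 0.95)
    radii = np.full(n_berries, berry_radius) * rng.uniform(0.92, 1.08, size=n_berries)
    # the background sphere stands in for the canopy/trellis a short distance
    # behind the bunch (field scenes are enclosed, not open); it also
    # guarantees every in-FoV ray hits geometry
    return SyntheticScene(centers=centers_arr, radii=radii, colors=colors,
                          background_radius=8.0, texture_seed=seed)


# -- trajectory ----------------------------------------------------------

@dataclass(frozen=True)
class CameraTrajectory:
    """Ordered ground-truth camera-to-world poses for each frame."""

    poses_c2w: tuple  # tuple[RigidTransform, ...]

    def __len__(self) -> int:
        return len(self.poses_c2w)

    def world_to_cam(self, t: int) -> RigidTransform:
        return self.poses_c2w[t].inverse()

    def relative_pose(self, t: int, t_prime: int) -> RigidTransform:
        """T_{t->t'}: maps camera-frame-t coordinates into camera frame t'."""
        return self.world_to_cam(t_prime).compose(self.poses_c2w[t])

    def relative_chain(self) -> list[RigidTransform]:
        """Consecutive relative poses T_{t->t+1} for t = 0..len-2."""
        return [self.relative_pose(t, t + 1) for t in range(len(self) - 1)]


def _look_at(position: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Camera-to-world pose with +z toward target and +y roughly world-down."""
    z = target - position
    z = z / np.linalg.norm(z)
    down = np.array([0.0, 1.0, 0.0])
    x = np.cross(down, z)
    nx = np.linalg.norm(x)
    if nx < 1e-9:  # looking straight up/down: pick an arbitrary right vector
        x = np.array([1.0, 0.0, 0.0])
    else:
        x = x / nx
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=1)
    return RigidTransform(rotation=R, translation=position)


def orbit_trajectory(n_frames: int = 20, radius: float = 4.0,
                     arc_degrees: float = 90.0, height: float = 0.0,
                     jitter: float = 0.02, seed: int = 0,
                     target: np.ndarray | None = None) -> CameraTrajectory:
    """Seeded circular orbit around the bunch centroid, viewing the centroid.

    ``jitter`` perturbs the camera position (fraction of the orbit radius)
    to emulate hand-held motion; every frame still views the target point.
    """
    rng = np.random.default_rng(seed)
    tgt = np.zeros(3) if target is None else np.asarray(target, float)
    closes = abs(arc_degrees % 360.0) < 1e-9 and arc_degrees > 0
    n_angle = n_frames if closes else max(n_frames - 1, 1)
    poses = []
    for i in range(n_frames):
        ang = np.deg2rad(arc_degrees) * i / n_angle
        pos = np.array([radius * np.sin(ang), height, -radius * np.cos(ang)])
        pos = pos + rng.normal(0, jitter * radius, size=3)
        poses.append(_look_at(pos + tgt, tgt))
    return CameraTrajectory(poses_c2w=tuple(poses))


# -- value noise ---------------------------------------------------------

def _lattice_hash(ix: np.ndarray, iy: np.ndarray, iz: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic pseudo-random values in [-1, 1] on the integer lattice."""
    h = (ix.astype(np.int64) * 73856093
         ^ iy.astype(np.int64) * 19349663
         ^ iz.astype(np.int64) * 83492791
         ^ np.int64(seed) * 2654435761)
    h = (h ^ (h >> 13)) * np.int64(1274126177)
    h = h ^ (h >> 16)
    return ((h & np.int64(0x7FFFFFFF)) / float(0x40000000)) - 1.0


def value_noise3(points: np.ndarray, seed: int = 0) -> np.ndarray:
    """Smooth trilinear value noise in [-1, 1] over (..., 3) points."""
    p = np.asarray(points, float)
    p0 = np.floor(p).astype(np.int64)
    f = p - p0
    f = f * f * (3.0 - 2.0 * f)  # smoothstep
    out = np.zeros(p.shape[:-1])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wgt = ((f[..., 0] if dx else 1 - f[..., 0])
                       * (f[..., 1] if dy else 1 - f[..., 1])
                       * (f[..., 2] if dz else 1 - f[..., 2]))
                out += wgt * _lattice_hash(p0[..., 0] + dx, p0[..., 1] + dy,
                                           p0[..., 2] + dz, seed)
    return out


# -- rendering -----------------------------------------------------------

@dataclass(frozen=True)
class RenderedView:
    """One ray-cast frame with exact ground truth.

    ``depth`` is the Euclidean distance from the camera center along the ray.
    ``points`` is the per-pixel 3D hit point in world coordinates (the
    correspondence map); ``ids`` is -1 outside the field of view, the berry
    index for berry hits, and ``n_berries`` for the background sphere.
    """

    image: np.ndarray        # (H, W, 3)
    depth: np.ndarray        # (H, W)
    valid: np.ndarray        # (H, W) bool, the camera field-of-view mask
    points: np.ndarray       # (H, W, 3) world hit points (nan outside FoV)
    ids: np.ndarray          # (H, W) int
    centers2d: pd.DataFrame  # columns: berry_id, x, y (visible berries only)


_LIGHT = np.array([0.35, -0.5, 0.75]) / np.linalg.norm([0.35, -0.5, 0.75])
_AMBIENT = 0.4


def _ray_sphere(origin: np.ndarray, dirs: np.ndarray, center: np.ndarray,
                radius: float) -> np.ndarray:
    """Smallest positive intersection distance per ray (inf for a miss)."""
    oc = center - origin
    b = dirs @ oc
    c = oc @ oc - radius * radius
    disc = b * b - c
    hit = disc >= 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    s_near = b - sq
    s_far = b + sq
    s = np.where(s_near > 1e-9, s_near, s_far)  # inside the sphere: far hit
    return np.where(hit & (s > 1e-9), s, np.inf)


def render_view(scene: SyntheticScene, pose_c2w: RigidTransform,
                cam: UOCMCamera) -> RenderedView:
    """Ray-cast the scene from one camera pose with exact analytic geometry."""
    h, w = cam.height, cam.width
    rays_cam, valid = unproject_mask(pixel_grid(cam), cam)
    dirs = rays_cam.reshape(-1, 3) @ pose_c2w.rotation.T
    origin = pose_c2w.translation
    n = scene.n_berries
    dists = np.full((h * w, n + 1), np.inf)
    for j in range(n):
        dists[:, j] = _ray_sphere(origin, dirs, scene.centers[j], scene.radii[j])
    dists[:, n] = _ray_sphere(origin, dirs, np.zeros(3), scene.background_radius)
    ids_flat = np.argmin(dists, axis=1)
    depth_flat = dists[np.arange(h * w), ids_flat]
    # every in-FoV ray hits the enclosing background sphere
    pts_flat = origin + dirs * depth_flat[:, None]

    # shading: Lambertian with fixed light + surface-attached value noise
    is_bg = ids_flat == n
    sphere_centers = np.vstack([scene.centers, np.zeros(3)])
    normals = pts_flat - sphere_centers[ids_flat]
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
    normals[is_bg] *= -1.0  # background is seen from inside
    lam = _AMBIENT + (1 - _AMBIENT) * np.maximum(normals @ -_LIGHT, 0.0)
    base = np.vstack([scene.colors, np.asarray(scene.background_color)])[ids_flat]
    freq = np.where(is_bg, scene.texture_frequency * 0.15, scene.texture_frequency)
    tex = 1.0 + scene.texture_amplitude * value_noise3(
        pts_flat * freq[:, None], seed=scene.texture_seed)
    img_flat = np.clip(base * (lam * tex)[:, None], 0.0, 1.0)

    valid_flat = valid.reshape(-1)
    img_flat[~valid_flat] = 0.0
    depth_flat = np.where(valid_flat, depth_flat, np.nan)
    pts_flat = np.where(valid_flat[:, None], pts_flat, np.nan)
    ids_flat = np.where(valid_flat, ids_flat, -1)

    image = img_flat.reshape(h, w, 3)
    depth = depth_flat.reshape(h, w)
    points = pts_flat.reshape(h, w, 3)
    ids = ids_flat.reshape(h, w)

    # visible berry centers: project each center; the berry is visible when
    # the surface rendered at that pixel belongs to it
    w2c = pose_c2w.inverse()
    rows = []
    cam_centers = w2c.apply(scene.centers)
    norms = np.linalg.norm(cam_centers, axis=1)
    front = cam_centers[:, 2] + cam.xi * norms > 1e-9
    for j in range(n):
        if not front[j]:
            continue
        uv = uocm_project(cam_centers[j], cam)
        ui, vi = int(round(uv[0])), int(round(uv[1]))
        if not (0 <= ui < w and 0 <= vi < h) or not valid[vi, ui]:
            continue
        if ids[vi, ui] == j:
            rows.append((j, float(uv[0]), float(uv[1])))
    centers2d = pd.DataFrame(rows, columns=["berry_id", "x", "y"])
    return RenderedView(image=image, depth=depth, valid=valid, points=points,
                        ids=ids, centers2d=centers2d)


def covisibility_mask(view_a: RenderedView, view_b: RenderedView,
                      pose_b_c2w: RigidTransform, cam: UOCMCamera,
                      rel_tol: float = 0.01) -> np.ndarray:
    """Pixels of view A whose 3D point is also visible (non-occluded) in view B.

    A point is covisible when its projection into B lands inside B's field of
    view and B's rendered depth there matches the point's distance to camera B
    within ``rel_tol`` (relative).
    """
    h, w = cam.height, cam.width
    mask = view_a.valid.copy()
    pts = view_a.points.reshape(-1, 3)
    ok = np.isfinite(pts[:, 0])
    w2c_b = pose_b_c2w.inverse()
    x_b = w2c_b.apply(np.where(ok[:, None], pts, 1.0))
    norms = np.linalg.norm(x_b, axis=1)
    front = x_b[:, 2] + cam.xi * norms > 1e-9
    ok &= front
    intr = cam.intrinsics
    denom = np.where(ok, x_b[:, 2] + cam.xi * norms, 1.0)
    u = intr.fx * x_b[:, 0] / denom + intr.cx
    v = intr.fy * x_b[:, 1] / denom + intr.cy
    ui = np.clip(np.round(u).astype(int), 0, w - 1)
    vi = np.clip(np.round(v).astype(int), 0, h - 1)
    inb = (u >= 0) & (u <= w - 1) & (v >= 0) & (v <= h - 1)
    ok &= inb & view_b.valid.reshape(h, w)[vi, ui]
    db = view_b.depth[vi, ui]
    same_depth = np.abs(db - norms) <= rel_tol * norms
    ok &= np.where(np.isfinite(db), same_depth, False)
    return (mask.reshape(-1) & ok).reshape(h, w)


# -- fixtures ------------------------------------------------------------

# Orbit radii are close range, as the bunches are filmed: the cluster fills
# a large fraction of the ~180° frame, the regime the method is designed for.
FIXTURE_PRESETS = {
    "orbit-small": dict(size=128, n_berries=30, n_frames=20, arc_degrees=90.0,
                        orbit_radius=3.0, berry_radius=0.35, spacing=0.65,
                        jitter=0.005, seed=0, fov_scale=1.4),
    # 180° over 60 frames ≈ 3°/frame, a hand-held 30 fps orbit subsampled in
    # time; fov_scale 2.8 frames the bunch filling most of the image, as the
    # real close-range captures do
    "train-tiny": dict(size=64, n_berries=25, n_frames=60, arc_degrees=180.0,
                       orbit_radius=2.6, berry_radius=0.35, spacing=0.65,
                       jitter=0.005, seed=0, fov_scale=2.8,
                       texture_amplitude=0.35),
}


@dataclass(frozen=True)
class Fixture:
    """In-memory fixture: scene, trajectory, camera and rendered views."""

    scene: SyntheticScene
    trajectory: CameraTrajectory
    camera: UOCMCamera
    views: tuple  # tuple[RenderedView, ...]


def build_fixture(name: str, seed: int | None = None) -> Fixture:
    """Render a named preset fully in memory (the test-suite entry point)."""
    if name not in FIXTURE_PRESETS:
        raise KeyError(f"unknown fixture preset {name!r}; "
                       f"choose from {sorted(FIXTURE_PRESETS)}")
    p = dict(FIXTURE_PRESETS[name])
    if seed is not None:
        p["seed"] = seed
    cam = default_synthetic_camera(size=p["size"], fov_scale=p.get("fov_scale", 1.0))
    scene = generate_bunch(n_berries=p["n_berries"], berry_radius=p["berry_radius"],
                           spacing=p["spacing"], seed=p["seed"])
    if "texture_amplitude" in p:
        import dataclasses
        scene = dataclasses.replace(scene, texture_amplitude=p["texture_amplitude"])
    traj = orbit_trajectory(n_frames=p["n_frames"], radius=p["orbit_radius"],
                            arc_degrees=p["arc_degrees"], jitter=p["jitter"],
                            seed=p["seed"] + 1)
    views = tuple(render_view(scene, pose, cam) for pose in traj.poses_c2w)
    return Fixture(scene=scene, trajectory=traj, camera=cam, views=views)


def make_fixture(name: str, outdir: str | Path, seed: int | None = None) -> Path:
    """Write a named preset to disk in the documented fixture layout.

    Layout: frames/NNNN.png, depth/NNNN.npy, correspond/NNNN.npy, poses.csv
    (camera-to-world, row-major R then t), centers.csv (frame, berry_id, x, y),
    calibration.yaml, scene.json.
    """
    fx = build_fixture(name, seed=seed)
    out = Path(outdir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "depth").mkdir(exist_ok=True)
    (out / "correspond").mkdir(exist_ok=True)
    pose_rows = []
    center_rows = []
    for t, view in enumerate(fx.views):
        imageio.imwrite(out / "frames" / f"{t:04d}.png",
                        (np.round(view.image * 255)).astype(np.uint8))
        np.save(out / "depth" / f"{t:04d}.npy", view.depth)
        np.save(out / "correspond" / f"{t:04d}.npy", view.points)
        pose = fx.trajectory.poses_c2w[t]
        pose_rows.append([t] + list(pose.rotation.reshape(-1)) + list(pose.translation))
        for _, row in view.centers2d.iterrows():
            center_rows.append([t, int(row.berry_id), row.x, row.y])
    pose_cols = (["frame"] + [f"r{i}{j}" for i in range(3) for j in range(3)]
                 + ["tx", "ty", "tz"])
    pd.DataFrame(pose_rows, columns=pose_cols).to_csv(out / "poses.csv", index=False)
    pd.DataFrame(center_rows, columns=["frame", "berry_id", "x", "y"]).to_csv(
        out / "centers.csv", index=False)
    save_calibration(fx.camera, out / "calibration.yaml")
    (out / "scene.json").write_text(json.dumps({
        "name": name,
        "berry_centers": fx.scene.centers.tolist(),
        "berry_radii": fx.scene.radii.tolist(),
        "background_radius": fx.scene.background_radius,
    }, indent=1))
    return out


def load_fixture(path: str | Path):
    """Read back a fixture directory written by :func:`make_fixture`."""
    from .camera import load_calibration

    path = Path(path)
    cam = load_calibration(path / "calibration.yaml")
    frames = []
    depths = []
    for f in sorted((path / "frames").glob("*.png")):
        frames.append(imageio.imread(f).astype(float) / 255.0)
        depths.append(np.load(path / "depth" / (f.stem + ".npy")))
    poses_df = pd.read_csv(path / "poses.csv")
    poses = []
    for _, row in poses_df.iterrows():
        R = np.array([[row[f"r{i}{j}"] for j in range(3)] for i in range(3)])
        poses.append(RigidTransform(rotation=R,
                                    translation=np.array([row.tx, row.ty, row.tz])))
    centers = pd.read_csv(path / "centers.csv")
    return cam, frames, depths, CameraTrajectory(poses_c2w=tuple(poses)), centers
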