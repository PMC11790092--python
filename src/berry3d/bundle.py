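"""Bundle adjustment with Huber-robust residuals on unit spheres.

Berry world positions ``w_j`` and camera poses ``T_t = (R_t, t_t)`` are
refined by minimizing

    sum_{t,j}  Huber_delta( || <x_{t,j}> - <R_t w_j + t_t> || )

where ``<x> = x / ||x||`` projects onto the unit sphere centered at each
camera — the natural residual for an omnidirectional camera — and the Huber
loss bounds the influence of outlier observations.  The first camera is the
gauge: ``T_1`` stays exactly the identity.

Because unit-sphere residuals are invariant to a global rescaling of all
points and translations, the objective has an exact scale null direction;
joint optimization is free to drift along it, while alternating between a
pose-only and a point-only half-step anchors the scale of each half-step in
the quantities held fixed and thus preserves the initial scale.

The inner solver is damped least squares (scipy's trust-region reflective
method) on a residual reparameterization ``g(r) = r * sqrt(2 H(|r|)) / |r|``
whose squared norm equals the Huber objective exactly.  Rotations are
optimized in a 3-parameter tangent (rotation-vector) increment around the
current estimate, avoiding Euler-angle singularities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .transforms import RigidTransform

__all__ = [
    "BAProblem",
    "BASolution",
    "sphere_residual",
    "objective",
    "solve_joint",
    "solve_alternating",
    "problem_from_tracks",
    "standard_perturbed_problem",
    "save_solution_json",
    "load_solution_json",
]

DEFAULT_HUBER_DELTA = 0.1


@dataclass(frozen=True)
class BAProblem:
    """Cameras, points and unit-sphere observations of one video part.

    ``obs_cam[k]``/``obs_point[k]`` index the camera and point of the k-th
    observation; ``obs_xyz[k]`` is the observed 3D position in that camera's
    frame (only its direction enters the objective).  ``poses[0]`` is pinned
    to the identity throughout optimization.
    """

    poses: tuple                 # tuple[RigidTransform]
    points: np.ndarray           # (J, 3)
    obs_cam: np.ndarray          # (M,) int
    obs_point: np.ndarray        # (M,) int
    obs_xyz: np.ndarray          # (M, 3)
    huber_delta: float = DEFAULT_HUBER_DELTA

    def __post_init__(self) -> None:
        if self.huber_delta <= 0:
            raise ValueError("huber_delta must be positive")
        if not self.poses[0].almost_equal(RigidTransform.identity(), tol=1e-12):
            raise ValueError("poses[0] must be the identity (gauge)")
        if self.obs_cam.max() >= len(self.poses) or self.obs_point.max() >= len(self.points):
            raise ValueError("observation indices out of range")

    @property
    def n_cameras(self) -> int:
        return len(self.poses)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def scale_metric(self) -> float:
        """Mean distance of the points to their centroid (the scale monitor)."""
        c = self.points.mean(axis=0)
        return float(np.linalg.norm(self.points - c, axis=1).mean())


@dataclass(frozen=True)
class BASolution:
    """Refined poses/points plus the optimization record."""

    problem: BAProblem           # with refined poses and points
    initial_objective: float
    final_objective: float
    trace: tuple                 # objective after each accepted (half-)step
    scale_before: float
    scale_after: float
    converged: bool = True


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("zero-norm vector cannot be projected onto the unit sphere")
    return x / n


def sphere_residual(obs: np.ndarray, w: np.ndarray, pose: RigidTransform) -> np.ndarray:
    """<obs> - <R w + t>; each row's norm lies in [0, 2]."""
    obs = np.atleast_2d(np.asarray(obs, float))
    w = np.atleast_2d(np.asarray(w, float))
    res = _normalize_rows(obs) - _normalize_rows(pose.apply(w))
    return res[0] if res.shape[0] == 1 and obs.ndim == 1 else res


def _residual_norms(problem: BAProblem, R: np.ndarray, t: np.ndarray,
                    points: np.ndarray) -> np.ndarray:
    """Norms of all unit-sphere residuals for stacked (N,3,3) R, (N,3) t."""
    pw = points[problem.obs_point]                       # (M, 3)
    Ro = R[problem.obs_cam]                              # (M, 3, 3)
    to = t[problem.obs_cam]
    proj = np.einsum("mij,mj->mi", Ro, pw) + to
    res = _normalize_rows(problem.obs_xyz) - _normalize_rows(proj)
    return np.linalg.norm(res, axis=1), res


def _huber(s: np.ndarray, delta: float) -> np.ndarray:
    return np.where(s <= delta, 0.5 * s * s, delta * (s - 0.5 * delta))


def objective(problem: BAProblem) -> float:
    """Sum of Huber losses of the unit-sphere residual norms."""
    R = np.stack([p.rotation for p in problem.poses])
    t = np.stack([p.translation for p in problem.poses])
    s, _ = _residual_norms(problem, R, t, problem.points)
    return float(_huber(s, problem.huber_delta).sum())


def _huber_residual_vector(problem: BAProblem, R, t, points) -> np.ndarray:
    """g(r) with 0.5 ||g||^2 == Huber objective (for least-squares solvers)."""
    s, res = _residual_norms(problem, R, t, points)
    h = _huber(s, problem.huber_delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(s > 0, np.sqrt(2.0 * h) / np.where(s > 0, s, 1.0), 1.0)
    return (res * scale[:, None]).ravel()


# -- parameter packing ---------------------------------------------------

def _unpack(problem: BAProblem, x: np.ndarray, opt_poses: bool, opt_points: bool):
    """Tangent-increment pose update and point coordinates from the vector x."""
    R0 = np.stack([p.rotation for p in problem.poses])
    t0 = np.stack([p.translation for p in problem.poses])
    n = problem.n_cameras
    idx = 0
    if opt_poses:
        k = (n - 1) * 6
        pv = x[idx:idx + k].reshape(n - 1, 6)
        idx += k
        dR = Rotation.from_rotvec(pv[:, :3]).as_matrix()
        R = R0.copy()
        t = t0.copy()
        R[1:] = np.einsum("nij,njk->nik", dR, R0[1:])
        t[1:] = t0[1:] + pv[:, 3:]
    else:
        R, t = R0, t0
    if opt_points:
        points = x[idx:idx + problem.n_points * 3].reshape(-1, 3)
    else:
        points = problem.points
    return R, t, points


def _pack_initial(problem: BAProblem, opt_poses: bool, opt_points: bool) -> np.ndarray:
    parts = []
    if opt_poses:
        parts.append(np.zeros((problem.n_cameras - 1) * 6))
    if opt_points:
        parts.append(problem.points.ravel())
    return np.concatenate(parts)


def _apply(problem: BAProblem, x, opt_poses, opt_points) -> BAProblem:
    R, t, points = _unpack(problem, x, opt_poses, opt_points)
    poses = tuple(RigidTransform(rotation=R[i], translation=t[i])
                  for i in range(problem.n_cameras))
    return replace(problem, poses=poses, points=np.asarray(points))


def _solve_step(problem: BAProblem, opt_poses: bool, opt_points: bool,
                max_nfev: int | None = None) -> BAProblem:
    x0 = _pack_initial(problem, opt_poses, opt_points)

    def fun(x):
        R, t, points = _unpack(problem, x, opt_poses, opt_points)
        return _huber_residual_vector(problem, R, t, points)

    res = least_squares(fun, x0, method="trf", max_nfev=max_nfev)
    updated = _apply(problem, res.x, opt_poses, opt_points)
    # trust-region steps only accept improvements, but guard regardless
    if objective(updated) > objective(problem):
        return problem
    return updated


# -- solvers -------------------------------------------------------------

def solve_joint(problem: BAProblem, max_nfev: int | None = None) -> BASolution:
    """Optimize all poses (T_1 pinned) and all points simultaneously."""
    f0 = objective(problem)
    s0 = problem.scale_metric()
    refined = _solve_step(problem, opt_poses=True, opt_points=True, max_nfev=max_nfev)
    f1 = objective(refined)
    return BASolution(problem=refined, initial_objective=f0, final_objective=f1,
                      trace=(f0, f1), scale_before=s0,
                      scale_after=refined.scale_metric(), converged=f1 <= f0)


def solve_alternating(problem: BAProblem, rounds: int = 10,
                      tol: float = 1e-8, max_nfev: int | None = None) -> BASolution:
    """Alternate pose-only and point-only half-steps.

    Each half-step holds one block fixed, anchoring the reconstruction scale;
    stops after ``rounds`` rounds or when the relative objective change in a
    round falls below ``tol``.
    """
    f0 = objective(problem)
    s0 = problem.scale_metric()
    trace = [f0]
    cur = problem
    for _ in range(rounds):
        before = trace[-1]
        cur = _solve_step(cur, opt_poses=True, opt_points=False, max_nfev=max_nfev)
        trace.append(objective(cur))
        cur = _solve_step(cur, opt_poses=False, opt_points=True, max_nfev=max_nfev)
        trace.append(objective(cur))
        if before > 0 and (before - trace[-1]) / before < tol:
            break
    return BASolution(problem=cur, initial_objective=f0, final_objective=trace[-1],
                      trace=tuple(trace), scale_before=s0,
                      scale_after=cur.scale_metric(), converged=trace[-1] <= f0)


# -- problem construction ------------------------------------------------

def problem_from_tracks(tracks, chain, huber_delta: float = DEFAULT_HUBER_DELTA,
                        frame_offset: int = 0) -> BAProblem:
    """Build a BA problem from berry tracks and the chained camera poses.

    Observations are the tracked berries' camera-frame 3D points; initial
    world points are the track means; initial poses the chained estimates.
    """
    obs_cam, obs_point, obs_xyz = [], [], []
    points = []
    for j, track in enumerate(tracks):
        points.append(track.mean_world_point)
        for o in track.observations:
            obs_cam.append(o.frame - frame_offset)
            obs_point.append(j)
            obs_xyz.append(o.cam_point)
    return BAProblem(
        poses=tuple(chain.cumulative),
        points=np.array(points),
        obs_cam=np.array(obs_cam, dtype=int),
        obs_point=np.array(obs_point, dtype=int),
        obs_xyz=np.array(obs_xyz, dtype=float),
        huber_delta=huber_delta,
    )


def standard_perturbed_problem(seed: int = 0, n_cameras: int = 20,
                               n_points: int = 50,
                               rot_noise_deg: float = 2.0,
                               trans_noise_frac: float = 0.02,
                               point_noise_frac: float = 0.02,
                               huber_delta: float = DEFAULT_HUBER_DELTA):
    """The reference perturbed instance for bundle-adjustment experiments.

    Exact unit-sphere observations of a synthetic bunch from an orbit of
    ``n_cameras`` cameras; initial poses carry ``rot_noise_deg`` rotation
    noise and translation noise of ``trans_noise_frac`` of the orbit radius;
    initial points carry noise of ``point_noise_frac`` of the bunch diameter.
    Returns ``(perturbed_problem, ground_truth_problem)``.
    """
    from .scene import generate_bunch, orbit_trajectory

    rng = np.random.default_rng(seed)
    orbit_radius = 3.0
    scene = generate_bunch(n_berries=n_points, seed=seed)
    traj = orbit_trajectory(n_frames=n_cameras, radius=orbit_radius,
                            arc_degrees=90.0, jitter=0.005, seed=seed + 1)
    c2w_1 = traj.poses_c2w[0]
    # gauge: world frame = first camera frame
    gt_poses = tuple(traj.world_to_cam(t).compose(c2w_1) for t in range(n_cameras))
    gt_points = c2w_1.inverse().apply(scene.centers)
    obs_cam, obs_point, obs_xyz = [], [], []
    for t in range(n_cameras):
        x = gt_poses[t].apply(gt_points)
        for j in range(n_points):
            obs_cam.append(t)
            obs_point.append(j)
            obs_xyz.append(x[j])
    gt = BAProblem(poses=gt_poses, points=gt_points,
                   obs_cam=np.array(obs_cam, int), obs_point=np.array(obs_point, int),
                   obs_xyz=np.array(obs_xyz, float), huber_delta=huber_delta)
    # perturb initial estimates (observations stay exact)
    diam = 2.0 * gt.scale_metric()
    poses = [gt_poses[0]]
    for t in range(1, n_cameras):
        drot = Rotation.from_rotvec(
            rng.normal(0, np.deg2rad(rot_noise_deg), 3)).as_matrix()
        dt = rng.normal(0, trans_noise_frac * orbit_radius, 3)
        poses.append(RigidTransform(rotation=drot @ gt_poses[t].rotation,
                                    translation=gt_poses[t].translation + dt))
    points = gt_points + rng.normal(0, point_noise_frac * diam, gt_points.shape)
    perturbed = replace(gt, poses=tuple(poses), points=points)
    return perturbed, gt


# -- serialization -------------------------------------------------------

def _problem_dict(problem: BAProblem) -> dict:
    return {
        "poses": [{"R": p.rotation.tolist(), "t": p.translation.tolist()}
                  for p in problem.poses],
        "points": problem.points.tolist(),
        "huber_delta": problem.huber_delta,
    }


def save_solution_json(solution: BASolution, path: str | Path) -> None:
    data = {
        "initial_objective": solution.initial_objective,
        "final_objective": solution.final_objective,
        "trace": list(solution.trace),
        "scale_before": solution.scale_before,
        "scale_after": solution.scale_after,
        "converged": solution.converged,
        "refined": _problem_dict(solution.problem),
    }
    Path(path).write_text(json.dumps(data, indent=1))


def load_solution_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
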