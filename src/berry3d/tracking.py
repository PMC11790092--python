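"""Lift 2D berry centers to 3D and link them across frames into tracks.

Berry centers (from an external instance-segmentation stage, or ground truth
on synthetic data) are unprojected with the estimated depth into each camera
frame, expressed in the world frame (camera frame of the first video frame)
through the chained relative poses, and linked frame-to-frame by mutual
nearest-neighbor search on 3D position: a pair is kept only when each
observation is the other's nearest neighbor in both the forward and the
backward direction.  Chains shorter than ``min_track_len`` (default five
consecutive frames) are discarded; surviving tracks carry the mean of their
world positions, the initial value for bundle adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .camera import UOCMCamera, unproject_mask
from .transforms import RigidTransform

__all__ = [
    "BerryObservation",
    "PoseChain",
    "BerryTrack",
    "chain_poses",
    "lift_centers",
    "match_mutual_nn",
    "build_tracks",
    "load_centers_csv",
    "save_tracks_csv",
    "DEFAULT_MIN_TRACK_LEN",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRACK_LEN = 5


@dataclass(frozen=True)
class BerryObservation:
    """One berry center seen in one frame, with its 3D lift."""

    frame: int
    center: tuple          # (u, v) pixel coordinates
    depth: float           # range along the ray, scene units
    cam_point: np.ndarray  # 3D point in the frame's camera coordinates
    world_point: np.ndarray  # same point in the world (first-camera) frame


@dataclass(frozen=True)
class PoseChain:
    """Cumulative poses T_t (world -> camera t) from consecutive relatives.

    T_1 is the identity (the first camera frame is the world frame) and
    T_{t+1} = T_{t->t+1} ∘ T_t.
    """

    relatives: tuple
    cumulative: tuple

    def __len__(self) -> int:
        return len(self.cumulative)

    def world_to_cam(self, t: int) -> RigidTransform:
        return self.cumulative[t]

    def cam_to_world(self, t: int) -> RigidTransform:
        return self.cumulative[t].inverse()


def chain_poses(rels: list[RigidTransform]) -> PoseChain:
    """Compose consecutive relative poses into cumulative world->camera poses."""
    cum = [RigidTransform.identity()]
    for rel in rels:
        if not isinstance(rel, RigidTransform):
            raise TypeError("chain_poses expects RigidTransform elements")
        cum.append(rel.compose(cum[-1]))
    return PoseChain(relatives=tuple(rels), cumulative=tuple(cum))


def _bilinear_depth(depth: np.ndarray, u: float, v: float) -> float:
    h, w = depth.shape
    u0 = int(np.clip(np.floor(u), 0, w - 2))
    v0 = int(np.clip(np.floor(v), 0, h - 2))
    du, dv = u - u0, v - v0
    patch = depth[v0:v0 + 2, u0:u0 + 2]
    if not np.all(np.isfinite(patch)):
        finite = patch[np.isfinite(patch)]
        if finite.size == 0:
            return np.nan
        return float(finite.mean())
    return float(patch[0, 0] * (1 - du) * (1 - dv) + patch[0, 1] * du * (1 - dv)
                 + patch[1, 0] * (1 - du) * dv + patch[1, 1] * du * dv)


def lift_centers(centers: np.ndarray, depth: np.ndarray, cam: UOCMCamera,
                 chain: PoseChain, t: int) -> list[BerryObservation]:
    """Unproject berry centers with sampled depth and express them in world frame.

    ``centers`` is (K, 2) pixel coordinates.  The camera-frame point is the
    unit ray scaled by the bilinearly-sampled depth; the world point applies
    the inverse cumulative pose.  Centers outside the field of view (or with
    undefined depth) are dropped with a logged warning.
    """
    centers = np.atleast_2d(np.asarray(centers, float))
    if centers.size == 0:
        return []
    rays, ok = unproject_mask(centers, cam)
    cam2world = chain.cam_to_world(t)
    out: list[BerryObservation] = []
    for k in range(len(centers)):
        u, v = centers[k]
        if not ok[k] or not (0 <= u <= cam.width - 1 and 0 <= v <= cam.height - 1):
            logger.warning("frame %d: center (%.1f, %.1f) outside FoV, dropped", t, u, v)
            continue
        d = _bilinear_depth(depth, u, v)
        if not np.isfinite(d) or d <= 0:
            logger.warning("frame %d: center (%.1f, %.1f) has no valid depth, dropped", t, u, v)
            continue
        cam_pt = rays[k] * d
        out.append(BerryObservation(
            frame=t, center=(float(u), float(v)), depth=d,
            cam_point=cam_pt, world_point=cam2world.apply(cam_pt)))
    return out


def match_mutual_nn(a: list[BerryObservation], b: list[BerryObservation],
                    max_dist: float | None = None) -> list[tuple[int, int]]:
    """Mutual nearest-neighbor pairs between two frames' world points.

    Pair (i, j) is kept iff j is i's nearest neighbor in ``b`` AND i is j's
    nearest neighbor in ``a`` AND their distance is <= ``max_dist``.  The
    default gate is 1.5x the median nearest-neighbor spacing within ``a``
    (an absolute gate would be meaningless at the arbitrary monocular scale).
    """
    if not a or not b:
        return []
    pa = np.array([o.world_point for o in a])
    pb = np.array([o.world_point for o in b])
    tree_a = cKDTree(pa)
    tree_b = cKDTree(pb)
    d_ab, nn_ab = tree_b.query(pa)   # for each a: nearest in b
    _, nn_ba = tree_a.query(pb)      # for each b: nearest in a
    if max_dist is None:
        if len(pa) >= 2:
            spacing, _ = tree_a.query(pa, k=2)
            max_dist = 1.5 * float(np.median(spacing[:, 1]))
        else:
            max_dist = np.inf
    pairs = []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] == i and d_ab[i] <= max_dist:
            pairs.append((i, int(j)))
    return pairs


@dataclass(frozen=True)
class BerryTrack:
    """Matched observations of one berry over consecutive frames."""

    observations: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        frames = [o.frame for o in self.observations]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be consecutive and increasing")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def frames(self) -> list[int]:
        return [o.frame for o in self.observations]

    @property
    def mean_world_point(self) -> np.ndarray:
        return np.mean([o.world_point for o in self.observations], axis=0)


def build_tracks(per_frame: list[list[BerryObservation]],
                 min_track_len: int = DEFAULT_MIN_TRACK_LEN,
                 max_dist: float | None = None) -> list[BerryTrack]:
    """Chain pairwise mutual-NN matches of consecutive frames into tracks.

    Tracks shorter than ``min_track_len`` are discarded.  Observations are
    partitioned: none belongs to two tracks.
    """
    open_tracks: dict[int, list[BerryObservation]] = {}  # keyed by index in current frame
    finished: list[list[BerryObservation]] = []
    prev = per_frame[0] if per_frame else []
    for i, obs in enumerate(prev):
        open_tracks[i] = [obs]
    for t in range(1, len(per_frame)):
        cur = per_frame[t]
        pairs = dict(match_mutual_nn(prev, cur, max_dist=max_dist))
        new_open: dict[int, list[BerryObservation]] = {}
        matched_js = set()
        for i, chain in open_tracks.items():
            j = pairs.get(i)
            if j is None:
                finished.append(chain)
            else:
                new_open[j] = chain + [cur[j]]
                matched_js.add(j)
        for j in range(len(cur)):
            if j not in matched_js:
                new_open[j] = [cur[j]]
        open_tracks = new_open
        prev = cur
    finished.extend(open_tracks.values())
    return [BerryTrack(observations=tuple(chain))
            for chain in finished if len(chain) >= min_track_len]


# -- CSV interfaces ------------------------------------------------------

def load_centers_csv(path: str | Path) -> dict[int, np.ndarray]:
    """Read a berry-center CSV with columns frame,x,y into per-frame arrays."""
    df = pd.read_csv(path)
    missing = {"frame", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"centers CSV {path} is missing columns {sorted(missing)}")
    return {int(f): g[["x", "y"]].to_numpy(float)
            for f, g in df.groupby("frame")}


def save_tracks_csv(tracks: list[BerryTrack], path: str | Path) -> None:
    """Write tracks as track_id,frame,x,y,X,Y,Z rows."""
    rows = []
    for tid, track in enumerate(tracks):
        for o in track.observations:
            rows.append([tid, o.frame, o.center[0], o.center[1],
                         o.world_point[0], o.world_point[1], o.world_point[2]])
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "X", "Y", "Z"]).to_csv(
        path, index=False)
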