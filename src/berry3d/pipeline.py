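"""End-to-end orchestration: frames in, per-part 3D berry positions out.

A bunch video is split into short parts (pose-network drift accumulates over
long sequences, so each part is reconstructed independently); per part the
pipeline runs depth/pose inference, chains the relative poses, lifts the 2D
berry centers to 3D, links them into tracks, refines everything by
alternating bundle adjustment, and exports point clouds, trajectories,
tracks and reports.  Merging parts into a whole-bunch model is intentionally
not implemented here.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd

from .bundle import BASolution, problem_from_tracks, solve_alternating
from .camera import UOCMCamera, fov_mask
from .networks import DepthNetwork, PoseNetwork
from .tracking import (
    DEFAULT_MIN_TRACK_LEN,
    BerryTrack,
    build_tracks,
    chain_poses,
    lift_centers,
    save_tracks_csv,
)
from .transforms import RigidTransform
from .viewsynth import LossWeights, normalized_inverse_depth

__all__ = [
    "PipelineConfig",
    "PartResult",
    "load_frames",
    "split_video",
    "reconstruct_part",
    "export_results",
    "export_ply",
    "load_ply",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Orchestration settings for one run."""

    part_len: int = 50
    part_overlap: int = 1
    min_track_len: int = DEFAULT_MIN_TRACK_LEN
    weights: LossWeights = field(default_factory=LossWeights)
    ba_rounds: int = 10
    huber_delta: float = 0.1
    depth_cutoff_percentile: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.part_len < self.min_track_len:
            raise ValueError("part_len must be >= min_track_len")


def load_frames(path: str | Path, target_size: int = 480) -> list[np.ndarray]:
    """Decode a video file or a directory of numbered images into [0,1] frames.

    Frames are resized to target_size x target_size by nearest-neighbor
    interpolation (an already-correctly-sized input passes through
    bit-identically).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        raw = [imageio.imread(f) for f in files]
    else:
        raw = [np.asarray(f) for f in imageio.mimread(path, memtest=False)]
    out = []
    for arr in raw:
        if arr.ndim == 2:
            arr = np.repeat(arr[..., None], 3, axis=2)
        arr = arr[..., :3]
        h, w = arr.shape[:2]
        if h != w:
            raise ValueError(f"frames must be square, got {h}x{w} (crop beforehand)")
        if h != target_size:
            idx = (np.arange(target_size) * h / target_size).astype(int)
            arr = arr[idx][:, idx]
        out.append(arr.astype(float) / 255.0)
    return out


def split_video(frames: list, part_len: int, overlap: int = 0) -> list[list]:
    """Split frames into consecutive parts; with ``overlap`` shared frames.

    The concatenation of parts (dropping the overlapped head of each
    subsequent part) reproduces the input order; a short tail part is kept
    and flagged with a log warning.
    """
    if part_len < 2:
        raise ValueError("part_len must be >= 2")
    if overlap >= part_len:
        raise ValueError("overlap must be < part_len")
    parts = []
    step = part_len - overlap
    start = 0
    while start < len(frames):
        part = frames[start:start + part_len]
        if len(part) <= overlap and parts:
            break
        parts.append(part)
        if start + part_len >= len(frames):
            break
        start += step
    if parts and len(parts[-1]) < part_len:
        logger.warning("short tail part with %d frames (< part_len %d)",
                       len(parts[-1]), part_len)
    return parts


@dataclass(frozen=True)
class PartResult:
    """All per-part intermediates."""

    frame_range: tuple           # (first, last+1) global frame indices
    frames: list                 # the part's RGB frames
    depths: list                 # per-frame depth maps
    relative_poses: list         # T_{t->t+1} within the part
    chain: object                # PoseChain
    tracks: list                 # list[BerryTrack]
    ba: BASolution | None
    ba_skipped_reason: str | None = None


def reconstruct_part(frames: list[np.ndarray], centers: dict[int, np.ndarray],
                     cam: UOCMCamera, cfg: PipelineConfig,
                     depth_net: DepthNetwork | None = None,
                     pose_net: PoseNetwork | None = None,
                     depths: list[np.ndarray] | None = None,
                     relative_poses: list[RigidTransform] | None = None,
                     frame_offset: int = 0) -> PartResult:
    """Reconstruct one part: inference, lifting, tracking, alternating BA.

    Either trained networks or precomputed depths/relative poses (e.g.
    synthetic ground truth) must be supplied.  ``centers`` maps local frame
    index -> (K, 2) pixel coordinates of berry centers.
    """
    n = len(frames)
    t_start = time.perf_counter()
    if depths is None:
        if depth_net is None:
            raise ValueError("provide depth_net or precomputed depths")
        depths = [depth_net.predict(f) for f in frames]
    if relative_poses is None:
        if pose_net is None:
            raise ValueError("provide pose_net or precomputed relative_poses")
        relative_poses = []
        for t in range(n - 1):
            # predict T_{t->t'} for sources (t-1 like, t+1): use pair (t, t+1)
            src_prev = frames[t - 1] if t > 0 else frames[t]
            poses = pose_net.predict(frames[t], [src_prev, frames[t + 1]])
            relative_poses.append(poses[1])
    chain = chain_poses(relative_poses)
    logger.info("part %s: %d frames, inference done in %.2fs",
                (frame_offset, frame_offset + n), n, time.perf_counter() - t_start)

    per_frame = []
    n_centers = 0
    for t in range(n):
        cts = centers.get(t, np.zeros((0, 2)))
        obs = lift_centers(cts, depths[t], cam, chain, t)
        n_centers += len(obs)
        per_frame.append(obs)
    tracks = build_tracks(per_frame, min_track_len=cfg.min_track_len)
    logger.info("lifted %d centers into %d tracks (min length %d)",
                n_centers, len(tracks), cfg.min_track_len)

    ba = None
    reason = None
    if tracks:
        problem = problem_from_tracks(tracks, chain, huber_delta=cfg.huber_delta)
        ba = solve_alternating(problem, rounds=cfg.ba_rounds)
        logger.info("BA: objective %.3g -> %.3g, scale %.4g -> %.4g",
                    ba.initial_objective, ba.final_objective,
                    ba.scale_before, ba.scale_after)
    else:
        reason = f"no tracks of length >= {cfg.min_track_len}; bundle adjustment skipped"
        logger.warning(reason)
    return PartResult(frame_range=(frame_offset, frame_offset + n),
                      frames=list(frames), depths=list(depths),
                      relative_poses=list(relative_poses), chain=chain,
                      tracks=tracks, ba=ba, ba_skipped_reason=reason)


# -- exports -------------------------------------------------------------

def export_ply(points: np.ndarray, colors: np.ndarray, path: str | Path) -> None:
    """Write an ASCII PLY point cloud (xyz + uchar RGB)."""
    points = np.asarray(points, float).reshape(-1, 3)
    colors = np.clip(np.asarray(colors, float).reshape(-1, 3) * 255, 0, 255).astype(np.uint8)
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(points)}",
        "property float x", "property float y", "property float z",
        "property uchar red", "property uchar green", "property uchar blue",
        "end_header",
    ]
    for p, c in zip(points, colors):
        lines.append(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g} {c[0]} {c[1]} {c[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_ply(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back an ASCII PLY written by :func:`export_ply`."""
    lines = Path(path).read_text().splitlines()
    start = lines.index("end_header") + 1
    data = np.array([[float(v) for v in ln.split()] for ln in lines[start:] if ln])
    return data[:, :3], data[:, 3:6] / 255.0


def _depth_heatmap(depth: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Inverse-depth heatmap (Jet-like: the closer, the redder); invalid -> 0."""
    from matplotlib import cm

    inv = np.where(valid & np.isfinite(depth) & (depth > 0), 1.0 / depth, 0.0)
    vmax = inv.max() if inv.max() > 0 else 1.0
    rgba = cm.jet(inv / vmax)
    rgba[~valid] = 0.0
    return (rgba[..., :3] * 255).astype(np.uint8)


def export_results(result: PartResult, cam: UOCMCamera, outdir: str | Path,
                   cfg: PipelineConfig | None = None) -> dict:
    """Write point clouds, trajectory, tracks, BA report and depth heatmaps.

    The per-frame point cloud keeps only valid pixels closer than the
    configured depth percentile (near regions carry the berries).  Returns a
    manifest dict (also written as JSON).
    """
    cfg = cfg or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mask = fov_mask(cam)
    manifest: dict = {"frame_range": list(result.frame_range), "files": []}

    # fused point cloud from per-frame depth (world frame = first part frame)
    from .camera import pixel_grid, unproject_mask
    rays, _ = unproject_mask(pixel_grid(cam), cam)
    for t, (frame, depth) in enumerate(zip(result.frames, result.depths)):
        valid = mask & np.isfinite(depth) & (depth > 0)
        if valid.any():
            cutoff = np.percentile(depth[valid], cfg.depth_cutoff_percentile)
            keep = valid & (depth <= cutoff)
        else:
            keep = valid
        pts_cam = rays[keep] * depth[keep][:, None]
        pts_world = result.chain.cam_to_world(t).apply(pts_cam)
        ply = out / f"cloud_{t:04d}.ply"
        export_ply(pts_world, frame[keep], ply)
        manifest["files"].append(ply.name)
        hm = out / f"invdepth_{t:04d}.png"
        imageio.imwrite(hm, _depth_heatmap(depth, mask))
        manifest["files"].append(hm.name)

    rows = []
    for t in range(len(result.chain)):
        pose = result.chain.world_to_cam(t)
        rows.append([t] + list(pose.rotation.reshape(-1)) + list(pose.translation))
    cols = ["frame"] + [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz"]
    pd.DataFrame(rows, columns=cols).to_csv(out / "trajectory.csv", index=False)
    manifest["files"].append("trajectory.csv")

    save_tracks_csv(result.tracks, out / "tracks.csv")
    manifest["files"].append("tracks.csv")

    report: dict = {"n_tracks": len(result.tracks)}
    if result.ba is not None:
        report.update(
            initial_objective=result.ba.initial_objective,
            final_objective=result.ba.final_objective,
            scale_before=result.ba.scale_before,
            scale_after=result.ba.scale_after,
            trace=list(result.ba.trace),
        )
        refined = np.asarray(result.ba.problem.points)
        export_ply(refined, np.tile([0.8, 0.2, 0.2], (len(refined), 1)),
                   out / "berries_refined.ply")
        manifest["files"].append("berries_refined.ply")
    else:
        report["skipped"] = result.ba_skipped_reason
    (out / "ba_report.json").write_text(json.dumps(report, indent=1))
    manifest["files"].append("ba_report.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
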