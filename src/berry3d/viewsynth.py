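"""Differentiable depth-image-based rendering (DIBR) and training losses.

Given the target frame's depth map and the relative pose to a source frame,
every target pixel is unprojected to a unit ray, scaled by its depth,
rigidly transformed into the source camera, and re-projected through the
omnidirectional model; bilinear resampling of the source at those continuous
coordinates reconstructs the target frame.  The photometric reconstruction
error (an SSIM + L1 mixture) plus an edge-aware smoothness term on the
mean-normalized inverse depth form the unsupervised training objective.

All losses are built from :mod:`berry3d.autodiff` tensors, so the same code
path serves plain numpy evaluation (constants in, ``.value`` out) and
gradient-based training.  Pixels that warp outside the source field of view
or behind the camera are excluded from every loss term rather than clamped:
a ~180° frame has a large invalid corner region, and border-clamping would
fabricate gradients there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, box_filter3, grid_sample, stack, where
from .camera import UOCMCamera, fov_mask, pixel_grid, unproject_mask
from .transforms import RigidTransform

__all__ = [
    "LossWeights",
    "SamplingGrid",
    "NoOverlapError",
    "compute_sampling_grid",
    "bilinear_resample",
    "photometric_error",
    "reprojection_loss",
    "smoothness_loss",
    "normalized_inverse_depth",
    "euler_rotation_t",
    "pose_vector_to_rt",
    "warp_coordinates_t",
    "reprojection_loss_t",
    "smoothness_loss_t",
    "total_loss_t",
]

_SSIM_C1 = 0.01**2
_SSIM_C2 = 0.03**2


class NoOverlapError(ValueError):
    """No valid pixel remained for a loss term (empty mask)."""


@dataclass(frozen=True)
class LossWeights:
    """alpha_pe: SSIM/L1 mixing weight in [0, 1]; lambda_smooth >= 0."""

    alpha_pe: float = 0.85
    lambda_smooth: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_pe <= 1.0:
            raise ValueError(f"alpha_pe must be in [0, 1], got {self.alpha_pe}")
        if self.lambda_smooth < 0:
            raise ValueError(f"lambda_smooth must be >= 0, got {self.lambda_smooth}")


@dataclass(frozen=True)
class SamplingGrid:
    """Continuous source-pixel coordinates for each target pixel, plus validity."""

    u: np.ndarray      # (H, W)
    v: np.ndarray      # (H, W)
    valid: np.ndarray  # (H, W) bool


# -- differentiable pose parameterization --------------------------------

def euler_rotation_t(angles: Tensor) -> Tensor:
    """Intrinsic XYZ Euler angles (3-tensor, radians) to a 3x3 rotation tensor."""
    one = Tensor(np.array(1.0))
    zero = Tensor(np.array(0.0))
    ax, ay, az = angles[0], angles[1], angles[2]
    ca, sa = ax.cos(), ax.sin()
    cb, sb = ay.cos(), ay.sin()
    cc, sc = az.cos(), az.sin()
    rx = stack([stack([one, zero, zero]), stack([zero, ca, -sa]), stack([zero, sa, ca])])
    ry = stack([stack([cb, zero, sb]), stack([zero, one, zero]), stack([-sb, zero, cb])])
    rz = stack([stack([cc, -sc, zero]), stack([sc, cc, zero]), stack([zero, zero, one])])
    return rx @ ry @ rz


def pose_vector_to_rt(vec: Tensor, angle_scale: float = 1.0) -> tuple[Tensor, Tensor]:
    """Six-vector (3 Euler angles, 3 translations) to (R, t) tensors.

    ``angle_scale`` multiplies the raw angle entries before conversion (the
    pose network emits pre-scaled outputs for optimization stability).
    """
    angles = vec[0:3] * angle_scale
    return euler_rotation_t(angles), vec[3:6]


def _as_rt_tensors(pose) -> tuple[Tensor, Tensor]:
    if isinstance(pose, RigidTransform):
        return Tensor(pose.rotation), Tensor(pose.translation)
    r, t = pose
    return (r if isinstance(r, Tensor) else Tensor(np.asarray(r, float)),
            t if isinstance(t, Tensor) else Tensor(np.asarray(t, float)))


# -- warp ----------------------------------------------------------------

def _sample_mask_bilinear(mask: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """True where the bilinear footprint of (u, v) lies entirely in `mask`."""
    h, w = mask.shape
    finite = np.isfinite(u) & np.isfinite(v)
    u = np.nan_to_num(u)
    v = np.nan_to_num(v)
    inb = finite & (u >= 0) & (u <= w - 1) & (v >= 0) & (v <= h - 1)
    u0 = np.clip(np.floor(u).astype(int), 0, max(w - 2, 0))
    v0 = np.clip(np.floor(v).astype(int), 0, max(h - 2, 0))
    m = (mask[v0, u0] & mask[v0, np.minimum(u0 + 1, w - 1)]
         & mask[np.minimum(v0 + 1, h - 1), u0]
         & mask[np.minimum(v0 + 1, h - 1), np.minimum(u0 + 1, w - 1)])
    return inb & m


def warp_coordinates_t(depth: Tensor, pose, cam: UOCMCamera,
                       target_valid: np.ndarray | None = None):
    """Differentiable warp: target depth + relative pose -> source coordinates.

    Returns ``(u, v, valid)`` where ``u``/``v`` are (H, W) tensors of
    continuous source-pixel coordinates and ``valid`` is a plain boolean
    mask (target in-FoV, point in front of the source model, footprint
    inside the source FoV).
    """
    h, w = cam.height, cam.width
    if depth.shape != (h, w):
        raise ValueError(f"depth shape {depth.shape} does not match camera {(h, w)}")
    rays, tgt_ok = unproject_mask(pixel_grid(cam), cam)
    tgt_ok = tgt_ok & np.isfinite(depth.data) & (depth.data > 0)
    if target_valid is not None:
        tgt_ok = tgt_ok & target_valid
    r_t, t_t = _as_rt_tensors(pose)
    depth = where(tgt_ok, depth, Tensor(np.ones_like(depth.data)))
    d_flat = depth.reshape(h * w, 1)
    x = d_flat * Tensor(rays.reshape(-1, 3))
    xp = x @ r_t.transpose(1, 0) + t_t
    n = (xp * xp).sum(axis=1).sqrt()
    z = xp[:, 2]
    denom_raw = z + float(cam.xi) * n
    front = denom_raw.data > 1e-9
    denom = where(front, denom_raw, Tensor(np.ones_like(denom_raw.data)))
    intr = cam.intrinsics
    u = (xp[:, 0] / denom) * intr.fx + intr.cx
    v = (xp[:, 1] / denom) * intr.fy + intr.cy
    src_mask = fov_mask(cam)
    ok = (tgt_ok.reshape(-1) & front
          & _sample_mask_bilinear(src_mask, u.data, v.data))
    return u.reshape(h, w), v.reshape(h, w), ok.reshape(h, w)


def compute_sampling_grid(depth: np.ndarray, pose: RigidTransform,
                          cam: UOCMCamera,
                          target_valid: np.ndarray | None = None) -> SamplingGrid:
    """Numpy-facing warp: see :func:`warp_coordinates_t`."""
    d = Tensor(np.asarray(depth, float))
    u, v, ok = warp_coordinates_t(d, pose, cam, target_valid)
    return SamplingGrid(u=u.value, v=v.value, valid=ok)


def bilinear_resample(source: np.ndarray, grid: SamplingGrid) -> np.ndarray:
    """Reconstruct the target frame by bilinear sampling of the source.

    Invalid grid cells receive NaN sentinels (they are excluded from losses).
    """
    src = np.asarray(source, float)
    chw = src.transpose(2, 0, 1) if src.ndim == 3 else src[None]
    out = grid_sample(chw, Tensor(grid.u), Tensor(grid.v)).value
    out = np.where(grid.valid[None], out, np.nan)
    return out.transpose(1, 2, 0) if src.ndim == 3 else out[0]


# -- photometric error ---------------------------------------------------

def _ssim_map_t(a: Tensor, b: Tensor) -> Tensor:
    """Per-pixel SSIM with a 3x3 mean-pooling window on (C, H, W) tensors."""
    mu_a = box_filter3(a)
    mu_b = box_filter3(b)
    sig_a = box_filter3(a * a) - mu_a * mu_a
    sig_b = box_filter3(b * b) - mu_b * mu_b
    cov = box_filter3(a * b) - mu_a * mu_b
    num = (mu_a * mu_b * 2.0 + _SSIM_C1) * (cov * 2.0 + _SSIM_C2)
    den = (mu_a * mu_a + mu_b * mu_b + _SSIM_C1) * (sig_a + sig_b + _SSIM_C2)
    return (num / den).mean(axis=0)


def _pe_map_t(a: Tensor, b: Tensor, w: LossWeights, valid: np.ndarray):
    """Per-pixel photometric error and the mask it may be averaged over.

    Both inputs are (C, H, W).  Invalid cells are zeroed before filtering so
    sentinel values can never leak into the loss; the usable mask is eroded
    by one pixel so every 3x3 SSIM window reads only valid pixels.
    """
    finite = np.isfinite(a.data).all(axis=0) & np.isfinite(b.data).all(axis=0)
    base = valid & finite
    a_c = where(base[None], a, Tensor(np.zeros_like(a.data)))
    b_c = where(base[None], b, Tensor(np.zeros_like(b.data)))
    mask = ndimage.binary_erosion(base, structure=np.ones((3, 3), bool))
    l1 = (a_c - b_c).abs().mean(axis=0)
    if w.alpha_pe > 0:
        ssim = _ssim_map_t(a_c, b_c)
        pe = (Tensor(np.array(1.0)) - ssim) * (w.alpha_pe / 2.0) + l1 * (1.0 - w.alpha_pe)
    else:
        pe = l1
    return pe, mask


def _masked_mean_t(x: Tensor, mask: np.ndarray) -> Tensor:
    n = int(mask.sum())
    if n == 0:
        raise NoOverlapError("empty valid mask in loss computation")
    return where(mask, x, Tensor(np.zeros_like(x.data))).sum() * (1.0 / n)


def _to_chw(img: np.ndarray | Tensor) -> Tensor:
    t = img if isinstance(img, Tensor) else Tensor(np.asarray(img, float))
    if t.ndim == 2:
        return t.reshape(1, *t.shape)
    return t.transpose(2, 0, 1)


def photometric_error(a: np.ndarray, b: np.ndarray, w: LossWeights | None = None,
                      valid: np.ndarray | None = None):
    """pe(a, b) = (alpha/2)(1 - SSIM) + (1 - alpha) L1, per pixel and averaged.

    Returns ``(error_map, scalar)``; the map is NaN outside the usable mask.
    """
    w = w or LossWeights()
    a_t = _to_chw(a)
    b_t = _to_chw(b)
    if a_t.shape != b_t.shape:
        raise ValueError(f"shape mismatch: {a_t.shape} vs {b_t.shape}")
    h, wd = a_t.shape[-2:]
    base = np.ones((h, wd), bool) if valid is None else np.asarray(valid, bool)
    pe, mask = _pe_map_t(a_t, b_t, w, base)
    scalar = _masked_mean_t(pe, mask)
    pe_map = np.where(mask, pe.value, np.nan)
    return pe_map, float(scalar.item())


# -- reprojection loss ---------------------------------------------------

def reprojection_loss_t(target: np.ndarray, sources: list, depth: Tensor,
                        poses: list, cam: UOCMCamera, w: LossWeights,
                        target_valid: np.ndarray | None = None) -> Tensor:
    """Sum over source frames of the masked photometric reconstruction error.

    ``poses[i]`` is the relative pose T_{t->t_i'} (a RigidTransform or a
    differentiable (R, t) tensor pair); pixels invalid in a warp are
    excluded from that term's mean.
    """
    if len(sources) != len(poses):
        raise ValueError(f"{len(sources)} sources but {len(poses)} poses")
    tgt = _to_chw(target)
    total = None
    for src, pose in zip(sources, poses):
        u, v, ok = warp_coordinates_t(depth, pose, cam, target_valid)
        src_chw = np.asarray(src, float)
        src_chw = src_chw.transpose(2, 0, 1) if src_chw.ndim == 3 else src_chw[None]
        recon = grid_sample(src_chw, u, v)
        pe, mask = _pe_map_t(tgt, recon, w, ok)
        if not mask.any():
            # the whole warp left the source frame: no overlap to penalize;
            # skip this term (other sources still constrain the estimate)
            continue
        term = _masked_mean_t(pe, mask)
        total = term if total is None else total + term
    if total is None:
        raise NoOverlapError("every source warp produced an empty valid mask")
    return total


def reprojection_loss(target: np.ndarray, sources: list, depth: np.ndarray,
                      poses: list[RigidTransform], cam: UOCMCamera,
                      w: LossWeights | None = None,
                      target_valid: np.ndarray | None = None) -> float:
    w = w or LossWeights()
    out = reprojection_loss_t(target, sources, Tensor(np.asarray(depth, float)),
                              poses, cam, w, target_valid)
    return float(out.item())


# -- smoothness loss -----------------------------------------------------

def normalized_inverse_depth(depth: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Inverse depth divided by its spatial mean over the valid mask."""
    d = np.asarray(depth, float)
    mask = np.isfinite(d) & (d > 0) if valid is None else np.asarray(valid, bool)
    inv = np.where(mask, 1.0 / np.where(mask, d, 1.0), 0.0)
    mean = inv[mask].mean()
    return np.where(mask, inv / mean, np.nan)


def smoothness_loss_t(depth: Tensor, image: np.ndarray,
                      valid: np.ndarray | None = None) -> Tensor:
    """Edge-aware smoothness of the mean-normalized inverse depth.

    mean over valid forward-difference pairs of
    |dx d*| e^{-|dx I|} + |dy d*| e^{-|dy I|}, image gradients averaged
    over color channels.
    """
    h, w = depth.shape
    img = np.asarray(image, float)
    if img.ndim == 2:
        img = img[..., None]
    if img.shape[:2] != (h, w):
        raise ValueError(f"image shape {img.shape[:2]} does not match depth {(h, w)}")
    mask = np.ones((h, w), bool) if valid is None else np.asarray(valid, bool)
    safe = where(mask, depth, Tensor(np.ones_like(depth.data)))
    inv = 1.0 / safe
    n = int(mask.sum())
    if n == 0:
        raise NoOverlapError("empty valid mask in smoothness loss")
    mean_inv = _masked_mean_t(inv, mask)
    dstar = inv / mean_inv
    gx_img = np.exp(-np.abs(np.diff(img, axis=1)).mean(axis=2))
    gy_img = np.exp(-np.abs(np.diff(img, axis=0)).mean(axis=2))
    mx = mask[:, 1:] & mask[:, :-1]
    my = mask[1:, :] & mask[:-1, :]
    if not (mx.any() or my.any()):
        raise NoOverlapError("no valid finite-difference pairs in smoothness loss")
    dx = (dstar[:, 1:] - dstar[:, :-1]).abs() * Tensor(gx_img)
    dy = (dstar[1:, :] - dstar[:-1, :]).abs() * Tensor(gy_img)
    total = None
    if mx.any():
        total = _masked_mean_t(dx, mx)
    if my.any():
        ty = _masked_mean_t(dy, my)
        total = ty if total is None else total + ty
    return total


def smoothness_loss(depth: np.ndarray, image: np.ndarray,
                    valid: np.ndarray | None = None) -> float:
    return float(smoothness_loss_t(Tensor(np.asarray(depth, float)), image, valid).item())


def total_loss_t(target: np.ndarray, sources: list, depth: Tensor, poses: list,
                 cam: UOCMCamera, w: LossWeights,
                 target_valid: np.ndarray | None = None) -> Tensor:
    """L = L_reprojection + lambda_smooth * L_smoothness."""
    loss = reprojection_loss_t(target, sources, depth, poses, cam, w, target_valid)
    if w.lambda_smooth > 0:
        loss = loss + smoothness_loss_t(depth, target, target_valid) * w.lambda_smooth
    return loss
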