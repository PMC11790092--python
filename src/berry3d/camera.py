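"""Pinhole and unified omnidirectional camera model (UOCM) geometry.

The UOCM describes wide field-of-view lenses (here a ~180° fisheye used to
film grape bunches at close range) by two successive projections: a 3D point
is first projected radially onto a unit sphere centered at the camera, and
the sphere point is then imaged by a pinhole camera whose center is displaced
by ``xi`` along the optical axis.  ``xi = 0`` recovers the ordinary pinhole
model exactly.

Conventions
-----------
* Camera frame: ``z`` along the optical axis, ``x`` right, ``y`` down.
* Pixel (0, 0) is the top-left pixel; integer coordinates are pixel centers.
* All functions are vectorized: points are ``(..., 3)`` arrays, pixels
  ``(..., 2)`` arrays; the scalar contract applies elementwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "UOCMCamera",
    "PointBehindCameraError",
    "DegeneratePointError",
    "OutsideModelError",
    "OutsideFovError",
    "CalibrationError",
    "pinhole_project",
    "uocm_project",
    "uocm_unproject",
    "fov_mask",
    "load_calibration",
    "default_synthetic_camera",
]


class PointBehindCameraError(ValueError):
    """A point with z <= 0 was passed to the pinhole projection."""


class DegeneratePointError(ValueError):
    """The zero vector cannot be projected onto the unit sphere."""


class OutsideModelError(ValueError):
    """The point lies behind the UOCM virtual pinhole center (z + xi*||x|| <= 0)."""


class OutsideFovError(ValueError):
    """The pixel lies outside the image of the unit sphere (negative discriminant)."""


class CalibrationError(ValueError):
    """A calibration file violated the camera-model invariants."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Focal lengths and principal point, assembled as the 3x3 matrix K."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise CalibrationError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        for name in ("fx", "fy", "cx", "cy"):
            if not np.isfinite(getattr(self, name)):
                raise CalibrationError(f"intrinsic {name} is not finite")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def K_inv(self) -> np.ndarray:
        return np.array(
            [
                [1.0 / self.fx, 0.0, -self.cx / self.fx],
                [0.0, 1.0 / self.fy, -self.cy / self.fy],
                [0.0, 0.0, 1.0],
            ]
        )


@dataclass(frozen=True)
class UOCMCamera:
    """Unified omnidirectional camera: intrinsics K plus sphere offset xi.

    ``xi`` is the dimensionless displacement of the virtual pinhole center
    behind the unit-sphere center along the optical axis; ``xi = 0``
    degenerates exactly to the pinhole model.
    """

    intrinsics: CameraIntrinsics
    xi: float
    image_size: tuple[int, int]  # (H, W)

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise CalibrationError(f"sphere offset xi must be >= 0, got {self.xi}")
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise CalibrationError(f"image_size must be positive, got {self.image_size}")

    @property
    def height(self) -> int:
        return int(self.image_size[0])

    @property
    def width(self) -> int:
        return int(self.image_size[1])


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError(f"points must have trailing dimension 3, got shape {pts.shape}")
    return pts


def pinhole_project(points: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Project 3D camera-frame points to pixels: (fx*x/z + cx, fy*y/z + cy).

    Raises :class:`PointBehindCameraError` if any point has z <= 0.
    """
    pts = _as_points(points)
    z = pts[..., 2]
    if np.any(z <= 0):
        raise PointBehindCameraError("pinhole projection requires z > 0 for all points")
    u = cam.fx * pts[..., 0] / z + cam.cx
    v = cam.fy * pts[..., 1] / z + cam.cy
    return np.stack([u, v], axis=-1)


def uocm_project(points: np.ndarray, cam: UOCMCamera) -> np.ndarray:
    """Project 3D camera-frame points through the unified omnidirectional model.

    The point is scaled onto the unit sphere, shifted by ``(0, 0, xi)`` into the
    virtual pinhole frame, and imaged by K:

        p = K (x + t_xi ||x||) / (z + xi ||x||)   (2D part)

    With ``xi = 0`` this equals :func:`pinhole_project` exactly.
    """
    pts = _as_points(points)
    norm = np.linalg.norm(pts, axis=-1)
    if np.any(norm == 0):
        raise DegeneratePointError("cannot project the zero vector")
    denom = pts[..., 2] + cam.xi * norm
    if np.any(denom <= 0):
        raise OutsideModelError("point behind the UOCM virtual pinhole center (z + xi*||x|| <= 0)")
    intr = cam.intrinsics
    u = intr.fx * pts[..., 0] / denom + intr.cx
    v = intr.fy * pts[..., 1] / denom + intr.cy
    return np.stack([u, v], axis=-1)


def uocm_unproject(pixels: np.ndarray, cam: UOCMCamera) -> np.ndarray:
    """Closed-form unprojection of pixels to unit rays in the camera frame.

    With ``m = K^-1 (u, v, 1)``:

        eta = (xi + sqrt(1 + (1 - xi^2)(||m||^2 - 1))) / ||m||^2
        ray = eta * m - (0, 0, xi)

    The ray has unit norm; depth along it is ambiguous by construction.
    Raises :class:`OutsideFovError` for pixels with a negative discriminant
    (outside the model's image of the sphere); zero discriminant is valid.
    """
    px = np.asarray(pixels, dtype=float)
    if px.shape[-1] != 2:
        raise ValueError(f"pixels must have trailing dimension 2, got shape {px.shape}")
    intr = cam.intrinsics
    mx = (px[..., 0] - intr.cx) / intr.fx
    my = (px[..., 1] - intr.cy) / intr.fy
    m_sq = mx * mx + my * my + 1.0
    disc = 1.0 + (1.0 - cam.xi**2) * (m_sq - 1.0)
    if np.any(disc < 0):
        raise OutsideFovError("pixel outside the field of view (negative discriminant)")
    eta = (cam.xi + np.sqrt(disc)) / m_sq
    ray = np.stack([eta * mx, eta * my, eta - cam.xi], axis=-1)
    # eta is constructed so the result is exactly unit norm; normalize to
    # remove the last ulps of rounding.
    ray /= np.linalg.norm(ray, axis=-1, keepdims=True)
    return ray


def pixel_grid(cam: UOCMCamera) -> np.ndarray:
    """(H, W, 2) array of pixel-center coordinates (u, v)."""
    h, w = cam.height, cam.width
    v, u = np.mgrid[0:h, 0:w].astype(float)
    return np.stack([u, v], axis=-1)


def unproject_mask(pixels: np.ndarray, cam: UOCMCamera) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized unprojection with a validity mask instead of raising.

    Valid pixels have a non-negative discriminant and a ray with z >= 0
    (the 180° field of view).  Rays at invalid pixels are set to (0, 0, 1).
    """
    px = np.asarray(pixels, dtype=float)
    intr = cam.intrinsics
    mx = (px[..., 0] - intr.cx) / intr.fx
    my = (px[..., 1] - intr.cy) / intr.fy
    m_sq = mx * mx + my * my + 1.0
    disc = 1.0 + (1.0 - cam.xi**2) * (m_sq - 1.0)
    ok = disc >= 0
    eta = np.where(ok, (cam.xi + np.sqrt(np.where(ok, disc, 0.0))) / m_sq, np.nan)
    ray = np.stack([eta * mx, eta * my, eta - cam.xi], axis=-1)
    ok = ok & (ray[..., 2] >= 0)
    ray = np.where(ok[..., None], ray, np.array([0.0, 0.0, 1.0]))
    ray /= np.linalg.norm(ray, axis=-1, keepdims=True)
    return ray, ok


def fov_mask(cam: UOCMCamera) -> np.ndarray:
    """(H, W) boolean mask of pixels whose unprojection is a valid 180° ray."""
    _, ok = unproject_mask(pixel_grid(cam), cam)
    return ok


def load_calibration(path: str | Path) -> UOCMCamera:
    """Load a YAML/JSON calibration file with keys fx, fy, cx, cy, xi, height, width.

    Validates the camera-model invariants and reports the offending field.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise CalibrationError(f"calibration file {path} does not contain a mapping")
    required = ["fx", "fy", "cx", "cy", "xi", "height", "width"]
    missing = [k for k in required if k not in data]
    if missing:
        raise CalibrationError(f"calibration file {path} is missing keys: {missing}")
    intr = CameraIntrinsics(fx=float(data["fx"]), fy=float(data["fy"]),
                            cx=float(data["cx"]), cy=float(data["cy"]))
    return UOCMCamera(intrinsics=intr, xi=float(data["xi"]),
                      image_size=(int(data["height"]), int(data["width"])))


def save_calibration(cam: UOCMCamera, path: str | Path) -> None:
    data = {
        "fx": float(cam.intrinsics.fx),
        "fy": float(cam.intrinsics.fy),
        "cx": float(cam.intrinsics.cx),
        "cy": float(cam.intrinsics.cy),
        "xi": float(cam.xi),
        "height": cam.height,
        "width": cam.width,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def default_synthetic_camera(size: int = 128, xi: float = 0.9,
                             fov_scale: float = 1.0) -> UOCMCamera:
    """A square omnidirectional camera for synthetic scenes.

    The 180° boundary ray (z = 0, unit norm) lands at pixel radius fx / xi
    from the principal point, so ``fx = xi * size / 2`` (``fov_scale = 1``)
    inscribes the full 180° circle in the frame.  Larger ``fov_scale``
    magnifies the central region, emulating how a filmed bunch fills a large
    fraction of the frame at close range.
    """
    f = fov_scale * xi * size / 2.0
    c = (size - 1) / 2.0
    return UOCMCamera(
        intrinsics=CameraIntrinsics(fx=f, fy=f, cx=c, cy=c),
        xi=xi,
        image_size=(size, size),
    )
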