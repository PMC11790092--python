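"""Rigid transforms (rotation + translation) and similarity alignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "euler_to_matrix", "umeyama_alignment"]

_ORTHO_TOL = 1e-9


def euler_to_matrix(angles: np.ndarray) -> np.ndarray:
    """Intrinsic XYZ Euler angles (radians) to a rotation matrix."""
    return Rotation.from_euler("XYZ", np.asarray(angles, dtype=float)).as_matrix()


@dataclass(frozen=True)
class RigidTransform:
    """A rigid motion x' = R x + t.

    ``a.compose(b)`` applies ``b`` first, then ``a`` (matrix product A·B).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6 or abs(np.linalg.det(R) - 1) > 1e-6:
            raise ValueError("rotation is not orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler_translation(cls, angles: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(rotation=euler_to_matrix(angles), translation=translation)

    @classmethod
    def from_rotvec_translation(cls, rotvec: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(rotation=Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   translation=translation)

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float)
        return cls(rotation=mat[:3, :3], translation=mat[:3, 3])

    def as_matrix(self) -> np.ndarray:
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.rotation, other.rotation, atol=tol)
            and np.allclose(self.translation, other.translation, atol=tol)
        )


def umeyama_alignment(src: np.ndarray, dst: np.ndarray, with_scale: bool = True):
    """Least-squares similarity (s, R, t) mapping src -> dst (Kabsch–Umeyama).

    Returns ``(s, R, t)`` minimizing ``sum ||dst_i - (s R src_i + t)||^2``.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2:
        raise ValueError("src and dst must be matching (N, d) arrays")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(src.shape[1])
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[-1, -1] = -1.0
    R = U @ S @ Vt
    var_s = (xs**2).sum() / len(src)
    s = float(np.trace(np.diag(D) @ S) / var_s) if with_scale else 1.0
    t = mu_d - s * R @ mu_s
    return s, R, t
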