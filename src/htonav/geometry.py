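"""Rigid-motion algebra and the registration residual/objective.

Conventions used throughout the package:

* lengths in millimetres, reported angles in degrees (trig internally in
  radians), right-handed coordinate frame;
* a :class:`RigidTransform` maps *model* ("moving", the virtual bone /
  holograph) coordinates into *physical* ("fixed", the real object)
  coordinates: ``p_fixed ≈ R @ p_moving + t``;
* the per-pair residual is ``e_i = p_i - (R p'_i + t)`` with ``p_i`` the fixed
  point and ``p'_i`` the moving point, and the overlay objective is
  ``J = 1/2 * sum_i |e_i|^2`` (mm^2).

The algebraic identity tolerance is 1e-9 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

_ORTHO_TOL = 1e-9


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.size == 3:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must have finite coordinates")
    return pts


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got shape {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection (det = -1), not a rotation")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> R @ p + t``.

    Parameters
    ----------
    R : (3, 3) array
        Rotation matrix, orthonormal with determinant +1.
    t : (3,) array
        Translation ("transfer") vector in mm.
    """

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", _check_rotation(self.R))
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, t=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` (through the origin), then translation."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be non-zero")
        axis = axis / n
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        return cls(R, np.asarray(t, dtype=float))

    def apply(self, points) -> np.ndarray:
        """Apply to an (n, 3) array (or a single point); returns (n, 3)."""
        pts = _as_points(points)
        return pts @ self.R.T + self.t

    def to_dict(self) -> dict:
        """Transform JSON schema: row-major rotation, translation, units."""
        return {
            "rotation": [float(v) for v in self.R.reshape(9)],
            "translation": [float(v) for v in self.t],
            "units": "mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        R = np.asarray(d["rotation"], dtype=float).reshape(3, 3)
        return cls(R, np.asarray(d["translation"], dtype=float))


@dataclass
class PointCloud:
    """An ordered set of 3D points in mm, with optional unique per-point labels."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if len(self.points) < 1:
            raise ValueError("a point cloud needs at least one point")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != len(self.points):
                raise ValueError("labels must match point count")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("labels must be unique")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CuttingPlane:
    """An osteotomy plane: origin on the bone surface, unit normal, role.

    ``role`` is ``"main"`` (the vertical-tunnel cut) or ``"side"`` (the
    horizontal-tunnel cut).
    """

    origin: np.ndarray
    normal: np.ndarray
    role: str = "main"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise DegenerateGeometryError("cutting plane normal must be non-zero")
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"cutting plane normal must be unit length (|n| = {norm:.3e})")
        self.normal = n
        if self.role not in ("main", "side"):
            raise ValueError(f"role must be 'main' or 'side', got {self.role!r}")


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Composite motion: apply ``inner`` first, then ``outer``."""
    return RigidTransform(outer.R @ inner.R, outer.R @ inner.t + outer.t)


def invert(T: RigidTransform) -> RigidTransform:
    """Inverse motion ``(R^T, -R^T t)``."""
    return RigidTransform(T.R.T, -T.R.T @ T.t)


def apply_transform(T: RigidTransform, cloud: PointCloud) -> PointCloud:
    """Map every point through ``T``; order and labels preserved."""
    return PointCloud(T.apply(cloud.points), None if cloud.labels is None else list(cloud.labels))


def rotation_angle_between(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic angle (degrees, in [0, 180]) between two rotations.

    Computed from the quaternion of ``Ra^T Rb`` (scipy), which stays accurate
    for near-identical rotations where the trace/arccos formula loses ~8
    digits.
    """
    from scipy.spatial.transform import Rotation

    Ra = _check_rotation(Ra)
    Rb = _check_rotation(Rb)
    return float(np.degrees(Rotation.from_matrix(Ra.T @ Rb).magnitude()))


def _paired(fixed: PointCloud, moving: PointCloud) -> tuple[np.ndarray, np.ndarray]:
    if len(fixed) != len(moving):
        raise ValueError(
            f"paired clouds must have equal counts (fixed {len(fixed)}, moving {len(moving)})"
        )
    return fixed.points, moving.points


def residual_errors(T: RigidTransform, fixed: PointCloud, moving: PointCloud) -> np.ndarray:
    """Per-pair residuals ``e_i = p_i - (R p'_i + t)`` as an (n, 3) array.

    ``fixed`` holds the real-object points ``p_i``; ``moving`` the model points
    ``p'_i``; pairing is by index.
    """
    p, q = _paired(fixed, moving)
    return p - T.apply(q)


def registration_objective(T: RigidTransform, fixed: PointCloud, moving: PointCloud) -> float:
    """Overlay objective ``J = 1/2 * sum_i |e_i|^2`` in mm^2 (>= 0)."""
    e = residual_errors(T, fixed, moving)
    return 0.5 * float(np.sum(e * e))
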