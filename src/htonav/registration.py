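"""Overlay solvers and registration accuracy metrics.

Two solvers cooperate in the two-stage procedure a navigation system performs:

* :func:`paired_point_register` — closed-form least-squares ("point matching"):
  given 3-7 index-paired landmarks it minimizes the overlay objective
  ``J = 1/2 sum |p_i - (R p'_i + t)|^2`` exactly via the SVD of the
  cross-covariance (Kabsch), with reflection correction so ``det(R) = +1``.
* :func:`icp_register` — iterative closest point ("surface matching"): given
  hundreds of unpaired surface points it alternates nearest-neighbour
  correspondence with the closed-form solve, monotonically decreasing the RMS
  nearest-point distance.

:func:`two_stage_register` chains them: the coarse landmark transform seeds
the ICP refinement.  Accuracy is quantified by the fiducial registration
error (RMS landmark residual) and the target registration error (mean
Euclidean deviation of target points under estimated vs true transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, LandmarkMatchError
from .geometry import (
    PointCloud,
    RigidTransform,
    invert,
    registration_objective,
    residual_errors,
)
from .meshio import LandmarkSet


@dataclass
class RegistrationResult:
    """Outcome of a registration solve.

    ``fre_mm`` is the RMS residual distance over the point pairs used by the
    final solve; for ICP, ``iterations`` and ``cost_history`` (RMS
    nearest-point distance after each transform update, non-increasing) are
    populated.
    """

    transform: RigidTransform
    fre_mm: float
    n_pairs: int
    iterations: int = 0
    cost_history: list[float] = field(default_factory=list)

    def metrics(self) -> dict:
        return {"fre_mm": self.fre_mm, "n_pairs": self.n_pairs, "iterations": self.iterations}


@dataclass
class TwoStageResult:
    """Coarse (point-matching) and refined (surface-matching) results."""

    coarse: RegistrationResult
    refined: RegistrationResult

    @property
    def transform(self) -> RigidTransform:
        return self.refined.transform


def paired_point_register(fixed: PointCloud, moving: PointCloud) -> RegistrationResult:
    """Closed-form rigid registration of index-paired clouds.

    Returns the global minimizer of ``J = 1/2 sum |p_i - (R p'_i + t)|^2``
    where ``fixed`` holds the real-object points ``p_i`` and ``moving`` the
    model points ``p'_i``.  Requires >= 3 non-collinear pairs; raises
    :class:`DegenerateGeometryError` for collinear configurations.  The
    smallest-singular-vector sign correction guarantees ``det(R) = +1``.
    """
    if len(fixed) != len(moving):
        raise ValueError("fixed and moving must have equal point counts")
    n = len(fixed)
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    p = fixed.points
    q = moving.points
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    H = qc.T @ pc  # cross-covariance, moving -> fixed
    # collinear configurations leave the rotation about the line unconstrained
    if np.linalg.matrix_rank(np.vstack([pc, qc]), tol=1e-9 * max(1.0, np.abs(pc).max(), np.abs(qc).max())) < 2:
        raise DegenerateGeometryError("point configuration is collinear; rotation is not determined")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = p.mean(axis=0) - R @ q.mean(axis=0)
    T = RigidTransform(R, t)
    fre = float(np.sqrt(2.0 * registration_objective(T, fixed, moving) / n))
    return RegistrationResult(transform=T, fre_mm=fre, n_pairs=n)


def nearest_correspondences(
    moving_now: PointCloud, fixed: PointCloud
) -> tuple[np.ndarray, np.ndarray]:
    """Pair every point of ``moving_now`` with its Euclidean-nearest point of
    ``fixed``; returns (indices into fixed, distances)."""
    tree = cKDTree(fixed.points)
    dist, idx = tree.query(moving_now.points, k=1)
    return np.asarray(idx, dtype=np.int64), np.asarray(dist, dtype=float)


def icp_register(
    fixed_surface: PointCloud,
    moving: PointCloud,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol_mm: float = 1e-4,
    trim_fraction: float = 0.0,
) -> RegistrationResult:
    """Point-to-point ICP of ``moving`` onto ``fixed_surface``.

    Alternates nearest-neighbour correspondence against ``fixed_surface`` with
    the closed-form paired solve, starting from ``init`` (identity when
    omitted), until the RMS nearest-point distance changes by less than
    ``tol_mm`` or ``max_iter`` is reached.  ``cost_history`` holds the RMS
    distance after each transform update and is non-increasing (with the
    default ``trim_fraction = 0``).  ``trim_fraction`` in [0, 0.5) discards
    that fraction of worst correspondences each iteration (off by default;
    useful against gross outliers but voids the monotonicity guarantee).
    """
    if tol_mm <= 0:
        raise ValueError("tol_mm must be > 0")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    T = RigidTransform.identity() if init is None else init
    tree = cKDTree(fixed_surface.points)
    history: list[float] = []
    prev = np.inf
    iterations = 0
    n_keep = max(3, int(np.ceil((1.0 - trim_fraction) * len(moving))))
    for iterations in range(1, max_iter + 1):
        moved = T.apply(moving.points)
        dist, idx = tree.query(moved, k=1)
        keep = np.sort(np.argsort(dist)[:n_keep]) if n_keep < len(moving) else slice(None)
        corr = PointCloud(fixed_surface.points[idx[keep]])
        kept_moving = PointCloud(moving.points[keep])
        T = paired_point_register(corr, kept_moving).transform
        rms = float(
            np.sqrt(np.mean(np.sum((corr.points - T.apply(kept_moving.points)) ** 2, axis=1)))
        )
        history.append(rms)
        if abs(prev - rms) < tol_mm:
            break
        prev = rms
    # final cost under fresh correspondences
    dist, _ = tree.query(T.apply(moving.points), k=1)
    fre = float(np.sqrt(np.mean(dist**2)))
    return RegistrationResult(
        transform=T,
        fre_mm=fre,
        n_pairs=len(moving),
        iterations=iterations,
        cost_history=history,
    )


def match_landmarks(
    fixed_landmarks: LandmarkSet, moving_landmarks: LandmarkSet
) -> tuple[PointCloud, PointCloud, list[str]]:
    """Pair landmark sets by shared labels (in fixed-set order); 3-7 shared
    labels are required, mirroring the point-matching protocol."""
    shared = [n for n in fixed_landmarks.names if n in set(moving_landmarks.names)]
    if len(shared) < 3:
        only_f = sorted(set(fixed_landmarks.names) - set(moving_landmarks.names))
        only_m = sorted(set(moving_landmarks.names) - set(fixed_landmarks.names))
        raise LandmarkMatchError(
            f"only {len(shared)} shared landmark labels {shared}; need 3-7 "
            f"(unmatched fixed: {only_f}, unmatched moving: {only_m})"
        )
    if len(shared) > 7:
        raise LandmarkMatchError(
            f"{len(shared)} shared landmark labels; point matching uses 3-7 points"
        )
    return (
        fixed_landmarks.subset(shared).as_cloud(),
        moving_landmarks.subset(shared).as_cloud(),
        shared,
    )


@dataclass
class TwoStageConfig:
    """Knobs for the two-stage procedure.

    ``query_side`` chooses which surface cloud supplies the ICP query points:
    ``"moving"`` (default, matching the plain ICP contract) queries the moving
    cloud against the fixed one; ``"fixed"`` queries the fixed cloud against
    the moving one, which is the right direction when the fixed cloud is a
    partial noisy scan of the full moving model (every scanned point then has
    a true counterpart, so partial visibility does not bias the fit).
    ``trim_fraction`` is passed through to the ICP stage.
    """

    min_surface_points: int = 10
    max_iter: int = 100
    tol_mm: float = 1e-4
    query_side: str = "moving"
    trim_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.query_side not in ("moving", "fixed"):
            raise ValueError("query_side must be 'moving' or 'fixed'")


def two_stage_register(
    fixed_landmarks: LandmarkSet,
    moving_landmarks: LandmarkSet,
    fixed_surface: PointCloud,
    moving_surface: PointCloud,
    config: TwoStageConfig | None = None,
) -> TwoStageResult:
    """Point matching then surface matching.

    Stage 1 solves the closed-form landmark registration ("coarse
    transformation matrix"); stage 2 refines it with ICP over the surface
    clouds.  Both results are returned so the refinement benefit can be
    measured.
    """
    config = config or TwoStageConfig()
    fixed_pts, moving_pts, _ = match_landmarks(fixed_landmarks, moving_landmarks)
    coarse = paired_point_register(fixed_pts, moving_pts)
    if min(len(fixed_surface), len(moving_surface)) < config.min_surface_points:
        raise ValueError(
            f"surface clouds must have at least {config.min_surface_points} points"
        )
    if config.query_side == "moving":
        refined = icp_register(
            fixed_surface,
            moving_surface,
            init=coarse.transform,
            max_iter=config.max_iter,
            tol_mm=config.tol_mm,
            trim_fraction=config.trim_fraction,
        )
    else:  # mirrored problem: register the fixed scan onto the moving model
        mirrored = icp_register(
            moving_surface,
            fixed_surface,
            init=invert(coarse.transform),
            max_iter=config.max_iter,
            tol_mm=config.tol_mm,
            trim_fraction=config.trim_fraction,
        )
        refined = RegistrationResult(
            transform=invert(mirrored.transform),
            fre_mm=mirrored.fre_mm,
            n_pairs=mirrored.n_pairs,
            iterations=mirrored.iterations,
            cost_history=mirrored.cost_history,
        )
    return TwoStageResult(coarse=coarse, refined=refined)


def fiducial_registration_error(
    T: RigidTransform, fixed_landmarks: PointCloud, moving_landmarks: PointCloud
) -> float:
    """RMS residual distance (mm) of the landmark pairs under ``T``."""
    e = residual_errors(T, fixed_landmarks, moving_landmarks)
    return float(np.sqrt(np.mean(np.sum(e * e, axis=1))))


def target_registration_error(
    T_est: RigidTransform, T_true: RigidTransform, targets: PointCloud
) -> float:
    """Mean Euclidean deviation (mm) of the targets under estimated vs true
    transform — the navigation-accuracy statistic."""
    d = T_est.apply(targets.points) - T_true.apply(targets.points)
    return float(np.mean(np.linalg.norm(d, axis=1)))
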