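"""Cutting-plane planning and planned-vs-achieved accuracy evaluation.

Coordinate convention (fixed throughout the package): the tibial shaft axis is
+Z (proximal up), X is medial-lateral, Y is anterior-posterior.  The two
osteotomy cuts — "main" (vertical tunnel) and "side" (horizontal tunnel) —
are near-transverse planes with near-Z normals, intersecting along a hinge
line that nominally runs anterior-posterior (Y).

Accuracy of an executed cut is reported as the angle between the planned and
achieved plane normals after projecting both onto the XZ or the YZ coordinate
plane, folded to [0, 90] degrees: the sagittal- and coronal-tilt errors of the
cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError
from .geometry import CuttingPlane, RigidTransform
from .meshio import TriangleMesh

PROJECTIONS = ("XZ", "YZ")
_DROP_AXIS = {"XZ": 1, "YZ": 0}  # coordinate zeroed by the projection


@dataclass
class PlanePair:
    """The planned main and side cutting planes plus their hinge line."""

    main: CuttingPlane
    side: CuttingPlane
    hinge_point: np.ndarray
    hinge_direction: np.ndarray

    def __post_init__(self) -> None:
        self.hinge_point = np.asarray(self.hinge_point, float).reshape(3)
        d = np.asarray(self.hinge_direction, float).reshape(3)
        self.hinge_direction = d / np.linalg.norm(d)
        ang = np.degrees(
            np.arccos(np.clip(abs(float(self.main.normal @ self.side.normal)), -1, 1))
        )
        if ang < 5.0:
            raise ValueError(
                f"main and side planes are nearly parallel ({ang:.2f} deg apart; need >= 5)"
            )

    def as_list(self) -> list[CuttingPlane]:
        return [self.main, self.side]


@dataclass
class AngleReport:
    """One projected planned-vs-achieved angle difference."""

    role: str  # "main" | "side"
    projection: str  # "XZ" | "YZ"
    angle_deg: float

    def __post_init__(self) -> None:
        if self.role not in ("main", "side"):
            raise ValueError(f"bad role {self.role!r}")
        if self.projection not in PROJECTIONS:
            raise ValueError(f"bad projection {self.projection!r}")
        if not 0.0 <= self.angle_deg <= 90.0:
            raise ValueError(f"angle {self.angle_deg} outside [0, 90]")


@dataclass
class PlaneConfig:
    """Placement of the planned cuts on a proximal tibia.

    ``main_height_frac`` positions the main cut along the shaft (fraction of
    the mesh's Z extent from the distal end); ``main_tilt_deg`` tilts the main
    plane about the hinge direction away from transverse; ``side_angle_deg``
    is the opening angle between the two cuts; ``side_offset_mm`` drops the
    side-cut origin below the main cut along the shaft.
    """

    main_height_frac: float = 0.8
    main_tilt_deg: float = 10.0
    side_angle_deg: float = 70.0
    side_offset_mm: float = 10.0


def make_cutting_planes(mesh: TriangleMesh, config: PlaneConfig | None = None) -> PlanePair:
    """Place the planned main/side cutting planes on a shaft-aligned tibia mesh.

    The hinge direction is +Y; the main normal is +Z tilted by
    ``main_tilt_deg`` about the hinge, the side normal is the main normal
    rotated a further ``side_angle_deg`` about the hinge (so the mutual angle
    equals ``side_angle_deg`` exactly, modulo the [0, 90] folding of reported
    angles).  Plane origins are snapped to the nearest mesh vertex on the
    medial (+X) cortex.
    """
    config = config or PlaneConfig()
    v = mesh.vertices
    zmin, zmax = float(v[:, 2].min()), float(v[:, 2].max())
    h = zmin + config.main_height_frac * (zmax - zmin)
    hinge = np.array([0.0, 1.0, 0.0])

    def rot_about_hinge(deg: float) -> np.ndarray:
        return RigidTransform.from_axis_angle(hinge, deg).R

    n_main = rot_about_hinge(config.main_tilt_deg) @ np.array([0.0, 0.0, 1.0])
    n_side = rot_about_hinge(config.side_angle_deg) @ n_main

    def snap(nominal: np.ndarray) -> np.ndarray:
        return v[np.argmin(np.linalg.norm(v - nominal, axis=1))]

    xmed = float(v[:, 0].max())
    o_main = snap(np.array([xmed, 0.0, h]))
    o_side = snap(np.array([xmed, 0.0, h - config.side_offset_mm]))
    pair = PlanePair(
        main=CuttingPlane(o_main, n_main, "main"),
        side=CuttingPlane(o_side, n_side, "side"),
        hinge_point=o_main,
        hinge_direction=hinge,
    )
    return pair


def transform_plane(T: RigidTransform, plane: CuttingPlane) -> CuttingPlane:
    """Map a plane through a rigid motion: origin affinely, normal by rotation."""
    return CuttingPlane(T.apply(plane.origin)[0], T.R @ plane.normal, plane.role)


def projected_angle_difference(
    planned: CuttingPlane, achieved: CuttingPlane, projection: str
) -> float:
    """Angle (degrees, folded to [0, 90]) between the planned and achieved
    plane normals after orthogonal projection onto the XZ or YZ plane.

    Symmetric in its plane arguments and invariant to flipping either normal.
    Raises :class:`DegenerateGeometryError` when a projected normal nearly
    vanishes (normal perpendicular to the projection plane).
    """
    if projection not in PROJECTIONS:
        raise ValueError(f"projection must be one of {PROJECTIONS}, got {projection!r}")
    drop = _DROP_AXIS[projection]
    u = planned.normal.copy()
    w = achieved.normal.copy()
    u[drop] = 0.0
    w[drop] = 0.0
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-6 or nw < 1e-6:
        raise DegenerateGeometryError(
            f"a plane normal is perpendicular to the {projection} plane; "
            "projected angle undefined"
        )
    # atan2 keeps full precision for near-identical normals (arccos loses
    # half the digits near 1); folding via |dot| lands the result in [0, 90]
    keep = [i for i in range(3) if i != drop]
    cross = abs(u[keep[0]] * w[keep[1]] - u[keep[1]] * w[keep[0]])
    return float(np.degrees(np.arctan2(cross, abs(float(u @ w)))))


def angle_reports(planned: PlanePair, achieved_main: CuttingPlane, achieved_side: CuttingPlane) -> list[AngleReport]:
    """The four projected angle differences {main, side} x {XZ, YZ}."""
    out = []
    for role, plan, ach in (("main", planned.main, achieved_main), ("side", planned.side, achieved_side)):
        for proj in PROJECTIONS:
            out.append(AngleReport(role, proj, projected_angle_difference(plan, ach, proj)))
    return out


def summarize_angle_differences(reports: pd.DataFrame) -> pd.DataFrame:
    """Summary statistics of angle differences per (modality, role, projection).

    ``reports`` needs columns ``modality``, ``role``, ``projection``,
    ``angle_deg``.  Returns one row per (modality, role, projection) group with
    mean, median, Q1/Q3 (linear-interpolation quantiles), min, max and n, plus
    one pooled row per modality (role = projection = "all") — the box-whisker
    summary of a trial series.
    """
    required = {"modality", "role", "projection", "angle_deg"}
    if not required.issubset(reports.columns):
        raise ValueError(f"reports must have columns {sorted(required)}")
    if reports.empty:
        raise ValueError("no angle reports to summarize")

    def stats(g: pd.Series) -> pd.Series:
        a = g.to_numpy(dtype=float)
        return pd.Series(
            {
                "mean": a.mean(),
                "median": np.quantile(a, 0.5),
                "q1": np.quantile(a, 0.25),
                "q3": np.quantile(a, 0.75),
                "min": a.min(),
                "max": a.max(),
                "n": len(a),
            }
        )

    per_group = (
        reports.groupby(["modality", "role", "projection"], sort=True)["angle_deg"]
        .apply(stats)
        .unstack()
        .reset_index()
    )
    pooled = (
        reports.groupby("modality", sort=True)["angle_deg"].apply(stats).unstack().reset_index()
    )
    pooled.insert(1, "role", "all")
    pooled.insert(2, "projection", "all")
    out = pd.concat([per_group, pooled], ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out


def boxplot_angle_differences(reports: pd.DataFrame, path: str) -> None:
    """Box-whisker figure of pooled angle differences per modality (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(reports["modality"].unique())
    data = [reports.loc[reports["modality"] == m, "angle_deg"].to_numpy() for m in groups]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel("angle difference (deg)")
    ax.set_xlabel("guidance modality")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
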