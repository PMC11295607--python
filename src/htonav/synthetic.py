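"""Synthetic sawbone generation and the simulated three-modality trial.

No external data: a parametric proximal-tibia stand-in (tubular shaft flaring
into a condylar head, modulated by smooth seeded bumps) plays the role of the
patient-specific sawbone models, with a known ground-truth pose per trial.
Three guidance modalities are emulated:

* ``metal`` — a patient-specific metal jig pinned to the bone: no registration
  step at all, only direct plane-tilt noise from jig seating and sawing.
* ``conventional`` — a tracked navigation workflow: five-landmark point
  matching followed by ICP surface matching, on noisier landmark picks but a
  precise digitized surface, plus screw-guided sawing tilt noise.
* ``ar`` — a tracker-less AR overlay: automatically extracted feature points
  registered pairwise then refined by ICP on a noisy, partially visible
  surface, plus freehand sawing tilt noise.

The default noise magnitudes are ILLUSTRATIVE: they are chosen to reflect the
relative error sources of the three workflows (jig-seated < screw-guided <
freehand; digitizer < tracker-less feature detection) and reproduce the
qualitative accuracy ordering metal < conventional < AR, not any measured
per-modality error budget.  See docs/methods.md.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .features import extract_feature_points, sample_surface_points
from .geometry import CuttingPlane, PointCloud, RigidTransform, compose, invert
from .meshio import LandmarkSet, TriangleMesh
from .planning import (
    AngleReport,
    PlaneConfig,
    PlanePair,
    angle_reports,
    make_cutting_planes,
    summarize_angle_differences,
    transform_plane,
)
from .registration import (
    TwoStageConfig,
    icp_register,
    paired_point_register,
    target_registration_error,
    two_stage_register,
)

MODALITIES = ("metal", "conventional", "ar")


@dataclass
class PatientShapeParams:
    """Shape of one synthetic proximal tibia.

    ``shaft_radius_mm`` is the diaphyseal radius; ``condylar_flare`` the ratio
    of maximal proximal radius to shaft radius (>= 1); ``shaft_length_mm`` the
    modelled segment length; ``bump_amplitude_mm`` the peak amplitude of the
    smooth seeded surface bumps standing in for anatomical relief.
    """

    shaft_radius_mm: float = 15.0
    condylar_flare: float = 1.8
    shaft_length_mm: float = 160.0
    bump_amplitude_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shaft_radius_mm, self.shaft_length_mm) <= 0:
            raise ValueError("radius and length must be positive")
        if self.condylar_flare < 1.0:
            raise ValueError("condylar flare must be >= 1")
        if self.bump_amplitude_mm < 0:
            raise ValueError("bump amplitude must be >= 0")
        if self.bump_amplitude_mm >= 0.5 * self.shaft_radius_mm:
            raise ValueError(
                "bump amplitude >= half the shaft radius risks a self-intersecting surface"
            )


def make_synthetic_tibia(
    params: PatientShapeParams, n_theta: int = 40, n_z: int = 48
) -> TriangleMesh:
    """Generate a closed tibia-like surface mesh, shaft axis along +Z.

    The radial profile is ``r(z) = R * (1 + (flare - 1) * s(z))`` with ``s`` a
    smoothstep ramp over the proximal 30% of the length, plus a smooth seeded
    low-order Fourier bump field that vanishes at both ends.  Deterministic
    per ``params.seed``.
    """
    R0, L = params.shaft_radius_mm, params.shaft_length_mm
    z = np.linspace(0.0, L, n_z)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    u = np.clip((z / L - 0.7) / 0.3, 0.0, 1.0)
    profile = R0 * (1.0 + (params.condylar_flare - 1.0) * u * u * (3 - 2 * u))

    rng = np.random.default_rng(params.seed)
    TH, ZZ = np.meshgrid(theta, z)  # (n_z, n_theta)
    bump = np.zeros_like(TH)
    for k in range(1, 4):
        for m in range(1, 4):
            amp = rng.normal()
            phase = rng.uniform(0, 2 * np.pi)
            bump += amp * np.cos(k * TH + phase) * np.sin(np.pi * m * ZZ / L)
    if params.bump_amplitude_mm > 0 and np.abs(bump).max() > 0:
        bump *= params.bump_amplitude_mm / np.abs(bump).max()
    else:
        bump[:] = 0.0

    r = profile[:, None] + bump
    if r.min() <= 0.1 * R0:
        raise ValueError("shape parameters collapse the surface (radial profile too small)")
    X = r * np.cos(TH)
    Y = r * np.sin(TH)
    verts = np.column_stack([X.ravel(), Y.ravel(), ZZ.ravel()])

    def vid(i: int, j: int) -> int:
        return i * n_theta + (j % n_theta)

    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append((a, b, d))
            faces.append((a, d, c))
    # cap each end by a fan from one rim vertex: keeps every vertex on the tube
    for j in range(1, n_theta - 1):
        faces.append((vid(0, 0), vid(0, j + 1), vid(0, j)))
        faces.append((vid(n_z - 1, 0), vid(n_z - 1, j), vid(n_z - 1, j + 1)))
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64))


def perturb_point_cloud(
    cloud: PointCloud,
    sigma_mm: float,
    outlier_fraction: float,
    overlap_fraction: float,
    seed: int,
) -> PointCloud:
    """Emulate a noisy partial scan of a point cloud, deterministically.

    Keeps ``ceil(overlap_fraction * n)`` points on one side of a seeded
    half-space cut (partial visibility), adds isotropic Gaussian noise of
    standard deviation ``sigma_mm`` per axis, then replaces
    ``round(outlier_fraction * m)`` of the retained points with uniform draws
    in a box twice the cloud's bounding box.  With ``sigma_mm = 0``,
    ``outlier_fraction = 0`` and ``overlap_fraction = 1`` the cloud is
    returned unchanged.
    """
    if not 0 <= outlier_fraction < 1:
        raise ValueError("outlier_fraction must be in [0, 1)")
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    rng = np.random.default_rng(seed)
    pts = cloud.points
    n = len(pts)
    m = int(np.ceil(overlap_fraction * n))
    if m < n:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        keep = np.sort(np.argsort(pts @ direction)[::-1][:m])
        pts = pts[keep]
    out = pts.copy()
    if sigma_mm > 0:
        out = out + rng.normal(scale=sigma_mm, size=out.shape)
    k = int(round(outlier_fraction * m))
    if k > 0:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        center, half = (lo + hi) / 2, (hi - lo) / 2
        idx = rng.choice(m, size=k, replace=False)
        out[idx] = rng.uniform(center - half * 2, center + half * 2, size=(k, 3))
    return PointCloud(out)


@dataclass
class ModalityErrorModel:
    """Error sources of one guidance modality (all illustrative defaults).

    ``landmark_sigma_mm`` applies to manually picked landmarks (conventional)
    or automatically detected feature points (AR); ``surface_sigma_mm``,
    ``outlier_fraction`` and ``overlap_fraction`` shape the simulated surface
    scan; ``tilt_sigma_deg`` is the direct plane-tilt noise of executing the
    cut (jig seating / screw guidance / freehand sawing).
    """

    name: str
    landmark_sigma_mm: float = 0.0
    surface_sigma_mm: float = 0.0
    outlier_fraction: float = 0.0
    overlap_fraction: float = 1.0
    tilt_sigma_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.name!r}")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if min(self.landmark_sigma_mm, self.surface_sigma_mm, self.tilt_sigma_deg) < 0:
            raise ValueError("noise magnitudes must be >= 0")


def default_error_models() -> dict[str, ModalityErrorModel]:
    """The three default arms; magnitudes are illustrative, not calibrated."""
    return {
        "metal": ModalityErrorModel(name="metal", tilt_sigma_deg=0.5),
        "conventional": ModalityErrorModel(
            name="conventional",
            landmark_sigma_mm=1.0,
            surface_sigma_mm=0.3,
            outlier_fraction=0.02,
            overlap_fraction=0.7,
            tilt_sigma_deg=1.0,
        ),
        "ar": ModalityErrorModel(
            name="ar",
            landmark_sigma_mm=2.0,
            surface_sigma_mm=1.0,
            outlier_fraction=0.05,
            overlap_fraction=0.6,
            tilt_sigma_deg=2.0,
        ),
    }


@dataclass
class TrialConfig:
    """Problem sizes and pose prior for one simulated trial."""

    n_surface_points: int = 300
    n_landmarks: int = 5  # conventional arm: five-point matching
    n_features: int = 50  # AR arm: auto-detected feature correspondences
    max_rotation_deg: float = 30.0
    max_translation_mm: float = 50.0
    icp_max_iter: int = 100
    icp_tol_mm: float = 1e-4


@dataclass
class TrialResult:
    """Per-sawbone outcome: estimated vs true pose and the four angle errors."""

    modality: str
    trial_id: str
    T_true: RigidTransform
    T_est: RigidTransform
    tre_mm: float
    reports: list[AngleReport]

    def __post_init__(self) -> None:
        if self.tre_mm < 0:
            raise ValueError("TRE must be >= 0")
        if len(self.reports) != 4:
            raise ValueError("a trial carries exactly 4 angle reports")


def _random_pose(rng: np.random.Generator, cfg: TrialConfig) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, cfg.max_rotation_deg)
    t = rng.uniform(-cfg.max_translation_mm, cfg.max_translation_mm, size=3)
    return RigidTransform.from_axis_angle(axis, angle, t)


def _tilt_plane(plane, rng: np.random.Generator, sigma_deg: float):
    """Rotate a plane's normal by an angle ~ N(0, sigma) about a random axis
    perpendicular to the normal (pure tilt, origin kept)."""
    if sigma_deg == 0:
        return plane
    a = rng.normal(size=3)
    a -= (a @ plane.normal) * plane.normal
    a /= np.linalg.norm(a)
    ang = rng.normal(scale=sigma_deg)
    R = RigidTransform.from_axis_angle(a, ang).R
    return CuttingPlane(plane.origin, R @ plane.normal, plane.role)


def simulate_trial(
    mesh: TriangleMesh,
    planes: PlanePair,
    model: ModalityErrorModel,
    seed: int,
    config: TrialConfig | None = None,
    trial_id: str = "trial",
) -> TrialResult:
    """Simulate one sawbone trial of the given modality.

    A ground-truth pose ``T_true`` (model -> physical frame) is drawn; noisy
    physical-side data are synthesized per the modality's error model; the
    modality's registration pipeline produces ``T_est``; the achieved cut
    planes are the planned planes mapped through ``invert(T_est) . T_true``
    (the surgeon cuts exactly on the displayed virtual plane, so navigation
    error is the only systematic error) plus direct tilt noise.  TRE is the
    mean Euclidean deviation at the plane origins.
    """
    cfg = config or TrialConfig()
    rng = np.random.default_rng(seed)
    T_true = _random_pose(rng, cfg)
    sub = rng.integers(0, 2**31 - 1, size=6)

    if model.name == "metal":
        # jig pinned to the bone: the pose is known by construction
        T_est = T_true
    else:
        base = sample_surface_points(mesh, cfg.n_surface_points, seed=int(sub[0]))
        scan = perturb_point_cloud(
            base,
            model.surface_sigma_mm,
            model.outlier_fraction,
            model.overlap_fraction,
            seed=int(sub[1]),
        )
        fixed_surface = PointCloud(T_true.apply(scan.points))
        n_pts = cfg.n_landmarks if model.name == "conventional" else cfg.n_features
        marks = extract_feature_points(mesh, n_pts, seed=int(sub[2]))
        lm_noise = np.random.default_rng(int(sub[3])).normal(
            scale=model.landmark_sigma_mm, size=marks.points.shape
        ) if model.landmark_sigma_mm > 0 else 0.0
        fixed_marks = T_true.apply(marks.points) + lm_noise
        # surface matching queries the digitized physical points against the
        # virtual model (query_side="fixed"): every scanned point has a true
        # counterpart, so partial visibility does not bias the fit
        icp_cfg = TwoStageConfig(
            max_iter=cfg.icp_max_iter, tol_mm=cfg.icp_tol_mm, query_side="fixed"
        )
        if model.name == "conventional":
            labels = [f"L{i}" for i in range(n_pts)]
            result = two_stage_register(
                LandmarkSet(labels, fixed_marks),
                LandmarkSet(labels, marks.points),
                fixed_surface,
                base,
                icp_cfg,
            )
            T_est = result.transform
        else:  # ar: paired feature registration, then ICP refinement
            coarse = paired_point_register(PointCloud(fixed_marks), marks)
            mirrored = icp_register(
                base,
                fixed_surface,
                init=invert(coarse.transform),
                max_iter=cfg.icp_max_iter,
                tol_mm=cfg.icp_tol_mm,
            )
            T_est = invert(mirrored.transform)

    targets = PointCloud(np.vstack([planes.main.origin, planes.side.origin]))
    tre = target_registration_error(T_est, T_true, targets)

    # achieved planes in the model frame: navigation error then saw-tilt noise
    D = compose(invert(T_est), T_true)
    tilt_rng = np.random.default_rng(int(sub[4]))
    ach_main = _tilt_plane(transform_plane(D, planes.main), tilt_rng, model.tilt_sigma_deg)
    ach_side = _tilt_plane(transform_plane(D, planes.side), tilt_rng, model.tilt_sigma_deg)
    reports = angle_reports(planes, ach_main, ach_side)
    return TrialResult(model.name, trial_id, T_true, T_est, tre, reports)


@dataclass
class ExperimentConfig:
    """A cohort experiment: patients x replicates x modalities."""

    n_patients: int = 10
    n_replicates: int = 1
    seed: int = 0
    models: dict[str, ModalityErrorModel] = field(default_factory=default_error_models)
    plane_config: PlaneConfig = field(default_factory=PlaneConfig)
    trial_config: TrialConfig = field(default_factory=TrialConfig)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "n_patients": self.n_patients,
                "n_replicates": self.n_replicates,
                "seed": self.seed,
                "models": {k: asdict(v) for k, v in sorted(self.models.items())},
                "plane_config": asdict(self.plane_config),
                "trial_config": asdict(self.trial_config),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _patient_params(rng: np.random.Generator) -> PatientShapeParams:
    return PatientShapeParams(
        shaft_radius_mm=rng.uniform(12.0, 18.0),
        condylar_flare=rng.uniform(1.5, 2.0),
        shaft_length_mm=rng.uniform(140.0, 180.0),
        bump_amplitude_mm=rng.uniform(0.5, 1.5),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def run_experiment(
    config: ExperimentConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full cohort: one trial per (patient, replicate, modality).

    Returns ``(reports, summary, provenance)``: ``reports`` has one row per
    (trial, plane role, projection) with its angle difference and the trial's
    TRE; ``summary`` is :func:`summarize_angle_differences` of it; provenance
    records the seed and a config hash.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for p in range(config.n_patients):
        params = _patient_params(rng)
        mesh = make_synthetic_tibia(params)
        planes = make_cutting_planes(mesh, config.plane_config)
        for r in range(config.n_replicates):
            for name in sorted(config.models):
                model = config.models[name]
                trial_seed = int(rng.integers(0, 2**31 - 1))
                trial = simulate_trial(
                    mesh,
                    planes,
                    model,
                    seed=trial_seed,
                    config=config.trial_config,
                    trial_id=f"P{p:02d}R{r:02d}",
                )
                for rep in trial.reports:
                    rows.append(
                        {
                            "patient": p,
                            "replicate": r,
                            "modality": name,
                            "trial_id": trial.trial_id,
                            "role": rep.role,
                            "projection": rep.projection,
                            "angle_deg": rep.angle_deg,
                            "tre_mm": trial.tre_mm,
                            "seed": trial_seed,
                        }
                    )
    reports = pd.DataFrame(rows)
    summary = summarize_angle_differences(reports)
    provenance = {"seed": config.seed, "config_hash": config.config_hash()}
    return reports, summary, provenance
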