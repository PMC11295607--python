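# Methods

## Problem setting and conventions

All computations live in a right-handed frame with lengths in millimetres and
reported angles in degrees.  The tibial shaft axis is +Z (proximal up), X is
medial–lateral, Y is anterior–posterior.  A `RigidTransform` maps *model*
("moving", the virtual bone) coordinates to *physical* ("fixed", the real
bone) coordinates, `p ↦ R p + t`; the per-pair residual is
`e_i = p_i − (R p'_i + t)` with `p_i` fixed and `p'_i` moving, and the overlay
objective is `J = ½ Σ ‖e_i‖²` (mm²).  Algebraic identities (orthonormality,
group laws, inverse round-trips) are held to 1e-9; validation of user-supplied
rotations accepts 1e-6 to tolerate transforms accumulated elsewhere.

## Registration

**Point matching.**  `paired_point_register` solves `min J` in closed form:
centroids are subtracted, the cross-covariance `H = Σ q̃_i p̃_iᵀ` is
decomposed by SVD, and `R = V diag(1, 1, det(VUᵀ)) Uᵀ` — the sign correction
on the smallest singular direction guarantees a proper rotation even for
planar or adversarially mirrored configurations.  Collinear configurations
leave a rotation about the line unconstrained and raise
`DegenerateGeometryError` (detected by a rank test on the centred points at a
scale-relative 1e-9 tolerance).  The solver is exact to machine precision on
noise-free pairs; the test suite cross-checks it against an independently
implemented quaternion (Horn) absolute-orientation solver.

**Surface matching.**  `icp_register` is plain point-to-point ICP: nearest
neighbours via a k-d tree, the closed-form solve on the matched pairs,
repeated until the RMS nearest-point distance changes by less than `tol_mm`
(default 1e-4 mm) or `max_iter` (default 100).  The recorded cost history is
the RMS distance after each transform update; with the default configuration
it is provably non-increasing (each solve minimizes the cost for the current
correspondences, and re-matching can only shrink each distance).  An optional
`trim_fraction` discards the worst correspondences per iteration for gross
outliers; it is off by default because it voids the monotonicity guarantee.
No random restarts: a poor initialization is the caller's problem, which is
precisely what the coarse stage exists for.

**Two-stage procedure.**  `two_stage_register` pairs landmark sets by shared
label (3–7 pairs enforced, mirroring the clinical point-matching protocol —
the conventional-navigation workflow is this code path with exactly 5
landmarks), solves the coarse transform, and seeds ICP with it.  Both results
are returned so the refinement benefit is measurable.  The
`query_side` option chooses which cloud supplies the ICP query points.  The
default (`"moving"`) matches the plain ICP contract.  `"fixed"` queries the
fixed cloud against the moving one and is the right direction when the fixed
cloud is a partial scan of the full model: every scanned point then has a
true counterpart, so partial visibility does not bias the fit.  (With the
default direction, model points outside the scanned region are dragged
toward the scan boundary; in simulation this inflated refined errors by an
order of magnitude at 60–70 % visibility.)

**Metrics.**  FRE is the RMS landmark residual (`√(2J/n)`); TRE is the mean
Euclidean deviation of target points under estimated vs true transform.
Rotation discrepancies are computed from the quaternion of `RₐᵀR_b` (scipy),
which stays accurate near identity where the trace/arccos formula loses half
the significant digits.

## Feature extraction

Real tracker feature detectors are proprietary; the package substitutes a
defined, reproducible operator.  Vertices are scored by angle-defect discrete
Gaussian curvature (2π minus the incident corner-angle sum).  Candidates are
the vertices at or above the 75th-percentile score (grown to at least `n`
when the quartile is too thin).  Selection is greedy farthest-point with a
curvature weight: the next feature maximizes `w · d_min`, where `d_min` is
the distance to the already-chosen set and `w ∈ [0.25, 1]` scales linearly
with the curvature score.  On a cube this selects exactly the corners; on a
uniform-curvature sphere it reduces to plain farthest-point sampling and
matches the brute-force optimal max-min vertex subset on a coarse icosphere.
Scores and distances are rounded to 1e-7 (mm scale) before comparison and
ties break by vertex index, so the selected vertices are equivariant under
rigid motion of the mesh; the seed only draws the starting feature among
maximal-curvature candidates.  The default feature count in the AR simulation
is 50; surface sampling (`sample_surface_points`) is standard area-weighted
barycentric sampling with a seeded generator.

## Cutting planes and the accuracy statistic

`make_cutting_planes` places the main plane at a configurable height along
the shaft (default 80 % of the Z extent), tilts it about the
anterior–posterior hinge direction (default 10°), and creates the side plane
by rotating the main normal a further `side_angle_deg` (default 70°) about
the hinge, so the mutual angle equals the configured value exactly.  Origins
snap to the nearest mesh vertex on the medial cortex.  The two normals must
be at least 5° apart.

The accuracy statistic projects both plane normals onto the XZ or YZ
coordinate plane and reports the angle between the projections, folded to
[0°, 90°] via the absolute dot product (cut orientation is sign-free).  The
angle is computed with atan2 of the 2-D cross and dot products, exact for
identical planes.  A normal perpendicular to the projection plane has no
defined projected angle and raises an error rather than returning 0.
Summaries use linear-interpolation quantiles (numpy's default) for
box-whisker reproducibility, and report every (modality, role, projection)
group plus a pooled per-modality row, so any pooling convention can be read
off the same table.

## Synthetic sawbones and the simulated trial

`make_synthetic_tibia` builds a closed surface of revolution: a tubular shaft
(default radius 15 mm, length 160 mm) whose radial profile ramps by a
smoothstep over the proximal 30 % to `condylar_flare` × radius (default 1.8),
plus a seeded low-order Fourier bump field (default peak 1 mm) standing in
for anatomical relief; bumps vanish at the ends and amplitudes ≥ half the
shaft radius are rejected as self-intersection risks.  End caps are fans from
rim vertices, so every vertex lies on the analytic profile — the flare and
the cylinder limit are directly measurable on the mesh.  Patient cohorts draw
shape parameters uniformly from radius 12–18 mm, flare 1.5–2.0, length
140–180 mm, bumps 0.5–1.5 mm.

`perturb_point_cloud` emulates a partial noisy scan: a seeded half-space cut
retains `⌈overlap · n⌉` points, isotropic Gaussian noise is added per axis,
and a fraction of points is replaced by uniform draws in a doubled bounding
box (outliers).

`simulate_trial` draws a ground-truth pose (rotation ≤ 30°, translation
≤ 50 mm per axis — tabletop-scale bounds), synthesizes the physical-side data
per modality, runs that modality's registration, and maps the planned planes
through `invert(T_est) ∘ T_true` — modelling a surgeon who cuts exactly on
the displayed virtual plane, so navigation error is the only systematic
error — plus a direct plane-tilt noise for the sawing itself.  TRE is
evaluated at the plane origins.  The physical surface scan is a perturbed
copy of the same base sample used for the virtual model rather than an
independent resampling: this makes the zero-noise limit exact (every
modality returns identically zero error, a sharp regression guard), while
noise, partial overlap and outliers still decorrelate the clouds in every
realistic configuration.

The three arms:

| arm | registration | landmark/feature σ | surface σ | overlap | outliers | tilt σ |
|---|---|---|---|---|---|---|
| metal | none (jig pinned to bone) | – | – | – | – | 0.5° |
| conventional | 5-point matching + ICP | 1.0 mm | 0.3 mm | 0.7 | 2 % | 1.0° |
| ar | 50 paired features + ICP | 2.0 mm | 1.0 mm | 0.6 | 5 % | 2.0° |

These magnitudes are **illustrative**.  They encode the relative error
structure of the three workflows — a seated jig needs no registration and
guides the saw rigidly; a tracked digitizer gives precise surfaces but
hand-picked landmarks and screw-guided cuts; a tracker-less overlay relies on
automatic feature detection, a noisier surface and freehand sawing — and
reproduce the qualitative accuracy ordering (metal < conventional < AR
pooled mean angle difference).  They are not calibrated to any measured
per-modality error budget, and the simulated degree values should not be
read as predictions for physical trials.

## Problem sizes and determinism

Default experiment: 10 patients × 1 replicate × 3 modalities (30 trials),
300 surface points per trial, ICP capped at 100 iterations — a full
experiment runs in well under a second, and the acceptance script's 20
repeated experiments plus all solver sweeps complete in seconds.  Every
stochastic step consumes an explicit seed (sub-seeds are spawned
deterministically), so identical configurations reproduce byte-identical
result tables; provenance (seed, config hash) is embedded in experiment
outputs.

## Limitations

The synthetic tibia is a smooth surface of revolution with mild bumps, far
more symmetric than real anatomy: rotational sliding during ICP is *harder*
here than on a real bone, making the simulated registration errors
conservative in that respect, but the generator captures no cortical
texture, osteophytes or soft-tissue occlusion.  The simulator models
navigation and sawing error only — no saw-blade kinematics, hinge fracture
or wedge planning — and the achieved-plane definition is a modelling choice,
not a measurement procedure.  Registration is single-shot; continuous
tracking loops are out of scope.
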