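"""Two-stage registration: point matching then ICP surface matching.

A synthetic tibia is posed at an unknown (to the solver) location.  Five
noisy landmarks give a coarse transform; a 300-point surface cloud with
0.2 mm digitization noise refines it.  The target registration error (TRE,
mean Euclidean deviation at anatomy-scale target points) shows the benefit
of the surface-matching stage.
"""

import numpy as np

import htonav as hn

tibia = hn.make_synthetic_tibia(hn.PatientShapeParams(seed=42))
landmarks = hn.extract_feature_points(tibia, 5, seed=1)
labels = [f"L{i}" for i in range(5)]
surface = hn.sample_surface_points(tibia, 300, seed=2)
targets = hn.PointCloud(tibia.vertices[::47])

rng = np.random.default_rng(3)
axis = rng.normal(size=3)
truth = hn.RigidTransform.from_axis_angle(axis, rng.uniform(0, 30), rng.uniform(-50, 50, 3))

noisy_landmarks = hn.LandmarkSet(labels, truth.apply(landmarks.points) + rng.normal(scale=2.0, size=(5, 3)))
noisy_surface = hn.PointCloud(truth.apply(surface.points) + rng.normal(scale=0.2, size=surface.points.shape))

result = hn.two_stage_register(
    fixed_landmarks=noisy_landmarks,
    moving_landmarks=hn.LandmarkSet(labels, landmarks.points),
    fixed_surface=noisy_surface,
    moving_surface=surface,
)

tre_coarse = hn.target_registration_error(result.coarse.transform, truth, targets)
tre_refined = hn.target_registration_error(result.refined.transform, truth, targets)
print(f"stage 1 (5-point matching)   TRE = {tre_coarse:.3f} mm")
print(f"stage 2 (ICP surface match)  TRE = {tre_refined:.3f} mm "
      f"after {result.refined.iterations} iterations")
# Surface matching averages hundreds of low-noise samples and should cut the
# TRE well below the landmark-only coarse stage (here roughly an order of
# magnitude).
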