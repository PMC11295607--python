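import numpy as np
import pytest

import htonav as hn
from htonav.errors import DegenerateGeometryError, LandmarkMatchError
from htonav.registration import TwoStageConfig

from conftest import random_transform
from oracles import brute_force_nearest, horn_quaternion


def make_landmarks(points, prefix="L"):
    return hn.LandmarkSet([f"{prefix}{i}" for i in range(len(points))], points)


class TestPairedPointRegister:
    def test_identical_clouds(self):
        c = hn.PointCloud(np.random.default_rng(0).uniform(-10, 10, (5, 3)))
        res = hn.paired_point_register(c, c)
        assert np.allclose(res.transform.R, np.eye(3), atol=1e-12)
        assert np.allclose(res.transform.t, 0, atol=1e-12)
        assert res.fre_mm == pytest.approx(0, abs=1e-12)

    def test_pure_translation(self):
        m = hn.PointCloud(np.random.default_rng(1).uniform(-10, 10, (4, 3)))
        f = hn.PointCloud(m.points + [1, 2, 3])
        res = hn.paired_point_register(f, m)
        assert np.allclose(res.transform.R, np.eye(3), atol=1e-12)
        assert np.allclose(res.transform.t, [1, 2, 3], atol=1e-12)

    def test_exact_recovery_of_known_transform(self):
        rng = np.random.default_rng(2)
        m = hn.PointCloud(rng.uniform(-50, 50, (6, 3)))
        T = hn.RigidTransform.from_axis_angle([0, 0, 1], 30, (5, -2, 1))
        res = hn.paired_point_register(hn.PointCloud(T.apply(m.points)), m)
        assert hn.rotation_angle_between(res.transform.R, T.R) < 1e-9
        assert np.linalg.norm(res.transform.t - T.t) < 1e-9

    def test_optimality_against_perturbations(self):
        # the returned J must beat thousands of random perturbations of (R, t)
        rng = np.random.default_rng(3)
        m = hn.PointCloud(rng.uniform(-30, 30, (8, 3)))
        f = hn.PointCloud(
            random_transform(rng).apply(m.points) + rng.normal(scale=1.0, size=(8, 3))
        )
        res = hn.paired_point_register(f, m)
        J0 = hn.registration_objective(res.transform, f, m)
        for _ in range(2000):
            d = random_transform(rng, max_angle_deg=rng.uniform(0.001, 30), max_t=rng.uniform(0.001, 5))
            T2 = hn.compose(d, res.transform)
            assert hn.registration_objective(T2, f, m) >= J0

    def test_matches_horn_quaternion_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(3, 30)
            m = rng.uniform(-40, 40, (n, 3))
            f = random_transform(rng).apply(m) + rng.normal(scale=0.5, size=(n, 3))
            res = hn.paired_point_register(hn.PointCloud(f), hn.PointCloud(m))
            R_ref, t_ref = horn_quaternion(f, m)
            assert np.abs(res.transform.R - R_ref).max() < 1e-6
            assert np.abs(res.transform.t - t_ref).max() < 1e-6

    def test_equivariance(self):
        # registering (G fixed, moving) yields G composed with T
        rng = np.random.default_rng(5)
        m = hn.PointCloud(rng.uniform(-20, 20, (7, 3)))
        f = hn.PointCloud(random_transform(rng).apply(m.points) + rng.normal(scale=0.3, size=(7, 3)))
        T1 = hn.paired_point_register(f, m).transform
        G = random_transform(rng)
        T2 = hn.paired_point_register(hn.apply_transform(G, f), m).transform
        expected = hn.compose(G, T1)
        assert np.allclose(T2.R, expected.R, atol=1e-9)
        assert np.allclose(T2.t, expected.t, atol=1e-7)

    def test_never_returns_reflection(self):
        # planar and noisy near-reflective configurations must yield det +1
        rng = np.random.default_rng(6)
        for _ in range(50):
            m = rng.uniform(-10, 10, (5, 3))
            m[:, 2] = 0  # planar
            f = m.copy()
            f[:, 0] = -f[:, 0]  # mirrored target
            res = hn.paired_point_register(hn.PointCloud(f), hn.PointCloud(m))
            assert np.linalg.det(res.transform.R) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs(self):
        line = hn.PointCloud(np.outer(np.arange(4.0), [1, 1, 0]))
        with pytest.raises(DegenerateGeometryError):
            hn.paired_point_register(line, line)
        two = hn.PointCloud(np.eye(3)[:2])
        with pytest.raises(ValueError):
            hn.paired_point_register(two, two)


class TestNearestCorrespondences:
    def test_single_fixed_point(self):
        moving = hn.PointCloud(np.random.default_rng(7).uniform(-5, 5, (10, 3)))
        fixed = hn.PointCloud([[1, 2, 3]])
        idx, dist = hn.nearest_correspondences(moving, fixed)
        assert (idx == 0).all()
        assert np.allclose(dist, np.linalg.norm(moving.points - [1, 2, 3], axis=1))

    def test_subset_self_pairs(self):
        fixed = hn.PointCloud(np.random.default_rng(8).uniform(-5, 5, (20, 3)))
        moving = hn.PointCloud(fixed.points[5:10])
        idx, dist = hn.nearest_correspondences(moving, fixed)
        assert np.array_equal(idx, np.arange(5, 10))
        assert np.allclose(dist, 0)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(9)
        moving = hn.PointCloud(rng.uniform(-10, 10, (50, 3)))
        fixed = hn.PointCloud(rng.uniform(-10, 10, (50, 3)))
        idx, dist = hn.nearest_correspondences(moving, fixed)
        ref_idx, ref_dist = brute_force_nearest(moving.points, fixed.points)
        assert np.array_equal(idx, ref_idx)
        assert np.allclose(dist, ref_dist)


class TestICP:
    def test_truth_init_converges_immediately(self, tibia):
        samples = hn.sample_surface_points(tibia, 200, seed=0)
        T = random_transform(np.random.default_rng(10), max_angle_deg=20)
        fixed = hn.PointCloud(T.apply(samples.points))
        res = hn.icp_register(fixed, samples, init=T)
        assert res.fre_mm == pytest.approx(0, abs=1e-9)
        assert res.iterations <= 2

    def test_small_misalignment_recovery(self, tibia):
        # 5 degree initial offset, noiseless: sub-0.1 degree final error
        samples = hn.sample_surface_points(tibia, 500, seed=1)
        T = hn.RigidTransform.from_axis_angle([0.3, 1.0, -0.5], 5.0)
        fixed = hn.PointCloud(T.apply(samples.points))
        res = hn.icp_register(fixed, samples)
        assert hn.rotation_angle_between(res.transform.R, T.R) < 0.1

    def test_cost_history_non_increasing(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = hn.PointCloud(rng.uniform(-20, 20, (80, 3)))
            T = random_transform(rng, max_angle_deg=25, max_t=10)
            f = hn.PointCloud(T.apply(m.points) + rng.normal(scale=0.5, size=(80, 3)))
            res = hn.icp_register(f, m)
            h = np.asarray(res.cost_history)
            assert (np.diff(h) <= 1e-12).all()

    def test_parameter_validation(self, tibia):
        samples = hn.sample_surface_points(tibia, 50, seed=2)
        with pytest.raises(ValueError):
            hn.icp_register(samples, samples, tol_mm=0)
        with pytest.raises(ValueError):
            hn.icp_register(samples, samples, trim_fraction=0.7)


class TestTwoStage:
    def test_noiseless_recovers_truth_in_both_stages(self, tibia):
        lm = hn.extract_feature_points(tibia, 5, seed=3)
        surf = hn.sample_surface_points(tibia, 200, seed=4)
        T = random_transform(np.random.default_rng(12), max_angle_deg=25)
        res = hn.two_stage_register(
            make_landmarks(T.apply(lm.points)),
            make_landmarks(lm.points),
            hn.PointCloud(T.apply(surf.points)),
            surf,
        )
        for stage in (res.coarse, res.refined):
            assert hn.rotation_angle_between(stage.transform.R, T.R) < 1e-9
            assert np.linalg.norm(stage.transform.t - T.t) < 1e-9

    def test_eight_landmarks_rejected(self):
        pts = np.random.default_rng(13).uniform(-10, 10, (8, 3))
        with pytest.raises(LandmarkMatchError):
            hn.match_landmarks(make_landmarks(pts), make_landmarks(pts))

    def test_too_few_shared_labels_listed(self):
        a = hn.LandmarkSet(["a", "b", "x"], np.eye(3))
        b = hn.LandmarkSet(["a", "b", "y"], np.eye(3))
        with pytest.raises(LandmarkMatchError, match=r"\['x'\]"):
            hn.match_landmarks(a, b)

    def test_surface_refinement_beats_coarse_under_noise(self, tibia):
        # noisy landmarks, nearly clean surface: ICP should not make it worse
        lm = hn.extract_feature_points(tibia, 5, seed=5)
        surf = hn.sample_surface_points(tibia, 300, seed=6)
        targets = hn.PointCloud(tibia.vertices[::97])
        wins = 0
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            T = random_transform(rng, max_angle_deg=25)
            res = hn.two_stage_register(
                make_landmarks(T.apply(lm.points) + rng.normal(scale=2.0, size=(5, 3))),
                make_landmarks(lm.points),
                hn.PointCloud(T.apply(surf.points) + rng.normal(scale=0.2, size=surf.points.shape)),
                surf,
            )
            t1 = hn.target_registration_error(res.coarse.transform, T, targets)
            t2 = hn.target_registration_error(res.refined.transform, T, targets)
            wins += t2 <= t1
        assert wins >= 18

    def test_mirrored_query_side_equivalent_when_clean(self, tibia):
        lm = hn.extract_feature_points(tibia, 4, seed=7)
        surf = hn.sample_surface_points(tibia, 150, seed=8)
        T = random_transform(np.random.default_rng(14), max_angle_deg=15)
        args = (
            make_landmarks(T.apply(lm.points)),
            make_landmarks(lm.points),
            hn.PointCloud(T.apply(surf.points)),
            surf,
        )
        a = hn.two_stage_register(*args, TwoStageConfig(query_side="moving"))
        b = hn.two_stage_register(*args, TwoStageConfig(query_side="fixed"))
        assert hn.rotation_angle_between(a.transform.R, b.transform.R) < 1e-9


class TestErrorMetrics:
    def test_fre_examples(self):
        c = hn.PointCloud(np.random.default_rng(15).uniform(-5, 5, (6, 3)))
        I = hn.RigidTransform.identity()
        assert hn.fiducial_registration_error(I, c, c) == 0
        shifted = hn.PointCloud(c.points + [1, 0, 0])
        assert hn.fiducial_registration_error(I, shifted, c) == pytest.approx(1.0)

    def test_fre_equals_sqrt_2J_over_n(self):
        rng = np.random.default_rng(16)
        f = hn.PointCloud(rng.uniform(-10, 10, (9, 3)))
        m = hn.PointCloud(rng.uniform(-10, 10, (9, 3)))
        T = random_transform(rng)
        J = hn.registration_objective(T, f, m)
        assert hn.fiducial_registration_error(T, f, m) == pytest.approx(
            np.sqrt(2 * J / 9), rel=1e-12
        )

    def test_tre_trivial_cases(self):
        targets = hn.PointCloud(np.random.default_rng(17).uniform(-10, 10, (5, 3)))
        T = random_transform(np.random.default_rng(18))
        assert hn.target_registration_error(T, T, targets) == 0
        T2 = hn.RigidTransform(T.R, T.t + [0, 0, 1])
        assert hn.target_registration_error(T2, T, targets) == pytest.approx(1.0)

    def test_tre_pure_rotation_closed_form(self):
        # rotation by theta about an axis through the centroid:
        # each point moves by 2 r_i sin(theta/2), r_i = distance to the axis
        rng = np.random.default_rng(19)
        targets = rng.uniform(-10, 10, (50, 3))
        centroid = targets.mean(axis=0)
        theta = 7.0
        Rz = hn.RigidTransform.from_axis_angle([0, 0, 1], theta).R
        t = centroid - Rz @ centroid
        T_est = hn.RigidTransform(Rz, t)
        T_true = hn.RigidTransform.identity()
        r = np.linalg.norm((targets - centroid)[:, :2], axis=1)
        expected = np.mean(2 * r * np.sin(np.deg2rad(theta) / 2))
        got = hn.target_registration_error(T_est, T_true, hn.PointCloud(targets))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_tre_decreases_with_landmark_noise(self, tibia):
        # monotone trend of mean TRE over noise levels 0, 0.5, 1, 2 mm
        lm = hn.extract_feature_points(tibia, 5, seed=9)
        targets = hn.PointCloud(tibia.vertices[::53])
        means = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            tres = []
            for trial in range(40):
                rng = np.random.default_rng(1000 + trial)
                T = random_transform(rng, max_angle_deg=25)
                noisy = T.apply(lm.points) + rng.normal(scale=sigma, size=(5, 3))
                est = hn.paired_point_register(hn.PointCloud(noisy), lm).transform
                tres.append(hn.target_registration_error(est, T, targets))
            means.append(np.mean(tres))
        assert means[0] < 1e-9
        assert all(a <= b for a, b in zip(means, means[1:]))
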