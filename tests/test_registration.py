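"""Landmark fit and ICP: exactness, optimality against a brute-force
rotation search, convergence behaviour, and noisy-recovery statistics."""

import numpy as np
import pytest

from zygonav import (ConvergenceError, IcpParams, IterativeClosestPoint,
                     LandmarkTransform, RigidTransform, ValidationError,
                     fine_alignment, icp, landmark_fit)
from zygonav.exceptions import DegenerateGeometryError

from conftest import brute_force_rigid_rms, pose_error, random_rigid


class TestLandmarkFit:
    def test_identity_on_identical_landmarks(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float)
        res = landmark_fit(pts, pts)
        assert res.transform.almost_equals(RigidTransform.identity(), tol=1e-12)
        assert res.rms_error < 1e-12

    def test_exact_recovery_of_known_transform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = random_rigid(rng)
            src = rng.uniform(-50, 50, size=(rng.integers(3, 8), 3))
            res = landmark_fit(src, t.apply(src))
            assert res.rms_error < 1e-9
            np.testing.assert_allclose(res.transform.matrix, t.matrix,
                                       atol=1e-9)

    def test_fre_matches_residual_definition(self):
        rng = np.random.default_rng(1)
        t = random_rigid(rng)
        src = rng.uniform(-50, 50, size=(5, 3))
        tgt = t.apply(src) + rng.normal(0, 0.4, size=(5, 3))
        res = landmark_fit(src, tgt)
        manual = np.sqrt(np.mean(np.sum(
            (res.transform.apply(src) - tgt) ** 2, axis=1)))
        assert res.rms_error == pytest.approx(manual, abs=1e-12)

    def test_matches_brute_force_rotation_search(self):
        # closed form is the global optimum: a direct search over rotations
        # never beats it, and agrees with it to high precision
        rng = np.random.default_rng(2)
        for i in range(8):
            t = random_rigid(rng)
            n = int(rng.integers(3, 7))
            src = rng.uniform(-40, 40, size=(n, 3))
            tgt = t.apply(src) + rng.normal(0, 0.5, size=(n, 3))
            closed = landmark_fit(src, tgt).rms_error
            brute = brute_force_rigid_rms(src, tgt, seed=i)
            assert closed <= brute + 1e-9
            assert abs(closed - brute) < 1e-6

    def test_matches_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(3)
        src = rng.uniform(-40, 40, size=(6, 3))
        tgt = random_rigid(rng).apply(src) + rng.normal(0, 0.3, size=(6, 3))
        res = landmark_fit(src, tgt)
        r_sp, _ = Rotation.align_vectors(tgt - tgt.mean(0), src - src.mean(0))
        np.testing.assert_allclose(res.transform.rotation, r_sp.as_matrix(),
                                   atol=1e-8)

    def test_reflection_configurations_resolve_to_proper_rotation(self):
        # a target set requiring a reflection for a perfect fit must still
        # yield det(R) = +1
        src = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
                       dtype=float)
        tgt = src.copy()
        tgt[:, 2] *= -1  # mirrored
        res = landmark_fit(src, tgt)
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)

    def test_too_few_pairs_is_an_error(self):
        with pytest.raises(ValidationError, match="at least 3"):
            landmark_fit([[0, 0, 0], [1, 0, 0]], [[0, 0, 0], [1, 0, 0]])

    def test_collinear_sources_identify_degenerate_direction(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                       dtype=float)
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            landmark_fit(src, src)

    def test_count_mismatch_is_an_error(self):
        with pytest.raises(ValidationError, match="differ"):
            landmark_fit(np.zeros((3, 3)), np.zeros((4, 3)))


class TestIcp:
    def test_already_aligned_converges_immediately(self, phantom):
        cloud = phantom.zygoma_planned_cloud()
        res = icp(cloud, cloud)
        assert res.iterations <= 2
        assert res.converged
        assert np.abs(res.transform.matrix - np.eye(4)).max() < 1e-6

    def test_recovers_known_dislocation_noiseless(self, phantom):
        res = icp(phantom.zygoma_dislocated_cloud(),
                  phantom.zygoma_planned_cloud())
        center = phantom.zygoma_planned_cloud().mean(axis=0)
        trans_err, rot_err = pose_error(res.transform, phantom.t_true, center)
        assert trans_err < 0.01
        assert rot_err < 0.01

    def test_rms_trace_is_non_increasing_untrimmed(self, phantom):
        rng = np.random.default_rng(4)
        src = phantom.zygoma_dislocated_cloud() + rng.normal(
            0, 0.2, size=phantom.zygoma_dislocated_cloud().shape)
        res = icp(src, phantom.zygoma_planned_cloud())
        trace = np.array(res.rms_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_iterations_bounded_by_max(self, phantom):
        params = IcpParams(max_iterations=3, convergence_tol=1e-15)
        res = icp(phantom.zygoma_dislocated_cloud(),
                  phantom.zygoma_planned_cloud(), params=params)
        assert res.iterations <= 3

    def test_empty_source_is_an_error(self):
        with pytest.raises(ValidationError, match="empty"):
            icp(np.empty((0, 3)), np.eye(3))

    def test_no_correspondences_under_gate_is_an_error(self):
        src = np.zeros((5, 3)) + 100.0
        tgt = np.zeros((5, 3))
        params = IcpParams(max_correspondence_distance=1.0)
        with pytest.raises(ConvergenceError, match="correspondences"):
            icp(src, tgt, params=params)

    def test_trimming_ignores_gross_outliers(self, phantom):
        cloud = phantom.zygoma_planned_cloud()
        src = np.vstack([cloud, cloud[:10] + 40.0])  # 10 gross outliers
        res = icp(src, cloud, params=IcpParams(trim_fraction=0.1))
        assert np.abs(res.transform.matrix - np.eye(4)).max() < 1e-3

    def test_subsampling_is_seeded_and_recorded(self, phantom):
        cloud = phantom.zygoma_planned_cloud()
        params = IcpParams(subsample_cap=100, seed=7)
        r1 = icp(phantom.zygoma_dislocated_cloud(), cloud, params=params)
        r2 = icp(phantom.zygoma_dislocated_cloud(), cloud, params=params)
        assert r1.seed == r2.seed == 7
        np.testing.assert_array_equal(r1.transform.matrix, r2.transform.matrix)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            IcpParams(trim_fraction=0.6)
        with pytest.raises(ValidationError):
            IcpParams(convergence_tol=0.0)


class TestFineAlignment:
    @staticmethod
    def _random_fixed_vertices(phantom, n, seed):
        # probed points coincide with target vertices: the noiseless case of
        # picking random points on the un-operated surface
        verts = phantom.planned.region_vertices("fixed")
        rng = np.random.default_rng(seed)
        return verts[rng.choice(len(verts), size=n, replace=False)]

    def test_noiseless_surface_points_fit_to_machine_precision(self, phantom):
        pts = self._random_fixed_vertices(phantom, 20, 0)
        coarse = landmark_fit(phantom.landmarks.coordinates,
                              phantom.landmarks.coordinates)
        res = fine_alignment(coarse, pts, phantom.planned)
        assert res.rms_error < 1e-6

    def test_too_few_points_is_an_error(self, phantom):
        coarse = landmark_fit(phantom.landmarks.coordinates,
                              phantom.landmarks.coordinates)
        with pytest.raises(ValidationError, match=">= 4"):
            fine_alignment(coarse, np.zeros((3, 3)), phantom.planned)

    def test_noisy_monte_carlo_translation_error(self, phantom):
        # 20 probed surface points with 0.3 mm pick noise; the registration
        # should land within 0.5 mm (at the skull surface) in >= 95% of runs
        mesh = phantom.planned
        coarse = landmark_fit(phantom.landmarks.coordinates,
                              phantom.landmarks.coordinates)
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            pts = self._random_fixed_vertices(phantom, 20, seed + 10_000)
            noisy = pts + rng.normal(0, 0.3, size=pts.shape)
            res = fine_alignment(coarse, noisy, mesh)
            trans_err, _ = pose_error(res.transform,
                                      RigidTransform.identity(),
                                      pts.mean(axis=0))
            if trans_err < 0.5:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestEstimators:
    def test_landmark_transform_estimator(self):
        rng = np.random.default_rng(5)
        t = random_rigid(rng)
        src = rng.uniform(-50, 50, size=(5, 3))
        est = LandmarkTransform().fit(src, t.apply(src))
        assert est.rms_error_ < 1e-9
        np.testing.assert_allclose(est.transform(src), t.apply(src), atol=1e-9)
        np.testing.assert_allclose(est.inverse_transform(t.apply(src)), src,
                                   atol=1e-9)

    def test_icp_estimator_params_and_attributes(self, phantom):
        est = IterativeClosestPoint(convergence_tol=1e-8)
        assert est.get_params()["convergence_tol"] == 1e-8
        est.set_params(convergence_tol=1e-6)
        est.fit(phantom.zygoma_dislocated_cloud(),
                phantom.zygoma_planned_cloud())
        assert est.converged_
        assert est.n_iter_ == len(est.rms_trace_)
        assert est.rms_error_ == est.rms_trace_[-1]

    def test_unfitted_transform_raises(self):
        with pytest.raises(ValidationError, match="not fitted"):
            IterativeClosestPoint().transform(np.zeros((3, 3)))

    def test_clone_compatible(self):
        from sklearn.base import clone
        est = IterativeClosestPoint(trim_fraction=0.1, seed=3)
        c = clone(est)
        assert c.get_params() == est.get_params()
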