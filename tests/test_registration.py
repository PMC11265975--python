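"""Losses, gradients, coarse init, and the joint optimizer."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scalpfit import (
    OptimConfig,
    PointCloud,
    PoseParams,
    coarse_init,
    fit_joint,
    normal_consistency,
    one_sided_chamfer,
    total_loss,
)
from scalpfit.registration import (
    _Problem,
    _loss_and_grad,
    _rotation_derivatives,
    JointShapeRegistration,
)


def brute_force_chamfer(sampled, target, squared):
    d = np.linalg.norm(sampled[:, None] - target[None], axis=2)
    mins = d.min(axis=1)
    return float(np.mean(mins**2 if squared else mins)), d.argmin(axis=1)


class TestOneSidedChamfer:
    def test_subset_gives_zero(self, rng):
        target = rng.standard_normal((50, 3))
        cd, idx = one_sided_chamfer(PointCloud(target[10:20]), PointCloud(target))
        assert cd == 0.0
        np.testing.assert_array_equal(idx, np.arange(10, 20))

    def test_single_pair_both_modes(self):
        s = PointCloud([[0.0, 0, 0]])
        t = PointCloud([[3.0, 4, 0]])
        assert one_sided_chamfer(s, t, squared=True)[0] == pytest.approx(25.0)
        assert one_sided_chamfer(s, t, squared=False)[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("squared", [True, False])
    def test_matches_brute_force(self, rng, squared):
        s = rng.standard_normal((150, 3))
        t = rng.standard_normal((200, 3))
        cd, idx = one_sided_chamfer(PointCloud(s), PointCloud(t), squared=squared)
        ecd, eidx = brute_force_chamfer(s, t, squared)
        assert cd == pytest.approx(ecd, abs=1e-9)
        np.testing.assert_array_equal(idx, eidx)

    def test_asymmetry(self, rng):
        s = rng.standard_normal((20, 3))
        t = np.vstack([s, s + 50.0])
        assert one_sided_chamfer(PointCloud(s), PointCloud(t))[0] == 0.0
        assert one_sided_chamfer(PointCloud(t), PointCloud(s))[0] > 0.0


class TestNormalConsistency:
    def test_identical_normals(self, rng):
        n = rng.standard_normal((30, 3))
        assert normal_consistency(n, n) == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_is_zero(self, rng):
        n = rng.standard_normal((30, 3))
        assert normal_consistency(n, -n) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_is_one(self):
        a = np.array([[1.0, 0, 0]] * 5)
        b = np.array([[0.0, 1, 0]] * 5)
        assert normal_consistency(a, b) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            normal_consistency(np.zeros((2, 3)), np.ones((2, 3)))


class TestTotalLoss:
    def test_pure_chamfer_limit(self):
        cfg = OptimConfig()
        pose = PoseParams.identity()
        loss, reg = total_loss(0.7, 0.0, np.zeros(5), pose, pose, cfg)
        assert reg == 0.0
        assert loss == pytest.approx(cfg.lambda1 * 0.7)

    def test_all_lambdas_zero(self, rng):
        cfg = OptimConfig(lambda1=0, lambda2=0, lambda3=0, lambda4=0)
        pose = PoseParams(np.ones(3) * 2, rng.standard_normal(3), rng.standard_normal(3))
        loss, reg = total_loss(3.0, 0.5, rng.standard_normal(4), pose,
                               PoseParams.identity(), cfg)
        assert loss == 0.0 and reg == 0.0

    def test_matches_frobenius_oracle(self, rng):
        cfg = OptimConfig(lambda1=2.5, lambda2=0.7, lambda3=1.3, lambda4=0.9)
        w = rng.standard_normal(6)
        pose = PoseParams(np.exp(rng.normal(0, 0.1, 3)), rng.normal(0, 0.2, 3),
                          rng.normal(0, 30, 3))
        pose0 = PoseParams(np.ones(3), np.zeros(3), rng.normal(0, 30, 3))
        loss, reg = total_loss(1.1, 0.2, w, pose, pose0, cfg)
        dT = pose.to_matrix(0.1) - pose0.to_matrix(0.1)
        expected_reg = 1.3 * np.sqrt(np.sum(w**2)) + 0.9 * np.sqrt(np.sum(dT**2))
        assert reg == pytest.approx(expected_reg, abs=1e-12)
        assert loss == pytest.approx(2.5 * 1.1 + 0.7 * 0.2 + expected_reg, abs=1e-12)


class TestRotationDerivatives:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed):
        r = np.random.default_rng(seed).normal(0, 0.5, 3)
        R = Rotation.from_rotvec(r).as_matrix()
        dR = _rotation_derivatives(r, R)
        h = 1e-7
        for a in range(3):
            rp, rm = r.copy(), r.copy()
            rp[a] += h
            rm[a] -= h
            fd = (
                Rotation.from_rotvec(rp).as_matrix()
                - Rotation.from_rotvec(rm).as_matrix()
            ) / (2 * h)
            np.testing.assert_allclose(dR[a], fd, atol=1e-6)

    def test_identity_limit(self):
        dR = _rotation_derivatives(np.zeros(3), np.eye(3))
        gen0 = np.array([[0, 0, 0], [0, 0, -1.0], [0, 1, 0]])
        np.testing.assert_allclose(dR[0], gen0, atol=1e-12)


class TestCoarseInit:
    def test_mean_vertices_give_identity(self, toy_model):
        pose = coarse_init(PointCloud(toy_model.mean_mesh.vertices), toy_model)
        np.testing.assert_allclose(pose.scale, 1.0, atol=1e-6)
        np.testing.assert_allclose(pose.rotation, 0.0, atol=1e-6)
        np.testing.assert_allclose(pose.translation, 0.0, atol=1e-6)

    def test_pure_shift_recovered(self, toy_model):
        pose = coarse_init(
            PointCloud(toy_model.mean_mesh.vertices + [10.0, 0, 0]), toy_model
        )
        np.testing.assert_allclose(pose.translation, [10.0, 0, 0], atol=1e-6)
        np.testing.assert_allclose(pose.rotation, 0.0, atol=1e-6)

    def test_rotated_scaled_beats_rejected_candidates(self, toy_model):
        true = PoseParams(
            np.array([1.1, 0.9, 1.0]),
            Rotation.from_euler("z", 30, degrees=True).as_rotvec(),
            np.zeros(3),
        )
        sampled = PointCloud(true.apply(toy_model.mean_mesh.vertices))
        from scalpfit.registration import coarse_init_candidates

        scored = coarse_init_candidates(sampled, toy_model)
        cds = [cd for cd, _ in scored]
        best_pose = scored[0][1]
        unposed_cd, _ = one_sided_chamfer(
            sampled, PointCloud(toy_model.mean_mesh.vertices[::5])
        )
        assert cds[0] < unposed_cd
        assert cds[0] <= min(cds[1:])
        # anisotropic scale tilts the moment axes, so the estimate is only
        # coarse: right branch (no flip/permutation), not degree-accurate
        rot_err = (
            Rotation.from_rotvec(best_pose.rotation)
            * Rotation.from_rotvec(true.rotation).inv()
        ).magnitude()
        assert np.degrees(rot_err) < 20.0

    def test_degenerate_spread_falls_back_to_isotropic(self, toy_model, rng):
        flat = rng.standard_normal((40, 3)) * [50, 50, 0] + [0, 0, 90]
        pose = coarse_init(PointCloud(flat), toy_model)
        assert pose.isotropic_fallback
        assert pose.scale[0] == pytest.approx(pose.scale[1], abs=1e-12)


def _gradient_instance(toy_model, seed, use_normals):
    rng = np.random.default_rng(seed)
    cfg = OptimConfig(use_normals=use_normals)
    pts = toy_model.mean_mesh.vertices[
        rng.choice(toy_model.n_vertices, 40, replace=False)
    ] + rng.normal(0, 3, (40, 3))
    normals = rng.standard_normal((40, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    problem = _Problem(toy_model, PointCloud(pts, normals), cfg)
    k = problem.k
    params = np.concatenate(
        [rng.normal(0, 0.5, k), rng.normal(0, 0.2, 3),
         rng.normal(0, 0.05, 3), rng.normal(0, 1, 3)]
    )
    T0 = PoseParams(
        np.exp(rng.normal(0, 0.05, 3)), rng.normal(0, 0.1, 3), rng.normal(0, 5, 3)
    ).to_matrix(0.1)
    return params, problem, T0


class TestGradients:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("use_normals", [False, True])
    def test_analytic_matches_central_differences(self, toy_model, seed, use_normals):
        params, problem, T0 = _gradient_instance(toy_model, seed, use_normals)
        X = problem.synthesize_cm(params[: problem.k])
        bn = problem.base_normals(X) if use_normals else None
        loss, _, grad, corr = _loss_and_grad(params, problem, T0, base_normals=bn)
        h = 1e-6
        for i in range(len(params)):
            pp, pm = params.copy(), params.copy()
            pp[i] += h
            pm[i] -= h
            fp = _loss_and_grad(pp, problem, T0, corr=corr, base_normals=bn)[0]
            fm = _loss_and_grad(pm, problem, T0, corr=corr, base_normals=bn)[0]
            fd = (fp - fm) / (2 * h)
            denom = max(abs(fd), abs(grad[i]), 1e-6)
            assert abs(fd - grad[i]) / denom < 1e-4


class TestFitJoint:
    def test_same_inputs_same_result(self, toy_model, rng):
        pts = toy_model.mean_mesh.vertices[::4] + rng.normal(0, 1, 1)
        cfg = OptimConfig(max_iter=80)
        a = fit_joint(toy_model, PointCloud(pts), config=cfg)
        b = fit_joint(toy_model, PointCloud(pts), config=cfg)
        assert np.array_equal(a.weights.w, b.weights.w)
        assert np.array_equal(a.pose.translation, b.pose.translation)
        np.testing.assert_array_equal(
            a.loss_history["total"], b.loss_history["total"]
        )

    def test_reconstructed_rederivable_from_weights_and_pose(self, toy_model):
        from scalpfit import synthesize

        pts = toy_model.mean_mesh.vertices[::4]
        fit = fit_joint(toy_model, PointCloud(pts), config=OptimConfig(max_iter=60))
        again = fit.pose.apply(synthesize(toy_model, fit.weights.w))
        np.testing.assert_allclose(
            fit.reconstructed.vertices, again.vertices, atol=1e-9
        )

    def test_large_weight_penalty_pins_shape_to_mean(self, toy_model):
        # all mean vertices: the moment-based coarse pose is then exact and
        # the regularizer-dominated fit keeps w at zero and the pose there
        pose_true = PoseParams(np.ones(3), np.zeros(3), np.array([5.0, 0, 0]))
        pts = pose_true.apply(toy_model.mean_mesh.vertices)
        cfg = OptimConfig(lambda3=1e4, learning_rate=5e-3, max_iter=400)
        fit = fit_joint(toy_model, PointCloud(pts), config=cfg)
        # Adam dithers around w = 0 at the learning-rate scale
        assert np.linalg.norm(fit.weights.w) < 0.01
        np.testing.assert_allclose(fit.pose.translation, [5.0, 0, 0], atol=1.0)

    def test_results_ignore_normals_when_term_disabled(self, toy_model, rng):
        pts = toy_model.mean_mesh.vertices[::4]
        n1 = rng.standard_normal(pts.shape)
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 = rng.standard_normal(pts.shape)
        n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
        cfg = OptimConfig(lambda2=0.0, use_normals=False, max_iter=60)
        a = fit_joint(toy_model, PointCloud(pts, n1), config=cfg)
        b = fit_joint(toy_model, PointCloud(pts, n2), config=cfg)
        np.testing.assert_array_equal(a.weights.w, b.weights.w)

    def test_equivariance_under_rigid_motion(self, toy_model, rng):
        pts = toy_model.mean_mesh.vertices[::3] + rng.normal(0, 0.5, 1)
        cfg = OptimConfig(
            lambda3=0.1, lambda4=0.1, learning_rate=2e-3,
            max_iter=1500, patience=200, min_delta=1e-10,
        )
        polish = OptimConfig(
            lambda3=0.1, lambda4=0.1, learning_rate=5e-5,
            max_iter=2000, patience=400, min_delta=0.0,
        )

        def converge(cloud, pose0):
            first = fit_joint(toy_model, cloud, pose0=pose0, config=cfg)
            return fit_joint(
                toy_model, cloud, pose0=pose0, config=polish,
                w0=first.weights.w,
            )

        pose0 = PoseParams.identity()
        base = converge(PointCloud(pts), pose0)

        R = Rotation.from_euler("z", 12, degrees=True)
        t = np.array([7.0, -4.0, 3.0])
        moved_pts = pts @ R.as_matrix().T + t
        moved_pose0 = PoseParams.from_matrix(
            PoseParams(np.ones(3), R.as_rotvec(), t).to_matrix()
            @ pose0.to_matrix()
        )
        moved = converge(PointCloud(moved_pts), moved_pose0)
        np.testing.assert_allclose(moved.weights.w, base.weights.w, atol=1e-4)
        # final poses conjugate: T_moved ~ T_rigid @ T_base
        expected = (
            PoseParams(np.ones(3), R.as_rotvec(), t).to_matrix()
            @ base.pose.to_matrix()
        )
        np.testing.assert_allclose(
            moved.pose.to_matrix(), expected, atol=5e-3
        )

    def test_nonfinite_loss_aborts_with_diagnostic(self, toy_model):
        pts = toy_model.mean_mesh.vertices[::4] * 1e160
        with pytest.raises((FloatingPointError, ValueError)):
            fit_joint(toy_model, PointCloud(pts), config=OptimConfig(max_iter=10))

    def test_estimator_sklearn_interface(self, toy_model):
        est = JointShapeRegistration(model=toy_model, max_iter=50)
        params = est.get_params()
        assert params["max_iter"] == 50
        est.set_params(max_iter=30)
        est.fit(toy_model.mean_mesh.vertices[::5])
        assert est.n_iter_ <= 30
        assert hasattr(est, "pose_") and hasattr(est, "weights_")
        assert est.score(toy_model.mean_mesh.vertices[::5]) <= 0.0
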