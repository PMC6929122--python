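"""Functional joint-center and hinge-axis estimation."""

import numpy as np
import pytest

from hipkin import joint_center as jc
from hipkin.exceptions import (
    DegenerateMotionError,
    InsufficientDataError,
    InvalidInputError,
)
from hipkin.preprocess import preprocess_recording
from hipkin.rotations import quat_from_axis_angle, quat_multiply, quat_to_matrix
from hipkin.synthdata import (
    ChainGeometry,
    DEFAULT_NOISE,
    Sinusoid,
    ZERO_PROFILE,
    simulate_ball_joint,
    simulate_hinge,
)

from conftest import vector_angle_deg


@pytest.fixture(scope="module")
def rich_sim():
    """Noiseless ball-joint simulation with 3D motion on both segments."""
    geom = ChainGeometry(r1=np.array([0.05, 0.25, 0.02]),
                         r2=np.array([-0.03, -0.20, 0.01]),
                         mount1=quat_from_axis_angle([0.3, 1, 0.2], 0.8),
                         mount2=quat_from_axis_angle([1, -0.5, 0.4], -1.1))
    profs = (Sinusoid(35, 0.45), Sinusoid(22, 0.35, 1.0), Sinusoid(18, 0.55, 2.0))
    base = (Sinusoid(0.15, 0.4), Sinusoid(0.12, 0.33, 0.8),
            Sinusoid(0.12, 0.5, 1.5))
    return simulate_ball_joint(profs, geom, duration=25.0, noise=None, seed=3,
                               base_euler=base)


class TestSelectHighMotionSamples:
    def test_exact_block_selected(self):
        w = np.zeros((4000, 3))
        w[1000:2500, 0] = 1.0
        idx = jc.select_high_motion_samples(w, np.zeros_like(w), n_min=1500)
        np.testing.assert_array_equal(idx, np.arange(1000, 2500))

    def test_monotone_magnitudes_pick_the_tail(self):
        n = 3000
        w = np.linspace(0, 1, n)[:, None] * np.ones(3)
        idx = jc.select_high_motion_samples(w, w, n_min=1500)
        np.testing.assert_array_equal(idx, np.arange(1500, 3000))

    def test_matches_full_sort_oracle(self, rng):
        w1 = rng.normal(size=(5000, 3))
        w2 = rng.normal(size=(5000, 3))
        idx = jc.select_high_motion_samples(w1, w2, n_min=1500)
        score = np.linalg.norm(w1, axis=1) + np.linalg.norm(w2, axis=1)
        oracle = np.sort(np.argsort(score)[-1500:])
        np.testing.assert_array_equal(idx, oracle)

    def test_too_few_samples_raises(self):
        with pytest.raises(InsufficientDataError, match="1500"):
            jc.select_high_motion_samples(np.zeros((100, 3)),
                                          np.zeros((100, 3)))


class TestEstimateJointCenter:
    def test_noiseless_recovery(self, rich_sim):
        R21 = quat_to_matrix(rich_sim.truth_q21)
        res = jc.estimate_joint_center(rich_sim.imu1, rich_sim.imu2, R21)
        g = rich_sim.truth_geometry
        assert np.max(np.abs(res.r1 - g.r1)) < 0.005
        assert np.max(np.abs(res.r2 - g.r2)) < 0.005
        assert res.n_obs >= 1500
        assert np.isfinite(res.residual)

    def test_noisy_recovery(self, rich_sim):
        g = rich_sim.truth_geometry
        sim = simulate_ball_joint(
            (Sinusoid(35, 0.45), Sinusoid(22, 0.35, 1.0), Sinusoid(18, 0.55, 2.0)),
            g, duration=25.0, noise=DEFAULT_NOISE, seed=5,
            base_euler=(Sinusoid(0.15, 0.4), Sinusoid(0.12, 0.33, 0.8),
                        Sinusoid(0.12, 0.5, 1.5)))
        imu1 = preprocess_recording(sim.imu1)
        imu2 = preprocess_recording(sim.imu2)
        res = jc.estimate_joint_center(imu1, imu2,
                                       quat_to_matrix(sim.truth_q21))
        assert np.max(np.abs(res.r1 - g.r1)) < 0.015
        assert np.max(np.abs(res.r2 - g.r2)) < 0.015

    def test_solution_order_free(self, rich_sim):
        R21 = quat_to_matrix(rich_sim.truth_q21)
        idx = jc.select_high_motion_samples(rich_sim.imu1.gyro,
                                            rich_sim.imu2.gyro)
        shuffled = np.random.default_rng(0).permutation(idx)
        a = jc.estimate_joint_center(rich_sim.imu1, rich_sim.imu2, R21,
                                     indices=idx)
        b = jc.estimate_joint_center(rich_sim.imu1, rich_sim.imu2, R21,
                                     indices=shuffled)
        np.testing.assert_allclose(a.r1, b.r1, atol=1e-10)

    def test_matches_pseudoinverse_oracle(self, rich_sim):
        """The least-squares solution equals the generic pseudo-inverse
        applied to the same stacked system."""
        from hipkin.preprocess import angular_acceleration
        from hipkin.rotations import skew
        imu1, imu2 = rich_sim.imu1, rich_sim.imu2
        R21 = quat_to_matrix(rich_sim.truth_q21)
        idx = jc.select_high_motion_samples(imu1.gyro, imu2.gyro)
        res = jc.estimate_joint_center(imu1, imu2, R21, indices=idx)
        wd1 = angular_acceleration(imu1.gyro, imu1.dt)
        wd2 = angular_acceleration(imu2.gyro, imu2.dt)
        A = np.empty((3 * len(idx), 6))
        b = np.empty(3 * len(idx))
        for row, k in enumerate(idx):
            K1 = skew(imu1.gyro[k]) @ skew(imu1.gyro[k]) + skew(wd1[k])
            K2 = skew(imu2.gyro[k]) @ skew(imu2.gyro[k]) + skew(wd2[k])
            A[3 * row:3 * row + 3, 0:3] = K1
            A[3 * row:3 * row + 3, 3:6] = -R21[k] @ K2
            b[3 * row:3 * row + 3] = imu1.accel[k] - R21[k] @ imu2.accel[k]
        x = np.linalg.pinv(A) @ b
        np.testing.assert_allclose(np.r_[res.r1, res.r2], x, atol=1e-8)

    def test_single_axis_motion_degenerate(self, hip_geometry):
        sim = simulate_ball_joint((Sinusoid(30, 0.5), ZERO_PROFILE,
                                   ZERO_PROFILE), hip_geometry,
                                  duration=15.0, noise=None, seed=0)
        with pytest.raises(DegenerateMotionError):
            jc.estimate_joint_center(sim.imu1, sim.imu2,
                                     quat_to_matrix(sim.truth_q21))

    def test_rotation_equivariance(self, rich_sim):
        """Rotating sensor-2's frame by a fixed rotation rotates r2
        accordingly and leaves r1 unchanged."""
        from dataclasses import replace
        Rf = quat_to_matrix(quat_from_axis_angle([0.3, -0.7, 0.2], 0.9))
        imu2 = rich_sim.imu2
        imu2_rot = replace(imu2, gyro=imu2.gyro @ Rf, accel=imu2.accel @ Rf,
                           mag=imu2.mag @ Rf)
        R21 = quat_to_matrix(rich_sim.truth_q21)
        a = jc.estimate_joint_center(rich_sim.imu1, imu2, R21)
        b = jc.estimate_joint_center(rich_sim.imu1, imu2_rot, R21 @ Rf)
        np.testing.assert_allclose(b.r1, a.r1, atol=1e-8)
        np.testing.assert_allclose(b.r2, Rf.T @ a.r2, atol=1e-8)


@pytest.fixture(scope="module")
def hinge_sim():
    geom = ChainGeometry(r1=np.array([0.02, 0.17, 0.06]),
                         r2=np.array([0.04, -0.12, -0.06]),
                         mount1=quat_from_axis_angle([0.5, 0.2, 1], 0.7),
                         mount2=quat_from_axis_angle([-0.3, 1, 0.1], 1.3))
    return simulate_hinge(
        Sinusoid(25, 0.4, offset=-30.0), [0, 0, 1.0], geom, duration=20.0,
        noise=None, seed=5,
        base_euler=(Sinusoid(0.3, 0.25, 0.2), Sinusoid(0.2, 0.31, 0.9),
                    Sinusoid(0.25, 0.4, 1.6)))


class TestEstimateHingeAxes:
    def test_recovers_true_axes(self, hinge_sim):
        axes = jc.estimate_hinge_axes(hinge_sim.imu1.gyro, hinge_sim.imu2.gyro)
        assert vector_angle_deg(axes.j1, hinge_sim.truth_axes.j1) < 1.0
        assert vector_angle_deg(axes.j2, hinge_sim.truth_axes.j2) < 1.0

    def test_identical_traces_give_identical_axes(self, rng):
        w = rng.normal(size=(400, 3)) * [1.0, 0.1, 0.1]
        axes = jc.estimate_hinge_axes(w, w)
        assert vector_angle_deg(axes.j1, axes.j2) < 1e-3

    def test_optimum_beats_random_axes(self, hinge_sim, rng):
        axes = jc.estimate_hinge_axes(hinge_sim.imu1.gyro, hinge_sim.imu2.gyro)
        w1, w2 = hinge_sim.imu1.gyro, hinge_sim.imu2.gyro
        for _ in range(1000):
            j1 = rng.normal(size=3)
            j2 = rng.normal(size=3)
            j1 /= np.linalg.norm(j1)
            j2 /= np.linalg.norm(j2)
            assert axes.cost <= jc.hinge_cost(j1, j2, w1, w2) + 1e-9

    def test_sign_convention_positively_correlated(self, hinge_sim):
        axes = jc.estimate_hinge_axes(hinge_sim.imu1.gyro, hinge_sim.imu2.gyro)
        s = np.sum((hinge_sim.imu1.gyro @ axes.j1) *
                   (hinge_sim.imu2.gyro @ axes.j2))
        assert s > 0


class TestCorrectHingeCenter:
    def test_orthogonal_estimates_unchanged(self):
        axes = jc.HingeAxes(j1=np.array([0, 0, 1.0]), j2=np.array([0, 0, 1.0]))
        r1, r2 = jc.correct_hinge_center([1.0, 2, 0], [0.5, -1, 0], axes)
        np.testing.assert_allclose(r1, [1.0, 2, 0])
        np.testing.assert_allclose(r2, [0.5, -1, 0])

    def test_axis_aligned_estimates_collapse(self):
        j = np.array([0, 0, 1.0])
        axes = jc.HingeAxes(j1=j, j2=j)
        r1, r2 = jc.correct_hinge_center(j, j, axes)
        np.testing.assert_allclose(r1, 0.0, atol=1e-12)
        np.testing.assert_allclose(r2, 0.0, atol=1e-12)

    def test_constraint_satisfied_after_correction(self, rng):
        for _ in range(50):
            j1 = rng.normal(size=3)
            j2 = rng.normal(size=3)
            j1 /= np.linalg.norm(j1)
            j2 /= np.linalg.norm(j2)
            axes = jc.HingeAxes(j1=j1, j2=j2)
            r1, r2 = jc.correct_hinge_center(rng.normal(size=3),
                                             rng.normal(size=3), axes)
            assert abs(np.dot(r1, j1) + np.dot(r2, j2)) < 1e-9

    def test_offset_centers_restored_to_foot_point(self, hinge_sim):
        """Shifting both true centers 10 cm along the hinge axis is removed
        by the correction up to the system's own axial ambiguity."""
        g = hinge_sim.truth_geometry
        axes = hinge_sim.truth_axes
        r1_shift = g.r1 + 0.10 * axes.j1
        r2_shift = g.r2 + 0.10 * axes.j2
        r1c, r2c = jc.correct_hinge_center(r1_shift, r2_shift, axes)
        # foot point: the corrected pair balances the axial components
        r1e, r2e = jc.correct_hinge_center(g.r1, g.r2, axes)
        assert np.linalg.norm(r1c - r1e) < 0.01
        assert np.linalg.norm(r2c - r2e) < 0.01

    def test_unit_axis_enforced(self):
        with pytest.raises(InvalidInputError):
            jc.HingeAxes(j1=np.array([0, 0, 2.0]), j2=np.array([0, 0, 1.0]))
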