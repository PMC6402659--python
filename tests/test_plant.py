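"""Rigid-chain dynamics, integration, CoM bookkeeping and fall detection."""

import numpy as np
import pytest

from posturesim import (DivergenceError, LinkParams, MuscleParams,
                        PerturbationSpec, PlantConfig, PlantState, Trajectory,
                        com_height, detect_fall, dynamics,
                        joint_torques_from_muscles, simulate, step,
                        total_energy)


def pendulum_config(mass=2.0, length=1.0, inertia=1e-9, g=9.81):
    """Point mass at the link tip (inertia about CoM ~ 0)."""
    return PlantConfig(
        links=(LinkParams(mass=mass, length=length, com_offset=length,
                          inertia=inertia),),
        joint_names=("j",), joint_limits=((-3.0, 3.0),),
        initial_pose=(0.0,), gravity=g,
    )


class TestJointTorques:
    def mk(self, ma):
        return MuscleParams(name="m", F0=1.0, L_opt=0.1, V_max=1.0,
                            L_ref=0.3, L_slack=0.1, moment_arms=ma, group="g")

    def test_single_muscle(self):
        tau = joint_torques_from_muscles([100.0], [self.mk((0.05,))])
        assert tau == pytest.approx([5.0])

    def test_antagonists_cancel(self):
        tau = joint_torques_from_muscles(
            [50.0, 50.0], [self.mk((0.05,)), self.mk((-0.05,))])
        assert tau == pytest.approx([0.0])

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(0)
        MA = rng.normal(size=(5, 3)) * 0.05
        F = rng.uniform(0, 200, 5)
        muscles = [self.mk(tuple(row)) for row in MA]
        tau = joint_torques_from_muscles(F, muscles)
        brute = [sum(F[i] * MA[i, j] for i in range(5)) for j in range(3)]
        assert tau == pytest.approx(brute)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            joint_torques_from_muscles([1.0, 2.0], [self.mk((0.05,))])


class TestDynamics:
    def test_upright_equilibrium(self):
        cfg = pendulum_config()
        st = PlantState(theta=np.zeros(1), theta_dot=np.zeros(1))
        assert dynamics(cfg, st, [0.0]) == pytest.approx([0.0])

    def test_pendulum_closed_form(self):
        cfg = pendulum_config(mass=2.0, length=1.0)
        st = PlantState(theta=np.array([0.3]), theta_dot=np.zeros(1))
        assert dynamics(cfg, st, [0.0]) == pytest.approx(
            [9.81 * np.sin(0.3)], rel=1e-9)

    def test_base_acceleration_linearized(self):
        cfg = pendulum_config(length=1.0)
        st = PlantState(theta=np.zeros(1), theta_dot=np.zeros(1))
        assert dynamics(cfg, st, [0.0], base_acc=2.0) == pytest.approx([-2.0])

    def test_torque_scaling(self):
        cfg = pendulum_config(mass=1.0, length=1.0, g=0.0)
        st = PlantState(theta=np.zeros(1), theta_dot=np.zeros(1))
        # m l^2 theta_dd = tau
        assert dynamics(cfg, st, [3.0]) == pytest.approx([3.0])


class TestStep:
    def test_rest_state_unchanged_without_forcing(self):
        cfg = pendulum_config(g=0.0)
        st = PlantState(theta=np.array([0.2]), theta_dot=np.zeros(1))
        out = step(cfg, st, [0.0], 0.0, 1e-3)
        assert out.theta == pytest.approx([0.2])
        assert out.theta_dot == pytest.approx([0.0])

    def test_rk4_convergence_order(self):
        # halving dt shrinks the error ~16x for a smooth pendulum swing
        cfg = pendulum_config(inertia=1e-9)

        def run(dt, T=0.5):
            s = PlantState(theta=np.array([0.5]), theta_dot=np.zeros(1))
            for _ in range(int(round(T / dt))):
                s = step(cfg, s, [0.0], 0.0, dt)
            return s.theta[0]

        ref = run(1.25e-4)
        e1 = abs(run(1e-3) - ref)
        e2 = abs(run(5e-4) - ref)
        assert e1 / e2 > 8.0  # at least ~3rd order observed

    def test_energy_drift_passive_conservative(self):
        cfg = PlantConfig(
            links=(LinkParams(2.0, 1.0, 0.5, 0.1),
                   LinkParams(1.0, 0.8, 0.4, 0.05)),
            joint_names=("a", "b"), joint_limits=((-3, 3), (-3, 3)),
            initial_pose=(0.0, 0.0), gravity=9.81)
        s = PlantState(theta=np.array([0.4, -0.3]),
                       theta_dot=np.array([0.0, 0.5]))
        e0 = total_energy(cfg, s)
        for _ in range(5000):  # 5 s at 1 ms
            s = step(cfg, s, [0.0, 0.0], 0.0, 1e-3)
        assert abs(total_energy(cfg, s) - e0) / abs(e0) < 1e-3


class TestComHeight:
    def test_single_upright_link(self):
        cfg = PlantConfig(
            links=(LinkParams(10.0, 1.0, 0.5, 0.1),), joint_names=("j",),
            joint_limits=((-3, 3),), initial_pose=(0.0,))
        st = PlantState(theta=np.zeros(1), theta_dot=np.zeros(1))
        assert com_height(cfg, st) == pytest.approx(0.5)

    def test_horizontal_link(self):
        cfg = PlantConfig(
            links=(LinkParams(10.0, 1.0, 0.5, 0.1),), joint_names=("j",),
            joint_limits=((-3, 3),), initial_pose=(0.0,))
        st = PlantState(theta=np.array([np.pi / 2]), theta_dot=np.zeros(1))
        assert com_height(cfg, st) == pytest.approx(0.0, abs=1e-12)

    def test_two_link_mass_weighted_oracle(self):
        m1, m2 = 3.0, 7.0
        cfg = PlantConfig(
            links=(LinkParams(m1, 1.0, 0.6, 0.1), LinkParams(m2, 0.8, 0.3, 0.1)),
            joint_names=("a", "b"), joint_limits=((-3, 3), (-3, 3)),
            initial_pose=(0.0, 0.0))
        th = np.array([0.3, -0.5])
        st = PlantState(theta=th, theta_dot=np.zeros(2))
        y1 = 0.6 * np.cos(th[0])
        y2 = 1.0 * np.cos(th[0]) + 0.3 * np.cos(th[0] + th[1])
        assert com_height(cfg, st) == pytest.approx(
            (m1 * y1 + m2 * y2) / (m1 + m2))


class TestDetectFall:
    def mk_traj(self, com):
        n = len(com)
        return Trajectory(
            t=np.arange(n) * 1e-3, theta=np.zeros((n, 1)),
            theta_dot=np.zeros((n, 1)), base_pos=np.zeros(n),
            activations=np.zeros((n, 1)), controls=np.zeros((n, 1)),
            com_height=np.asarray(com, float), L_MT=np.zeros((n, 1)),
            Ldot_MT=np.zeros((n, 1)), dt=1e-3)

    def test_standing_returns_horizon(self):
        traj = self.mk_traj(np.full(5001, 1.0))
        assert detect_fall(traj, 0.9) == pytest.approx(5000.0)

    def test_first_crossing(self):
        com = np.full(5001, 1.0)
        com[2500:] = 0.85
        assert detect_fall(self.mk_traj(com), 0.9) == pytest.approx(2500.0)

    def test_immediate_failure(self):
        assert detect_fall(self.mk_traj([0.5, 0.5]), 0.9) == 0.0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            detect_fall(self.mk_traj([]), 0.9)


class TestSimulate:
    def test_unactuated_inverted_pendulum_falls(self):
        # negligible muscle strength: uncontrolled inverted pendulum
        from posturesim import FixtureSpec, make_fixture
        cfg, muscles, skeleton = make_fixture(
            FixtureSpec("single_link", strength=1e-3))
        ctrl = skeleton.replace(k_p={g: 0.0 for g in skeleton.k_p},
                                k_d={g: 0.0 for g in skeleton.k_d})
        traj = simulate(cfg, muscles, ctrl, None, T_simu=5000.0)
        assert detect_fall(traj, cfg.fall_threshold()) < 5000.0

    def test_platform_follows_profile(self, single_link):
        cfg, muscles, skeleton = single_link
        pert = PerturbationSpec(direction_deg=90.0, onset=100.0)
        traj = simulate(cfg, muscles, skeleton, pert, T_simu=900.0)
        from posturesim import translation_profile
        expected = 0.01 * translation_profile(traj.t * 1e3, pert)
        assert np.allclose(traj.base_pos, expected, atol=1e-12)

    def test_reproducible(self, single_link):
        cfg, muscles, skeleton = single_link
        pert = PerturbationSpec(direction_deg=270.0)
        a = simulate(cfg, muscles, skeleton, pert, T_simu=1500.0)
        b = simulate(cfg, muscles, skeleton, pert, T_simu=1500.0)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.activations, b.activations)

    def test_mirror_symmetry_frontal(self, frontal_2link):
        """Mirrored perturbations swap the left/right muscle traces."""
        cfg, muscles, skeleton = frontal_2link
        sym_kp = dict.fromkeys(skeleton.k_p, 1.5)
        sym_kd = dict.fromkeys(skeleton.k_d, 0.5)
        ctrl = skeleton.replace(k_p=sym_kp, k_d=sym_kd)
        left = simulate(cfg, muscles, ctrl,
                        PerturbationSpec(direction_deg=180.0), T_simu=1500.0)
        right = simulate(cfg, muscles, ctrl,
                         PerturbationSpec(direction_deg=0.0), T_simu=1500.0)
        names = list(left.muscle_names)
        swap = {"evertor": "invertor", "invertor": "evertor",
                "bend_right": "bend_left", "bend_left": "bend_right"}
        for name, partner in swap.items():
            i, j = names.index(name), names.index(partner)
            assert np.allclose(left.activations[:, i],
                               right.activations[:, j], atol=1e-10)
        assert np.allclose(left.theta, -right.theta, atol=1e-10)

    def test_dt_cap_enforced(self, single_link):
        cfg, muscles, skeleton = single_link
        with pytest.raises(ValueError):
            simulate(cfg, muscles, skeleton, None, T_simu=100.0, dt=5e-3)
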