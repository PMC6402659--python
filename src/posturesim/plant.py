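"""Rigid multi-link standing plant on a horizontally translating base.

The body is a planar serial chain of rigid links hinged at the ankle to a
platform.  The feet are rigidly attached to the platform, so platform motion
enters the equations of motion purely as an inertial forcing term: in the
platform frame each link's center of mass feels a horizontal pseudo-force
``-m * base_acc``.  Joint angles are relative; internally the dynamics are
evaluated in absolute link angles (measured from the upward vertical,
positive toward the positive horizontal axis of the plant's plane), where
the compound-pendulum equations take the classic form

    M(phi) phi_dd + C(phi, phi_d) - g G sin(phi) + A G cos(phi) = Q

with S = B' diag(m) B, M_ij = S_ij cos(phi_i - phi_j) + delta_ij I_i,
C_i = sum_j S_ij sin(phi_i - phi_j) phi_d_j^2, and G_i = sum_k m_k B_ki the
first mass moments.  ``B_kj`` is the distance factor of link k's center of
mass with respect to absolute angle j (full link lengths below, the CoM
offset on the link itself).

Integration is fixed-step explicit Runge-Kutta 4 with dt = 1 ms by default;
the activation states in the closed-loop simulation use the same step, so
the 40 ms neural delays fall exactly on the sample grid.

A fall is declared when the whole-body center of mass drops below a
threshold height; for toy plants the threshold defaults to a fraction
(0.9) of the initial CoM height so plants of any stature behave like the
full-scale 0.9 m criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .controller import ControllerParams
from .muscles import DEFAULT_CURVES, HillCurves, MuscleParams
from .perturbation import (PerturbationSpec, direction_components,
                           translation_profile,
                           translation_velocity_acceleration)

__all__ = [
    "LinkParams",
    "PlantConfig",
    "PlantState",
    "Trajectory",
    "DivergenceError",
    "joint_torques_from_muscles",
    "dynamics",
    "step",
    "com_height",
    "total_energy",
    "detect_fall",
    "simulate",
]


class DivergenceError(RuntimeError):
    """Raised when the simulated state becomes non-finite.

    Carries the time of failure and the partial trajectory.
    """

    def __init__(self, t_fail: float, trajectory: "Trajectory"):
        super().__init__(f"simulation diverged at t = {t_fail * 1e3:.0f} ms")
        self.t_fail = t_fail
        self.trajectory = trajectory


@dataclass(frozen=True)
class LinkParams:
    mass: float  # kg
    length: float  # m, joint-to-joint
    com_offset: float  # m, proximal joint to CoM
    inertia: float  # kg m^2, about the CoM

    def __post_init__(self) -> None:
        if min(self.mass, self.length, self.com_offset, self.inertia) <= 0:
            raise ValueError("link mass, length, CoM offset and inertia must be > 0")


@dataclass(frozen=True)
class PlantConfig:
    links: tuple[LinkParams, ...]
    joint_names: tuple[str, ...]
    joint_limits: tuple[tuple[float, float], ...]  # rad
    initial_pose: tuple[float, ...]  # rad
    plane: str = "sagittal"  # sagittal | frontal
    gravity: float = 9.80665  # m/s^2
    fall_height_fraction: float = 0.9
    fall_height_abs: float | None = None  # m, overrides the fraction if set

    def __post_init__(self) -> None:
        n = len(self.links)
        if not (len(self.joint_names) == len(self.joint_limits)
                == len(self.initial_pose) == n):
            raise ValueError("joint count must equal link (DoF) count")
        if self.plane not in ("sagittal", "frontal"):
            raise ValueError("plane must be 'sagittal' or 'frontal'")
        if not (0 < self.fall_height_fraction < 1):
            raise ValueError("fall_height_fraction must lie in (0, 1)")

    @property
    def n_joints(self) -> int:
        return len(self.links)

    def fall_threshold(self) -> float:
        """Absolute CoM-height fall threshold in meters."""
        if self.fall_height_abs is not None:
            return self.fall_height_abs
        state0 = PlantState(
            theta=np.asarray(self.initial_pose, dtype=float),
            theta_dot=np.zeros(self.n_joints),
        )
        return self.fall_height_fraction * com_height(self, state0)


@dataclass
class PlantState:
    theta: np.ndarray  # relative joint angles, rad
    theta_dot: np.ndarray  # rad/s
    base_pos: float = 0.0  # m
    base_vel: float = 0.0  # m/s
    base_acc: float = 0.0  # m/s^2
    t: float = 0.0  # s

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.theta_dot = np.asarray(self.theta_dot, dtype=float)
        if not (np.all(np.isfinite(self.theta))
                and np.all(np.isfinite(self.theta_dot))):
            raise ValueError("plant state must be finite")


@dataclass
class Trajectory:
    """Time-indexed record of a closed-loop (or passive) run.

    All series share the uniform time grid ``t`` (seconds).  ``diverged``
    flags runs that ended because the state became non-finite.
    """

    t: np.ndarray  # s
    theta: np.ndarray  # (n_steps, n_joints)
    theta_dot: np.ndarray
    base_pos: np.ndarray  # m
    activations: np.ndarray  # (n_steps, n_muscles)
    controls: np.ndarray  # clipped total control u
    com_height: np.ndarray  # m
    L_MT: np.ndarray  # (n_steps, n_muscles), m
    Ldot_MT: np.ndarray  # m/s
    dt: float  # s
    muscle_names: tuple[str, ...] = ()
    joint_names: tuple[str, ...] = ()
    diverged: bool = False

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] * 1e3)

    def to_frame(self):
        """Tidy one-row-per-step table (time, joints, base, CoM, muscles)."""
        import pandas as pd

        data = {"time_s": self.t, "base_pos_m": self.base_pos,
                "com_height_m": self.com_height}
        jn = self.joint_names or tuple(
            f"q{j+1}" for j in range(self.theta.shape[1]))
        for j, name in enumerate(jn):
            data[f"theta_{name}"] = self.theta[:, j]
            data[f"theta_dot_{name}"] = self.theta_dot[:, j]
        mn = self.muscle_names or tuple(
            f"m{i+1}" for i in range(self.activations.shape[1]))
        for i, name in enumerate(mn):
            data[f"a_{name}"] = self.activations[:, i]
            data[f"u_{name}"] = self.controls[:, i]
            data[f"L_MT_{name}"] = self.L_MT[:, i]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _chain_constants(config: PlantConfig):
    """(masses, B, S, G, inertias) of the absolute-angle formulation."""
    n = config.n_joints
    m = np.array([lk.mass for lk in config.links])
    L = np.array([lk.length for lk in config.links])
    r = np.array([lk.com_offset for lk in config.links])
    I = np.array([lk.inertia for lk in config.links])
    B = np.zeros((n, n))
    for k in range(n):
        B[k, :k] = L[:k]
        B[k, k] = r[k]
    S = B.T @ (m[:, None] * B)
    G = m @ B  # G_j = sum_k m_k B_kj
    return m, B, S, G, I


def joint_torques_from_muscles(forces, muscles: list[MuscleParams]) -> np.ndarray:
    """tau_j = sum_i F_i * ma_ij (moment-arm weighted sum)."""
    F = np.asarray(forces, dtype=float)
    if F.shape[0] != len(muscles):
        raise ValueError("force count must equal muscle count")
    MA = np.array([m.moment_arms for m in muscles], dtype=float)
    return F @ MA


def _accel_fast(theta, theta_dot, Q, base_acc, S, G, I, g, n):
    """Relative accelerations; Q is the absolute-coordinate torque vector."""
    phi = np.add.accumulate(theta)
    phi_dot = np.add.accumulate(theta_dot)
    dphi = phi[:, None] - phi
    M = S * np.cos(dphi)
    M.flat[:: n + 1] += I
    cor = (S * np.sin(dphi)) @ (phi_dot * phi_dot)
    rhs = Q - cor + (g * np.sin(phi) - base_acc * np.cos(phi)) * G
    phi_dd = np.linalg.solve(M, rhs)
    out = np.empty(n)
    out[0] = phi_dd[0]
    out[1:] = phi_dd[1:] - phi_dd[:-1]
    return out


def _abs_torque(torques) -> np.ndarray:
    """Joint torques -> absolute-coordinate generalized forces.

    Joint torque j acts on link j and reacts on link j-1, so the absolute
    generalized force on link j is tau_j - tau_{j+1}.
    """
    tau = np.asarray(torques, dtype=float)
    Q = np.empty_like(tau)
    Q[:-1] = tau[:-1] - tau[1:]
    Q[-1] = tau[-1]
    return Q


def _accel(config: PlantConfig, theta, theta_dot, torques, base_acc,
           consts=None) -> np.ndarray:
    if consts is None:
        consts = _chain_constants(config)
    _, _, S, G, I = consts
    try:
        return _accel_fast(np.asarray(theta, float), np.asarray(theta_dot, float),
                           _abs_torque(torques), base_acc, S, G, I,
                           config.gravity, config.n_joints)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError("singular mass matrix") from exc


def dynamics(config: PlantConfig, state: PlantState, joint_torques,
             base_acc: float = 0.0) -> np.ndarray:
    """Relative joint accelerations of the chain, rad/s^2."""
    return _accel(config, state.theta, state.theta_dot, joint_torques, base_acc)


def step(config: PlantConfig, state: PlantState, joint_torques,
         base_acc=0.0, dt: float = 1e-3) -> PlantState:
    """Advance one fixed RK4 step with joint torques held constant.

    ``base_acc`` may be a constant or a callable of time (seconds), in which
    case it is evaluated at the RK4 substep times.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    consts = _chain_constants(config)
    acc = base_acc if callable(base_acc) else (lambda _t: base_acc)
    q, qd, t = state.theta, state.theta_dot, state.t

    def f(ti, qi, qdi):
        return qdi, _accel(config, qi, qdi, joint_torques, acc(ti), consts)

    k1q, k1v = f(t, q, qd)
    k2q, k2v = f(t + dt / 2, q + dt / 2 * k1q, qd + dt / 2 * k1v)
    k3q, k3v = f(t + dt / 2, q + dt / 2 * k2q, qd + dt / 2 * k2v)
    k4q, k4v = f(t + dt, q + dt * k3q, qd + dt * k3v)
    q_new = q + dt * (k1q + 2 * k2q + 2 * k3q + k4q) / 6.0
    qd_new = qd + dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
    if not (np.all(np.isfinite(q_new)) and np.all(np.isfinite(qd_new))):
        raise DivergenceError(t + dt, _empty_trajectory(config, dt))
    return PlantState(theta=q_new, theta_dot=qd_new, base_acc=acc(t + dt),
                      t=t + dt)


def com_height(config: PlantConfig, state: PlantState) -> float:
    """Whole-body CoM height above the platform surface, m."""
    m, B, _, _, _ = _chain_constants(config)
    phi = np.cumsum(state.theta)
    y = B @ np.cos(phi)
    return float(m @ y / m.sum())


def total_energy(config: PlantConfig, state: PlantState) -> float:
    """Kinetic + gravitational energy of the chain (platform at rest), J."""
    m, B, S, G, I = _chain_constants(config)
    phi = np.cumsum(state.theta)
    phi_dot = np.cumsum(state.theta_dot)
    dphi = phi[:, None] - phi[None, :]
    M = S * np.cos(dphi)
    M[np.diag_indices_from(M)] += I
    T = 0.5 * phi_dot @ M @ phi_dot
    V = config.gravity * float(G @ np.cos(phi))
    return float(T + V)


def detect_fall(traj: Trajectory, threshold: float) -> float:
    """First time (ms) the CoM height drops below threshold, else run length.

    Returns the full trajectory duration when the CoM stays at or above the
    threshold throughout.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    below = traj.com_height < threshold
    if not below.any():
        return traj.duration_ms
    return float(traj.t[int(np.argmax(below))] * 1e3)


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

def _empty_trajectory(config: PlantConfig, dt: float) -> Trajectory:
    n = config.n_joints
    return Trajectory(
        t=np.zeros(0), theta=np.zeros((0, n)), theta_dot=np.zeros((0, n)),
        base_pos=np.zeros(0), activations=np.zeros((0, 0)),
        controls=np.zeros((0, 0)), com_height=np.zeros(0),
        L_MT=np.zeros((0, 0)), Ldot_MT=np.zeros((0, 0)), dt=dt,
        joint_names=config.joint_names, diverged=True,
    )


def simulate(config: PlantConfig, muscles: list[MuscleParams],
             controller: ControllerParams,
             perturbation: PerturbationSpec | None = None,
             T_simu: float = 5000.0, dt: float = 1e-3,
             curves: HillCurves = DEFAULT_CURVES,
             initial_activations=None,
             stop_on_fall: bool = True) -> Trajectory:
    """Run the closed neuromuscular loop and record a Trajectory.

    T_simu is in ms, dt in seconds (dt <= 1 ms).  Each step computes muscle
    kinematics, delayed PD feedback, the clipped total control, activation
    dynamics, Hill muscle forces, joint torques and one RK4 plant step.  The
    platform follows the perturbation's direction-projected translation
    profile for this plant's plane (anterior component for sagittal plants,
    lateral for frontal).  On a fall the run is truncated at the first step
    whose CoM height is below the threshold; on divergence the partial
    trajectory is recorded and flagged.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must not exceed 1 ms")
    n_steps = int(round(T_simu / (dt * 1e3))) + 1
    n_mus = len(muscles)
    n_j = config.n_joints

    MA = np.array([m.moment_arms for m in muscles], dtype=float)
    if MA.shape[1] != n_j:
        raise ValueError("muscle moment-arm dimension must match joint count")
    F0 = np.array([m.F0 for m in muscles])
    L_opt = np.array([m.L_opt for m in muscles])
    L_slack = np.array([m.L_slack for m in muscles])
    L_ref = np.array([m.L_ref for m in muscles])
    V_max = np.array([m.V_max for m in muscles])
    t_act = np.array([m.t_act for m in muscles])
    t_deact = np.array([m.t_deact for m in muscles])
    kp = controller.kp_vector()
    kd = controller.kd_vector()
    u_ff = controller.u_ff
    L0 = controller.L0_MT
    lo, hi = controller.u_clip
    lag_fb = int(round(controller.tau_fb / dt))
    lag_trans = int(round(controller.tau_trans / dt))

    # direction-projected platform motion for this plant's plane, SI units
    if perturbation is not None:
        lat, ant = direction_components(perturbation.direction_deg)
        comp = ant if config.plane == "sagittal" else lat

        def base_pos_fn(t_s):
            return comp * 0.01 * translation_profile(t_s * 1e3, perturbation)

        def base_acc_fn(t_s):
            _, a = translation_velocity_acceleration(t_s * 1e3, perturbation)
            return comp * a * 1e4  # cm/ms^2 -> m/s^2
    else:
        base_pos_fn = lambda t_s: 0.0
        base_acc_fn = lambda t_s: 0.0

    consts = _chain_constants(config)
    m_arr, B = consts[0], consts[1]
    m_total = m_arr.sum()
    threshold = config.fall_threshold()
    gamma = curves.gamma_fl
    A_f, F_len, ecc_c = curves.A_f, curves.F_len, curves.ecc_c
    k_PE, eps0 = curves.k_PE, curves.eps0_PE
    epk = np.expm1(k_PE)

    theta = np.asarray(config.initial_pose, dtype=float).copy()
    theta_dot = np.zeros(n_j)
    # start at rest with the feed-forward tone established
    a = (np.clip(u_ff, lo, hi) if initial_activations is None
         else np.asarray(initial_activations, dtype=float).copy())

    t_grid = np.arange(n_steps) * dt
    TH = np.empty((n_steps, n_j)); THD = np.empty((n_steps, n_j))
    ACT = np.empty((n_steps, n_mus)); U = np.empty((n_steps, n_mus))
    LMT = np.empty((n_steps, n_mus)); LDOT = np.empty((n_steps, n_mus))
    COM = np.empty(n_steps); BPOS = np.empty(n_steps)
    # delay histories on the grid (integer lags: no interpolation needed)
    L_hist = np.empty((n_steps, n_mus)); LD_hist = np.empty((n_steps, n_mus))
    U_hist = np.empty((n_steps, n_mus))

    diverged = False
    k_end = n_steps
    for k in range(n_steps):
        t = t_grid[k]
        # muscle kinematics
        L = L_ref - MA @ theta
        Ldot = -(MA @ theta_dot)
        L_hist[k] = L; LD_hist[k] = Ldot
        # delayed PD feedback -> total control
        kb = k - lag_fb if k >= lag_fb else 0
        u_fb = kp * (L_hist[kb] - L0) / L0 + kd * LD_hist[kb] / V_max
        u = np.clip(u_ff + u_fb, lo, hi)
        U_hist[k] = u
        # CoM and bookkeeping
        phi = np.cumsum(theta)
        com = float(m_arr @ (B @ np.cos(phi)) / m_total)
        TH[k] = theta; THD[k] = theta_dot; ACT[k] = a; U[k] = u
        LMT[k] = L; LDOT[k] = Ldot; COM[k] = com; BPOS[k] = base_pos_fn(t)
        if stop_on_fall and com < threshold:
            k_end = k + 1
            break
        if k == n_steps - 1:
            break
        # activation dynamics driven by the transmission-delayed control
        ut = U_hist[k - lag_trans if k >= lag_trans else 0]
        a = _activation_rk4(a, ut, dt, t_act, t_deact)
        # Hill forces at the current kinematic state
        l_n = (L - L_slack) / L_opt
        v_n = Ldot / V_max
        fl = np.exp(-((l_n - 1.0) ** 2) / gamma)
        fv = np.where(
            v_n <= -1.0, 0.0,
            np.where(v_n <= 0.0,
                     (1.0 + v_n) / (1.0 - v_n / A_f),
                     (F_len * v_n + ecc_c) / (v_n + ecc_c)))
        fpe = np.expm1(k_PE * np.maximum(l_n - 1.0, 0.0) / eps0) / epk
        F = F0 * (ACT[k] * fl * fv + fpe)
        tau = F @ MA
        # plant RK4 step (torque frozen over the step)
        try:
            q, qd = _rk4_plant(config, theta, theta_dot, tau, base_acc_fn,
                               t, dt, consts)
        except np.linalg.LinAlgError:
            diverged = True
            k_end = k + 1
            break
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd))):
            diverged = True
            k_end = k + 1
            break
        theta, theta_dot = q, qd

    traj = Trajectory(
        t=t_grid[:k_end], theta=TH[:k_end], theta_dot=THD[:k_end],
        base_pos=BPOS[:k_end], activations=ACT[:k_end], controls=U[:k_end],
        com_height=COM[:k_end], L_MT=LMT[:k_end], Ldot_MT=LDOT[:k_end],
        dt=dt, muscle_names=tuple(m.name for m in muscles),
        joint_names=config.joint_names, diverged=diverged,
    )
    if diverged:
        raise DivergenceError(t_grid[k_end - 1], traj)
    return traj


def _activation_rk4(a, u, dt, t_act, t_deact):
    def f(ai):
        tau = np.where(u > ai, t_act * (0.5 + 1.5 * ai),
                       t_deact / (0.5 + 1.5 * ai))
        return (u - ai) / tau

    k1 = f(a)
    k2 = f(np.clip(a + 0.5 * dt * k1, 0.0, 1.0))
    k3 = f(np.clip(a + 0.5 * dt * k2, 0.0, 1.0))
    k4 = f(np.clip(a + dt * k3, 0.0, 1.0))
    return np.clip(a + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0, 0.0, 1.0)


def _rk4_plant(config, q, qd, tau, acc_fn, t, dt, consts):
    _, _, S, G, I = consts
    g, n = config.gravity, config.n_joints
    Q = _abs_torque(tau)
    a_mid = acc_fn(t + dt / 2)

    k1v = _accel_fast(q, qd, Q, acc_fn(t), S, G, I, g, n)
    k2q, k2v_in = q + dt / 2 * qd, qd + dt / 2 * k1v
    k2v = _accel_fast(k2q, k2v_in, Q, a_mid, S, G, I, g, n)
    k3q, k3v_in = q + dt / 2 * k2v_in, qd + dt / 2 * k2v
    k3v = _accel_fast(k3q, k3v_in, Q, a_mid, S, G, I, g, n)
    k4q, k4v_in = q + dt * k3v_in, qd + dt * k3v
    k4v = _accel_fast(k4q, k4v_in, Q, acc_fn(t + dt), S, G, I, g, n)
    return (q + dt * (qd + 2 * k2v_in + 2 * k3v_in + k4v_in) / 6.0,
            qd + dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0)
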