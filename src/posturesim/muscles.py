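"""Hill-type muscle-tendon actuators.

Each actuator produces force

    F = F0 * (a * f_L(l) * f_V(v) + f_PE(l))

where ``a`` is the activation, ``l`` the fiber length normalized by the
optimal fiber length and ``v`` the lengthening velocity normalized by the
maximum contraction velocity.  The tendon is treated as rigid: fiber length
is musculotendon length minus a constant slack length, so the whole model is
driven by normalized quantities only.

Muscle paths are affine in the joint angles: a constant moment arm per joint
maps joint rotation to musculotendon length change,

    L_MT = L_ref - sum_j ma_j * theta_j,

which keeps the length-torque duality (virtual work) exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HillCurves",
    "MuscleParams",
    "MuscleState",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
    "muscle_force",
    "musculotendon_kinematics",
]


@dataclass(frozen=True)
class HillCurves:
    """Shape constants of the dimensionless Hill curves.

    gamma_fl : width of the Gaussian active force-length curve.
    A_f      : force-velocity shape constant (Hill parameter).
    F_len    : eccentric force plateau (> 1).
    k_PE     : passive exponential shape constant.
    eps0_PE  : passive strain at which the normalized passive force is 1.
    """

    gamma_fl: float = 0.45
    A_f: float = 0.25
    F_len: float = 1.4
    k_PE: float = 4.0
    eps0_PE: float = 0.6

    def __post_init__(self) -> None:
        if self.gamma_fl <= 0:
            raise ValueError("gamma_fl must be positive")
        if not (0 < self.A_f < 1):
            raise ValueError("A_f must lie in (0, 1)")
        if self.F_len <= 1:
            raise ValueError("F_len must exceed 1")
        if self.k_PE <= 0 or self.eps0_PE <= 0:
            raise ValueError("k_PE and eps0_PE must be positive")

    @property
    def ecc_c(self) -> float:
        """Eccentric-branch constant giving slope continuity at v = 0."""
        return (self.F_len - 1.0) / (1.0 + 1.0 / self.A_f)


DEFAULT_CURVES = HillCurves()


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one muscle-tendon actuator.

    moment_arms maps joint index -> constant moment arm in meters; the sign
    encodes flexor/extensor action (positive moment arm: shortening produces
    positive joint torque and positive joint rotation shortens the muscle).
    """

    name: str
    F0: float  # maximum isometric force, N
    L_opt: float  # optimal fiber length, m
    V_max: float  # maximum lengthening-velocity scale, m/s
    L_ref: float  # musculotendon length at zero joint angles, m
    L_slack: float  # constant series slack length, m
    moment_arms: tuple[float, ...]  # per-joint, m
    group: str
    t_act: float = 0.010  # activation time constant, s
    t_deact: float = 0.040  # deactivation time constant, s

    def __post_init__(self) -> None:
        for attr in ("F0", "L_opt", "V_max", "t_act", "t_deact"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be positive")
        if not any(ma != 0.0 for ma in self.moment_arms):
            raise ValueError(f"{self.name}: needs at least one nonzero moment arm")


@dataclass
class MuscleState:
    """Instantaneous mechanical and activation state of one muscle."""

    a: float = 0.0
    L_MT: float = 0.0
    Ldot_MT: float = 0.0
    l_norm: float = 0.0
    v_norm: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("activation must lie in [0, 1]")


def active_force_length(l_norm, curves: HillCurves = DEFAULT_CURVES):
    """Gaussian active force-length curve, maximum 1 at l_norm = 1."""
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm < 0):
        raise ValueError("normalized fiber length must be nonnegative")
    return np.exp(-((l_norm - 1.0) ** 2) / curves.gamma_fl)


def force_velocity(v_norm, curves: HillCurves = DEFAULT_CURVES):
    """Force-velocity curve: 0 at/below v = -1, 1 at v = 0, F_len plateau.

    Concentric branch (1+v)/(1-v/A_f); eccentric branch (F_len*v+c)/(v+c)
    with c chosen so the slope is continuous at v = 0.
    """
    v = np.asarray(v_norm, dtype=float)
    c = curves.ecc_c
    con = (1.0 + v) / (1.0 - v / curves.A_f)
    ecc = (curves.F_len * v + c) / (v + c)
    out = np.where(v <= -1.0, 0.0, np.where(v <= 0.0, con, ecc))
    return out if out.ndim else float(out)


def passive_force_length(l_norm, curves: HillCurves = DEFAULT_CURVES):
    """Exponential passive curve: 0 up to l = 1, reaches 1 at l = 1 + eps0_PE."""
    l = np.asarray(l_norm, dtype=float)
    if np.any(l < 0):
        raise ValueError("normalized fiber length must be nonnegative")
    strain = np.maximum(l - 1.0, 0.0)
    out = np.expm1(curves.k_PE * strain / curves.eps0_PE) / np.expm1(curves.k_PE)
    return out if out.ndim else float(out)


def muscle_force(params: MuscleParams, a, l_norm, v_norm,
                 curves: HillCurves = DEFAULT_CURVES):
    """Total actuator force F = F0 * (a*f_L*f_V + f_PE), in N."""
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    fl = active_force_length(l_norm, curves)
    fv = force_velocity(v_norm, curves)
    fpe = passive_force_length(l_norm, curves)
    return params.F0 * (a * fl * fv + fpe)


def musculotendon_kinematics(params: MuscleParams, joint_angles, joint_velocities):
    """Map joint state to (L_MT, Ldot_MT, l_norm, v_norm) via the affine path."""
    theta = np.asarray(joint_angles, dtype=float)
    theta_dot = np.asarray(joint_velocities, dtype=float)
    ma = np.asarray(params.moment_arms, dtype=float)
    if theta.shape != ma.shape or theta_dot.shape != ma.shape:
        raise ValueError(
            f"{params.name}: expected {ma.shape[0]} joint angles/velocities"
        )
    L_MT = params.L_ref - float(ma @ theta)
    if L_MT <= 0:
        raise ValueError(f"{params.name}: degenerate geometry, L_MT = {L_MT:.4f} <= 0")
    Ldot_MT = -float(ma @ theta_dot)
    l_norm = (L_MT - params.L_slack) / params.L_opt
    v_norm = Ldot_MT / params.V_max
    return L_MT, Ldot_MT, l_norm, v_norm
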