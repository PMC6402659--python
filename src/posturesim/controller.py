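"""Neural controller: feed-forward plus delayed PD feedback.

The control of muscle i is

    u_i(t) = u_ff,i + u_fb,i(t)
    u_fb,i(t) = k_p,i * (L_i(t - tau_fb) - L0_i) / L0_i
              + k_d,i * (Ldot_i(t - tau_fb) - 0) / V_max,i

with constant feed-forward activations u_ff, PD gains shared within muscle
groups, and target lengths L0 taken from the initial posture (target
velocity is zero).  The control reaches the muscle after a transmission
delay tau_trans and drives first-order activation dynamics whose time
constant depends on the activation state:

    da/dt = (u(t - tau_trans) - a) / tau(a, u)
    tau = t_act * (0.5 + 1.5 a)   if u(t - tau_trans) > a   (activating)
        = t_deact / (0.5 + 1.5 a) otherwise                 (deactivating)

so activation is faster than deactivation.  With tau_fb = tau_trans = 40 ms
and the activation lag of roughly 40 ms the total sensing-to-force latency
is about 120 ms, a physiological neurological time delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .muscles import MuscleParams

__all__ = [
    "ControllerParams",
    "DelayBuffer",
    "ControlSignal",
    "feedback_control",
    "total_control",
    "activation_time_constant",
    "activation_step",
    "control_update",
]


@dataclass
class ControllerParams:
    """Feed-forward vector, grouped PD gains, delays and targets.

    u_ff, L0_MT and muscle_names are per-muscle (same order); k_p and k_d
    are keyed by group label and every muscle must map to exactly one group.
    """

    muscle_names: tuple[str, ...]
    u_ff: np.ndarray  # per-muscle constant activation
    k_p: dict[str, float]  # per-group proportional gain
    k_d: dict[str, float]  # per-group derivative gain
    group_map: dict[str, str]  # muscle name -> group label
    L0_MT: np.ndarray  # per-muscle target length, m
    tau_fb: float = 0.040  # s
    tau_trans: float = 0.040  # s
    Ldot0_MT: float = 0.0  # target lengthening velocity (zero at rest)
    u_clip: tuple[float, float] = (0.001, 1.0)

    def __post_init__(self) -> None:
        self.u_ff = np.asarray(self.u_ff, dtype=float)
        self.L0_MT = np.asarray(self.L0_MT, dtype=float)
        n = len(self.muscle_names)
        if self.u_ff.shape != (n,) or self.L0_MT.shape != (n,):
            raise ValueError("u_ff and L0_MT must have one entry per muscle")
        if np.any(self.u_ff < 0) or np.any(self.u_ff > 1):
            raise ValueError("u_ff components must lie in [0, 1]")
        if self.tau_fb < 0 or self.tau_trans < 0:
            raise ValueError("delays must be nonnegative")
        for name in self.muscle_names:
            if name not in self.group_map:
                raise ValueError(f"muscle {name!r} is not mapped to a group")
            g = self.group_map[name]
            if g not in self.k_p or g not in self.k_d:
                raise ValueError(f"group {g!r} has no PD gains")
        if any(v < 0 for v in self.k_p.values()) or any(
            v < 0 for v in self.k_d.values()
        ):
            raise ValueError("PD gains must be nonnegative")

    def kp_vector(self) -> np.ndarray:
        """Per-muscle proportional gains expanded from the group gains."""
        return np.array([self.k_p[self.group_map[m]] for m in self.muscle_names])

    def kd_vector(self) -> np.ndarray:
        return np.array([self.k_d[self.group_map[m]] for m in self.muscle_names])

    @property
    def uff_norm_sq(self) -> float:
        return float(np.sum(self.u_ff**2))

    # -- lossless serialization -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "muscle_names": list(self.muscle_names),
            "u_ff": self.u_ff.tolist(),
            "k_p": dict(self.k_p),
            "k_d": dict(self.k_d),
            "group_map": dict(self.group_map),
            "L0_MT": self.L0_MT.tolist(),
            "tau_fb": self.tau_fb,
            "tau_trans": self.tau_trans,
            "Ldot0_MT": self.Ldot0_MT,
            "u_clip": list(self.u_clip),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerParams":
        d = dict(d)
        d["muscle_names"] = tuple(d["muscle_names"])
        d["u_clip"] = tuple(d["u_clip"])
        return cls(**d)

    def replace(self, **kw) -> "ControllerParams":
        d = self.to_dict()
        for k, v in kw.items():
            d[k] = v
        return ControllerParams.from_dict(d)


class DelayBuffer:
    """History of per-muscle signals sampled on the integrator grid.

    Reads at lag tau return the signal at t - tau; reads reaching before the
    first sample return the t = 0 value (the system is assumed at rest at
    its target prior to the start).  Lags that are integer multiples of the
    step need no interpolation; otherwise the read is linearly interpolated.
    """

    def __init__(self, dt: float, n_signals: int):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = dt
        self.n_signals = n_signals
        self._data: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self._data)

    def append(self, values) -> None:
        v = np.asarray(values, dtype=float)
        if v.shape != (self.n_signals,):
            raise ValueError("signal dimension mismatch")
        self._data.append(v)

    def read(self, t: float, lag: float) -> np.ndarray:
        """Signal at time t - lag; samples are at 0, dt, 2 dt, ..."""
        if not self._data:
            raise ValueError("cannot read from an empty buffer")
        s = (t - lag) / self.dt
        if s <= 0:
            return self._data[0]
        i = int(np.floor(s))
        frac = s - i
        last = len(self._data) - 1
        if i >= last:
            return self._data[last]
        if frac < 1e-9:
            return self._data[i]
        return (1.0 - frac) * self._data[i] + frac * self._data[i + 1]


@dataclass
class ControlSignal:
    """Total, feedback and feed-forward control for all muscles at one time."""

    u: np.ndarray
    u_fb: np.ndarray
    u_ff: np.ndarray
    u_unclipped: np.ndarray
    uff_norm_sq: float


def feedback_control(L_delayed, Ldot_delayed, params: ControllerParams,
                     V_max) -> np.ndarray:
    """Delayed PD feedback on musculotendon length and velocity.

    May be negative; the total control is clipped later.
    """
    L0 = params.L0_MT
    V_max = np.asarray(V_max, dtype=float)
    if np.any(L0 <= 0) or np.any(V_max <= 0):
        raise ValueError("L0_MT and V_max must be positive")
    kp = params.kp_vector()
    kd = params.kd_vector()
    return kp * (np.asarray(L_delayed) - L0) / L0 + kd * (
        np.asarray(Ldot_delayed) - params.Ldot0_MT
    ) / V_max


def total_control(u_ff, u_fb, u_clip=(0.001, 1.0)):
    """Clipped sum of feed-forward and feedback control.

    Returns (u, u_unclipped); the unclipped sum is kept for diagnostics.
    """
    raw = np.asarray(u_ff, dtype=float) + np.asarray(u_fb, dtype=float)
    return np.clip(raw, u_clip[0], u_clip[1]), raw


def activation_time_constant(a, u_delayed, t_act=0.010, t_deact=0.040):
    """State-dependent activation time constant tau(a, u)."""
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    u = np.asarray(u_delayed, dtype=float)
    tau = np.where(u > a, t_act * (0.5 + 1.5 * a), t_deact / (0.5 + 1.5 * a))
    return tau if tau.ndim else float(tau)


def _a_dot(a, u, t_act, t_deact):
    tau = np.where(u > a, t_act * (0.5 + 1.5 * a), t_deact / (0.5 + 1.5 * a))
    return (u - a) / tau


def activation_step(a, u_delayed, dt, t_act=0.010, t_deact=0.040):
    """Advance the activation ODE one RK4 step with u held constant."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=float)
    u = np.asarray(u_delayed, dtype=float)
    t_act = np.asarray(t_act, dtype=float)
    t_deact = np.asarray(t_deact, dtype=float)
    k1 = _a_dot(a, u, t_act, t_deact)
    k2 = _a_dot(np.clip(a + 0.5 * dt * k1, 0.0, 1.0), u, t_act, t_deact)
    k3 = _a_dot(np.clip(a + 0.5 * dt * k2, 0.0, 1.0), u, t_act, t_deact)
    k4 = _a_dot(np.clip(a + dt * k3, 0.0, 1.0), u, t_act, t_deact)
    out = np.clip(a + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0, 0.0, 1.0)
    return out if out.ndim else float(out)


def control_update(t: float, sensor_buffer: DelayBuffer,
                   transmission_buffer: DelayBuffer,
                   params: ControllerParams,
                   muscles: list[MuscleParams]) -> ControlSignal:
    """One controller tick.

    Reads length/velocity at t - tau_fb from the sensor buffer, computes the
    PD feedback, composes the clipped total control, and writes it to the
    transmission buffer (to be consumed by the activation dynamics at lag
    tau_trans).
    """
    n = len(muscles)
    delayed = sensor_buffer.read(t, params.tau_fb)
    L_delayed, Ldot_delayed = delayed[:n], delayed[n:]
    V_max = np.array([m.V_max for m in muscles])
    u_fb = feedback_control(L_delayed, Ldot_delayed, params, V_max)
    u, raw = total_control(params.u_ff, u_fb, params.u_clip)
    transmission_buffer.append(u)
    return ControlSignal(
        u=u, u_fb=u_fb, u_ff=params.u_ff, u_unclipped=raw,
        uff_norm_sq=params.uff_norm_sq,
    )
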