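"""Evaluation pipelines: directional muscle responses and ankle stiffness.

Pipeline 1 — directional tuning.  For each muscle and platform direction,
the reactive response magnitude is the baseline-subtracted time integral of
activation 70-270 ms after perturbation onset (baseline: mean activation
50-150 ms before onset).  The twelve per-direction magnitudes form a tuning
vector which is normalized to [0, 1] (max over directions = 1) for radar
display, and min-max mapped to [-1, +1] for cosine-similarity comparison
against a reference tuning vector.  The null distribution of similarities
is estimated by Monte Carlo with random 12-vectors whose components are
uniform on [-1, 1]; assuming normality, the cumulative probability of an
observed similarity is Phi((s - mean)/std).

Pipeline 2 — passive ankle stiffness.  Over the first 70 ms after onset
(before reactive activation changes can act), the ankle torque produced by
passive muscle elasticity plus the active force attributable to the
constant feed-forward activation is regressed on ankle angle, velocity and
acceleration:

    T_passive = K * theta + B * theta_dot + I * theta_dd + C      (per degree)

by linear least squares.  The relative stiffness 2K/(m g h) — with K
converted to per-radian — compares K against the critical stiffness m g h
of the equivalent inverted pendulum; values below one mean passive
mechanisms alone cannot stabilize stance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm as _norm

from .muscles import (DEFAULT_CURVES, HillCurves, MuscleParams,
                      active_force_length, force_velocity,
                      passive_force_length)
from .plant import Trajectory

__all__ = [
    "ResponseProfile",
    "StiffnessFit",
    "SimilarityNull",
    "baseline_activation",
    "integrated_response",
    "normalize_unit_max",
    "normalize_signed",
    "cosine_similarity",
    "random_similarity_null",
    "passive_torque",
    "fit_stiffness",
    "relative_stiffness",
    "profile_from_trajectories",
]

RAD_PER_DEG = np.pi / 180.0


# ---------------------------------------------------------------------------
# directional muscle responses
# ---------------------------------------------------------------------------

def _trace_arrays(times_ms, trace):
    t = np.asarray(times_ms, dtype=float)
    a = np.asarray(trace, dtype=float)
    if t.shape != a.shape:
        raise ValueError("trace and time grid must have the same length")
    return t, a


def baseline_activation(times_ms, trace, onset: float) -> float:
    """Mean activation over [onset-150, onset-50] ms."""
    t, a = _trace_arrays(times_ms, trace)
    lo, hi = onset - 150.0, onset - 50.0
    if t[0] > lo + 1e-9:
        raise ValueError("trace does not cover the pre-onset baseline window")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    return float(np.trapezoid(a[mask], t[mask]) / (t[mask][-1] - t[mask][0]))


def integrated_response(times_ms, trace, onset: float,
                        a_baseline: float) -> float:
    """Integral of (a - baseline) over [onset+70, onset+270] ms, in seconds."""
    t, a = _trace_arrays(times_ms, trace)
    lo, hi = onset + 70.0, onset + 270.0
    if t[-1] < hi - 1e-9 or t[0] > lo + 1e-9:
        raise ValueError("trace does not cover the observation window")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    return float(np.trapezoid(a[mask] - a_baseline, t[mask]) * 1e-3)  # ms -> s


def normalize_unit_max(values) -> np.ndarray:
    """v / max(v); negative scaled entries are clipped to 0."""
    v = np.asarray(values, dtype=float)
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("degenerate profile: no positive response")
    return np.clip(v / vmax, 0.0, None)


def normalize_signed(values) -> np.ndarray:
    """Affine min-max map of the vector onto [-1, +1]."""
    v = np.asarray(values, dtype=float)
    vmin, vmax = v.min(), v.max()
    if vmax - vmin <= 0:
        raise ValueError("degenerate profile: constant vector")
    return 2.0 * (v - vmin) / (vmax - vmin) - 1.0


def cosine_similarity(v1, v2) -> float:
    """Normalized dot product, in [-1, 1]."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass(frozen=True)
class SimilarityNull:
    """Monte-Carlo null distribution of cosine similarity vs a reference."""

    mean: float
    std: float
    n: int

    def cumulative_prob(self, observed: float) -> float:
        """Normal-approximation CDF of the null at the observed similarity."""
        return float(_norm.cdf((observed - self.mean) / self.std))


def random_similarity_null(v_ref, n: int = 100_000,
                           seed: int | None = None) -> SimilarityNull:
    """Similarities between n random vectors (components U[-1,1]) and v_ref."""
    if n < 1000:
        raise ValueError("need at least 1000 null samples")
    ref = np.asarray(v_ref, dtype=float)
    rng = np.random.default_rng(seed)
    # draw in manageable blocks to bound memory at large n
    sims = np.empty(n)
    done = 0
    while done < n:
        block = min(n - done, 20_000)
        V = rng.uniform(-1.0, 1.0, size=(block, ref.size))
        sims[done:done + block] = (V @ ref) / (
            np.linalg.norm(V, axis=1) * np.linalg.norm(ref))
        done += block
    return SimilarityNull(mean=float(sims.mean()), std=float(sims.std(ddof=0)),
                          n=n)


@dataclass
class ResponseProfile:
    """12-direction integrated response magnitudes of one muscle."""

    muscle: str
    directions_deg: np.ndarray
    integrated: np.ndarray  # s
    reference: np.ndarray | None = None

    @property
    def normalized_01(self) -> np.ndarray:
        return normalize_unit_max(self.integrated)

    @property
    def normalized_signed(self) -> np.ndarray:
        return normalize_signed(self.integrated)

    def similarity_to_reference(self) -> float:
        if self.reference is None:
            raise ValueError("no reference tuning vector supplied")
        return cosine_similarity(self.normalized_signed, self.reference)


def profile_from_trajectories(trajs_by_direction: dict, muscle: str,
                              onset: float,
                              reference=None) -> ResponseProfile:
    """Build a ResponseProfile from per-direction Trajectory records.

    ``trajs_by_direction`` maps direction (deg) to a Trajectory (or list of
    Trajectories, e.g. one per plane) containing the muscle.
    """
    directions = sorted(trajs_by_direction)
    values = []
    for d in directions:
        trajs = trajs_by_direction[d]
        if isinstance(trajs, Trajectory):
            trajs = [trajs]
        traj = next((tr for tr in trajs if muscle in tr.muscle_names), None)
        if traj is None:
            raise ValueError(f"muscle {muscle!r} not found for direction {d}")
        i = traj.muscle_names.index(muscle)
        t_ms = traj.t * 1e3
        trace = traj.activations[:, i]
        base = baseline_activation(t_ms, trace, onset)
        values.append(integrated_response(t_ms, trace, onset, base))
    return ResponseProfile(
        muscle=muscle, directions_deg=np.array(directions, dtype=float),
        integrated=np.array(values),
        reference=None if reference is None else np.asarray(reference, float),
    )


# ---------------------------------------------------------------------------
# passive ankle stiffness
# ---------------------------------------------------------------------------

def passive_torque(traj: Trajectory, muscles: list[MuscleParams],
                   u_ff, ankle_joint: int = 0,
                   window_ms: tuple[float, float] | None = None,
                   curves: HillCurves = DEFAULT_CURVES) -> tuple[np.ndarray, np.ndarray]:
    """Ankle torque series from passive elasticity plus feed-forward tone.

    Per step, each muscle contributes F0*(a_ff*f_L*f_V + f_PE)*ma_ankle with
    the *feed-forward* activation a_ff (not the instantaneous one), summed
    over muscles.  Returns (times_ms, torque) restricted to window_ms.
    """
    a_ff = np.asarray(u_ff, dtype=float)
    t_ms = traj.t * 1e3
    if window_ms is not None:
        lo, hi = window_ms
        if t_ms[-1] < hi - 1e-9:
            raise ValueError("trajectory does not cover the requested window")
        mask = (t_ms >= lo - 1e-9) & (t_ms <= hi + 1e-9)
    else:
        mask = np.ones(t_ms.size, dtype=bool)
    L_opt = np.array([m.L_opt for m in muscles])
    L_slack = np.array([m.L_slack for m in muscles])
    V_max = np.array([m.V_max for m in muscles])
    F0 = np.array([m.F0 for m in muscles])
    ma = np.array([m.moment_arms[ankle_joint] for m in muscles])
    l_n = (traj.L_MT[mask] - L_slack) / L_opt
    v_n = traj.Ldot_MT[mask] / V_max
    fl = active_force_length(l_n, curves)
    fv = force_velocity(v_n, curves)
    fpe = passive_force_length(l_n, curves)
    T = (F0 * (a_ff * fl * fv + fpe) * ma).sum(axis=1)
    return t_ms[mask], T


@dataclass(frozen=True)
class StiffnessFit:
    K: float  # N m / deg
    B: float  # N m s / deg
    I: float  # N m s^2 / deg
    C: float  # N m
    relative_stiffness: float
    m: float  # kg
    g: float  # m/s^2
    h: float  # m
    residual_rms: float


def fit_stiffness(T_passive, theta_ankle_deg, dt: float, m: float, g: float,
                  h: float) -> StiffnessFit:
    """Least-squares fit T = K*theta + B*theta_dot + I*theta_dd + C.

    ``theta_ankle_deg`` in degrees, ``dt`` in seconds; derivatives by
    second-order central differences with the endpoints dropped from the
    fit.  K is reported per degree and converted to per-radian inside the
    relative-stiffness formula.
    """
    T = np.asarray(T_passive, dtype=float)
    th = np.asarray(theta_ankle_deg, dtype=float)
    if T.shape != th.shape:
        raise ValueError("torque and angle series must have the same length")
    if T.size < 10:
        raise ValueError("need at least 10 samples for the fit")
    thd = np.gradient(th, dt, edge_order=2)
    thdd = np.gradient(thd, dt, edge_order=2)
    sl = slice(2, -2)
    X = np.column_stack([th[sl], thd[sl], thdd[sl], np.ones(th[sl].size)])
    if np.linalg.matrix_rank(X) < 4:
        raise np.linalg.LinAlgError(
            "singular stiffness fit: degenerate angle series")
    beta, *_ = np.linalg.lstsq(X, T[sl], rcond=None)
    resid = T[sl] - X @ beta
    K, B, I, C = (float(b) for b in beta)
    return StiffnessFit(
        K=K, B=B, I=I, C=C,
        relative_stiffness=relative_stiffness(K, m, g, h),
        m=m, g=g, h=h,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def relative_stiffness(K_per_deg: float, m: float, g: float, h: float) -> float:
    """2 K / (m g h) with K converted from per-degree to per-radian."""
    if m <= 0 or h <= 0:
        raise ValueError("mass and CoM height must be positive")
    K_rad = K_per_deg / RAD_PER_DEG
    return 2.0 * K_rad / (m * g * h)


def read_reference_csv(path):
    """Read reference 12-direction tuning vectors from CSV.

    Expected layout: a ``direction_deg`` column plus one column per muscle
    (12 rows, one per direction).  Returns (directions, {muscle: vector}).
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "direction_deg" not in df.columns:
        raise ValueError("reference CSV needs a 'direction_deg' column")
    df = df.sort_values("direction_deg")
    if len(df) != 12:
        raise ValueError(f"expected 12 direction rows, got {len(df)}")
    directions = df["direction_deg"].to_numpy(dtype=float)
    vectors = {c: df[c].to_numpy(dtype=float)
               for c in df.columns if c != "direction_deg"}
    return directions, vectors


def plot_radar(profile: ResponseProfile, ax=None, color="tab:red"):
    """Render a 12-spoke radar chart of the normalized response profile.

    Requires matplotlib.  Returns the polar axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    angles = np.deg2rad(np.append(profile.directions_deg,
                                  profile.directions_deg[0]))
    values = profile.normalized_01
    values = np.append(values, values[0])
    ax.plot(angles, values, color=color)
    ax.fill(angles, values, color=color, alpha=0.3)
    ax.set_ylim(0, 1)
    ax.set_title(profile.muscle)
    return ax
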