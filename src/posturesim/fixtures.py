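"""Deterministic fixture plants and synthetic-data generators.

Three desk-scale plants stand in for a full 15-DoF, 70-muscle body:

* ``single_link`` — the classic ankle inverted pendulum (72 kg, CoM 0.914 m
  above the ankle) with an antagonist plantarflexor/dorsiflexor pair.
* ``sagittal_3link`` — ankle-knee-hip pitch chain with an antagonist pair
  per joint plus one biarticular (gastrocnemius-like) muscle: 7 muscles,
  7 gain groups.
* ``frontal_2link`` — subtalar inversion/eversion and lateral hip/lumbar
  bend, left-right symmetric, with two antagonist pairs.

Each actuator is a lumped group-equivalent muscle aggregating the muscles
of both legs acting in that direction, sized so that recovering from the
standard 3 cm translation genuinely engages the activation ceiling (the
standing problem stays nontrivial); moment arms and optimal fiber lengths
stay anatomical.  Fiber slack lengths are chosen so every muscle sits on
the ascending limb of the force-length curve (l = 0.94) in the initial
pose: stretch then raises active force, so feed-forward tone contributes
genuine intrinsic (zero-delay) stiffness and, through the force-velocity
slope, intrinsic damping.

The fixture gain-ratio table keeps the standard 11-group (P, D) ratio
pattern but multiplies it by a fixture scale that maps the dimensionless
gains onto the lumped-actuator normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .controller import ControllerParams
from .muscles import MuscleParams, musculotendon_kinematics
from .tuning import PAPER_GAIN_RATIOS, CmaConfig, GainRatioTable, base_gains

__all__ = [
    "FixtureSpec",
    "FIXTURE_NAMES",
    "make_fixture",
    "fixture_gain_table",
    "fixture_cma_config",
    "fixture_stage2_setup",
    "gain_upper_vector",
    "synth_torque_angle",
    "SynthTraces",
    "synth_activation_traces",
]

FIXTURE_NAMES = ("single_link", "sagittal_3link", "frontal_2link")

#: fixture-table multiplier mapping dimensionless gains onto the lumped
#: actuators (gains of order ten then stabilize the chain)
_FIXTURE_GAIN_SCALE = 36.0

#: normalized fiber length of every muscle in the initial pose
_L_NORM_POSE = 0.94


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    scale: float = 1.0  # anthropometry scale (lengths and masses)
    strength: float = 1.0  # muscle F0 multiplier
    seed: int | None = None  # for noise in the synthetic generators

    def __post_init__(self) -> None:
        if self.name not in FIXTURE_NAMES:
            raise ValueError(
                f"unknown fixture {self.name!r}; available: {FIXTURE_NAMES}")
        if self.scale <= 0 or self.strength <= 0:
            raise ValueError("scale and strength must be positive")


def fixture_gain_table(scale: float = _FIXTURE_GAIN_SCALE) -> GainRatioTable:
    """Standard 11-group ratio table rescaled for the lumped actuators."""
    return GainRatioTable(
        {g: (rp * scale, rd * scale) for g, (rp, rd) in PAPER_GAIN_RATIOS.items()})


#: reflex-gain ceiling: proportional gains may not exceed the table value
#: at sweep scalar 3.5, and the delayed velocity gain is capped at a flat
#: 1.0 per group.  The velocity cap reflects the physiological limit on
#: delayed velocity feedback (it amplifies noise and, at an 80 ms loop
#: delay, injects energy into the fast joint modes); damping beyond it
#: must come from the muscles' own force-velocity slope, which scales with
#: feed-forward tone.
_KP_CEILING_SCALAR = 3.5
_KD_CEILING = 1.0


def gain_upper_vector(skeleton: ControllerParams,
                      table: GainRatioTable | None = None) -> np.ndarray:
    """Per-group gain upper bounds in optimization order (sorted, kp then kd)."""
    table = table or fixture_gain_table()
    groups = sorted(set(skeleton.group_map.values()))
    return np.array(
        [table.ratios[g][0] * _KP_CEILING_SCALAR for g in groups]
        + [_KD_CEILING for _ in groups])


def fixture_cma_config(skeleton: ControllerParams, seed: int | None = None,
                       popsize: int = 8, max_iter: int = 50,
                       stop_on_stand: bool = True) -> CmaConfig:
    """Desk-scale CMA-ES settings for fixture gain optimization.

    sigma0 is scaled to the order-one fixture gains (the full-scale default
    of 0.005 matches a search initialized very close to a solution); gains
    are bounded above by the reflex-gain ceiling.
    """
    return CmaConfig(popsize=popsize, sigma0=0.4, max_iter=max_iter,
                     seed=seed, gain_upper=gain_upper_vector(skeleton),
                     stop_on_stand=stop_on_stand)


def fixture_stage2_setup(config, muscles, skeleton, candidate,
                         table: GainRatioTable | None = None):
    """Posture-matched stage-2 (plant, controller) for one u_ff candidate.

    PD gains are initialized from the candidate's generating (P, D) sweep
    scalars, clipped just inside the reflex-gain ceiling.
    """
    from .tuning import posture_matched_setup

    table = table or fixture_gain_table()
    P, D = candidate.provenance
    groups = set(skeleton.group_map.values())
    k_p = {g: min(table.ratios[g][0] * P,
                  table.ratios[g][0] * _KP_CEILING_SCALAR * 0.97)
           for g in groups}
    k_d = {g: min(table.ratios[g][1] * D, _KD_CEILING * 0.95)
           for g in groups}
    return posture_matched_setup(config, muscles, skeleton, candidate,
                                 k_p=k_p, k_d=k_d)


def _mk_muscle(name, group, F0, L_opt, V_max, L_ref, moment_arms, pose):
    """Build a muscle whose slack length puts it at l = 0.94 in the pose."""
    ma = tuple(moment_arms)
    L_pose = L_ref - float(np.dot(ma, pose))
    L_slack = L_pose - _L_NORM_POSE * L_opt
    return MuscleParams(name=name, F0=F0, L_opt=L_opt, V_max=V_max,
                        L_ref=L_ref, L_slack=L_slack, moment_arms=ma,
                        group=group)


def make_fixture(spec: FixtureSpec):
    """Deterministic (PlantConfig, muscles, controller skeleton) triple.

    The controller skeleton has zero feed-forward, target lengths taken
    from the initial pose, the standard 40 ms delays, and PD gains from the
    fixture table at P = D = 2.
    """
    from .plant import LinkParams, PlantConfig  # local to avoid cycle

    s, f = spec.scale, spec.strength
    if spec.name == "single_link":
        links = (LinkParams(mass=72.0 * s, length=1.70 * s,
                            com_offset=0.914 * s, inertia=14.0 * s**3),)
        joints = ("ankle",)
        limits = ((-1.0, 1.0),)
        pose = (0.04,)
        muscle_defs = [
            ("ankle_ext", "ankle_extensor", 4000.0, 0.060, 0.60, 0.400,
             (-0.080,)),
            ("ankle_flex", "ankle_flexor", 2500.0, 0.060, 0.60, 0.350,
             (+0.055,)),
        ]
        plane = "sagittal"
    elif spec.name == "sagittal_3link":
        links = (
            LinkParams(mass=7.0 * s, length=0.44 * s, com_offset=0.20 * s,
                       inertia=0.10 * s**3),
            LinkParams(mass=15.0 * s, length=0.44 * s, com_offset=0.19 * s,
                       inertia=0.25 * s**3),
            LinkParams(mass=50.0 * s, length=0.80 * s, com_offset=0.22 * s,
                       inertia=3.00 * s**3),
        )
        joints = ("ankle", "knee", "hip")
        limits = ((-1.0, 1.0), (-1.0, 1.0), (-1.2, 1.2))
        pose = (0.05, -0.03, 0.04)
        muscle_defs = [
            ("ankle_ext", "ankle_extensor", 4000.0, 0.060, 0.60, 0.400,
             (-0.080, 0.0, 0.0)),
            ("ankle_flex", "ankle_flexor", 2500.0, 0.060, 0.60, 0.350,
             (+0.055, 0.0, 0.0)),
            ("knee_ext", "knee_extensor", 5000.0, 0.070, 0.70, 0.350,
             (0.0, +0.055, 0.0)),
            ("knee_flex", "knee_flexor", 5000.0, 0.070, 0.70, 0.350,
             (0.0, -0.055, 0.0)),
            ("hip_ext", "hip_extensor", 6000.0, 0.100, 1.00, 0.400,
             (0.0, 0.0, -0.090)),
            ("hip_flex", "hip_flexor", 4000.0, 0.100, 1.00, 0.400,
             (0.0, 0.0, +0.070)),
            ("gastroc", "biarticular", 3000.0, 0.060, 0.60, 0.450,
             (-0.050, -0.030, 0.0)),
        ]
        plane = "sagittal"
    else:  # frontal_2link
        links = (
            LinkParams(mass=21.0 * s, length=0.85 * s, com_offset=0.45 * s,
                       inertia=1.00 * s**3),
            LinkParams(mass=51.0 * s, length=0.85 * s, com_offset=0.30 * s,
                       inertia=3.00 * s**3),
        )
        joints = ("subtalar", "lateral_bend")
        limits = ((-0.8, 0.8), (-1.0, 1.0))
        pose = (0.0, 0.0)
        muscle_defs = [
            ("evertor", "subtalar_evertor", 8000.0, 0.050, 0.50, 0.300,
             (+0.040, 0.0)),
            ("invertor", "subtalar_invertor", 8000.0, 0.050, 0.50, 0.300,
             (-0.040, 0.0)),
            ("bend_right", "lumbar_extensor", 6000.0, 0.090, 0.90, 0.400,
             (0.0, +0.090)),
            ("bend_left", "lumbar_flexor", 6000.0, 0.090, 0.90, 0.400,
             (0.0, -0.090)),
        ]
        plane = "frontal"

    config = PlantConfig(
        links=links, joint_names=joints, joint_limits=limits,
        initial_pose=pose, plane=plane,
    )
    pose_arr = np.asarray(pose, dtype=float)
    muscles = [
        _mk_muscle(name, group, F0 * f, L_opt, V_max, L_ref * s,
                   tuple(m * s for m in ma), pose_arr)
        for name, group, F0, L_opt, V_max, L_ref, ma in muscle_defs
    ]
    L0 = np.array([
        musculotendon_kinematics(m, pose_arr, np.zeros_like(pose_arr))[0]
        for m in muscles
    ])
    table = fixture_gain_table()
    k_p, k_d = base_gains(table, 2.0, 2.0)
    groups = {m.name: m.group for m in muscles}
    k_p = {g: k_p[g] for g in set(groups.values())}
    k_d = {g: k_d[g] for g in set(groups.values())}
    skeleton = ControllerParams(
        muscle_names=tuple(m.name for m in muscles),
        u_ff=np.zeros(len(muscles)), k_p=k_p, k_d=k_d, group_map=groups,
        L0_MT=L0,
    )
    return config, muscles, skeleton


# ---------------------------------------------------------------------------
# synthetic-data generators (analytic ground truth for the evaluation tests)
# ---------------------------------------------------------------------------

def synth_torque_angle(K: float, B: float, I: float, C: float,
                       duration: float, dt: float, noise_sd: float = 0.0,
                       seed: int | None = None):
    """Seeded smooth angle trajectory and the torque it implies.

    theta (degrees) is a random sum of low-frequency sinusoids; the torque
    series is T = K theta + B theta_dot + I theta_dd + C plus Gaussian
    noise of standard deviation noise_sd, with the derivatives taken by the
    same second-order central differences the stiffness fit uses (so the
    noiseless series is an exact self-consistency oracle for the fit).
    Returns (T, theta_deg, t_s).
    """
    n = int(round(duration / dt)) + 1
    if n < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    freqs = rng.uniform(0.5, 4.0, size=4)  # Hz
    amps = rng.uniform(0.3, 1.5, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    w = 2 * np.pi * freqs
    theta = sum(a * np.sin(wi * t + p) for a, wi, p in zip(amps, w, phases))
    theta_dot = np.gradient(theta, dt, edge_order=2)
    theta_dd = np.gradient(theta_dot, dt, edge_order=2)
    T = K * theta + B * theta_dot + I * theta_dd + C
    if noise_sd > 0:
        T = T + rng.normal(0.0, noise_sd, size=n)
    return T, theta, t


@dataclass
class SynthTraces:
    """Per-direction synthetic activation traces with known response areas."""

    times_ms: np.ndarray
    traces: dict[float, np.ndarray]
    areas: dict[float, float]  # true integrated responses, s
    baseline: float
    onset: float


def synth_activation_traces(directions_deg, peak_direction_deg: float = 90.0,
                            max_area: float = 0.01, baseline: float = 0.1,
                            onset: float = 500.0, T_ms: float = 1000.0,
                            dt_ms: float = 1.0, noise_sd: float = 0.0,
                            seed: int | None = None) -> SynthTraces:
    """Cosine-tuned half-sine response bumps over a constant baseline.

    The bump of direction d occupies the 70-270 ms observation window after
    onset and its area is max_area * max(cos(d - peak_direction), 0), so
    the integrated-response and similarity pipelines have analytic ground
    truth.
    """
    t = np.arange(0.0, T_ms + dt_ms / 2, dt_ms)
    rng = np.random.default_rng(seed)
    lo, hi = onset + 70.0, onset + 270.0
    width_s = (hi - lo) * 1e-3
    traces, areas = {}, {}
    for d in directions_deg:
        area = max_area * max(
            np.cos(np.deg2rad(d - peak_direction_deg)), 0.0)
        peak = area * np.pi / (2.0 * width_s)
        bump = np.where((t >= lo) & (t <= hi),
                        peak * np.sin(np.pi * (t - lo) / (hi - lo)), 0.0)
        trace = baseline + bump
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, size=t.size)
        traces[float(d)] = trace
        areas[float(d)] = area
    return SynthTraces(times_ms=t, traces=traces, areas=areas,
                       baseline=baseline, onset=onset)
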