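"""Two-stage parameter adjustment.

Stage 1 (feed-forward generation): run the closed loop with zero neural
delays, zero feed-forward and PD gains taken from a fixed per-group ratio
table scaled by two sweep factors (P, D).  Whenever the model stands the
full horizon, the time-averaged activations over a late window become a
feed-forward candidate u_ff; candidates are indexed by their squared norm
||u_ff||^2, which measures whole-body muscle tone / stiffness.

Stage 2 (gain optimization): for a selected u_ff and a perturbation
direction, optimize the per-group PD gains with CMA-ES against

    J = w_fail * (T_simu - T_fall)/T_fall + w_pos * sum_j int |theta_j(t) - theta_j(0)| dt,

which first rewards standing the full horizon (J_fail = 0) and then small
postural deviation.  The deviation integral uses absolute values so that
oscillation around the target cannot cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cma import CmaEs
from .controller import ControllerParams
from .muscles import MuscleParams
from .perturbation import PerturbationSpec
from .plant import DivergenceError, PlantConfig, Trajectory, detect_fall, simulate

__all__ = [
    "PAPER_GAIN_RATIOS",
    "GainRatioTable",
    "UffCandidate",
    "ObjectiveConfig",
    "CmaConfig",
    "OptimizationResult",
    "base_gains",
    "uff_from_trace",
    "sweep_uff_candidates",
    "select_by_norm",
    "objective_J",
    "optimize_gains",
    "posture_matched_setup",
]

#: per-group (P-multiplier, D-multiplier) base gain ratios for the standard
#: 11 muscle groups of a full-body standing model
PAPER_GAIN_RATIOS: dict[str, tuple[float, float]] = {
    "lumbar_extensor": (0.50, 0.23),
    "lumbar_flexor": (0.48, 0.11),
    "hip_extensor": (0.45, 0.05),
    "hip_flexor": (0.50, 0.16),
    "knee_extensor": (0.33, 0.05),
    "knee_flexor": (0.28, 0.23),
    "ankle_extensor": (0.17, 0.06),
    "ankle_flexor": (0.30, 0.27),
    "subtalar_evertor": (0.50, 0.11),
    "subtalar_invertor": (0.49, 0.05),
    "biarticular": (0.39, 0.05),
}


@dataclass(frozen=True)
class GainRatioTable:
    """Per-group base (P, D) ratios; gains are ratio * sweep scalar."""

    ratios: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for g, (rp, rd) in self.ratios.items():
            if rp <= 0 or rd <= 0:
                raise ValueError(f"group {g!r}: ratios must be positive")

    def covers(self, groups) -> bool:
        return all(g in self.ratios for g in groups)


@dataclass(frozen=True)
class UffCandidate:
    u_ff: np.ndarray
    norm_sq: float
    provenance: tuple[float, float]  # (P, D) of the generating run
    stood: bool
    settle_pose: tuple[float, ...] | None = None  # mean pose over the window

    @staticmethod
    def from_vector(u_ff, provenance, stood=True,
                    settle_pose=None) -> "UffCandidate":
        u = np.asarray(u_ff, dtype=float)
        return UffCandidate(u_ff=u, norm_sq=float(np.sum(u**2)),
                            provenance=tuple(provenance), stood=bool(stood),
                            settle_pose=None if settle_pose is None
                            else tuple(float(x) for x in settle_pose))


@dataclass(frozen=True)
class ObjectiveConfig:
    w_fail: float = 10000.0
    w_pos: float = 1.0
    T_simu: float = 5000.0  # ms
    fall_threshold: float | None = None  # m; None -> plant default
    fail_sentinel: float = 1e9  # stands in for 1/T_fall at T_fall = 0

    def __post_init__(self) -> None:
        if self.w_fail < 0 or self.w_pos < 0:
            raise ValueError("weights must be nonnegative")
        if self.T_simu <= 0:
            raise ValueError("T_simu must be positive")


@dataclass(frozen=True)
class CmaConfig:
    popsize: int = 18
    sigma0: float = 0.005
    max_iter: int = 1500
    seed: int | None = None
    gain_lower: float = 0.0
    gain_upper: np.ndarray | float | None = None
    stop_on_stand: bool = False  # stop once a standing solution is found

    def __post_init__(self) -> None:
        if self.popsize < 4:
            raise ValueError("popsize must be at least 4")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")


@dataclass
class OptimizationResult:
    controller: ControllerParams
    k_p: dict[str, float]
    k_d: dict[str, float]
    J: float
    J_fail: float
    J_pos: float
    converged: bool  # a standing solution was found
    history: list[dict]


def base_gains(table: GainRatioTable, P: float, D: float) -> tuple[dict, dict]:
    """Per-group (k_p, k_d) = (ratio_p * P, ratio_d * D)."""
    if P <= 0 or D <= 0:
        raise ValueError("P and D must be positive")
    k_p = {g: rp * P for g, (rp, rd) in table.ratios.items()}
    k_d = {g: rd * D for g, (rp, rd) in table.ratios.items()}
    return k_p, k_d


def uff_from_trace(times_ms, activations, window=(3000.0, 5000.0),
                   provenance=(np.nan, np.nan), stood: bool = True,
                   settle_pose=None) -> UffCandidate:
    """Time-averaged activations over [t_lo, t_hi] ms (trapezoidal).

    c_i = int_{t_lo}^{t_hi} a_i(t) dt / (t_hi - t_lo)
    """
    t = np.asarray(times_ms, dtype=float)
    a = np.atleast_2d(np.asarray(activations, dtype=float))
    if a.shape[0] != t.shape[0]:
        a = a.T
    t_lo, t_hi = window
    if t[0] > t_lo + 1e-9 or t[-1] < t_hi - 1e-9:
        raise ValueError(
            f"trace [{t[0]:.0f}, {t[-1]:.0f}] ms does not cover the "
            f"averaging window [{t_lo:.0f}, {t_hi:.0f}] ms")
    mask = (t >= t_lo - 1e-9) & (t <= t_hi + 1e-9)
    c = np.trapezoid(a[mask], t[mask], axis=0) / (t[mask][-1] - t[mask][0])
    return UffCandidate.from_vector(c, provenance, stood, settle_pose)


def sweep_uff_candidates(config: PlantConfig, muscles: list[MuscleParams],
                         skeleton: ControllerParams, table: GainRatioTable,
                         P_values, D_values, T_simu: float = 5000.0,
                         dt: float = 1e-3, window=(3000.0, 5000.0),
                         dedup_tol: float = 1e-9) -> list[UffCandidate]:
    """Zero-delay, zero-u_ff runs over a (P, D) grid.

    Only runs that stand the full horizon yield candidates; failed runs are
    skipped silently.  Candidates with identical ||u_ff||^2 (within
    dedup_tol) are deduplicated, keeping the first.
    """
    groups = set(skeleton.group_map.values())
    if not table.covers(groups):
        missing = sorted(groups - set(table.ratios))
        raise ValueError(f"gain table does not cover groups: {missing}")
    threshold = config.fall_threshold()
    candidates: list[UffCandidate] = []
    for P in P_values:
        for D in D_values:
            k_p, k_d = base_gains(table, P, D)
            ctrl = skeleton.replace(
                u_ff=np.zeros(len(muscles)), k_p=k_p, k_d=k_d,
                tau_fb=0.0, tau_trans=0.0)
            try:
                traj = simulate(config, muscles, ctrl, perturbation=None,
                                T_simu=T_simu, dt=dt)
            except DivergenceError:
                continue
            if detect_fall(traj, threshold) < T_simu - 1e-9:
                continue
            mask = traj.t * 1e3 >= window[0] - 1e-9
            cand = uff_from_trace(traj.t * 1e3, traj.activations, window,
                                  provenance=(P, D), stood=True,
                                  settle_pose=traj.theta[mask].mean(axis=0))
            if any(abs(cand.norm_sq - c.norm_sq) <= dedup_tol
                   for c in candidates):
                continue
            candidates.append(cand)
    return candidates


def select_by_norm(candidates: list[UffCandidate], n: int) -> list[UffCandidate]:
    """Pick n candidates closest to equally spaced ||u_ff||^2 targets.

    Targets span [min, max] of the observed norms; ties break toward the
    smaller norm.  Returns all candidates (sorted) if fewer than n exist.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not candidates:
        raise ValueError("no candidates to select from")
    ordered = sorted(candidates, key=lambda c: c.norm_sq)
    if len(ordered) <= n:
        import warnings
        if len(ordered) < n:
            warnings.warn(
                f"only {len(ordered)} candidates available, requested {n}")
        return ordered
    norms = np.array([c.norm_sq for c in ordered])
    targets = np.linspace(norms[0], norms[-1], n)
    picked: list[int] = []
    for tgt in targets:
        dist = np.abs(norms - tgt)
        dist[picked] = np.inf
        # argmin returns the first (smallest-norm) index on ties
        picked.append(int(np.argmin(dist)))
    return [ordered[i] for i in sorted(set(picked))]


def objective_J(traj: Trajectory, config: ObjectiveConfig,
                initial_pose, fall_threshold: float) -> tuple[float, float, float]:
    """(J, J_fail, J_pos) of a completed or truncated run.

    J_fail = (T_simu - T_fall) / T_fall (a large sentinel at T_fall = 0);
    J_pos = sum_j int_0^{T_fall} |theta_j(t) - theta_j(0)| dt in rad s.
    """
    T_fall = detect_fall(traj, fall_threshold)
    if traj.diverged:
        T_fall = min(T_fall, traj.duration_ms)
    if T_fall <= 0:
        J_fail = config.fail_sentinel * config.T_simu
    else:
        J_fail = (config.T_simu - T_fall) / T_fall
    theta0 = np.asarray(initial_pose, dtype=float)
    mask = traj.t * 1e3 <= T_fall + 1e-9
    dev = np.abs(traj.theta[mask] - theta0)
    J_pos = float(np.trapezoid(dev, traj.t[mask], axis=0).sum()) if mask.sum() > 1 else 0.0
    J = config.w_fail * J_fail + config.w_pos * J_pos
    return J, J_fail, J_pos


def posture_matched_setup(config: PlantConfig, muscles: list[MuscleParams],
                          skeleton: ControllerParams,
                          candidate: UffCandidate,
                          k_p: dict | None = None,
                          k_d: dict | None = None):
    """Stage-2 plant and controller consistent with a candidate's tone.

    The initial pose is the posture the feed-forward tone actually
    maintains (the mean pose of the generating run over the averaging
    window), and the feedback target lengths are recomputed there.  By
    construction the tone then holds the starting posture, so its only
    dynamic effect is the intrinsic muscle stiffness and damping it
    recruits — as in quiet stance, where posture and tone are consistent.
    """
    import dataclasses

    from .muscles import musculotendon_kinematics

    if candidate.settle_pose is None:
        raise ValueError("candidate carries no settle pose "
                         "(generate it with sweep_uff_candidates)")
    pose = np.asarray(candidate.settle_pose, dtype=float)
    new_config = dataclasses.replace(config, initial_pose=tuple(pose))
    L0 = np.array([
        musculotendon_kinematics(m, pose, np.zeros_like(pose))[0]
        for m in muscles])
    ctrl = skeleton.replace(
        u_ff=candidate.u_ff.tolist(), L0_MT=L0.tolist(),
        **({"k_p": k_p} if k_p is not None else {}),
        **({"k_d": k_d} if k_d is not None else {}),
    )
    return new_config, ctrl


def _gain_vector(ctrl: ControllerParams, groups: list[str]) -> np.ndarray:
    return np.array([ctrl.k_p[g] for g in groups]
                    + [ctrl.k_d[g] for g in groups])


def _gains_from_vector(x: np.ndarray, groups: list[str]) -> tuple[dict, dict]:
    k = len(groups)
    return ({g: float(x[i]) for i, g in enumerate(groups)},
            {g: float(x[k + i]) for i, g in enumerate(groups)})


def optimize_gains(config: PlantConfig, muscles: list[MuscleParams],
                   controller: ControllerParams,
                   perturbation: PerturbationSpec,
                   cma: CmaConfig, objective: ObjectiveConfig,
                   dt: float = 1e-3) -> OptimizationResult:
    """CMA-ES over the per-group PD gain vector for one perturbation.

    The search starts from the gains stored in ``controller`` (which also
    carries the feed-forward vector under test).  Every candidate is scored
    by a full perturbed closed-loop simulation.  Candidate evaluations
    within an iteration are independent; they are evaluated serially here,
    and the result is identical to any concurrent evaluation order.
    """
    groups = sorted(set(controller.group_map.values()))
    x0 = _gain_vector(controller, groups)
    ndim = x0.size
    lower = np.full(ndim, cma.gain_lower)
    if cma.gain_upper is None:
        upper = np.full(ndim, np.inf)
    else:
        upper = np.broadcast_to(
            np.asarray(cma.gain_upper, dtype=float), (ndim,)).copy()
    threshold = (objective.fall_threshold if objective.fall_threshold
                 is not None else config.fall_threshold())

    def evaluate(x: np.ndarray) -> tuple[float, float, float]:
        k_p, k_d = _gains_from_vector(x, groups)
        ctrl = controller.replace(k_p=k_p, k_d=k_d)
        try:
            traj = simulate(config, muscles, ctrl,
                            perturbation=perturbation,
                            T_simu=objective.T_simu, dt=dt)
        except DivergenceError as exc:
            traj = exc.trajectory
            if len(traj) == 0:
                return objective.w_fail * objective.fail_sentinel, np.inf, np.inf
        return objective_J(traj, objective, config.initial_pose, threshold)

    es = CmaEs(x0, cma.sigma0, popsize=cma.popsize,
               bounds=(lower, upper), seed=cma.seed)
    best_x = x0.copy()
    best = evaluate(x0)
    history: list[dict] = [{
        "iteration": 0, "best_J": best[0], "best_J_fail": best[1],
        "sigma": cma.sigma0,
    }]
    for it in range(1, cma.max_iter + 1):
        X = es.ask()
        scores = [evaluate(x) for x in X]
        f = np.array([s[0] for s in scores])
        es.tell(X, f)
        i_best = int(np.argmin(f))
        if f[i_best] < best[0]:
            best = scores[i_best]
            best_x = X[i_best].copy()
        history.append({
            "iteration": it, "best_J": best[0], "best_J_fail": best[1],
            "sigma": es.sigma,
        })
        if cma.stop_on_stand and best[1] == 0.0:
            break
    k_p, k_d = _gains_from_vector(best_x, groups)
    return OptimizationResult(
        controller=controller.replace(k_p=k_p, k_d=k_d),
        k_p=k_p, k_d=k_d, J=best[0], J_fail=best[1], J_pos=best[2],
        converged=(best[1] == 0.0), history=history,
    )
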