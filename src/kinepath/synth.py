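"""Synthetic reaching experiments with the structure the analysis assumes.

Generates three groups of simulated subjects performing blocked
center-to-target reaches while coupled to a haptic object (double pendulum
or point mass).  Each trial's hand path is a geometric blend between the
straight segment and the effort-optimal curved path for that target pair,

    w(trial) = w∞ · (1 − exp(−λ · trial)),

traversed with a minimum-jerk speed profile plus smooth, endpoint-anchored
motor noise.  Group 1 (veridical feedback) converges toward the curved path
(w∞ < 1: convergence is incomplete, and its motor noise is larger); Groups 2
and 3 (incongruent feedback) keep w∞ = 0 and stay on straight paths.  Forces
are obtained by driving the group's haptic object through the spring-damper
coupling at the haptic rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import Path, Trajectory, as_points
from .dynamics import (
    CouplingParams,
    PendulumParams,
    PointMassParams,
    simulate_coupled,
)
from .paths import TargetLayout, _quintic, default_layout, effort_optimal_trajectory, straight_path

__all__ = [
    "GroupSpec",
    "ExperimentConfig",
    "TrialRecord",
    "ExperimentDataset",
    "default_group_specs",
    "generate_trial",
    "generate_experiment",
]


@dataclass(frozen=True)
class GroupSpec:
    """Behavioral model of one experimental group.

    ``w_inf`` is the asymptotic weight on the energy-optimal curved path
    (0 = persistent straight reaching), ``learning_rate`` the per-trial
    exponential rate toward it, ``sigma`` the motor-noise amplitude (m) of
    the smooth within-path perturbation and ``endpoint_sigma`` the standard
    deviation (m) of start/end landing scatter around the target centers.
    """

    label: int
    haptic_object: str = "pendulum"  # "pendulum" | "point_mass"
    w_inf: float = 0.0
    learning_rate: float = 0.0
    sigma: float = 0.004
    endpoint_sigma: float = 0.002

    def __post_init__(self):
        if not 0.0 <= self.w_inf <= 1.0:
            raise ValueError("w_inf must lie in [0, 1]")
        if self.learning_rate < 0 or self.sigma < 0 or self.endpoint_sigma < 0:
            raise ValueError("rates and noise amplitudes must be nonnegative")
        if self.haptic_object not in ("pendulum", "point_mass"):
            raise ValueError("haptic_object must be 'pendulum' or 'point_mass'")


def default_group_specs() -> tuple[GroupSpec, GroupSpec, GroupSpec]:
    """The three study conditions.

    Group 1: veridical pendulum vision + haptics — converges most of the way
    (w∞ = 0.9) to the curved path, with larger movement variability.
    Group 2: endpoint-cursor vision, pendulum haptics — stays straight.
    Group 3: pendulum vision, point-mass haptics — stays straight (and its
    least-energy path *is* the straight path).
    """
    return (
        GroupSpec(label=1, haptic_object="pendulum", w_inf=0.9, learning_rate=0.004,
                  sigma=0.005, endpoint_sigma=0.002),
        GroupSpec(label=2, haptic_object="pendulum", w_inf=0.0, learning_rate=0.0,
                  sigma=0.004, endpoint_sigma=0.002),
        GroupSpec(label=3, haptic_object="point_mass", w_inf=0.0, learning_rate=0.0,
                  sigma=0.004, endpoint_sigma=0.002),
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Sizes and rates of one experiment run."""

    subjects: int = 8
    blocks: int = 10
    reaches_per_block: int = 48
    T: float = 1.0          # movement duration, s
    rate: float = 100.0     # recording rate, Hz
    hold: float = 0.5       # hold at the target, s
    lead: float = 0.1       # stationary lead-in before movement onset, s
    sim_dt: float = 1e-3    # haptic simulation step, s
    seed: int = 0

    def __post_init__(self):
        if min(self.subjects, self.blocks, self.reaches_per_block) <= 0:
            raise ValueError("subjects, blocks and reaches must be positive")
        if min(self.T, self.rate, self.sim_dt) <= 0 or self.hold < 0 or self.lead < 0:
            raise ValueError("durations and rates must be positive")


@dataclass
class TrialRecord:
    """One reach: identifiers plus the recorded hand trajectory with forces."""

    group: int
    subject: int
    block: int
    trial: int
    start_target: int
    end_target: int
    trajectory: Trajectory

    def __post_init__(self):
        if self.start_target == self.end_target:
            raise ValueError("start and end targets must be distinct")


@dataclass
class ExperimentDataset:
    """A collection of trials plus the configuration that produced them."""

    trials: list
    config: ExperimentConfig
    specs: tuple
    layout: TargetLayout

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def _resample_by_arclength(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at ``n`` points uniform in normalized arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(points[:1], n, axis=0)
    s /= s[-1]
    s_new = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(s_new, s, points[:, k]) for k in range(2)])


def _noise_profile(rng: np.random.Generator, s: np.ndarray, sigma: float, n_modes: int = 4):
    """Smooth 1-D noise field on [0, 1] vanishing at both ends (m)."""
    if sigma == 0.0:
        return np.zeros_like(s)
    k = np.arange(1, n_modes + 1)
    coeffs = rng.normal(0.0, 1.0, n_modes) / k
    # normalize so the field's RMS over s is ~sigma
    scale = sigma / np.sqrt(0.5 * np.sum(1.0 / k**2))
    return scale * np.sin(np.pi * np.outer(s, k)) @ coeffs


def _nominal_path(
    spec: GroupSpec, p_start, p_end, curved: np.ndarray | None, w: float,
    rng: np.random.Generator, n_dense: int = 201,
) -> np.ndarray:
    """Blended, noise-perturbed spatial path as a dense polyline."""
    straight = as_points(straight_path(p_start, p_end, n_dense))
    s = np.linspace(0.0, 1.0, n_dense)
    if w > 0.0 and curved is not None:
        curved_rs = _resample_by_arclength(curved, n_dense)
        # pin the reference path to this trial's (possibly scattered) endpoints
        curved_rs = curved_rs + np.outer(1.0 - s, straight[0] - curved_rs[0]) + np.outer(
            s, straight[-1] - curved_rs[-1]
        )
        pts = (1.0 - w) * straight + w * curved_rs
    else:
        pts = straight.copy()
    if spec.sigma > 0.0:
        # perturb orthogonally to the local tangent, anchored at the endpoints
        tang = np.gradient(pts, axis=0)
        norms = np.linalg.norm(tang, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        tang /= norms
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        pts = pts + _noise_profile(rng, s, spec.sigma)[:, None] * normal
    return pts


def generate_trial(
    spec: GroupSpec,
    layout: TargetLayout,
    pair: tuple[int, int],
    trial_index: int,
    rng: np.random.Generator,
    cfg: ExperimentConfig | None = None,
    curved_path: Path | np.ndarray | None = None,
    pend_params: PendulumParams | None = None,
    pm_params: PointMassParams | None = None,
    coupling: CouplingParams | None = None,
    simulate_forces: bool = True,
    block: int = 0,
    subject: int = 0,
) -> TrialRecord:
    """Synthesize one reach of a subject following ``spec``.

    ``curved_path`` is the effort-optimal spatial path for this ordered
    target pair (computed on the fly if omitted and needed).  When
    ``simulate_forces`` is true the hand trajectory is generated at the
    haptic rate, the coupled object is simulated, and forces are recorded at
    the recording rate; otherwise the trial is purely kinematic.
    """
    cfg = cfg or ExperimentConfig()
    pend_params = pend_params or PendulumParams()
    pm_params = pm_params or PointMassParams()
    coupling = coupling or CouplingParams()
    start, end = pair
    p_start = layout.center(start) + rng.normal(0.0, spec.endpoint_sigma, 2)
    p_end = layout.center(end) + rng.normal(0.0, spec.endpoint_sigma, 2)
    w = spec.w_inf * (1.0 - np.exp(-spec.learning_rate * trial_index))
    if w > 0.0 and curved_path is None:
        obj = pend_params if spec.haptic_object == "pendulum" else pm_params
        curved_path = effort_optimal_trajectory(obj, layout.center(start), layout.center(end),
                                                T=cfg.T).path()
    curved = as_points(curved_path) if curved_path is not None else None
    pts = _nominal_path(spec, p_start, p_end, curved, w, rng)
    # arc-length parametrization of the noisy path
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    arc_n = arc / arc[-1] if arc[-1] > 0 else arc

    gen_rate = 1.0 / cfg.sim_dt if simulate_forces else cfg.rate
    dt = 1.0 / gen_rate
    n_total = int(round((cfg.lead + cfg.T + cfg.hold) * gen_rate))
    t = np.arange(n_total + 1) * dt
    tau = np.clip((t - cfg.lead) / cfg.T, 0.0, 1.0)
    s_time, _, _ = _quintic(tau)
    pos = np.column_stack([np.interp(s_time, arc_n, pts[:, k]) for k in range(2)])
    vel = np.gradient(pos, dt, axis=0)
    hand = Trajectory(t=t, pos=pos, vel=vel)

    if simulate_forces:
        obj = pend_params if spec.haptic_object == "pendulum" else pm_params
        sim = simulate_coupled(obj, coupling, hand, dt=cfg.sim_dt, record_rate=cfg.rate)
        traj = sim.hand_trajectory()
    else:
        stride = max(1, int(round(gen_rate / cfg.rate)))
        traj = Trajectory(t=t[::stride], pos=pos[::stride], vel=vel[::stride])
    return TrialRecord(
        group=spec.label, subject=subject, block=block, trial=trial_index,
        start_target=start, end_target=end, trajectory=traj,
    )


def _block_visit_sequence(
    rng: np.random.Generator, current: int, n_targets: int, per_target: int,
    max_tries: int = 1000,
) -> list[int]:
    """A random visit order with equal target counts and no immediate repeats."""
    for _ in range(max_tries):
        counts = np.full(n_targets, per_target)
        seq: list[int] = []
        cur = current
        ok = True
        for _ in range(n_targets * per_target):
            options = [tgt for tgt in range(n_targets) if tgt != cur and counts[tgt] > 0]
            if not options:
                ok = False
                break
            cur = int(rng.choice(options))
            counts[cur] -= 1
            seq.append(cur)
        if ok:
            return seq
    raise RuntimeError("could not build a balanced no-repeat target sequence")


def generate_experiment(
    cfg: ExperimentConfig | None = None,
    specs: tuple | None = None,
    layout: TargetLayout | None = None,
    pend_params: PendulumParams | None = None,
    pm_params: PointMassParams | None = None,
    coupling: CouplingParams | None = None,
    simulate_forces: bool = True,
    subject_jitter: float = 0.15,
) -> ExperimentDataset:
    """Generate a full multi-group experiment.

    Deterministic given ``cfg.seed``: all randomness (target orders, subject
    parameter jitter, motor noise) flows from one seeded generator tree.
    Per-subject learning rates and noise amplitudes are jittered
    log-normally (``subject_jitter`` is the log-sd) around the group values.
    Reference curved paths are computed once per ordered target pair.
    """
    cfg = cfg or ExperimentConfig()
    specs = specs or default_group_specs()
    layout = layout or default_layout()
    pend_params = pend_params or PendulumParams()
    pm_params = pm_params or PointMassParams()
    coupling = coupling or CouplingParams()
    n_targets = layout.n_targets
    if cfg.reaches_per_block % n_targets != 0:
        raise ValueError("reaches per block must be divisible by the number of targets")
    per_target = cfg.reaches_per_block // n_targets

    # curved (effort-optimal) reference paths, one per ordered pair per object
    curved: dict[tuple[str, tuple[int, int]], np.ndarray] = {}
    for spec in specs:
        if spec.w_inf > 0.0:
            obj = pend_params if spec.haptic_object == "pendulum" else pm_params
            for pair in layout.ordered_pairs():
                key = (spec.haptic_object, pair)
                if key not in curved:
                    traj = effort_optimal_trajectory(
                        obj, layout.center(pair[0]), layout.center(pair[1]), T=cfg.T
                    )
                    curved[key] = traj.pos

    root = np.random.SeedSequence(cfg.seed)
    group_seeds = root.spawn(len(specs))
    trials: list[TrialRecord] = []
    for spec, gseed in zip(specs, group_seeds):
        for subj, sseed in enumerate(gseed.spawn(cfg.subjects), start=1):
            rng = np.random.default_rng(sseed)
            lam = spec.learning_rate * rng.lognormal(0.0, subject_jitter)
            sig = spec.sigma * rng.lognormal(0.0, subject_jitter)
            subj_spec = replace(spec, learning_rate=lam, sigma=sig)
            trial_index = 0
            cur = 0  # every subject starts at target 0
            for block in range(1, cfg.blocks + 1):
                for tgt in _block_visit_sequence(rng, cur, n_targets, per_target):
                    pair = (cur, tgt)
                    trials.append(
                        generate_trial(
                            subj_spec, layout, pair, trial_index, rng, cfg,
                            curved_path=curved.get((spec.haptic_object, pair)),
                            pend_params=pend_params, pm_params=pm_params,
                            coupling=coupling, simulate_forces=simulate_forces,
                            block=block, subject=subj,
                        )
                    )
                    cur = tgt
                    trial_index += 1
    return ExperimentDataset(trials=trials, config=cfg, specs=tuple(specs), layout=layout)
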