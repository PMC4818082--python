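"""Trajectory-similarity and reaching-movement statistics.

Implements the discrete Fréchet distance (the study's trajectory-similarity
measure), movement segmentation by the 10 %-of-peak-speed rule, time
normalization of segmented reaches, and across-trial path averaging with
pointwise confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _kernels
from .containers import Path, Trajectory, as_points

__all__ = [
    "discrete_frechet",
    "segment_movement",
    "time_normalize",
    "average_paths",
    "SegmentedTrial",
    "NoMovementError",
]


class NoMovementError(ValueError):
    """Raised when a trajectory has no detectable movement (zero peak speed)."""


def discrete_frechet(P, Q) -> float:
    """Discrete Fréchet distance between two planar point sequences (m).

    The minimax "leash length" over all order-preserving couplings of the two
    sequences: two walkers traverse P and Q monotonically (arbitrary speeds,
    no backtracking) and the distance is the shortest leash that keeps them
    connected throughout.  Computed by the standard dynamic program;
    symmetric in its arguments.
    """
    P = as_points(P)
    Q = as_points(Q)
    if P.shape[0] == 0 or Q.shape[0] == 0:
        raise ValueError("discrete Fréchet distance is undefined for an empty path")
    return float(_kernels.dfd_table(np.ascontiguousarray(P), np.ascontiguousarray(Q)))


@dataclass
class SegmentedTrial:
    """A reach clipped to its movement interval.

    ``onset``/``offset`` are sample indices into the source trajectory; the
    clipped trajectory spans them inclusively.
    """

    onset: int
    offset: int
    onset_time: float
    offset_time: float
    trajectory: Trajectory

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError("onset must precede offset")


def _smoothed_speed(traj: Trajectory, window: int) -> np.ndarray:
    """Speed from central differences of position, moving-average smoothed."""
    dt = np.gradient(traj.t)
    vx = np.gradient(traj.pos[:, 0]) / dt
    vy = np.gradient(traj.pos[:, 1]) / dt
    speed = np.hypot(vx, vy)
    if window > 1:
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(speed, pad, mode="edge")
        speed = np.convolve(padded, kernel, mode="same")[pad : pad + speed.shape[0]]
    return speed


def segment_movement(
    traj: Trajectory, frac: float = 0.10, smooth_window: int = 5
) -> SegmentedTrial:
    """Clip a trial to its movement using a fraction-of-peak-speed threshold.

    Onset is the first sample whose (smoothed) speed reaches ``frac`` of the
    peak speed, offset the last such sample; the default 10 % threshold is
    the study's movement initiation/termination rule.  ``frac=0`` keeps the
    full span between the first and last samples with nonzero speed.
    """
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    speed = _smoothed_speed(traj, smooth_window)
    peak = float(np.max(speed))
    if peak <= 0.0:
        raise NoMovementError("no movement: peak speed is zero")
    moving = speed >= frac * peak if frac > 0 else speed > 0
    idx = np.nonzero(moving)[0]
    onset, offset = int(idx[0]), int(idx[-1])
    if offset == onset:  # single-sample movement: widen minimally
        offset = min(onset + 1, len(traj) - 1)
        onset = max(offset - 1, 0)
    clipped = Trajectory(
        t=traj.t[onset : offset + 1],
        pos=traj.pos[onset : offset + 1],
        vel=traj.vel[onset : offset + 1],
        force=None if traj.force is None else traj.force[onset : offset + 1],
    )
    return SegmentedTrial(
        onset=onset,
        offset=offset,
        onset_time=float(traj.t[onset]),
        offset_time=float(traj.t[offset]),
        trajectory=clipped,
    )


def time_normalize(traj: Trajectory | SegmentedTrial, n: int = 100) -> Path:
    """Resample positions at ``n`` uniform time fractions of the movement.

    Endpoints are preserved exactly; interpolation is linear in time.
    """
    if isinstance(traj, SegmentedTrial):
        traj = traj.trajectory
    if n < 2:
        raise ValueError("time normalization needs n >= 2 samples")
    t_new = np.linspace(traj.t[0], traj.t[-1], n)
    pos = np.column_stack(
        [np.interp(t_new, traj.t, traj.pos[:, k]) for k in range(2)]
    )
    pos[0], pos[-1] = traj.pos[0], traj.pos[-1]
    return Path(pos)


def average_paths(paths: list, n: int | None = None, confidence: float = 0.95):
    """Pointwise mean of time-normalized paths with confidence half-widths.

    All paths must share the same number of samples (time-normalize first).
    Returns ``(mean_path, half_widths)`` where ``half_widths`` is an (n, 2)
    array of per-coordinate t-interval half-widths
    ``t_{1-α/2, k-1} · sd / √k`` for ``k`` paths (zeros for a single path).
    """
    if not paths:
        raise ValueError("no paths to average")
    arrays = [as_points(p) for p in paths]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"paths have mixed lengths {sorted(lengths)}; time-normalize first")
    if n is not None and lengths != {n}:
        raise ValueError(f"paths have {lengths.pop()} samples, expected {n}")
    stack = np.stack(arrays)
    k = stack.shape[0]
    mean = stack.mean(axis=0)
    if k < 2:
        half = np.zeros_like(mean)
    else:
        sd = stack.std(axis=0, ddof=1)
        tq = stats.t.ppf(0.5 + confidence / 2.0, k - 1)
        half = tq * sd / np.sqrt(k)
    return Path(mean), half
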