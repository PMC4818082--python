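"""Core in-memory containers shared across the package.

A :class:`Path` is a purely geometric object — an ordered sequence of planar
points with no timing.  A :class:`Trajectory` adds uniform timestamps, hand
velocities and (optionally) the force applied to the manipulated object, which
is exactly the information the mechanical-work functional integrates over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Path", "Trajectory", "as_points"]


def as_points(obj) -> np.ndarray:
    """Coerce a Path or array-like into an (N, 2) float array of points."""
    if isinstance(obj, Path):
        return obj.points
    pts = np.asarray(obj, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (N, 2) point array, got shape {pts.shape}")
    return pts


class Path:
    """An ordered, speed-free sequence of planar points (meters).

    Consecutive duplicate points are removed on construction; coordinates must
    be finite and there must be at least one point.
    """

    __slots__ = ("points",)

    def __init__(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"a Path needs (N, 2) coordinates, got shape {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a Path needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("Path coordinates must be finite")
        if pts.shape[0] > 1:
            keep = np.ones(pts.shape[0], dtype=bool)
            keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
            pts = pts[keep]
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.points, dtype=dtype)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Path(n={len(self)}, start={self.points[0]}, end={self.points[-1]})"

    @property
    def start(self) -> np.ndarray:
        return self.points[0]

    @property
    def end(self) -> np.ndarray:
        return self.points[-1]

    def length(self) -> float:
        """Total polygonal arc length."""
        if len(self) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class Trajectory:
    """Time-stamped planar hand motion, optionally with applied-force samples.

    Attributes
    ----------
    t : (N,) strictly increasing timestamps in seconds.
    pos : (N, 2) positions in meters.
    vel : (N, 2) velocities in m/s.
    force : (N, 2) force applied to the object in newtons, or ``None`` for a
        purely kinematic trajectory.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    force: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        n = self.t.shape[0]
        if self.pos.shape != (n, 2) or self.vel.shape != (n, 2):
            raise ValueError("t, pos and vel must have matching lengths")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
            if self.force.shape != (n, 2):
                raise ValueError("force series length must match timestamps")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.vel, axis=1)

    def path(self) -> Path:
        """The geometric shape of the trajectory, timing discarded."""
        return Path(self.pos)
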