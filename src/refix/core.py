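"""Core scanpath data model and saccade-pair geometry.

Coordinates are screen-centered degrees of visual angle, x rightward and
y upward.  A trajectory is the ordered fixation sequence of one
(subject, image, trial).  The central geometric statistic is the pair
delta: for saccade *n* (the saccade ending at fixation ``i``) and a
look-back depth ``nback``, the reference vector is the composite
displacement from fixation ``i - 1 - nback`` to fixation ``i - 1``.
``dphi`` is the unsigned angle in [0, 180] degrees between saccade *n*
and that reference, so 0 means "keep going" (forward saccade) and 180
means "go back"; ``da`` is the signed amplitude difference.  An exact
n-back return (landing on fixation ``i - 1 - nback``) therefore has
``dphi = 180`` and ``da = 0``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: classification thresholds: returns have dphi strictly above 178 degrees
#: and |da| strictly below 2 degrees; forwards mirror this at dphi below 2.
RETURN_ANGLE_THRESHOLD = 178.0
FORWARD_ANGLE_THRESHOLD = 2.0
AMPLITUDE_TOLERANCE = 2.0
#: default radius (degrees) of the circular return region used by the
#: temporal, saliency and foraging analyses.
RETURN_REGION_RADIUS = 2.0


class EmptyTrajectoryError(ValueError):
    """Raised when a trajectory has too few fixations for an operation."""


@dataclass(frozen=True)
class Fixation:
    """A single gaze sample: position in degrees, duration in milliseconds."""

    subject_id: str
    image_id: str
    trial_id: str
    index: int
    x: float
    y: float
    duration: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("fixation coordinates must be finite")
        if not self.duration > 0:
            raise ValueError("fixation duration must be positive (ms)")


@dataclass
class Trajectory:
    """Ordered fixations of one (subject, image, trial).

    Positions and durations are stored as aligned arrays; ``n_saccades``
    is one less than the number of fixations.
    """

    subject: str
    image: str
    trial: str
    x: np.ndarray
    y: np.ndarray
    duration: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.duration = np.asarray(self.duration, dtype=float)
        if not (self.x.shape == self.y.shape == self.duration.shape):
            raise ValueError("x, y, duration must have equal length")
        if self.x.ndim != 1:
            raise ValueError("trajectory arrays must be 1-D")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise ValueError("fixation coordinates must be finite")
        if np.any(self.duration <= 0):
            raise ValueError("fixation durations must be positive (ms)")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_saccades(self) -> int:
        return max(len(self.x) - 1, 0)

    def fixations(self) -> list[Fixation]:
        return [
            Fixation(self.subject, self.image, self.trial, i,
                     float(self.x[i]), float(self.y[i]), float(self.duration[i]))
            for i in range(len(self))
        ]


@dataclass(frozen=True)
class Saccade:
    """A gaze shift between consecutive fixations.

    ``amplitude`` is the Euclidean displacement length (degrees) and
    ``direction`` the polar angle of the displacement vector in [0, 360).
    """

    amplitude: float
    direction: float
    source: int
    target: int


@dataclass(frozen=True)
class PairDelta:
    """Angle/amplitude difference of a saccade against its n-back reference."""

    dphi: float  # unsigned turning angle, degrees in [0, 180]
    da: float    # signed amplitude difference, degrees
    nback: int
    saccade_index: int = -1  # index of saccade n within its trajectory


def _displacements(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    return np.diff(traj.x), np.diff(traj.y)


def compute_saccades(traj: Trajectory, *, drop_zero_amplitude: bool = True
                     ) -> list[Saccade]:
    """Derive the saccade sequence of a trajectory.

    Consecutive identical coordinates yield a zero-amplitude displacement
    whose direction is undefined; such saccades are dropped with a warning
    (set ``drop_zero_amplitude=False`` to receive them with direction 0).
    """
    if len(traj) < 2:
        raise EmptyTrajectoryError(
            f"trajectory {traj.subject}/{traj.image}/{traj.trial} has "
            f"{len(traj)} fixation(s); need at least 2 for a saccade")
    dx, dy = _displacements(traj)
    amp = np.hypot(dx, dy)
    direction = np.degrees(np.arctan2(dy, dx)) % 360.0
    out: list[Saccade] = []
    for i in range(len(amp)):
        if amp[i] == 0.0:
            if drop_zero_amplitude:
                logger.warning(
                    "dropping zero-amplitude saccade %d in %s/%s/%s",
                    i, traj.subject, traj.image, traj.trial)
                continue
        out.append(Saccade(float(amp[i]), float(direction[i]), i, i + 1))
    return out


def _angle_between(vx1, vy1, vx2, vy2):
    """Unsigned angle in degrees [0, 180] between two vectors (vectorized)."""
    dot = vx1 * vx2 + vy1 * vy2
    cross = vx1 * vy2 - vy1 * vx2
    return np.degrees(np.abs(np.arctan2(cross, dot)))


def pair_deltas(traj: Trajectory, nback: int = 1) -> list[PairDelta]:
    """Angle/amplitude differences of each saccade against its n-back reference.

    For the saccade ending at fixation ``i`` the reference vector runs from
    fixation ``i - 1 - nback`` to fixation ``i - 1``; for ``nback=1`` it is
    simply the previous saccade.  Trajectories shorter than ``nback + 2``
    fixations yield an empty list.  Saccades or references with zero length
    are skipped (turning angle undefined).
    """
    if nback < 1:
        raise ValueError("nback must be >= 1")
    n = len(traj)
    if n < nback + 2:
        return []
    x, y = traj.x, traj.y
    # saccade ending at fixation i, for i = nback+1 .. n-1
    i = np.arange(nback + 1, n)
    sx, sy = x[i] - x[i - 1], y[i] - y[i - 1]
    rx, ry = x[i - 1] - x[i - 1 - nback], y[i - 1] - y[i - 1 - nback]
    s_amp = np.hypot(sx, sy)
    r_amp = np.hypot(rx, ry)
    valid = (s_amp > 0) & (r_amp > 0)
    dphi = np.full(len(i), np.nan)
    dphi[valid] = _angle_between(sx[valid], sy[valid], rx[valid], ry[valid])
    da = s_amp - r_amp
    out = []
    for k in range(len(i)):
        if not valid[k]:
            logger.warning("skipping degenerate pair delta at saccade %d in "
                           "%s/%s/%s", i[k] - 1, traj.subject, traj.image,
                           traj.trial)
            continue
        out.append(PairDelta(float(dphi[k]), float(da[k]), nback,
                             saccade_index=int(i[k] - 1)))
    return out


def pair_delta_arrays(trajectories: Iterable[Trajectory], nback: int = 1
                      ) -> pd.DataFrame:
    """Pool pair deltas over trajectories into a tidy frame.

    Columns: subject, image, trial, saccade_index, dphi, da.
    """
    rows = []
    for t in trajectories:
        for d in pair_deltas(t, nback):
            rows.append((t.subject, t.image, t.trial, d.saccade_index,
                         d.dphi, d.da))
    return pd.DataFrame(rows, columns=["subject", "image", "trial",
                                       "saccade_index", "dphi", "da"])


def classify_return(delta: PairDelta,
                    angle_threshold: float = RETURN_ANGLE_THRESHOLD,
                    amp_tolerance: float = AMPLITUDE_TOLERANCE) -> bool:
    """True iff the delta is a return saccade: dphi > 178 and |da| < 2.

    Both inequalities are strict; boundary values do not qualify.
    """
    return (delta.dphi > angle_threshold) and (abs(delta.da) < amp_tolerance)


def classify_forward(delta: PairDelta,
                     angle_threshold: float = FORWARD_ANGLE_THRESHOLD,
                     amp_tolerance: float = AMPLITUDE_TOLERANCE) -> bool:
    """True iff the delta is a forward saccade: dphi < 2 and |da| < 2 (strict)."""
    return (delta.dphi < angle_threshold) and (abs(delta.da) < amp_tolerance)


def in_return_region(fix: Fixation | tuple[float, float],
                     earlier: Fixation | tuple[float, float],
                     radius: float = RETURN_REGION_RADIUS) -> bool:
    """True iff ``fix`` lies strictly within ``radius`` degrees of ``earlier``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    fx, fy = (fix.x, fix.y) if isinstance(fix, Fixation) else fix
    ex, ey = (earlier.x, earlier.y) if isinstance(earlier, Fixation) else earlier
    return float(np.hypot(fx - ex, fy - ey)) < radius


def count_returns(trajectories: Sequence[Trajectory], nback: int = 1,
                  criterion: Callable[[PairDelta], bool] = classify_return,
                  ) -> tuple[pd.Series, float]:
    """Per-subject fraction of saccades that are n-back returns.

    The denominator is the number of saccades eligible for an n-back
    delta (those with a defined reference vector).  Returns the
    per-subject Series (NaN where a subject has no eligible saccade) and
    the pooled fraction over all subjects.
    """
    hits: dict[str, int] = {}
    total: dict[str, int] = {}
    for t in trajectories:
        deltas = pair_deltas(t, nback)
        total[t.subject] = total.get(t.subject, 0) + len(deltas)
        hits[t.subject] = hits.get(t.subject, 0) + sum(
            criterion(d) for d in deltas)
    subjects = sorted(total)
    frac = pd.Series(
        {s: (hits[s] / total[s]) if total[s] > 0 else np.nan for s in subjects},
        name=f"{nback}-back return fraction")
    n_all = sum(total.values())
    pooled = (sum(hits.values()) / n_all) if n_all else float("nan")
    if frac.isna().any():
        warnings.warn("some subjects have no eligible saccades; "
                      "their fraction is reported as missing")
    return frac, pooled
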