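"""Relative cell-cycle time assignment.

Every cell observation gets a relative cell-cycle time ``r ∈ [0, 1]`` from
the division events observed on its own trajectory, anchored by the movie's
mean cell-cycle duration ``T``.  With divisions at trajectory-internal times
``d_1 < … < d_n`` (frames since the track's first observation), observation
time ``t`` and track length ``t_w``:

* between two divisions, ``d_i < t ≤ d_{i+1}``:  ``r = (t − d_i) / (d_{i+1} − d_i)``
* before the first division, ``t ≤ d_1``:        ``r = 1 − t / max(d_1, T)``
* after the last division, ``t > d_n``:          ``r = (t − d_n) / max(t_w − d_n, T)``
* no divisions at all:                            ``r = t / t_w``

``T`` is the total trajectory length divided by the total number of division
events in the movie.  All four branches map into ``[0, 1]``; a division
frame receives ``r = 1`` (end of cycle), so mitosis lands at late cycle
time.  Intervals between divisions are treated half-open, ``(d_i, d_{i+1}]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import Trajectory
from .errors import InsufficientDataError


def estimate_T(trajectories: Sequence[Trajectory]) -> float:
    """Mean cell-cycle duration of a movie, in frames.

    Quotient of summed trajectory lengths (last minus first observed frame)
    over the total number of division events.  With zero division events the
    quotient is undefined and the longest trajectory length is returned as a
    lower bound on the cycle length; a floor of one frame keeps ``T`` positive
    for degenerate single-frame movies.
    """
    if len(trajectories) == 0:
        raise InsufficientDataError("cannot estimate cycle duration of an empty movie")
    total_len = sum(t.span for t in trajectories)
    n_div = sum(int(t.division_times.size) for t in trajectories)
    if n_div == 0:
        return float(max(max(t.span for t in trajectories), 1))
    return max(total_len / n_div, 1.0)


def assign_cycle_time(traj: Trajectory, T: float) -> np.ndarray:
    """Relative cell-cycle time for every observation of one trajectory."""
    if T <= 0:
        raise InsufficientDataError(f"mean cycle duration must be positive, got {T}")
    t = (traj.frames - traj.frames[0]).astype(float)
    t_w = float(t[-1]) if len(t) > 1 else 0.0
    d = np.sort(traj.division_times - traj.frames[0]).astype(float)

    r = np.empty_like(t)
    if d.size == 0:
        if t_w == 0.0:  # single observation, no anchor: start of cycle
            return np.zeros_like(t)
        return t / t_w

    before = t <= d[0]
    r[before] = 1.0 - t[before] / max(d[0], T)
    after = t > d[-1]
    r[after] = (t[after] - d[-1]) / max(t_w - d[-1], T)
    for d0, d1 in zip(d[:-1], d[1:]):
        mid = (t > d0) & (t <= d1)
        r[mid] = (t[mid] - d0) / (d1 - d0)
    return r


def cycle_bins(r: np.ndarray, n_bins: int = 6) -> np.ndarray:
    """Equal-width cycle-time bins: ``floor(r·n_bins)`` clipped so r=1 → last bin."""
    r = np.asarray(r, dtype=float)
    return np.clip(np.floor(r * n_bins).astype(int), 0, n_bins - 1)


@dataclass
class CycleAnnotation:
    """Cycle-time annotation of one movie: mean duration ``T`` and per-track r."""

    T: float
    r: dict  # trajectory_id -> np.ndarray aligned with the trajectory's frames

    def bins(self, n_bins: int = 6) -> dict:
        return {k: cycle_bins(v, n_bins) for k, v in self.r.items()}


def annotate_movie(trajectories: Sequence[Trajectory]) -> CycleAnnotation:
    """Estimate ``T`` for a movie and assign r to every observation."""
    T = estimate_T(trajectories)
    return CycleAnnotation(T=T, r={t.trajectory_id: assign_cycle_time(t, T) for t in trajectories})
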