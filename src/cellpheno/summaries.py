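"""Dynamic and static descriptors of an annotated experiment.

Given Viterbi paths and cell-cycle times these produce the standard
diagnostics: the cycle-time distribution of every phenotype class, median
holding times (how long a cell stays in a class before switching to a
specific other class), and a display ordering of Viterbi paths by
average-linkage clustering on Hamming distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .cellcycle import cycle_bins
from .errors import InsufficientDataError
from .hmm import StatePath

FRAME_MINUTES = 30  # acquisition interval; used only when reporting in minutes


@dataclass
class HoldingTimeTable:
    """Median run lengths per (from_state, to_state) transition.

    Only observed transitions appear.  Terminal runs are censored (their
    destination is unobserved) and excluded unless requested.
    """

    entries: dict  # (from_state, to_state) -> median run length in frames

    def in_minutes(self) -> dict:
        return {k: v * FRAME_MINUTES for k, v in self.entries.items()}


def _runs(states: np.ndarray):
    """Maximal constant runs of a path as (state, length, next_state|None)."""
    out = []
    start = 0
    for t in range(1, len(states) + 1):
        if t == len(states) or states[t] != states[start]:
            nxt = None if t == len(states) else int(states[t])
            out.append((int(states[start]), t - start, nxt))
            start = t
    return out


def holding_times(paths: Sequence[StatePath], include_censored: bool = False) -> HoldingTimeTable:
    """Median time spent in a class before changing to a specific other class.

    With ``include_censored`` terminal runs enter the table under destination
    ``None`` as right-censored lengths.
    """
    if len(paths) == 0:
        raise InsufficientDataError("no paths")
    lengths: dict = {}
    for p in paths:
        for state, length, nxt in _runs(p.states):
            if nxt is None and not include_censored:
                continue
            lengths.setdefault((state, nxt), []).append(length)
    return HoldingTimeTable(entries={k: float(np.median(v)) for k, v in lengths.items()})


def state_cycle_profile(
    paths: Sequence[StatePath],
    r_values: Sequence[np.ndarray],
    N: int,
    n_bins: int = 6,
) -> dict:
    """Cycle-time distribution for every phenotype class.

    ``r_values`` aligns 1:1 with ``paths``.  Returns, per state, the
    histogram over equal-width cycle-time bins plus the mean and median r;
    states never visited get an empty profile.
    """
    if len(paths) == 0:
        raise InsufficientDataError("no paths")
    if len(paths) != len(r_values):
        raise ValueError("paths and r_values must align")
    per_state_r: dict = {s: [] for s in range(N)}
    for p, r in zip(paths, r_values):
        r = np.asarray(r, dtype=float)
        if len(r) != len(p):
            raise ValueError(f"r/path length mismatch for trajectory {p.trajectory_id!r}")
        for s in range(N):
            per_state_r[s].append(r[p.states == s])
    out = {}
    for s in range(N):
        rs = np.concatenate(per_state_r[s]) if per_state_r[s] else np.array([])
        if rs.size == 0:
            out[s] = {"count": 0, "hist": np.zeros(n_bins, dtype=int), "mean_r": np.nan, "median_r": np.nan}
            continue
        hist = np.bincount(cycle_bins(rs, n_bins), minlength=n_bins)
        out[s] = {
            "count": int(rs.size),
            "hist": hist,
            "mean_r": float(rs.mean()),
            "median_r": float(np.median(rs)),
        }
    return out


def order_paths_for_display(paths: Sequence[StatePath]) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded path matrix ordered for display.

    States are shifted to 1-based so 0 can serve as padding; rows (paths,
    padded to the maximal length) are ordered by average-linkage clustering
    on Hamming distance.  Returns ``(matrix[leaf_order], leaf_order)``.
    """
    if len(paths) < 2:
        raise InsufficientDataError("need at least two paths to order")
    max_len = max(len(p) for p in paths)
    M = np.zeros((len(paths), max_len), dtype=int)
    for i, p in enumerate(paths):
        M[i, : len(p)] = p.states + 1
    Z = linkage(pdist(M, metric="hamming"), method="average")
    order = leaves_list(Z)
    return M[order], order
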