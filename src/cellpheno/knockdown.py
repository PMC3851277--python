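"""Knockdown-specific (abnormal) phenotype extraction.

A phenotype class (HMM state) is called knockdown-specific when its
occupancy in the knockdown movie exceeds 1.95 times its occupancy in the
pooled plate-matched negative controls, and it covers at least 5% of the
knockdown cells.  Occupancy counts cell-observations (frames of Viterbi
paths) by default; a trajectory-level variant is available.  A gene is kept
for fingerprinting only when at least 3 replicate movies using at least 2
distinct siRNAs each show some knockdown-specific state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ROLE_KNOCKDOWN, serializable
from .errors import InsufficientDataError
from .hmm import StatePath


@serializable("abnormal_state_report")
@dataclass
class AbnormalStateReport:
    """Per-state knockdown vs pooled-control occupancy comparison."""

    unit_id: object
    state_freq_kd: np.ndarray
    state_freq_ctrl: np.ndarray
    ratio: np.ndarray
    abnormal: np.ndarray
    gene: object = None
    sirna_id: object = None

    def __post_init__(self) -> None:
        self.state_freq_kd = np.asarray(self.state_freq_kd, dtype=float)
        self.state_freq_ctrl = np.asarray(self.state_freq_ctrl, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.abnormal = np.asarray(self.abnormal, dtype=bool)

    @property
    def abnormal_states(self) -> np.ndarray:
        return np.flatnonzero(self.abnormal)

    @property
    def has_abnormal(self) -> bool:
        return bool(self.abnormal.any())

    def to_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "state_freq_kd": self.state_freq_kd,
            "state_freq_ctrl": self.state_freq_ctrl,
            "ratio": self.ratio,
            "abnormal": self.abnormal,
            "gene": self.gene,
            "sirna_id": self.sirna_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AbnormalStateReport":
        return cls(**d)


@dataclass
class GeneEvidence:
    """Replicate-level evidence that a gene's knockdown is phenotypic."""

    gene: object
    n_replicates_with_abnormal: int
    n_distinct_sirnas_with_abnormal: int

    @property
    def passes(self) -> bool:
        return self.n_replicates_with_abnormal >= 3 and self.n_distinct_sirnas_with_abnormal >= 2


def _state_frequencies(paths: Sequence[StatePath], N: int, unit: str) -> np.ndarray:
    counts = np.zeros(N)
    for p in paths:
        if unit == "frames":
            counts += np.bincount(p.states, minlength=N)
        elif unit == "trajectories":
            counts += np.bincount(np.unique(p.states), minlength=N) > 0
        else:
            raise ValueError(f"unknown counting unit {unit!r}")
    total = counts.sum()
    if total == 0:
        raise InsufficientDataError("no observations in path set")
    return counts / total


def detect_abnormal_states(
    paths_kd: Sequence[StatePath],
    paths_ctrl: Sequence[StatePath],
    N: int,
    ratio_threshold: float = 1.95,
    min_presence: float = 0.05,
    unit_id: object = None,
    counting_unit: str = "frames",
) -> AbnormalStateReport:
    """Flag HMM states over-represented in the knockdown arm.

    A state is abnormal iff its knockdown/control occupancy ratio strictly
    exceeds ``ratio_threshold`` (ratio is +inf where the control occupancy is
    zero but the knockdown's is not) and its knockdown occupancy is at least
    ``min_presence``.  Controls are pooled into a single denominator.
    """
    if len(paths_kd) == 0 or len(paths_ctrl) == 0:
        raise InsufficientDataError("both knockdown and control path sets must be non-empty")
    freq_kd = _state_frequencies(paths_kd, N, counting_unit)
    freq_ctrl = _state_frequencies(paths_ctrl, N, counting_unit)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            freq_ctrl > 0,
            freq_kd / np.where(freq_ctrl > 0, freq_ctrl, 1.0),
            np.where(freq_kd > 0, np.inf, 0.0),
        )
    abnormal = (ratio > ratio_threshold) & (freq_kd >= min_presence)
    return AbnormalStateReport(
        unit_id=unit_id,
        state_freq_kd=freq_kd,
        state_freq_ctrl=freq_ctrl,
        ratio=ratio,
        abnormal=abnormal,
    )


def gene_evidence_filter(reports: Sequence[AbnormalStateReport]) -> list[GeneEvidence]:
    """Count, per gene, replicates and distinct siRNAs with abnormal states."""
    by_gene: dict = {}
    for rep in reports:
        by_gene.setdefault(rep.gene, []).append(rep)
    out = []
    for gene, reps in by_gene.items():
        hits = [r for r in reps if r.has_abnormal]
        out.append(
            GeneEvidence(
                gene=gene,
                n_replicates_with_abnormal=len(hits),
                n_distinct_sirnas_with_abnormal=len({r.sirna_id for r in hits}),
            )
        )
    return out


def extract_abnormal_cells(
    table: pd.DataFrame,
    paths: Sequence[StatePath],
    report: AbnormalStateReport,
    movie_id: object = None,
) -> pd.DataFrame:
    """Rows of knockdown cells whose Viterbi state is flagged abnormal.

    Returns the matching rows of ``table`` (original, pre-PCA features and
    metadata) with added ``state`` and ``unit_id`` columns.  With no abnormal
    states the result is empty.
    """
    ann = []
    for p in paths:
        ann.append(
            pd.DataFrame(
                {
                    "movie_id": movie_id if movie_id is not None else p.trajectory_id[0],
                    "trajectory_id": p.trajectory_id if movie_id is not None else p.trajectory_id[1],
                    "state": p.states,
                    "_order": np.arange(len(p)),
                }
            )
        )
    ann = pd.concat(ann, ignore_index=True)

    kd = table[table["role"] == ROLE_KNOCKDOWN]
    if movie_id is not None:
        kd = kd[kd["movie_id"] == movie_id]
    kd = kd.sort_values(["movie_id", "trajectory_id", "frame"], kind="stable").reset_index(drop=True)
    kd["_order"] = kd.groupby(["movie_id", "trajectory_id"]).cumcount()
    merged = kd.merge(ann, on=["movie_id", "trajectory_id", "_order"], how="inner").drop(columns="_order")
    flagged = merged[merged["state"].isin(report.abnormal_states)].copy()
    flagged["unit_id"] = report.unit_id
    return flagged.reset_index(drop=True)
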