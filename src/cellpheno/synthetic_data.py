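"""Synthetic RNAi time-lapse screens with known ground truth.

Generates cell tables with the statistical structure the phenotyping method
assumes, so every downstream stage is testable without a real screen:

* each cell trajectory is a cyclic Markov chain over ``n_cycle_states``
  phenotype states with dominant self-transitions and first-upper-diagonal
  advances; the wrap from the last cycle state back to the first marks a
  division event (assigned to the mother's frame);
* emissions are multivariate Gaussians ``N(μ_state, Σ)`` in ``p_features``
  dimensions, with feature correlations induced by a random loading matrix
  and state means placed pairwise ``mean_separation`` apart;
* plates carry one knockdown movie per gene plus at least three
  negative-control movies; genes are targeted by multiple siRNAs across
  replicates;
* knockdown movies optionally route a prescribed fraction of per-frame
  occupancy (the *prevalence*) through gene-specific abnormal states entered
  from late-cycle states — mimicking knockdown phenotypes whose frequency
  rises with cell-cycle time — while controls contain no abnormal states by
  construction.

Trajectory starts are drawn from the movie chain's stationary distribution,
so the realized abnormal occupancy matches the prevalence in expectation.
Track lengths are truncated uniformly at random (minimum 5 frames) to
emulate cells entering and leaving the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .data_model import ROLE_CONTROL, ROLE_KNOCKDOWN
from .errors import ConfigError


class AbnormalSpec(NamedTuple):
    """Abnormal-state specification for one gene.

    morphologies: ids of shared abnormal morphologies (genes listing the same
    id share the same abnormal emission distribution).
    prevalence: target stationary fraction of knockdown cell-frames spent in
    the gene's abnormal states, in [0, 1).
    """

    morphologies: tuple
    prevalence: float


@dataclass
class SimConfig:
    """Configuration of a synthetic screen; defaults are the study conditions.

    ``replicates_per_gene`` is the total number of knockdown movies per gene
    (about 6 in the screens this emulates), distributed round-robin over
    ``sirnas_per_gene`` distinct siRNAs.  Movies run 96 frames of 30 minutes
    (48 h) with 60 tracked cells each; the regular cell cycle has 6 states
    with self-loop probability ``self_loop`` (expected cycle length
    ``n_cycle_states / (1 - self_loop)`` frames).
    """

    n_genes: int = 6
    replicates_per_gene: int = 6
    sirnas_per_gene: int = 2
    controls_per_plate: int = 3
    cells_per_movie: int = 60
    n_frames: int = 96
    p_features: int = 20
    n_cycle_states: int = 6
    abnormal_states: Mapping[str, AbnormalSpec] = field(default_factory=dict)
    mean_separation: float = 4.0
    noise_sd: float = 1.0
    self_loop: float = 0.8
    abnormal_self_loop: float = 0.95
    per_state_covariance: bool = False
    truncate_tracks: bool = True
    min_track_len: int = 5
    seed: int = 0

    def gene_names(self) -> list[str]:
        return [f"g{i:02d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Everything the generator knows: true states, abnormal ids, chains."""

    states: pd.DataFrame  # movie_id, trajectory_id, frame, true_state, is_abnormal
    abnormal_state_ids: dict  # gene -> list of global state ids
    transition_matrices: dict  # movie_id -> {"A": local matrix, "state_ids": global ids}
    means: np.ndarray  # (n_global_states, p)
    covariance: np.ndarray  # shared (p, p) emission covariance


def _stationary(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _base_chain(nc: int, q: float) -> np.ndarray:
    A = np.zeros((nc, nc))
    for i in range(nc):
        A[i, i] = q
        A[i, (i + 1) % nc] = 1.0 - q
    return A


def _kd_chain(nc: int, q: float, n_abn: int, entry_total: float, s_abn: float) -> np.ndarray:
    """Cycle chain with abnormal states appended, entered from late-cycle states."""
    n = nc + n_abn
    A = np.zeros((n, n))
    A[:nc, :nc] = _base_chain(nc, q)
    late = [nc - 1] if nc < 2 else [nc - 2, nc - 1]
    for i in late:
        adv = (i + 1) % nc
        A[i, adv] -= entry_total
        for j in range(n_abn):
            A[i, nc + j] += entry_total / n_abn
    for j in range(nc, n):
        A[j, j] = s_abn
        A[j, 0] = 1.0 - s_abn
    return A


def _calibrate_entry(nc: int, q: float, n_abn: int, prevalence: float, s_abn: float) -> float:
    """Binary-search the late-state entry mass so the stationary abnormal
    occupancy equals the target prevalence."""
    if prevalence <= 0.0:
        return 0.0
    cap = 0.95 * (1.0 - q)

    def occ(e: float) -> float:
        return float(_stationary(_kd_chain(nc, q, n_abn, e, s_abn))[nc:].sum())

    if occ(cap) < prevalence:
        raise ConfigError(
            f"prevalence {prevalence} unreachable with self_loop={q}, "
            f"abnormal_self_loop={s_abn} (max ~{occ(cap):.3f})"
        )
    lo, hi = 0.0, cap
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if occ(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_movie(rng, A, state_ids, nc_global, n_frames, n_cells, cfg, chol, means, cov_scale):
    """Sample one movie's trajectories.  Returns per-trajectory arrays."""
    pi = _stationary(A)
    nc = cfg.n_cycle_states
    n_local = A.shape[0]
    cum_A = np.cumsum(A, axis=1)
    trajs = []
    for cell in range(n_cells):
        if cfg.truncate_tracks:
            lo = min(cfg.min_track_len, n_frames)
            length = int(rng.integers(lo, n_frames + 1))
            start = int(rng.integers(0, n_frames - length + 1))
        else:
            length, start = n_frames, 0
        frames = np.arange(start, start + length)
        states = np.empty(length, dtype=int)
        states[0] = rng.choice(n_local, p=pi)
        u = rng.random(length - 1)
        for t in range(1, length):
            states[t] = np.searchsorted(cum_A[states[t - 1]], u[t - 1], side="right")
        # division: wrap from the last cycle state to the first, mother keeps the frame
        is_div = np.zeros(length, dtype=bool)
        if length > 1:
            is_div[:-1] = (states[:-1] == nc - 1) & (states[1:] == 0)
        gstates = state_ids[states]
        z = rng.standard_normal((length, cfg.p_features))
        scale = cov_scale[gstates][:, None] if cov_scale is not None else 1.0
        X = means[gstates] + (z @ chol.T) * scale
        trajs.append((f"t{cell:03d}", frames, gstates, states >= nc, is_div, X))
    return trajs


def simulate_screen(cfg: SimConfig):
    """Generate a synthetic screen.

    Returns
    -------
    table : pandas.DataFrame
        Long-format cell table (canonical metadata columns + ``f0..f{p-1}``).
    truth : GroundTruth
        True per-frame states, abnormal-state identities and the generator's
        transition matrices.
    """
    rng = np.random.default_rng(cfg.seed)
    nc = cfg.n_cycle_states
    if cfg.controls_per_plate < 3:
        raise ConfigError("controls_per_plate must be at least 3")
    genes = cfg.gene_names()
    for gene, spec in cfg.abnormal_states.items():
        if gene not in genes:
            raise ConfigError(f"abnormal spec for unknown gene {gene!r}")
        spec = AbnormalSpec(tuple(spec[0]), float(spec[1]))
        if spec.prevalence > 0 and len(spec.morphologies) == 0:
            raise ConfigError(f"gene {gene!r}: positive prevalence but no abnormal state spec")
        if not (0.0 <= spec.prevalence < 1.0):
            raise ConfigError(f"gene {gene!r}: prevalence must lie in [0, 1)")

    specs = {
        g: AbnormalSpec(tuple(s[0]), float(s[1]))
        for g, s in cfg.abnormal_states.items()
        if float(s[1]) > 0.0
    }
    morph_ids = sorted({m for s in specs.values() for m in s.morphologies})
    n_states_total = nc + len(morph_ids)
    if cfg.p_features < n_states_total:
        raise ConfigError(
            f"p_features={cfg.p_features} too small for {n_states_total} distinct states"
        )
    morph_to_global = {m: nc + i for i, m in enumerate(morph_ids)}

    # state means: orthonormal directions scaled so pairwise distance = mean_separation
    basis, _ = np.linalg.qr(rng.standard_normal((cfg.p_features, n_states_total)))
    means = (cfg.mean_separation / np.sqrt(2.0)) * basis.T
    # correlated noise from a random loading matrix: random orthogonal loadings
    # over a bounded eigenvalue spectrum (condition number <= 4), normalized to
    # unit feature variances so noise_sd sets the per-feature scale and the
    # generator's separability invariants stay meaningful
    Q, _ = np.linalg.qr(rng.standard_normal((cfg.p_features, cfg.p_features)))
    lam = rng.permutation(np.geomspace(0.5, 2.0, cfg.p_features))
    C = (Q * lam) @ Q.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    cov = cfg.noise_sd**2 * C
    chol = np.linalg.cholesky(cov)
    cov_scale = None
    if cfg.per_state_covariance:
        cov_scale = rng.uniform(0.7, 1.3, size=n_states_total)

    base_A = _base_chain(nc, cfg.self_loop)
    base_ids = np.arange(nc)

    rows_meta, rows_X, truth_rows = [], [], []
    transition_matrices: dict = {}

    def emit(movie_id, plate_id, role, gene, sirna, A, state_ids, n_cells):
        transition_matrices[movie_id] = {"A": A, "state_ids": state_ids}
        for traj_id, frames, gstates, is_abn, is_div, X in _sample_movie(
            rng, A, state_ids, nc, cfg.n_frames, n_cells, cfg, chol, means, cov_scale
        ):
            n = len(frames)
            rows_meta.append(
                pd.DataFrame(
                    {
                        "movie_id": movie_id,
                        "plate_id": plate_id,
                        "role": role,
                        "gene": gene,
                        "sirna_id": sirna,
                        "trajectory_id": traj_id,
                        "frame": frames,
                        "is_division": is_div,
                    }
                )
            )
            rows_X.append(X)
            truth_rows.append(
                pd.DataFrame(
                    {
                        "movie_id": movie_id,
                        "trajectory_id": traj_id,
                        "frame": frames,
                        "true_state": gstates,
                        "is_abnormal": is_abn,
                    }
                )
            )

    n_plates = cfg.replicates_per_gene if cfg.n_genes > 0 else 1
    for rep in range(n_plates):
        plate = f"P{rep:02d}"
        for j in range(cfg.controls_per_plate):
            emit(f"ctrl_{plate}_{j}", plate, ROLE_CONTROL, None, None, base_A, base_ids, cfg.cells_per_movie)
        for gene in genes:
            sirna = f"{gene}_s{rep % cfg.sirnas_per_gene + 1}"
            spec = specs.get(gene)
            if spec is None:
                A, ids = base_A, base_ids
            else:
                m = len(spec.morphologies)
                e = _calibrate_entry(nc, cfg.self_loop, m, spec.prevalence, cfg.abnormal_self_loop)
                A = _kd_chain(nc, cfg.self_loop, m, e, cfg.abnormal_self_loop)
                ids = np.concatenate([base_ids, [morph_to_global[mm] for mm in spec.morphologies]]).astype(int)
            emit(f"{gene}_r{rep:02d}", plate, ROLE_KNOCKDOWN, gene, sirna, A, ids, cfg.cells_per_movie)

    meta = pd.concat(rows_meta, ignore_index=True)
    X = np.concatenate(rows_X, axis=0)
    feats = pd.DataFrame(X, columns=[f"f{i}" for i in range(cfg.p_features)])
    table = pd.concat([meta, feats], axis=1)
    truth = GroundTruth(
        states=pd.concat(truth_rows, ignore_index=True),
        abnormal_state_ids={
            g: [morph_to_global[m] for m in s.morphologies] for g, s in specs.items()
        },
        transition_matrices=transition_matrices,
        means=means,
        covariance=cov,
    )
    return table, truth
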