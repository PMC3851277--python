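"""End-to-end orchestration: from a cell table to fingerprints.

One *analysis unit* is a knockdown movie together with the (≥3) pooled
negative-control movies of the same plate.  Per unit the pipeline fits the
standardized PCA on the pooled cells, initializes the HMM from cell-cycle
bins, trains it by Baum-Welch on all trajectories of the pool, annotates
every trajectory by Viterbi, and flags knockdown-specific states.  Across
units it applies the replicate/siRNA evidence filter, pools abnormal cells,
fits the universal phenotype mixture and produces replicate/gene
fingerprints, their clustering and the per-gene siRNA scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cellcycle
from .data_model import ROLE_CONTROL, ROLE_KNOCKDOWN, feature_columns, to_trajectories
from .errors import InsufficientDataError, ModelError
from .fingerprints import (
    Fingerprint,
    FingerprintClustering,
    UniversalPhenotypeGMM,
    average_gene_fingerprint,
    cluster_fingerprints,
    fingerprint,
    sirna_score,
)
from .hmm import GaussianCycleHMM, StatePath
from .knockdown import (
    AbnormalStateReport,
    GeneEvidence,
    detect_abnormal_states,
    extract_abnormal_cells,
    gene_evidence_filter,
)
from .preprocess import StandardizedPCA


@dataclass
class UnitResult:
    """Everything computed for one knockdown + pooled-controls unit."""

    unit_id: object
    gene: object
    sirna_id: object
    plate_id: object
    pca: StandardizedPCA
    model: GaussianCycleHMM
    report: AbnormalStateReport
    paths_kd: list
    paths_ctrl: list
    cycle_r: dict  # (movie_id, trajectory_id) -> r array
    abnormal_cells: pd.DataFrame


def analysis_units(table: pd.DataFrame, min_controls: int = 3) -> list[dict]:
    """Enumerate knockdown movies with their plate-matched control movies."""
    units = []
    movies = table[["movie_id", "plate_id", "role", "gene", "sirna_id"]].drop_duplicates("movie_id")
    ctrl_by_plate = {
        plate: grp["movie_id"].tolist()
        for plate, grp in movies[movies["role"] == ROLE_CONTROL].groupby("plate_id")
    }
    for _, row in movies[movies["role"] == ROLE_KNOCKDOWN].iterrows():
        controls = ctrl_by_plate.get(row["plate_id"], [])
        if len(controls) < min_controls:
            raise InsufficientDataError(
                f"movie {row['movie_id']!r}: plate {row['plate_id']!r} has "
                f"{len(controls)} control movies, need >= {min_controls}"
            )
        units.append(
            {
                "unit_id": row["movie_id"],
                "kd_movie": row["movie_id"],
                "control_movies": controls,
                "gene": row["gene"],
                "sirna_id": row["sirna_id"],
                "plate_id": row["plate_id"],
            }
        )
    return units


def run_unit(
    table: pd.DataFrame,
    unit: dict,
    n_states: int = 6,
    ridge: float = 0.08,
    variance_target: float = 0.95,
    ratio_threshold: float = 1.95,
    min_presence: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_init: int = 2,
) -> UnitResult:
    """Train and annotate one analysis unit.

    Baum-Welch is run from the cell-cycle-bin initialization and, when
    ``n_init >= 2``, additionally from a deterministic k-means seeding; the
    fit with the higher final training log-likelihood is kept.  The restart
    guards against the EM local optimum in which a rare knockdown-specific
    morphology is absorbed into a regular-cycle state.
    """
    movie_ids = [unit["kd_movie"], *unit["control_movies"]]
    sub = table[table["movie_id"].isin(movie_ids)]
    movies = to_trajectories(sub)

    # cell-cycle annotation per movie (T is movie-specific)
    cycle_r: dict = {}
    trajs = []
    for movie_id in movie_ids:
        ann = cellcycle.annotate_movie(movies[movie_id])
        for traj in movies[movie_id]:
            cycle_r[(movie_id, traj.trajectory_id)] = ann.r[traj.trajectory_id]
            trajs.append(traj)

    X_pool = np.concatenate([t.X for t in trajs], axis=0)
    bins = np.concatenate(
        [cellcycle.cycle_bins(cycle_r[(t.movie_id, t.trajectory_id)], n_states) for t in trajs]
    )
    pca = StandardizedPCA(variance_target=variance_target).fit(X_pool)
    Z_pool = pca.transform(X_pool)
    lengths = [len(t) for t in trajs]

    candidates = []
    model = GaussianCycleHMM(n_states=n_states, ridge=ridge, max_iter=max_iter, tol=tol)
    model.initialize_from_cycle(Z_pool, bins)
    model.fit(Z_pool, lengths=lengths)
    candidates.append(model)
    for restart in range(1, n_init):
        alt = GaussianCycleHMM(
            n_states=n_states, ridge=ridge, max_iter=max_iter, tol=tol, random_state=restart - 1
        )
        alt.fit(Z_pool, lengths=lengths)  # k-means seeding
        candidates.append(alt)
    model = max(candidates, key=lambda m: m.history_[-1])

    paths_kd, paths_ctrl = [], []
    offset = 0
    for t, n in zip(trajs, lengths):
        log_prob, states = model.decode(Z_pool[offset : offset + n])
        offset += n
        path = StatePath(trajectory_id=(t.movie_id, t.trajectory_id), states=states, log_prob=log_prob)
        (paths_kd if t.movie_id == unit["kd_movie"] else paths_ctrl).append(path)

    report = detect_abnormal_states(
        paths_kd,
        paths_ctrl,
        N=model.n_states_,
        ratio_threshold=ratio_threshold,
        min_presence=min_presence,
        unit_id=unit["unit_id"],
    )
    report.gene = unit["gene"]
    report.sirna_id = unit["sirna_id"]

    kd_paths_local = [
        StatePath(trajectory_id=p.trajectory_id[1], states=p.states, log_prob=p.log_prob)
        for p in paths_kd
    ]
    abnormal = extract_abnormal_cells(sub, kd_paths_local, report, movie_id=unit["kd_movie"])
    return UnitResult(
        unit_id=unit["unit_id"],
        gene=unit["gene"],
        sirna_id=unit["sirna_id"],
        plate_id=unit["plate_id"],
        pca=pca,
        model=model,
        report=report,
        paths_kd=paths_kd,
        paths_ctrl=paths_ctrl,
        cycle_r=cycle_r,
        abnormal_cells=abnormal,
    )


@dataclass
class ScreenResult:
    """Screen-level outputs: per-unit results, evidence, fingerprints, scores."""

    units: list
    evidence: list
    passing_genes: list
    gmm: UniversalPhenotypeGMM | None
    replicate_fingerprints: list
    gene_fingerprints: list
    clustering: FingerprintClustering | None
    sirna_scores: dict
    abnormal_cells: pd.DataFrame

    def fingerprint_table(self) -> pd.DataFrame:
        rows = {fp.owner: fp.vector for fp in self.gene_fingerprints}
        return pd.DataFrame.from_dict(rows, orient="index")

    def annotation_table(self) -> pd.DataFrame:
        """Per-cell state annotation: movie, trajectory, frame, state, cycle_time."""
        chunks = []
        for u in self.units:
            for p in u.paths_kd + u.paths_ctrl:
                movie_id, traj_id = p.trajectory_id
                r = u.cycle_r[(movie_id, traj_id)]
                chunks.append(
                    pd.DataFrame(
                        {
                            "unit_id": u.unit_id,
                            "movie_id": movie_id,
                            "trajectory_id": traj_id,
                            "frame": np.arange(len(p)),
                            "state": p.states,
                            "cycle_time": r,
                        }
                    )
                )
        return pd.concat(chunks, ignore_index=True)


def run_screen(
    table: pd.DataFrame,
    n_states: int = 6,
    ridge: float = 0.08,
    n_fingerprint_components: int = 20,
    seed: int | None = 0,
    min_controls: int = 3,
    **unit_kwargs,
) -> ScreenResult:
    """Run the full phenotyping pipeline on a cell table."""
    units = [
        run_unit(table, u, n_states=n_states, ridge=ridge, **unit_kwargs)
        for u in analysis_units(table, min_controls=min_controls)
    ]
    evidence = gene_evidence_filter([u.report for u in units])
    passing = [e.gene for e in evidence if e.passes]

    feats = feature_columns(table)
    pooled = [u.abnormal_cells for u in units if u.gene in passing and len(u.abnormal_cells)]
    if not pooled:
        return ScreenResult(units, evidence, passing, None, [], [], None, {}, pd.DataFrame())
    abnormal = pd.concat(pooled, ignore_index=True)
    if len(abnormal) < n_fingerprint_components:
        raise ModelError(
            f"{len(abnormal)} pooled abnormal cells cannot support "
            f"{n_fingerprint_components} universal classes"
        )
    gmm = UniversalPhenotypeGMM(n_components=n_fingerprint_components, random_state=seed).fit(
        abnormal[feats].to_numpy()
    )

    rep_fps = []
    for u in units:
        if u.gene in passing and len(u.abnormal_cells):
            rep_fps.append(
                fingerprint(u.abnormal_cells[feats].to_numpy(), gmm, owner=(u.gene, u.sirna_id, u.unit_id))
            )
    gene_fps = []
    for gene in passing:
        fps = [fp for fp in rep_fps if fp.owner[0] == gene]
        if fps:
            gene_fps.append(average_gene_fingerprint(fps, owner=gene))

    clustering = cluster_fingerprints(gene_fps) if len(gene_fps) >= 2 else None

    scores: dict = {}
    for gene in passing:
        by_sirna: dict = {}
        for fp in rep_fps:
            if fp.owner[0] == gene:
                by_sirna.setdefault(fp.owner[1], []).append(fp)
        eligible = [s for s, fps in by_sirna.items() if len(fps) >= 2]
        if len(eligible) >= 2:
            s1, s2 = eligible[:2]
            scores[gene] = sirna_score(by_sirna[s1], by_sirna[s2])

    return ScreenResult(
        units=units,
        evidence=evidence,
        passing_genes=passing,
        gmm=gmm,
        replicate_fingerprints=rep_fps,
        gene_fingerprints=gene_fps,
        clustering=clustering,
        sirna_scores=scores,
        abnormal_cells=abnormal,
    )
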