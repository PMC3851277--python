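"""Optional matplotlib visualizations (thin layer over the CSV outputs)."""

from __future__ import annotations

import numpy as np


def transition_heatmap(transmat: np.ndarray, ax=None, mask_diagonal: bool = True):
    """Transition-matrix heatmap; the diagonal is masked by default since
    self-transitions dominate and would flatten the color scale."""
    import matplotlib.pyplot as plt

    A = np.array(transmat, dtype=float)
    if mask_diagonal:
        np.fill_diagonal(A, np.nan)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(A, cmap="viridis")
    ax.set_xlabel("to state")
    ax.set_ylabel("from state")
    ax.figure.colorbar(im, ax=ax, label="transition probability")
    return ax


def viterbi_raster(matrix: np.ndarray, ax=None):
    """Raster of display-ordered, zero-padded Viterbi paths (rows = cells)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(matrix, aspect="auto", interpolation="nearest", cmap="tab10")
    ax.set_xlabel("frame")
    ax.set_ylabel("trajectory")
    return ax


def cycle_profile_plot(profile: dict, n_bins: int = 6, ax=None):
    """Cycle-time histograms per phenotype class, normalized within class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = (np.arange(n_bins) + 0.5) / n_bins
    for state, summ in sorted(profile.items()):
        h = np.asarray(summ["hist"], dtype=float)
        if h.sum() > 0:
            ax.plot(centers, h / h.sum(), marker="o", label=f"state {state + 1}")
    ax.set_xlabel("relative cell-cycle time r")
    ax.set_ylabel("class-conditional frequency")
    ax.legend(fontsize="small")
    return ax


def fingerprint_heatmap(clustering, ax=None):
    """Z-scored fingerprint heatmap in dendrogram leaf order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    M = clustering.display_matrix
    im = ax.imshow(M, aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(clustering.owners)))
    ax.set_yticklabels([str(clustering.owners[i]) for i in clustering.leaf_order], fontsize="small")
    ax.set_xlabel("universal phenotype class")
    ax.figure.colorbar(im, ax=ax, label="z-score")
    return ax
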