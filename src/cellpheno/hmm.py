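"""Gaussian-emission hidden Markov model with cell-cycle initialization.

The phenotyping core: hidden states are phenotype classes, emissions are
multivariate Gaussians over (PCA-reduced) morphological features, and each
cell trajectory is one observation sequence.  The model is trained by
Baum-Welch with a ridge (a constant diagonal, 0.08 by default) added to
every covariance in every learning step to prevent numerical singularity.
Emission parameters are initialized from the empirical moments of the cells
falling into equal-width cell-cycle-time windows; the transition matrix and
initial distribution start uniform (fully connected, self-loops allowed).

Trajectories are never concatenated: each is an independent Markov chain
sharing the parameters.  The forward-backward recursions use per-frame
normalization constants, and Viterbi runs in the log domain, so 90-frame
sequences do not underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, clone
from sklearn.cluster import KMeans

from .data_model import serializable
from .errors import InitializationError, InsufficientDataError, ModelError, NumericalError


@dataclass
class StatePath:
    """Viterbi annotation of one trajectory: the most likely hidden-state sequence."""

    trajectory_id: object
    states: np.ndarray
    log_prob: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def __len__(self) -> int:
        return int(self.states.shape[0])


def _log_gaussian(X: np.ndarray, means: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """Per-state multivariate normal log density, shape (T, N)."""
    T, k = X.shape
    N = means.shape[0]
    out = np.empty((T, N))
    for j in range(N):
        try:
            L = np.linalg.cholesky(covars[j])
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"covariance of state {j} is not positive definite") from exc
        diff = X - means[j]
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, j] = -0.5 * (maha + logdet + k * np.log(2.0 * np.pi))
    return out


def _scaled_forward(logB: np.ndarray, startprob: np.ndarray, transmat: np.ndarray):
    """Scaled forward pass.  Returns (alpha, per-frame shifts, log c, loglik)."""
    T, N = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    alpha = np.empty((T, N))
    c = np.empty(T)
    a = startprob * B[0]
    c[0] = a.sum()
    if c[0] <= 0.0 or not np.isfinite(c[0]):
        raise NumericalError("forward underflow at frame 0")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transmat) * B[t]
        c[t] = a.sum()
        if c[t] <= 0.0 or not np.isfinite(c[t]):
            raise NumericalError(f"forward underflow at frame {t}")
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + shift.sum())
    return alpha, B, c, loglik


def _scaled_backward(B: np.ndarray, c: np.ndarray, transmat: np.ndarray) -> np.ndarray:
    T, N = B.shape
    beta = np.empty((T, N))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transmat @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


class GaussianCycleHMM(BaseEstimator):
    """Hidden Markov model with multivariate Gaussian emissions.

    Parameters
    ----------
    n_states : int, default 6
        Number of hidden phenotype classes.
    ridge : float, default 0.08
        Constant added to every covariance diagonal in every learning step
        (and at initialization) to keep covariances positive definite.
    max_iter : int, default 500
        Maximum Baum-Welch iterations.
    tol : float, default 1e-6
        Convergence threshold on the relative change of the total
        log-likelihood.
    strict_init : bool, default False
        If True, an empty cell-cycle bin aborts initialization; otherwise
        the empty bin is merged with its nearest non-empty neighbour (the
        effective number of states is reduced) with a warning.
    random_state : int or None
        Used only by the k-means fallback initialization when no cycle bins
        are supplied.

    Attributes
    ----------
    startprob_ : (N,) initial state distribution.
    transmat_ : (N, N) row-stochastic transition matrix.
    means_ : (N, k) emission means.
    covars_ : (N, k, k) emission covariances.
    n_states_ : effective number of states after any bin merging.
    history_ : per-iteration total log-likelihood of the last fit.
    """

    def __init__(
        self,
        n_states: int = 6,
        ridge: float = 0.08,
        max_iter: int = 500,
        tol: float = 1e-6,
        strict_init: bool = False,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol
        self.strict_init = strict_init
        self.random_state = random_state

    # -- initialization ----------------------------------------------------

    def initialize_from_cycle(self, X: np.ndarray, cycle_bin: np.ndarray) -> "GaussianCycleHMM":
        """Moment-match emissions to cell-cycle-time bins; uniform A and pi.

        Each of the ``n_states`` equal-width cycle-time windows contributes
        the empirical mean and covariance (plus ridge) of the feature vectors
        of the cells falling into it.
        """
        X = np.asarray(X, dtype=float)
        cycle_bin = np.asarray(cycle_bin, dtype=int)
        if X.shape[0] != cycle_bin.shape[0]:
            raise ModelError("X and cycle_bin must align row-wise")
        N = self.n_states
        counts = np.bincount(cycle_bin, minlength=N)
        empty = np.flatnonzero(counts == 0)
        if empty.size and self.strict_init:
            raise InitializationError(f"cell-cycle bin {int(empty[0])} is empty")
        labels = cycle_bin.copy()
        if empty.size:
            nonempty = np.flatnonzero(counts > 0)
            if nonempty.size == 0:
                raise InitializationError("all cell-cycle bins are empty")
            warnings.warn(
                f"empty cell-cycle bin(s) {empty.tolist()} merged with nearest "
                f"non-empty neighbour; effective n_states reduced to {nonempty.size}",
                stacklevel=2,
            )
            remap = {b: nonempty[np.argmin(np.abs(nonempty - b))] for b in range(N)}
            labels = np.array([remap[b] for b in cycle_bin])
            keep = nonempty
        else:
            keep = np.arange(N)

        k = X.shape[1]
        means, covs = [], []
        for b in keep:
            Xb = X[labels == b]
            means.append(Xb.mean(axis=0))
            covs.append(np.cov(Xb, rowvar=False, ddof=0).reshape(k, k) + self.ridge * np.eye(k))
        n_eff = len(keep)
        self.means_ = np.array(means)
        self.covars_ = np.array(covs)
        self.startprob_ = np.full(n_eff, 1.0 / n_eff)
        self.transmat_ = np.full((n_eff, n_eff), 1.0 / n_eff)
        self.n_states_ = n_eff
        self.history_ = []
        return self

    def _kmeans_init(self, X: np.ndarray) -> None:
        N, k = self.n_states, X.shape[1]
        km = KMeans(n_clusters=N, random_state=self.random_state, n_init=5).fit(X)
        cov = np.cov(X, rowvar=False, ddof=0).reshape(k, k) + self.ridge * np.eye(k)
        self.means_ = km.cluster_centers_
        self.covars_ = np.repeat(cov[None], N, axis=0)
        self.startprob_ = np.full(N, 1.0 / N)
        self.transmat_ = np.full((N, N), 1.0 / N)
        self.n_states_ = N
        self.history_ = []

    # -- EM ----------------------------------------------------------------

    def _split(self, X, lengths):
        X = np.asarray(X, dtype=float)
        if lengths is None:
            return [X]
        bounds = np.cumsum(lengths)
        if bounds[-1] != X.shape[0]:
            raise ModelError("lengths do not sum to the number of rows")
        return np.split(X, bounds[:-1])

    def fit(self, X, lengths=None, cycle_bin=None, update_emissions: bool = True):
        """Baum-Welch estimation over a set of independent sequences.

        Parameters
        ----------
        X : (sum(lengths), k) stacked observation matrix.
        lengths : sequence lengths; a single sequence if None.
        cycle_bin : optional per-row cell-cycle bins for initialization;
            ignored when the model already carries parameters.
        update_emissions : if False, only ``startprob_`` and ``transmat_``
            are re-estimated (means/covariances stay bit-identical), which
            yields experiment-specific transition matrices under shared
            emissions.
        """
        seqs = self._split(X, lengths)
        if any(s.shape[0] < 1 for s in seqs) or not seqs:
            raise InsufficientDataError("every sequence must have at least one frame")
        if not hasattr(self, "means_"):
            Xall = np.concatenate(seqs, axis=0)
            if cycle_bin is not None:
                self.initialize_from_cycle(Xall, cycle_bin)
            else:
                self._kmeans_init(Xall)

        N = self.n_states_
        history: list[float] = []
        prev_ll = None
        for it in range(self.max_iter):
            ll, stats = self._e_step(seqs)
            history.append(ll)
            if prev_ll is not None and abs(ll - prev_ll) <= self.tol * (abs(prev_ll) + 1e-12):
                break
            prev_ll = ll
            self._m_step(stats, update_emissions)
        if self.max_iter == 0 or not history:
            history.append(self._total_loglik(seqs))
        self.history_ = history
        return self

    def _e_step(self, seqs):
        N = self.n_states_
        k = self.means_.shape[1]
        start_acc = np.zeros(N)
        trans_acc = np.zeros((N, N))
        gamma_sum = np.zeros(N)
        x_acc = np.zeros((N, k))
        xx_acc = np.zeros((N, k, k))
        total_ll = 0.0
        for seq in seqs:
            logB = _log_gaussian(seq, self.means_, self.covars_)
            alpha, B, c, ll = _scaled_forward(logB, self.startprob_, self.transmat_)
            beta = _scaled_backward(B, c, self.transmat_)
            gamma = alpha * beta
            total_ll += ll
            start_acc += gamma[0]
            if seq.shape[0] > 1:
                # sum_t xi_t = A ∘ (alpha[:-1]ᵀ · (B·beta / c)[1:])
                right = (B[1:] * beta[1:]) / c[1:, None]
                trans_acc += self.transmat_ * (alpha[:-1].T @ right)
            gamma_sum += gamma.sum(axis=0)
            x_acc += gamma.T @ seq
            for j in range(N):
                xx_acc[j] += (seq * gamma[:, j][:, None]).T @ seq
        return total_ll, (start_acc, trans_acc, gamma_sum, x_acc, xx_acc, len(seqs))

    def _m_step(self, stats, update_emissions: bool) -> None:
        start_acc, trans_acc, gamma_sum, x_acc, xx_acc, n_seq = stats
        N = self.n_states_
        self.startprob_ = start_acc / start_acc.sum()
        rows = trans_acc.sum(axis=1, keepdims=True)
        new_A = np.where(rows > 0, trans_acc / np.where(rows > 0, rows, 1.0), 1.0 / N)
        self.transmat_ = new_A / new_A.sum(axis=1, keepdims=True)
        if not update_emissions:
            return
        k = self.means_.shape[1]
        denom = np.maximum(gamma_sum, 1e-300)
        means = x_acc / denom[:, None]
        covs = np.empty_like(self.covars_)
        for j in range(N):
            cov = xx_acc[j] / denom[j] - np.outer(means[j], means[j])
            cov = 0.5 * (cov + cov.T) + self.ridge * np.eye(k)
            covs[j] = cov
        self.means_ = means
        self.covars_ = covs

    def _total_loglik(self, seqs) -> float:
        return float(
            sum(
                _scaled_forward(
                    _log_gaussian(s, self.means_, self.covars_), self.startprob_, self.transmat_
                )[3]
                for s in seqs
            )
        )

    # -- inference ---------------------------------------------------------

    def score(self, X, lengths=None) -> float:
        """Total marginal log-likelihood log p(X | model) over the sequences."""
        return self._total_loglik(self._split(X, lengths))

    def decode(self, seq: np.ndarray):
        """Viterbi decoding of one sequence: (log joint probability, states).

        Ties are broken toward the lowest state index.
        """
        seq = np.atleast_2d(np.asarray(seq, dtype=float))
        logB = _log_gaussian(seq, self.means_, self.covars_)
        T, N = logB.shape
        with np.errstate(divide="ignore"):
            log_pi = np.log(self.startprob_)
            log_A = np.log(self.transmat_)
        delta = np.empty((T, N))
        psi = np.zeros((T, N), dtype=int)
        delta[0] = log_pi + logB[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + log_A
            psi[t] = np.argmax(cand, axis=0)  # argmax returns the lowest index on ties
            delta[t] = cand[psi[t], np.arange(N)] + logB[t]
        states = np.empty(T, dtype=int)
        states[-1] = int(np.argmax(delta[-1]))
        for t in range(T - 2, -1, -1):
            states[t] = psi[t + 1, states[t + 1]]
        return float(delta[-1].max()), states

    def predict(self, X, lengths=None) -> np.ndarray:
        """Viterbi state annotation, stacked across sequences."""
        return np.concatenate([self.decode(s)[1] for s in self._split(X, lengths)])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "startprob": self.startprob_,
            "transmat": self.transmat_,
            "means": self.means_,
            "covars": self.covars_,
            "n_states_eff": self.n_states_,
            "history": list(getattr(self, "history_", [])),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianCycleHMM":
        model = cls(**d["params"])
        model.startprob_ = np.asarray(d["startprob"], dtype=float)
        model.transmat_ = np.asarray(d["transmat"], dtype=float)
        model.means_ = np.asarray(d["means"], dtype=float)
        model.covars_ = np.asarray(d["covars"], dtype=float)
        model.n_states_ = int(d["n_states_eff"])
        model.history_ = list(d["history"])
        return model


serializable("hmm_model")(GaussianCycleHMM)


class FrozenMixture:
    """Gaussian mixture whose components are taken from a fitted HMM.

    Only the mixture proportions are learned (EM over weights with the
    component means/covariances frozen); it serves as the time-independent
    comparator to the HMM on held-out trajectories.
    """

    def __init__(self, means: np.ndarray, covars: np.ndarray):
        self.means = np.asarray(means, dtype=float)
        self.covars = np.asarray(covars, dtype=float)
        self.weights_ = np.full(self.means.shape[0], 1.0 / self.means.shape[0])

    def fit(self, X: np.ndarray, max_iter: int = 500, tol: float = 1e-8) -> "FrozenMixture":
        X = np.asarray(X, dtype=float)
        logB = _log_gaussian(X, self.means, self.covars)
        prev = None
        for _ in range(max_iter):
            with np.errstate(divide="ignore"):
                logw = np.log(self.weights_)
            joint = logB + logw
            ll = float(logsumexp(joint, axis=1).sum())
            resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
            self.weights_ = resp.mean(axis=0)
            if prev is not None and abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                break
            prev = ll
        return self

    def score(self, X: np.ndarray) -> float:
        """Log-likelihood of the rows under the mixture (frames independent)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logB = _log_gaussian(X, self.means, self.covars)
        with np.errstate(divide="ignore"):
            return float(logsumexp(logB + np.log(self.weights_), axis=1).sum())


# ---------------------------------------------------------------------------
# functional wrappers

def init_from_cycle(X_pool, cycle_bin, N: int = 6, ridge: float = 0.08, strict: bool = False) -> GaussianCycleHMM:
    return GaussianCycleHMM(n_states=N, ridge=ridge, strict_init=strict).initialize_from_cycle(
        X_pool, cycle_bin
    )


def baum_welch(model: GaussianCycleHMM, sequences, max_iter: int = 500, tol: float = 1e-6) -> GaussianCycleHMM:
    """Return a newly trained copy of ``model`` (input left untouched)."""
    out = clone(model)
    out.set_params(max_iter=max_iter, tol=tol)
    for attr in ("startprob_", "transmat_", "means_", "covars_", "n_states_"):
        setattr(out, attr, np.copy(getattr(model, attr)) if attr != "n_states_" else model.n_states_)
    X = np.concatenate([np.atleast_2d(s) for s in sequences], axis=0)
    lengths = [len(s) for s in sequences]
    return out.fit(X, lengths=lengths)


def viterbi(model: GaussianCycleHMM, seq, trajectory_id=None) -> StatePath:
    log_prob, states = model.decode(seq)
    return StatePath(trajectory_id=trajectory_id, states=states, log_prob=log_prob)


def marginal_loglik(model: GaussianCycleHMM, seq) -> float:
    return model.score(np.atleast_2d(np.asarray(seq, dtype=float)))


def refit_transitions(model: GaussianCycleHMM, sequences, max_iter: int = 500, tol: float = 1e-6) -> GaussianCycleHMM:
    """Experiment-specific pi/A under frozen emissions (new copy)."""
    out = clone(model)
    out.set_params(max_iter=max_iter, tol=tol)
    out.startprob_ = np.copy(model.startprob_)
    out.transmat_ = np.copy(model.transmat_)
    out.means_ = model.means_  # shared by reference: bit-identical by contract
    out.covars_ = model.covars_
    out.n_states_ = model.n_states_
    X = np.concatenate([np.atleast_2d(s) for s in sequences], axis=0)
    lengths = [len(s) for s in sequences]
    return out.fit(X, lengths=lengths, update_emissions=False)


def gmm_comparator(model: GaussianCycleHMM, X_pool) -> FrozenMixture:
    """Mixture with the HMM's components; only the proportions are learned."""
    return FrozenMixture(model.means_, model.covars_).fit(np.asarray(X_pool, dtype=float))
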