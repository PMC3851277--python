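import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cellpheno.synthetic_data import AbnormalSpec, SimConfig, simulate_screen


# ---------------------------------------------------------------------------
# exhaustive-enumeration HMM oracle (independent of the package's recursions)

def _joint_log_probs(pi, A, means, covs, seq):
    """Log joint probability of every one of the |S|^T state sequences."""
    T = seq.shape[0]
    N = len(pi)
    emis = np.array(
        [[multivariate_normal.logpdf(seq[t], means[j], covs[j]) for j in range(N)] for t in range(T)]
    )
    S = np.array(list(itertools.product(range(N), repeat=T)))
    lp = np.log(pi)[S[:, 0]] + emis[0, S[:, 0]]
    logA = np.log(A)
    for t in range(1, T):
        lp += logA[S[:, t - 1], S[:, t]] + emis[t, S[:, t]]
    return S, lp


def brute_force_loglik(pi, A, means, covs, seq):
    """log p(seq) by summing the joint over all |S|^T state sequences."""
    from scipy.special import logsumexp

    _, lp = _joint_log_probs(pi, A, means, covs, seq)
    return logsumexp(lp)


def brute_force_viterbi(pi, A, means, covs, seq):
    """Most probable state sequence by exhaustive argmax."""
    S, lp = _joint_log_probs(pi, A, means, covs, seq)
    i = int(np.argmax(lp))
    return S[i], lp[i]


def random_hmm_instance(rng, max_states=3, max_T=8, dim=2):
    """A random small HMM plus an observation sequence for oracle checks."""
    N = int(rng.integers(1, max_states + 1))
    T = int(rng.integers(1, max_T + 1))
    pi = rng.dirichlet(np.ones(N))
    A = rng.dirichlet(np.ones(N), size=N)
    means = rng.normal(scale=2.0, size=(N, dim))
    covs = np.array([np.diag(rng.uniform(0.3, 1.5, dim)) for _ in range(N)])
    seq = rng.normal(scale=2.0, size=(T, dim))
    return pi, A, means, covs, seq


def sample_hmm(rng, pi, A, means, covs, T):
    """Sample one observation sequence from an HMM."""
    N = len(pi)
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(N, p=pi)
    for t in range(1, T):
        states[t] = rng.choice(N, p=A[states[t - 1]])
    X = np.array([rng.multivariate_normal(means[s], covs[s]) for s in states])
    return X, states


# ---------------------------------------------------------------------------
# shared synthetic fixtures

@pytest.fixture(scope="session")
def small_screen():
    """One knockdown + 3 controls with a 15%-prevalence abnormal state."""
    cfg = SimConfig(
        n_genes=1,
        replicates_per_gene=1,
        cells_per_movie=40,
        n_frames=72,
        abnormal_states={"g00": AbnormalSpec((0,), 0.15)},
        seed=11,
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def control_only_screen():
    cfg = SimConfig(n_genes=0, controls_per_plate=3, cells_per_movie=30, n_frames=48, seed=5)
    return simulate_screen(cfg)
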