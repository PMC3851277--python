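# Methods

`cellpheno` implements unsupervised phenotyping of RNAi time-lapse screens
from per-cell tracking/feature tables. This note documents the model, its
parameters, the synthetic-data generator used for validation, and the
numerical and design choices that were genuinely open.

## The model

Each tracked cell nucleus contributes one observation sequence
`x = (x_1, …, x_T)` of morphological feature vectors (one per 30-minute
frame). Sequences are modelled by a hidden Markov model with `N` hidden
states (phenotype classes), initial distribution `π`, row-stochastic
transition matrix `A`, and multivariate Gaussian emissions
`b_j(x) = N(x; μ_j, Σ_j)`. Trajectories are treated as independent chains
sharing parameters; they are never concatenated, because different cells are
biologically independent.

Parameters are estimated by Baum-Welch (EM) with per-frame scaled
forward-backward recursions. After every M-step a constant ridge (0.08 by
default) is added to the diagonal of every covariance matrix to prevent
numerical singularity; the same ridge is applied at initialization and is
exposed as a parameter because its natural scale is that of the z-scored
principal components the model is trained on. Viterbi decoding (log domain,
ties broken toward the lowest state index for determinism) assigns each cell
observation a phenotype class.

### Preprocessing

Features are z-score standardized and projected onto the smallest set of
principal components explaining ≥95% of the variance. Components are not
whitened — the HMM covariances absorb scale. The reduction is fitted per
analysis unit (one knockdown movie plus its pooled plate controls), the same
population the HMM is trained on; a global fit is possible by applying the
transformer to the whole table (`pca_scope` is effectively a caller choice
since the estimator is population-agnostic). Zero-variance features are
dropped with a warning rather than an error, since constant columns are
common in real exports.

### Cell-cycle time and initialization

Division events (from the tracker) anchor a relative cell-cycle time
`r ∈ [0, 1]` for every observation; the movie's mean cycle duration `T` is
total trajectory length over total division count. The four piecewise
branches (between divisions, before the first, after the last, no divisions)
are given in `cellcycle`'s module docstring. Conventions the source formulas
leave open, fixed here: intervals between divisions are half-open
`(t_i, t_{i+1}]`, so a division frame receives `r = 1` (mitosis lands at
late cycle time); `t` is measured from the trajectory's own first observed
frame; with zero division events `T` falls back to the longest observed
trajectory length, the best available lower bound on the cycle length.

The cycle is partitioned into `N` equal-width windows of `r`, and the
empirical mean and covariance of the cells in each window initialize the
emission of one state; `A` and `π` start uniform (fully connected,
self-loops allowed). An empty window is merged into its nearest non-empty
neighbour with a warning (reducing the effective `N`) unless strict mode is
set — small movies can miss a window, and aborting would be unhelpful.

### Multi-start EM

The pooled training population is dominated by regular-cycle cells, and a
rare knockdown-specific morphology (a few percent of pooled frames) can be
absorbed into a regular state at an inferior EM local optimum. The unit
pipeline therefore runs Baum-Welch from the cell-cycle initialization and,
by default, once more from a deterministic k-means seeding, keeping the fit
with the higher final training log-likelihood (`n_init`, default 2). The
selection criterion is the likelihood alone; on strongly cycle-structured
data the cycle initialization typically wins or ties.

### Convergence

EM stops when the relative change of the total log-likelihood falls below
`tol = 1e-6` or after `max_iter = 500` iterations. The training
log-likelihood is non-decreasing up to the perturbation introduced by the
covariance ridge; on the PCA scale used here the perturbation is below the
convergence tolerance in practice.

## Knockdown-specific states and fingerprints

For each analysis unit, Viterbi state occupancies are computed separately
over the knockdown trajectories and over the pooled (≥3) plate-matched
control trajectories. Occupancy counts cell-observations (frames); a
trajectory-level count is available via `counting_unit` since "fraction of
cells" is ambiguous — frames is the finer unit and matches the shape of the
Viterbi output. A state is knockdown-specific when its knockdown/control
occupancy ratio strictly exceeds 1.95 (ratio is +∞ when the control
occupancy is zero and the knockdown's is not) and its knockdown occupancy is
at least 5%. These are fixed thresholds, not hypothesis tests, so no
multiplicity correction applies.

A gene is retained only if ≥3 replicate movies using ≥2 distinct siRNAs show
some knockdown-specific state. Cells of flagged states ("abnormal cells")
are pooled across retained genes and clustered by a 20-component
full-covariance Gaussian mixture on globally z-scored **original** features
(not unit-specific PCA coordinates — each unit has its own basis, so
original features are the only representation comparable across units). The
mixture is k-means-initialized from a fixed seed and regularized with the
same ridge as the HMM. A knockdown's fingerprint is the vector of relative
hard (argmax-responsibility) cluster assignments of its abnormal cells;
gene fingerprints are renormalized means over replicates. Fingerprints are
grouped by average-linkage hierarchical clustering on Euclidean distances of
the raw vectors; per-column z-scoring is applied to the heatmap display
only (both choices are switchable).

### siRNA score

For two siRNA sets S1, S2 targeting one gene,

    score = [ (Σ_{i<j∈S1} d_ij + Σ_{i<j∈S2} d_ij) / (|S1|+|S2|) ]
          / [ (Σ_{i∈S1, j∈S2} d_ij) / (|S1|·|S2|) ]

with `d` the Euclidean fingerprint distance and unordered within-set pairs.
Note the numerator's normalizer is the summed set size, not the within-pair
count; a `normalized_pairs` option provides the pair-count convention. Low
scores mean replicates of one siRNA sit tighter together than fingerprints
across siRNAs. The score is undefined (error) when the between-set distance
is zero.

## Dynamic descriptors

From Viterbi paths the package computes: per-state cycle-time histograms
(equal-width bins of `r`), median holding times per (from-state, to-state)
transition — terminal runs are excluded as right-censored, their destination
being unobserved, with an option to include them — and a display ordering of
zero-padded paths by average-linkage clustering on Hamming distance. For
display, states are shifted to 1-based so that 0 is reserved for padding;
internal indexing stays 0-based. Experiment-specific dynamics can be
compared by re-estimating `π` and `A` on one arm with emissions frozen
(`refit_transitions`), and the time-independence gain of the HMM is
quantified against a mixture with the HMM's own components and re-learned
weights only (`gmm_comparator`), compared by marginal likelihood of held-out
trajectories.

## Synthetic screens

The generator emulates the statistical structure the method assumes, not
any real screen's feature marginals:

- **Regular cycle.** A cyclic Markov chain over 6 states with self-loop
  probability 0.8 and first-upper-diagonal advances; the wrap from the last
  state to the first marks a division on the mother's frame. Expected cycle
  length is 30 frames (15 h at 30 min/frame), within the range of cultured
  human cell lines.
- **Emissions.** Gaussian, state means placed pairwise `mean_separation`
  (default 4.0) apart along random orthonormal directions in 20 features;
  noise covariance is a random-loading correlation matrix with eigenvalues
  bounded in [0.5, 2] (condition number ≤ 4), scaled by `noise_sd`
  (default 1.0) and normalized to unit feature variances. The bounded
  spectrum keeps the generator identifiable — with unbounded random
  loadings, worst-direction noise would swamp the nominal separation and
  the generator's own separability invariants would be meaningless.
- **Screen layout.** Per gene, 6 replicate knockdown movies distributed
  round-robin over 2 siRNAs; each plate carries one movie of every gene
  plus 3 negative-control movies; 60 cells per movie, 96 frames (48 h).
  Track lengths are truncated uniformly at random (minimum 5 frames) to
  emulate cells entering/leaving the field of view.
- **Abnormal phenotypes.** Extra near-absorbing states (self-loop 0.95,
  exit back to cycle start) entered from the two late-cycle states, so
  abnormal occupancy rises with cell-cycle time, as knockdown phenotypes
  acting at mitosis do. Genes may share abnormal morphologies (shared
  emission means), which is what makes fingerprint-based gene grouping
  testable. The late-state entry mass is calibrated by bisection so the
  chain's stationary abnormal occupancy equals the requested prevalence,
  and initial states are drawn from the stationary distribution, making
  realized occupancy unbiased. Controls contain no abnormal states by
  construction.

What passing on synthetic screens does **not** show: robustness to
segmentation/tracking errors, non-Gaussian or heavy-tailed feature noise,
batch effects beyond plate pairing, or cell-density-dependent morphology
drift. Those require real screen data.

### State-count choice on synthetic units

The screens this method was designed for have fewer visually distinct
regular-cycle morphologies than the 6 model states, leaving spare capacity
for knockdown-specific classes. The synthetic generator deliberately makes
all 6 cycle states distinct, so validation units are trained with
`n_states = 7` (cycle states plus one injected morphology) — the same
capacity-driven reasoning by which the state count is chosen by inspecting
class-mean similarity in real data. Control-only recovery checks use
`n_states = 6`, matching the generator chain.

## Validation problem sizes

Chosen to keep the full suite within desk-scale runtimes: held-out
comparison on one 70-cell movie (60 train / 10 held out, full-length
tracks); transition recovery on one control-only plate at generator
defaults (3 movies × 60 cells × 96 frames); abnormal-state detection over
20 seeded single-unit screens plus 20 null screens at 40 cells × 72 frames
per movie; fingerprint recovery on a 6-gene screen (3 shared-morphology
pairs, 36 units) at 30 cells × 60 frames. Separation, noise, prevalence and
thresholds stay at their defaults throughout. Oracle equivalence uses 100
random instances with ≤3 states and ≤8 frames, where exhaustive enumeration
is feasible.

## Known limitations

- The HMM state count is fixed by the caller; no order selection is
  provided beyond inspecting class-mean similarity.
- Fixed occupancy thresholds (1.95 ratio, 5% presence) have no error
  control; the replicate/siRNA filter is the only false-positive guard.
- Fingerprints depend on the universal mixture's seed through component
  boundaries; distances between fingerprints are stable under component
  relabeling but not under a different local optimum of the mixture fit.
- Division events are taken from the input table as ground truth; no
  mitosis detection from morphology is attempted.
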