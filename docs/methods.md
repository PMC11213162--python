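# Methods

This note documents the models and procedures `gfcband` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Problem setting

The pipeline discriminates two groups of subjects — a stable and a
progressive mild-cognitive-impairment-like group — from resting-state ROI
time series. Each subject contributes an `M × T` matrix of band-limited
BOLD-like signals (defaults: `M = 136` ROIs, `T = 135` retained samples at
`TR = 2 s`, i.e. 140 acquired volumes with the first 5 discarded, signals
limited to 0.01–0.1 Hz). The analysis chain is:

1. tapered sliding-window functional connectivity (FC) on the unfiltered
   ("full-band") signals;
2. edge-wise two-group Wilcoxon rank-sum sparsification of the full-band FC
   into a per-subject sparse adjacency;
3. graph Fourier filtering of the time series into low/middle/high
   graph-frequency bands using each subject's own adjacency spectrum;
4. a 100-feature signed-network description (25 metrics × 4 bands);
5. wrapper feature selection (binary PSO or simulated annealing) with
   inner-cross-validated SVM accuracy as fitness, run inside each outer
   training fold;
6. nested stratified 10-fold SVM-RBF evaluation with pooled-confusion
   accuracy, sensitivity (progressive-detection rate) and specificity, plus
   an ROC over pooled decision values.

## Synthetic cohorts

Real cohorts of this kind are access-controlled, so the generator in
`gfcband.synthetic` emulates the acquisition: zero-mean multivariate
Gaussian noise with a prescribed stationary correlation matrix (Cholesky
factor applied to white noise), zero-phase Butterworth band-pass (order 4,
applied forward–backward) to 0.01–0.1 Hz, and the initial-volume discard.
Because the same linear filter is applied to every ROI, the zero-lag
cross-correlation of the filtered series equals the generating correlation
matrix, so planted group differences are exactly recoverable in expectation;
tests confirm empirical recovery to |Δr| < 0.05 at T = 20 000 and > 95 % of
spectral power inside the pass band.

Group B's correlation matrix is group A's with a configurable set of edges
shifted by a configurable Δr, re-projected to the nearest positive
semidefinite correlation matrix (eigenvalue clipping at 1e-8, diagonal
renormalization); generation fails if the repair moves any planted
correlation by more than 0.02 or a target leaves (−1, 1). Subject *k* of
both groups shares a random substream, so a zero effect gives bit-identical
groups and planted effects are isolated from sampling noise. The default
base matrix is modular (four equal blocks, within-block r = 0.35, between
0.05) — a generic community-structured connectome stand-in; a factor-model
"random" template is also provided. Default group sizes are 142/136.

What the generator does **not** emulate: hemodynamic autocorrelation,
scanner drift and motion artifacts, spatially structured noise, non-Gaussian
or non-stationary dynamics, and realistic whole-connectome covariance.
Passing tests therefore establish correctness and calibration of the
machinery, not expected classification accuracy on real cohorts.

## Sliding-window FC

The window is a unit rectangle of 50 TR convolved with a discretized
Gaussian of σ = 3 TR truncated at ±4σ, normalized to sum 1 (length
50 + 2·12 = 74). Windows advance one TR and only fully contained windows are
used: with T = 135 and width 74 there are 62 windows. Within each window the
taper is used as observation weights in a weighted Pearson correlation (not
as a point-wise multiplier of the signals — the weighted-correlation
convention is standard in tapered dynamic-FC work); the subject's FC entry
is the median over windows (midpoint rule for even counts). Diagonals are
zeroed. A window in which an ROI has zero weighted variance is excluded from
the affected pairs' medians; pairs with no valid window raise an error by
default, except for band-filtered series (below) where they are set to 0
with a warning, since an ROI isolated in the sparse adjacency legitimately
carries no energy in some graph bands.

## Sparsification

Each upper-triangle edge's full-band FC values are compared between groups
with a two-sided Wilcoxon rank-sum test (tie-corrected normal approximation
with continuity correction; edges constant across all subjects get p = 1).
Edges with p < α form a single shared mask; each subject's sparse adjacency
keeps its own full-band values there and is zero elsewhere. The default is
α = 0.05 uncorrected — the threshold is a free parameter of the method and a
Benjamini–Hochberg switch (`fdr=True`) is provided. Monte-Carlo tests
confirm the null retention rate is α ± 0.02.

## Graph-spectral filtering

The combinatorial Laplacian `L = D − A` is built per subject from the sparse
adjacency. Correlations can be negative; by default absolute weights are
used so that L is positive semidefinite and the low/high frequency ordering
of eigenvalues is well defined (a `signed_laplacian` flag uses raw weights
instead). Eigenvectors are ordered by ascending eigenvalue with a
deterministic sign convention (largest-magnitude entry positive, first index
on ties). The GFT is `x̃ = Vᵀx`, the inverse `x = Vx̃`, and band filtering is
the ideal projector `x_F = V G Vᵀ x` with G diagonal 0/1. Bands follow the
first-third / last-third rule: the low band is the first ⌊M/3⌋ modes, the
high band the last ⌊M/3⌋, the middle band the remainder — for M = 136 this
is 45/46/45. Disconnected adjacencies are allowed; the extra zero modes fall
in the low band and a component count is logged.

## Feature set

Per band, 25 metrics in five families (100 features total; names are
`<band>.<family>.<metric>`):

* **Graph (9)** — global efficiency, mean eccentricity, radius, diameter
  (shortest paths on the positive subgraph with edge length 1/w, the Brain
  Connectivity Toolbox convention; eccentricity summaries are undefined on a
  disconnected positive subgraph), degree assortativity over positive edges
  (0 with a warning on regular graphs), mean weighted clustering coefficient
  (geometric-mean triangle formula on positive weights, no max-weight
  rescaling), mean eigenvector centrality (unit-norm Perron vector of |FC|,
  guaranteeing a real non-negative eigenvector), mean signed strength, and
  Louvain modularity on positive weights (γ = 1, best of 10 seeded
  restarts).
* **MST (7)** — the minimum spanning tree of the positive subgraph under the
  correlation distance d = 1 − w (equivalent to the single-linkage
  dendrogram construction; tests verify the edge set against Kruskal).
  Metrics are computed on the unweighted tree topology: hop radius and
  diameter, maximum degree, leaf fraction LF, maximum betweenness
  (normalized by (M−1)(M−2)/2), tree hierarchy LF/(2·BC_max), and
  κ = Σk²/Σk.
* **Triads (5)** — all ROI triples whose three edges are nonzero, classified
  by positive-edge count into T₀ (− − −) … T₃ (+ + +), plus the network
  energy `Un = −Σ w_xy w_xz w_yz / Δ` over the Δ qualifying triads. The
  census and energy are computed with trace identities and verified against
  an exhaustive triple loop.
* **TMH (2)** — hub tendency Σ Dᵢ²/Σ Dᵢ with Dᵢ the positive (resp. the
  magnitude of the negative) degree; the negative index uses magnitudes so
  both are non-negative.
* **Links (2)** — counts of strictly positive and strictly negative
  upper-triangle entries.

Band metrics are computed on the full (unsparsified) per-band FC matrices; a
metric undefined for a subject (no triads, no negative links, disconnected
positive subgraph) is flagged and imputed with the cohort median when the
table is assembled (a column undefined for every subject falls back to 0),
with counts logged. All metrics are ROI-permutation invariant, which tests
verify.

## Feature selection

Fitness of a mask is the mean stratified 5-fold inner-CV accuracy of the
SVM-RBF on the masked, per-fold-standardized features (empty mask: 0).
Within one optimizer run, fitness is memoized by mask — it is a pure
function of the mask under the fixed inner split — so the recorded best
fitness always equals a recomputation.

* **Binary PSO** — swarm 20, cognitive = social = 1.5, inertia 0.72, global
  best topology. The search space is a bit mask, so velocities (clipped to
  ±4) are mapped through a sigmoid to per-bit Bernoulli updates. Default 50
  iterations.
* **SA** — single-bit-flip neighborhood; improvements always accepted, worse
  moves with Boltzmann probability exp(−θ/T) where θ is the shortfall
  against the best-so-far fitness; T₀ = 10 with geometric cooling (ratio
  0.95, 20 steps per temperature, floor 1e-3).

The iteration budgets are exposed in the configs; the test suite and the
acceptance script run the optimizers at smaller budgets (PSO 8 iterations;
SA T₀ = 1, ratio 0.8, floor 0.1) — these are problem-size choices for the
desk-scale synthetic studies, where the recovery criteria are met comfortably.
No cardinality penalty is applied: parsimony is an outcome, not an
objective. An all-zero best mask is repaired to the best single feature.

## Evaluation

Outer 10-fold stratified CV with seeded shuffling. Standardization, feature
selection and SVM training all happen inside the training fold; a test
showing that corrupting a held-out fold's features leaves that fold's
selected mask unchanged guards the no-leakage property. The SVM uses C = 1
and the 1/(n_features·Var) gamma rule by default (no hyperparameter search).
Headline accuracy/sensitivity/specificity come from pooled confusion counts,
with fold-averaged values reported alongside; the positive class is the
progressive-like group B. ROC points are swept over pooled decision values
with trapezoidal AUC.

## Numerical choices and degenerate inputs

* Weighted-correlation variances below 1e-20 of the window's power are
  treated as zero (a constant series has rounding-level variance, not 0).
* Eigenvector sign fixing and seeded Louvain restarts make runs
  deterministic end to end; identical config + seed reproduces bit-identical
  cohorts, feature tables and reports.
* PSD repairs (base covariance, effect injection) clip eigenvalues at 1e-8
  and renormalize the diagonal.
* M < 3 has no band split; M < 4 is rejected by the cohort generator; MST
  metrics require M ≥ 3 and a connected positive subgraph.

## Problem sizes

The default synthetic study used by the tests and the acceptance script is
M = 20 ROIs with 10–60 subjects per group — large enough for every stage to
be exercised (190 edges, C(20,3) = 1140 triads, 45 windows of SW-FC per
band) while a full run of the pipeline completes in seconds. The rank-sum
calibration uses 300–500 replicates of 210 edges at n = 20/20; the planted
power study uses a 0.4 correlation shift on 10 of 190 edges at n = 60/60.

## Known limitations

* Per-subject graph spectra mean band-filtered signals are not directly
  comparable across subjects in the spectral domain; comparability is
  restored at the feature level. A common group-level graph is a documented
  alternative not implemented here.
* The absolute-value Laplacian discards the sign structure the triadic
  metrics later use; the `signed_laplacian` flag exists but makes the
  frequency ordering ill-defined when negative eigenvalues appear.
* The Wilcoxon sparsification uses the whole cohort (both groups) before
  cross-validation. Selection and classification are leakage-free given the
  features, but the adjacency itself is group-informed — a property of the
  method being implemented, worth remembering when interpreting absolute
  accuracies.
* Louvain modularity is a stochastic heuristic; best-of-10 restarts makes it
  reproducible under a fixed seed but not provably optimal.
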