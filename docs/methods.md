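# Methods

`tvmanifold` implements an end-to-end analysis of manifold learning on
time-varying functional connectivity (tvFC): sliding-window tvFC
construction, three manifold learners written from their defining equations,
intrinsic-dimension estimation, surrogate-data null models, and clustering /
predictive evaluation at the scan and group level, exercised on a synthetic
multi-task dataset. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Sliding-window tvFC

Given an ROI-by-acquisition matrix with `N` regions, the number of unique
connections is `N_cons = N(N-1)/2` and the number of windows of duration
`W_dur` sliding by `W_step` over `N_acq` acquisitions is
`N_wins = floor((N_acq - (W_dur - W_step)) / W_step)`. Windows are half-open,
0-based `[start, start + W_dur)`; each column of the tvFC matrix is the
Fisher-z transformed (arctanh) Pearson correlation of the windowed ROI
pairs, vectorized in row-major upper-triangle order. Correlations are clipped
at `|r| = 1 - 1e-7` before `arctanh` so degenerate windows cannot produce
infinities. Row normalization ("z-scoring") uses the population (1/N) standard
deviation, which makes the unit-variance invariant exact. A window is
*task-homogeneous* iff every acquisition in it carries the same task label and
none fall in an instruction period; all other windows are `"mixed"`.
Dissimilarities between windows (the samples) use Euclidean, correlation
(1 - Pearson r), or cosine distance; k-nearest-neighbor queries break ties by
ascending sample index so all graph constructions are deterministic.

## Laplacian Eigenmaps

The affinity is the weighted mutual-kNN scheme: `W_ij = 1` when i and j are
in each other's neighbor sets, `0.5` when the relation holds in one direction,
`0` otherwise (a strictly binary variant is exposed). With degree matrix `D`
and Laplacian `L = D - W`, the generalized problem `L f = lambda D f` is
solved through the symmetric normalized form `D^(-1/2) L D^(-1/2)` for
numerical stability; the constant eigenvector `f_0` (eigenvalue 0) is dropped
and dimensions `f_1..f_m` returned. Each eigenvector is scaled so its
largest-magnitude entry is positive, making output deterministic across
platforms; the first `m'` columns of an `m`-dimensional solution equal the
`m'`-dimensional solution by construction. Disconnected graphs are embedded
jointly with a warning (the zero eigenvalue's multiplicity then equals the
component count), mirroring how low-k group graphs still produce
subject-separated embeddings.

## T-SNE

High-dimensional affinities are conditional Gaussians whose per-sample widths
are calibrated by bisection on `log sigma` so the perplexity `2^H(p_.|i)`
matches the requested value (tolerance 1e-5 in entropy; if all neighbors are
equidistant any width is admissible and the bracket midpoint is returned).
The joint distribution is `P_ij = (p_i|j + p_j|i) / (2n)` — the `1/n` factor
makes `P` a proper distribution so `KL(P||Q)` is well defined. Low-dimensional
affinities use the Student-t kernel normalized over ordered pairs. The layout
minimizes `KL(P||Q)` by exact O(n^2) gradient descent with the method's
published schedule: early exaggeration factor 4 for the first 100 iterations,
momentum 0.5 switching to 0.8 at iteration 250, up to 1000 iterations.
"PCA" initialization is implemented as classical MDS (PCoA) of the input
dissimilarity matrix — identical to PCA scores when the metric is Euclidean,
and the natural analogue when the embedder is handed only dissimilarities —
scaled to a 1e-4 spread; random initialization is seeded. Barnes-Hut style
approximations are out of scope at the few-hundred-to-thousand-window sizes
this package targets.

## UMAP

Phase 1 builds the fuzzy graph: over the directed k-NN edge set, edge weights
are `exp(-max(0, d - rho_i) / sigma_i)` with `rho_i` the smallest positive
neighbor distance and `sigma_i` solved by bisection (tolerance 1e-5, <= 64
iterations, bracket `[1e-8, 1e3] * d_max`) so the membership mass equals
`log2(k)`; when ties at `rho_i` leave the mass above the target for every
width, `sigma` is pinned to the bracket floor with a warning. The symmetric
graph is the fuzzy union `C = B + B^T - B o B^T`. The embedding-space kernel
`1/(1 + a d^(2b))` is fitted by least squares to the piecewise target (1 up to
`min_dist`, exponential decay beyond) on a 300-point grid over `[0, 3]`;
`min_dist` defaults to 0.8.

Phase 2 is asynchronous per-edge stochastic gradient descent on the edge-wise
cross-entropy, compiled with numba: attractive updates move both endpoints of
edges sampled every `max_weight / weight` epochs (edges below
`max_weight / n_epochs` never fire), repulsive updates use uniform negative
sampling at rate 5 per attractive update, gradient components are clipped at
±4, and the learning rate decays linearly to zero over 500 epochs. The
asynchrony matters: batching the per-edge forces into one vectorized update
per epoch averages them into something close to plain gradient descent and
suppresses the instability at high learning rates that the sequential scheme
(and the evaluation below) exhibits. Initialization is spectral (the LE of
`C`, scaled to a 10-unit box) with a seeded random fallback for disconnected
graphs. Per-epoch mean coordinate displacement is recorded so optimization
smoothness can be inspected.

## Intrinsic dimension

*TwoNN*: under a locally uniform density the ratio `mu = r2/r1` of second- to
first-neighbor distances is Pareto with CDF `1 - mu^(-d)`; `d` is the slope of
a least-squares fit of `-log(1 - F)` on `log mu` through the origin, computed
on the smallest 90% of ratios. The truncation-robust fit is used rather than
a plain MLE on the truncated sample, which is biased upward by roughly the
inverse of the kept fraction (measured ~1.34 on an exactly 1-dimensional
sample). Duplicate points are dropped with a warning. *lPCA*: the estimate is
the number of principal components reaching 0.95 cumulative explained
variance, globally or per-sample over k-NN neighborhoods (k >= 5; default
local grid {50, 75, ..., 200}). Both operate on windows as points in
connection space with Euclidean distances, their native metric.

## Null models

*Connectivity randomization* permutes row order independently within each
tvFC column (preserving each column's value multiset exactly), destroying the
row-to-connection correspondence. *Phase randomization* replaces each ROI's
positive-frequency Fourier phases with i.i.d. Uniform(0, 2pi) draws while
keeping amplitudes; the DC component — and, for even length, the Nyquist
component — is kept real so the inverse transform is exactly real-valued.
Amplitude preservation implies the autocovariance is preserved
(Wiener–Khinchin) while timing is destroyed. Phases are drawn independently
per ROI; a cross-spectrum-preserving variant is deliberately not offered.

## Evaluation

Silhouettes use Euclidean distance in embedding space (or directly on tvFC
columns for the ambient-space score); mixed windows are excluded from task
scoring. Group aggregation is either "Concatenate + Embed" (column-wise
concatenation, optional per-scan row z-scoring, one embedding) or "Embed +
Procrustes" (scan-level embeddings aligned to a reference — default the first
scan, with an optional 5-pass generalized mode aligning to the evolving mean —
using the first `align_dims` dimensions). The Procrustes fit is the
closed-form similarity transform (translation, rotation/reflection, uniform
scale); its disparity equals the normalized residual sum of squares.
Classification uses multiclass logistic regression with an L1 penalty
(regularization strength C = 1, saga solver), macro-averaged F1, and either
split-half folds (first half of each scan's windows vs second, swapped and
averaged — halves defined in windows) or leave-one-subject-out folds. The
stability study re-embeds one scan with distinct sub-seeds and reports the
silhouette distribution (median, IQR, 1.5*IQR outlier count); T-SNE
repetitions use random initialization, since with deterministic PCA-style
initialization its gradient descent has no run-to-run variability to measure.

## Synthetic data generator

The generator emulates the multi-task study design: four tasks (rest, memory,
math, attention), each in two separated 180-s blocks preceded by 12-s
instructions, TR 1.5 s, block order drawn by seeded rejection sampling so no
task repeats back-to-back. Scan length follows from the schedule
(8 x 128 = 1024 acquisitions by default); the published per-block window
counts are properties of the block length alone and are checked through the
counting operations. The default test size is 30 ROIs; 157-ROI generation is
supported but not default.

ROI signals follow a latent-factor model chosen so each real-data feature the
analysis relies on has an explicit knob:

- a **shared backbone** (6 factors) carries `1 - task_modulation^2` of the
  signal variance in every state — most connectivity structure is common
  across tasks;
- **state-specific factors** (8 for rest, 4 per task, separate instruction
  factors) carry the remaining variance. `task_modulation = 0.5` was
  calibrated so the ambient-space scan-level task silhouette lands near the
  value reported for real multi-task tvFC (~0.12-0.17 here); tasks that are
  too distinct make the window cloud an unrealistically clean 4-cluster
  geometry;
- **engagement drift**: state-specific factor amplitudes follow a slow
  lognormal AR(1) envelope (scale 0.5, 45-s time constant), so window
  covariances move on a manifold whose dimension tracks the active factor
  count rather than only reflecting correlation sampling noise;
- **block non-stationarity**: each block perturbs its state's loading matrix
  (`block_jitter = 0.35`), so the two blocks of one task are related but
  distinguishable, as embeddings of real scans show;
- **inter-subject variability**: per-subject loading perturbations
  (`subject_loading_jitter = 0.3`) make scan embedding geometries agree only
  up to a higher-dimensional similarity transform — the property that makes
  Procrustes alignment with more dimensions valuable;
- **fingerprints** (off by default; `fingerprint_config` enables them):
  per-ROI affine offsets/gains cannot alter Pearson correlations, so subject
  identity is injected as (a) a subject-specific background latent factor
  whose rank-1 loading outer product shifts connection-level FC means, and
  (b) per-ROI gains applied to the signal before additive noise, which
  modulate each connection's SNR and hence its FC mean and volatility;
- AR(1) smoothing (coefficient 0.6) applied after mixing, plus white noise
  (`noise_sd = 0.5` relative to unit signal variance).

`id_contrast_config` defines the dedicated parameter-recovery condition for
the rest-vs-task intrinsic-dimension contrast (`task_modulation = 0.9`,
`noise_sd = 0.2`, no block jitter, 2 backbone factors): at ~182 windows per
task, drift must dominate correlation sampling noise for the factor-count
difference (8 vs 4) to be recoverable; under the default condition the
contrast only emerges with group-level statistics over many scans.

What the generator does **not** emulate: hemodynamic-response convolution,
physiological noise and motion, spatial voxel structure, and real anatomical
network topology. Passing tests therefore show that the algorithms behave as
specified on data with the assumed covariance/autocorrelation/fingerprint
structure — not that any particular real dataset will yield the same
silhouettes or dimensions.

## Problem sizes and numerical choices

Canonical experiments (the `study` module) run on 30-ROI scans. Scan-level
hyper-parameter contrasts use full window resolution (w_step = 1, 995
windows) because the small-neighborhood failure mode is driven by the
window-overlap autocorrelation chain and weakens when windows are subsampled.
The stability study subsamples to w_step = 3 (332 windows, 20 repetitions)
and the concatenation study to w_step = 10, keeping repeated optimizations
affordable; the group Procrustes study stays at full resolution. Degenerate
inputs fail loudly and name the offending window, ROI, connection, or node;
seeded generators are threaded through every stochastic step, and repeated
runs with the same configuration are bit-identical.

## Known limitations

The exact T-SNE gradient is O(n^2) per iteration and practical to roughly a
couple of thousand windows. The UMAP negative-sampling schedule makes its
layout non-deterministic across library versions only through the numba RNG;
within an environment it is seed-stable. The silhouette-based evaluation
inherits the caveat demonstrated by the phase-randomization control: temporal
autocorrelation alone produces locally smooth embeddings, so task silhouettes
should always be read against the null-model baselines. Statistical testing
across hyper-parameter grids (multiple-comparison-corrected group contrasts)
is out of scope.
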