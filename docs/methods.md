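# Methods

## Problem and model

A functional brain network over `n` ROIs is a symmetric nonnegative
edge-weight matrix `W` with zero diagonal. Given a scan `X ∈ ℝ^{m×n}`
(column-standardized: mean-centered, unit Euclidean norm per column, so
`A = XᵀX` is the Pearson correlation matrix), the accurate-module estimator
seeks the network closest to `A` that is nonnegative, sparse, and has
*exactly* `k` connected components:

    min_{W ≥ 0} ‖W − A‖²_F + λ Σ_ij W_ij   s.t.  rank(L_W) = n − k.

Under the nonnegativity constraint the ℓ1 penalty reduces to the plain sum
of entries. The rank constraint works because the zero-eigenvalue
multiplicity of a graph Laplacian equals the number of connected
components; forcing `rank(L_W) = n − k` therefore forces `k` modules
exactly, rather than approximately as ℓ1/trace-norm relaxations do.

## Solver

The constraint is relaxed through a penalty `α Σ_{i≤k} σ_i(L_W)` on the sum
of the `k` smallest Laplacian eigenvalues, rewritten via the Ky Fan theorem
as `α · min_{FᵀF=I} Tr(Fᵀ L_W F)` and optimized by alternating
minimization:

* **F-step** — with `W` fixed, the optimum is the `k` eigenvectors of
  `L_W` with smallest eigenvalues (any orthonormal basis of the invariant
  subspace under degeneracy; all downstream logic is subspace-invariant).
* **W-step** — with `F` fixed, using
  `Tr(Fᵀ L_W F) = ½ Σ_ij f_ij W_ij` with `f_ij = ‖f_i − f_j‖²`, the problem
  separates per entry into a one-dimensional nonnegative quadratic with the
  closed form `W_ij = max(0, a_ij − α f_ij / 4 − λ / 2)`, diagonal zeroed.
* **α schedule** — after each W-step the number `z` of numerically zero
  eigenvalues of the new `L_W` is counted; α is doubled if `z < k`, halved
  if `z > k`, and held at `z == k`. The run stops when `z == k` and the
  objective change at an unchanged α falls below `obj_rtol` (default 1e-6
  relative), or at `max_outer_iters` (default 50), in which case
  `converged=False` is reported with full per-iteration diagnostics.

Initialization is `W⁰ = max(A, 0)` with zero diagonal — the penalty-free
(α→0, λ→0) solution, i.e. the nonnegative Pearson network — giving a warm
start with no arbitrary randomness; α starts at 0.1.

### Normalized Laplacian and lagged degrees

By default the F-step and the rank count use the symmetric normalized
Laplacian `I − D^{-1/2} W D^{-1/2}`. This serves two purposes: weakly
connected single ROIs are not split off spuriously (a module hanging on a
tiny but genuine edge has an O(1) normalized Fiedler value, whereas its
unnormalized counterpart is arbitrarily small), and the spectrum is bounded
by 2, so an absolute zero-eigenvalue tolerance (1e-8) is scale-free.

The exact normalized coupling makes the W-step non-separable, so the
embedding rows are rescaled as `f_i / √d_i` with degrees taken from the
*current* iterate before the step ("lagged degrees"). At that point the
identity `½ Σ_ij f̃_ij W_ij = Tr(Fᵀ L_sym F)` is exact, and holding the
rescaled distances fixed through the W-step preserves the closed form —
the standard device in constrained-Laplacian-rank methods.

**Monotonicity guarantee.** Within each outer iteration, at its α and its
degree snapshot, the chain `objective(before) ≥ objective(after F-step) ≥
objective(after W-step)` is exact for both Laplacian variants (each step is
an exact minimizer of the joint objective in its block) and is asserted on
every iteration of every test run with 1e-9 slack. For the unnormalized
variant the chain also extends across iteration boundaries whenever α is
unchanged, and is tested there too; for the normalized variant the degree
re-snapshot between iterations makes cross-iteration values not directly
comparable, which is a property of all lagged-degree schemes, not of this
implementation.

**Isolated nodes.** Zero-degree nodes get a zero diagonal entry in the
normalized Laplacian (Chung's convention), so each isolated node carries a
zero eigenvalue and counts as its own component. The alternative convention
(diagonal 1) would break the equality between zero-eigenvalue multiplicity
and component count, which the α schedule and the module count rely on.

**Eigenvalue/edge tolerances.** Zero eigenvalues are counted below an
absolute 1e-8; edges exist above 1e-10. AM-PC outputs have exactly-zero
suppressed entries by construction (closed-form clipping), so component
counting on the estimator output needs no extra thresholding.

## Baseline estimators

* **pc / pc+** — `W = XᵀX` (diagonal zeroed) and its negative-edge-removed
  variant.
* **sparse-pc** — regression form `min ‖X − XW‖²_F + λ‖W‖₁`, solved per
  column by coordinate-descent lasso with that column excluded from the
  design (the zero-diagonal constraint; without it `W = I` would be a
  trivial near-minimizer), then symmetrized `(W + Wᵀ)/2`. A closed-form
  soft-threshold variant `min ‖W − XᵀX‖²_F + λ‖W‖₁` is exposed as
  `variant="soft-threshold"`; the literature uses both under the same name
  and they are not equivalent, so the choice is explicit at the call site.
* **m-pc** — `min ‖X − XW‖²_F + λ₁‖W‖₁ + λ₂‖W‖_*`, solved by consensus
  ADMM with two splitting variables (soft-threshold prox for ℓ1 + diagonal
  constraint; singular-value shrinkage for the trace norm); the quadratic
  update reuses a cached eigendecomposition of `XᵀX`. Tests verify the
  attained objective against an independent primal-dual (Condat–Vũ)
  reference to 1e-4 relative and against the lasso solver at λ₂ = 0.

## Classification protocol

Each scan's network is flattened to its strict upper triangle
(`n(n−1)/2` features; 6,670 at n = 116). Feature selection is a two-sample
pooled-variance Student's t-test at fixed `p < 0.05` (Welch optional),
fitted on training data only; zero-variance features get `p = 1`; if
nothing passes, the single smallest-p feature is kept (logged) so a
classifier always exists. The classifier is a linear SVM with `C = 1`.
Evaluation is 5-fold **subject-level** cross-validation: subjects (not
scans) are shuffled within class and dealt round-robin into folds, so all
scans of a subject stay on one side of every split; each class must have at
least as many subjects as folds. Estimator hyperparameters (the λ grid) are
chosen per outer fold by an inner 5-fold subject-level CV on the training
subjects only, by mean accuracy with ties to the earliest grid point.
Networks are estimated once per (scan, grid point) — estimation never sees
labels — and both fold layers are re-randomized each repeat. Metrics are
ACC, SEN, SPE (patient class positive) and rank-based AUC, computed per
scan on held-out folds; the report aggregates per-repeat means into overall
mean ± sd. A ranked-edge export (t, p per ROI pair, ascending p) supports
discriminative-connection reporting at a configurable p cutoff.

## Synthetic cohorts

The generator produces exactly the second-order structure the estimators
consume: scans are drawn from a zero-mean Gaussian whose correlation matrix
is block-modular — `within_corr` (default 0.7) inside each of `k_true`
(default 8) modules, `between_corr` (default 0) elsewhere, unit variances.
Defaults mirror the targeted study conditions: 116 ROIs, 137 time points
per scan, 48 control and 95 patient subjects with 2 scans each. Class
differences live on `n_discriminative_edges` (default 12) randomly chosen
**within-module** edges whose correlation is lowered by `effect_size`
(default 0.3) in the patient class — weakened connectivity. Placement
inside modules is deliberate: the rank constraint drives between-module
edges to exactly zero in both classes, so between-module differences would
be erased by the estimator itself and could not support classification.
A per-subject symmetric jitter (sd 0.02) on the correlation matrix, shared
by all scans of a subject and re-projected to positive definite, makes
same-subject scans more alike than cross-subject scans, so subject-level CV
is materially different from scan-level CV. Covariances are checked for
positive definiteness; small violations are repaired by eigenvalue clipping
with unit-variance restoration, and strongly negative spectra raise with
advice to reduce the effect size. Everything derives from `(spec, seed)`
via spawned generators, so cohorts are byte-identical across runs.

What the generator does *not* emulate: haemodynamic response shape,
temporal autocorrelation, motion or physiological artifacts, and site
effects. Passing tests therefore demonstrate correctness of the estimation
and evaluation machinery under a known second-order model, not robustness
to real fMRI noise.

## Problem sizes in tests and the acceptance script

Full-size checks (116 ROIs, k = 8, 137 time points) are run where the
quantity itself is size-specific: the 6,670-feature identity, exact module
count, and planted-partition recovery. Cohort-level cross-validation runs
use reduced cohorts (20–30 ROIs, 18–26 subjects, 2 scans each, 5 repeats of
5 folds) — the protocol's properties (split integrity, separability,
chance behavior under permuted labels) do not depend on matrix size, and
these sizes keep the whole suite fast enough to run on every change. The
t-test type-I check uses the full 6,670-feature width at 100 (suite) / 50
(script) Monte-Carlo replicates.

## Known limitations

* The alternating scheme converges to a stationary pair (W, F), not a
  certified global optimum of the rank-constrained problem; different λ or
  α trajectories can yield different partitions on low-SNR data.
* The α schedule assumes the zero-eigenvalue count responds monotonically
  to α; on adversarial inputs it can oscillate until `max_outer_iters`, in
  which case the result honestly reports `converged=False`.
* Between-module connectivity is by construction zero in converged AM-PC
  networks, so analyses of between-module edges require a different
  estimator.
* The ℓ1 regression-form solver symmetrizes post hoc; the symmetrized
  matrix is no longer the exact minimizer of the asymmetric objective
  (the AM-PC W-step is symmetric by construction and has no such gap).
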