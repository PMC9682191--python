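# Methods

## Model and assumptions

`agmfs` fits a joint least-squares regression of one-hot class labels on
several feature blocks that share a sample axis.  Three devices shape the
solution:

1. **Row sparsity.** Each modality's weight matrix `W_v` is penalized by the
   ℓ2,1 norm Σ_i ‖w_i‖₂, smoothed as Σ_i √(w_iᵀw_i + ε) so the objective is
   differentiable at zero rows.  Rows, not entries, are eliminated: a zeroed
   row removes the feature for all classes at once.
2. **A simplex feature weight θ.** One nonnegative weight per feature,
   summing to one over all modalities jointly.  It multiplies the data
   inside the residual (`W_vᵀ Θ_v X_vᵀ`), so features compete for a fixed
   budget of total weight; within-modality sums of θ are reported as
   modality importance.
3. **Anchor-graph Laplacian smoothing.** Per modality, `m` anchors are drawn
   from the samples, each sample is linked to its `k_nn` nearest anchors
   with the closed-form weights of the sparse affinity problem (the row-wise
   regularizer is absorbed by the (k+1)-th neighbor distance, so `k_nn` is
   the only parameter), and the penalty tr(W_vᵀX_vᵀ(I−BBᵀ)X_vW_v) discourages
   predictions that differ across strongly connected samples.  Because the
   implied similarity BBᵀ is row-stochastic, its degree matrix is exactly
   the identity and the Laplacian needs no explicit degree computation; all
   quadratic forms are evaluated in O(nmc) from the factor B.

The model assumes features at comparable scale (blocks are z-scored per
column by default — squared-Euclidean anchor distances and one shared α
across a 93-dimensional and a 3-dimensional modality are meaningless
otherwise), labels encoded one-hot, and a linear relation between features
and class indicators.  Binary labels are the primary use; k > 2 is
supported by the algebra.

## Optimization

Alternating exact block minimization:

* **Bias** `b = (1/n)(Y1 − WᵀΘXᵀ1)` — closed form (with the per-modality
  predictions averaged in `independent` coupling, summed in `additive`).
* **Weights** `W_v` solve the regularized normal system
  (Θ_vX_vᵀX_vΘ_v + αN_v + βX_vᵀ(I−BBᵀ)X_v) W_v = Θ_vX_vᵀ(Ỹᵀ − 1bᵀ) by
  Cholesky, where N_v = diag(1/(2√(w_iᵀw_i+ε))) is the standard
  iteratively-reweighted surrogate for the smoothed ℓ2,1 penalty,
  recomputed once per sweep.  `Ỹ` is `Y` (independent) or `Y` minus the
  other modalities' predictions (additive block coordinate descent).
* **θ** solves the simplex quadratic program min θᵀQθ − θᵀs with
  Q = (XᵀHX)∘(WWᵀ) and s = diag(2XᵀHYᵀWᵀ); H = I − (1/n)11ᵀ is applied
  implicitly by column centering (it absorbs the bias).  Q is positive
  semidefinite (Schur product of PSD matrices), so the QP is convex.

### Coupling modes

The per-modality weight updates fit the labels modality-by-modality, while
the θ step couples all modalities through one concatenated residual.  These
two readings cannot both be exact block descent on a single scalar
objective.  The default `additive` mode makes the concatenated residual the
objective everywhere, so every step is an exact minimizer of one function
and the recorded objective history is non-increasing (the fit raises an
error if it ever increases beyond 1e-6 relative — a contract, not a hope).
`independent` mode keeps the printed per-modality updates verbatim and
carries no monotonicity contract.

### The simplex QP solver

The θ step uses an augmented Lagrangian with slack `u ≥ 0`: alternate the
linear solve θ = E⁻¹g with E = 2Q + μI + μ11ᵀ (Sherman–Morrison over a
one-time eigendecomposition of 2Q, so each inner iteration is O(d²)), the
projection u = pos(θ + λ₁/μ), and multiplier updates.  Two numerical
choices matter and were set after measuring failure modes:

* **Scale-adaptive penalty.** μ starts at `mu0` times the problem scale
  max(‖2Q‖₂, ‖s‖∞) and grows by ρ = 1.1 up to 10× its start.  The Q
  matrices arising during a fit span many orders of magnitude; a penalty
  far above ‖2Q‖ makes the proximal step inert, so the iterate satisfies
  the constraints long before it is optimal, while a penalty far below
  needs thousands of iterations for feasibility.
* **Optimality certificate.** Stopping requires primal feasibility
  (max(‖θ−u‖∞, |θᵀ1−1|) ≤ `alm_tol`, default 1e-8) *and* a small
  Frank–Wolfe gap uᵀ(2Qu−s) − min_i(2Qu−s)_i, which upper-bounds the
  suboptimality of any feasible point of a convex QP over the simplex.
  Feasibility alone is not a convergence criterion.
* **Active-set finish.** Once the support stabilizes, a primal active-set
  refinement (ratio-test steps toward face minimizers, KKT certification)
  finishes to machine precision; a just-admitted variable that is
  immediately re-blocked at a zero-length step indicates the apparent dual
  violation is below the numerical resolution of the KKT solve (this
  happens when Q is severely ill-conditioned) and is excluded from
  re-entry.  The solver is verified against a brute-force simplex grid
  (d=3), a projected-gradient oracle (d=20), and hand-checkable KKT cases.

### Initialization and the θ warm-up

θ starts uniform (1/d), W at zero, b at zero.  The θ step is held back for
the first `theta_warmup` sweeps (default 10), or until the frozen problem
converges, whichever comes first.  The reason is structural: at W ≈ 0 the
QP's quadratic term (quadratic in W) is negligible against its linear term
(linear in W), the subproblem degenerates to a linear program, and its
exact solution is a single vertex — all weight on one feature.  That
collapse is absorbing: features with θ_i = 0 receive zero weight rows in
every later sweep, so the alternation cannot recover.  Holding θ at its
uniform initialization until the reweighted solves bring W to the scale of
the data keeps the quadratic term competitive and yields spread,
informative θ.  Warm-up sweeps are still exact block descent on the same
objective, so the monotonicity contract is unaffected.

### Stopping

Outer sweeps stop when |obj(t+1)−obj(t)|/obj(t) ≤ `outer_tol` (default
1e-5) with θ participating, or at `max_outer_iters` (default 50).  On the
default synthetic configuration the fit converges in ~40 sweeps in well
under a second.

## Defaults and their rationale

| parameter | default | rationale |
|---|---|---|
| α (ℓ2,1 weight) | 0.1 | sensitivity study on the default synthetic conditions: support recovery of the full model peaks near α=0.1; far smaller values under-sparsify, far larger values push W into a regime where the θ step degenerates |
| β (graph weight) | 1e-4 | the data term carries Θ² ~ 1/d² while the graph term is unscaled, so the operative β range is ~1e-4..1e-3; larger values let graph smoothing dominate the fit |
| ε (smoothing) | 1e-8 | small enough not to bias row norms, large enough to keep N_v finite |
| m (anchors) | min(4⌈√n⌉, n) | standard anchor-count heuristic; n=200 → 60 anchors |
| k_nn | 5 | sparse but connected affinity rows |
| outer_tol | 1e-5 | the stated convergence criterion of the evaluation protocol |
| theta_warmup | 10 | frozen-phase convergence typically needs ~10–20 sweeps; see above |
| α/β grid | {1e-3,1e-2,1e-1,1,10,1e2,1e3} | the protocol's tuning range (a printed duplicate entry read as 10⁻¹) |

`seed` controls anchor sampling and data generation only; the updates
themselves are deterministic.

## Synthetic data: what it emulates and what it does not

The generator mirrors the shape of a multi-modal biomarker cohort: n=200
subjects, three modalities of dimension 93/93/3, balanced binary labels
(remainder samples join the first class), a small informative subset per
modality (default 10/10/1), and unequal modality usefulness.  Features are
independent unit-variance Gaussians; informative columns receive an
additive class-conditional mean shift of
`effect_size × modality_strength[v] × noise_sd` (defaults: effect 1.5,
strengths 0.5/0.35/0.15), so modality strength scales signal, not noise,
and the learned modality weights have a direct ground-truth analogue.

Deliberately absent: inter-feature covariance (real ROI features are
strongly correlated), site/scanner effects, non-Gaussian tails, label
noise, and longitudinal structure.  Passing tests on this generator show
that the optimizer and the ranking behave as designed under the model's own
assumptions — independent features with mean-shift signal — not that the
method ranks well on real neuroimaging data.

## Evaluation harness

Stratified k-fold cross-validation (default 10 folds).  Per fold, the
selector (scaling and anchor graphs included) is fit on the training rows
only; the top `n_select` features by θ-weighted row norm are passed to a
linear max-margin classifier (scikit-learn `LinearSVC` behind a narrow
trainer/scorer contract); accuracy, sensitivity (TP/(TP+FN), positive
class = label 1), specificity (TN/(TN+FP)) and AUC (Mann–Whitney midrank
statistic) are computed on the held-out fold.  Metrics undefined for a
single-class fold are reported as NaN, never as 0.  The α/β grid sweep
reports every cell; it never selects the test-best cell.

## Numerical details and degenerate inputs

* Distance ties in anchor affinities break by anchor index (stable sort);
  a row whose k+1 nearest anchor distances are all equal falls back to
  uniform 1/k weights with a logged warning.
* Zero-mass anchor columns are dropped before forming B (logged).
* Constant feature columns survive z-scoring as zeros and are annihilated
  by the centering in the θ step.
* A singular weight system (possible only at forced α→0) falls back to a
  least-squares solve with a logged warning.
* Score ties in feature ranking break toward the smaller index.

## Known limitations

* **The θ coupling can hurt ranking.**  On the default synthetic
  conditions, the frozen-θ reduction (plain smoothed-ℓ2,1 selection)
  recovers ~96% of the planted support in the top-10, while the full model
  with learned θ recovers ~82–83%: with binary labels every informative
  feature predicts the same label direction, so the θ step — least squares
  over highly correlated rank-one predictors on a simplex — concentrates
  weight on a strict subset of the useful features and starves the rest.
  This is a property of the objective, not of the solver: it persists
  under exact optimization at every (α, β) in and around the tuning grid
  and in both coupling modes.  Users who need pure support recovery should
  use `freeze_theta=True` or the `row_norm` score; the learned θ is most
  useful as a modality-importance summary.
* Alternating minimization guarantees monotone descent, not global
  optimality; different warm-up lengths can reach different fixed points.
* The anchor graph assumes Euclidean geometry in the z-scored feature
  space; `m` and `k_nn` defaults are heuristics, not validated against any
  external dataset.
* Multi-class (k > 2) runs are supported but untuned; the evaluation
  harness is binary-only.
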