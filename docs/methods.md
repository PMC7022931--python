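# Methods

## Model

For a longitudinal two-class study with d variables, n samples tracked
over T time points (cube χ = {X₁, …, X_T}, X_t ∈ ℝ^(d×n), labels
y ∈ {−1, +1}ⁿ), the model is one linear scorer per time point with a
jointly regularized coefficient matrix B = [β₁, …, β_T] ∈ ℝ^(d×T):

* data term: Σ_t ‖y_t − X_tᵀβ_t‖² — classification cast as regression on
  the ±1 labels, classified by the sign of the score (sign(0) = +1);
* group (l2,1) term, weight γ₁: Σ_j ‖βʲ‖₂ over variable rows. A variable
  is either in or out of all T models jointly, giving a common compact
  marker set;
* nuclear term, weight γ₂: ‖B‖\* = Σ σᵢ(B). Low rank means the per-time
  models are near-linear combinations of a few shared patterns — the
  formalization of "association patterns at consecutive time points are
  similar". With γ₂ = 0 the model reduces to the LFS baseline; with
  γ₁ = γ₂ = 0 to independent per-time least squares.

The key modeling assumption is that biologically meaningful markers
discriminate over a period rather than at one isolated time point; both
penalties encode that temporal coupling, which per-time PLS-DA ignores.

## Solver

Both penalties are nonsmooth; the solver is the iteratively reweighted
least-squares scheme in which each iteration (1) forms the row weights
D(j,j) = ½(Σ_t b_tj² + ε)^(−1/2), (2) forms
D̃ = ½(BBᵀ + εI)^(−1/2) from the thin SVD of B, (3) solves
(X_tX_tᵀ + γ₁D + γ₂D̃)β_t = X_t y_t for every t. Each step is an exact
majorize–minimize step for the ε-smoothed objective, so the recorded
objective trace is non-increasing; iteration stops when the relative
Frobenius change of B falls below `tol`.

Numerical choices:

* **ε-smoothing** (`eps_reweight`, default 1e-8) keeps D and D̃ finite for
  zero rows and rank-deficient B. Consequence: coefficients approach but
  never exactly reach zero, so variable selection downstream is
  threshold- or rank-based rather than exact-zero-based.
* **Loss convention.** D and D̃ absorb a factor ½, so the update above is
  the stationarity condition of the objective with an unhalved loss;
  relative to the conventional half-loss form the effective penalty
  weights are γ/2. Since γ is tuned on decade grids this is a
  reparameterization, not a model change; the objective trace records the
  half-loss-scale quantity the iteration monotonically decreases, and
  `gnnr_objective` reports the conventional ½‖·‖² + γ₁·group + γ₂·nuclear
  form.
* **Convergence** defaults: `tol` 1e-6 relative Frobenius change,
  `max_iter` 100. IRLS converges linearly with a rate that degrades as
  coefficients are driven toward the ε floor, so strongly regularized fits
  may legitimately exhaust `max_iter`; the result is returned with
  `converged=False` and a warning. Rank-based selections stabilize long
  before the tolerance is met.
* **Initialization**: per-time ridge regression
  (X_tX_tᵀ + λI)⁻¹X_t y_t with λ = `ridge_init` (default 1e-3), computed
  by the push-through identity X(X_tᵀX_t + λI)⁻¹y when d > n. Plain least
  squares is ill-posed for d ≫ n.
* **Linear algebra**: the reference path Cholesky-solves the dense d×d
  system. Because X_tX_tᵀ has rank ≤ n and D̃ is a scaled identity plus a
  rank-≤T correction, the system is diagonal-plus-low-rank; an exact
  Woodbury path solves it in O(d(n+T)²) and is chosen automatically when
  d > 4(n+T). The two paths agree to solver tolerance (tested) — at
  d = 1500 the fast path turns a ~0.4 s dense solve into milliseconds,
  which is what makes multi-seed full-scale experiments practical.
* **Standardization** (default on): per-(variable, time) mean-0/SD-1
  scaling before fitting, because both penalties are scale sensitive and
  feature tables mix intensity scales. Constants are stored in the fit and
  applied at prediction; inside cross-validation they are recomputed from
  each training fold only, so no information leaks into the held-out fold.
* With γ₁ = γ₂ = 0 and a rank-deficient X_tX_tᵀ the system is singular and
  the solver raises an error advising nonzero regularization.
* The solver itself uses no random numbers: results are a deterministic
  function of dataset and configuration.

## PLS-DA and VIP

The cross-sectional baseline is PLS1 (single ±1 response) with NIPALS
deflation, delegated to scikit-learn's `PLSRegression`; this package owns
the variables-in-rows orientation, the bounds check 1 ≤ h ≤ min(n−1, p),
the VIP computation and the sign classification rule. VIP_j =
√(p Σ_k SS_k (w_jk/‖w_k‖)² / Σ_k SS_k) with SS_k = b_k²t_kᵀt_k; the mean
of squared VIP scores is identically 1, which the tests verify, and the
conventional biomarker screen keeps VIP > 2 (strict). The component count
h is a parameter (no principled universal default exists; the examples use
small h and the CV metrics can arbitrate).

## Validation statistics

* **LPOCV / CE_AUC**: every (positive, negative) pair is held out once,
  the model is refit, and the pair contributes H(f(x₊) − f(x₋)) with
  H(0) = ½ (standard AUC tie convention; the definition leaves H(0) open).
  Under stratified k-fold CV the same statistic is computed from the
  pooled out-of-sample scores over all positive–negative pairs.
* **DQ²** = 1 − PRESSD/TSS, where PRESSD ignores errors beyond the label
  (predictions above +1 for class +1, below −1 for class −1) and TSS is
  the total sum of squares of y about its mean (for balanced ±1 labels the
  mean is 0, so the centering choice is invisible in balanced designs).
* **Stratified k-fold** splits each class into k folds and joins one fold
  per class, so each test set matches the full class proportions within
  one sample per class; the permutation is fully seed-driven.
* Cross-validation always refits the entire pipeline, including
  standardization, inside each fold.

## Hyperparameter selection

Grid search walks the decade grid {10⁻⁶, …, 1, …, 10³} (singletons for
LFS, the cross-product for GNNR), evaluating each point with the chosen
CV (LPOCV for small n ≤ 20, stratified 10-fold otherwise). Because the T
time points rarely peak at the same parameters, selection uses minimax
regret: regret(p, t) = max_q perf(q, t) − perf(p, t), select
argmin_p max_t regret(p, t). Metrics are oriented larger-is-better (NMC is
negated) so one code path serves all; ties break toward the larger
(γ₁, γ₂) lexicographically — the more parsimonious model. Failed grid
cells are recorded as NaN and skipped.

## Synthetic data

The generator emulates a preprocessed feature table, not raw LC-MS
signals: independent normal draws with SD 1.5 around per-(group, class,
time) means from the palette {2.1, 1.7, 1.2, −1.3}. Defaults: 100 samples
(50 per class), 4 time points, 8 profile groups of 40 variables, 1180
background variables (mean 1.2 both classes), 1500 variables total.

The published profile curves exist only graphically, so the default
profile set is a reconstruction constrained by the design's printed
numbers (group size 40, the mean palette, 1300 of 1500 variables never
discriminative, background block of 1180): groups 1–4 carry the class
contrast (2.1 vs −1.3) at exactly one time point each, group 5 at all
four time points, and groups 6–8 are "undistinguishable" trends — means
that vary over time (1.7/1.2 palette) but identically for both classes,
mimicking fragments that respond to the stimulus without separating the
classes. A selection landing in groups 6–9 is a false recovery. The
profile set is a plain dataclass, so alternative reconstructions are one
object away. Draw streams are split per variable (one child seed sequence
per variable index), so adding or removing variables leaves the other
variables' draws untouched.

What the generator does **not** emulate: retention-time drift,
missingness, heteroscedastic or correlated noise, intensity-dependent
variance. Tests passing on this generator show the algorithms behave as
designed under the stated model, not that they are robust to those
real-data pathologies.

## Recovery evaluation and the method comparison

Selections are scored as recovery ratios |selected_t ∩ group g| / |group
g| per (group, time point). Two selection rules are provided: median
|coefficient| over time points > 10⁻² (strict) for the biomarker-set
workflow — the exact-zero rule is unusable under ε-smoothing — and
top-n per time point ranked by |coefficient| (amplitude), n = 160 at the
first time point and 200 at the others under the default design, ties
broken toward the smaller variable index.

The package's headline comparison tunes both LFS and GNNR by the same
protocol — stratified 10-fold CV, DQ², minimax regret — on an independent
tuning realization of the generator, then compares background
false-recovery ratios across fresh simulation replicates. The tuning grid
uses the central decades {10⁻², 10⁻¹, 1, 10}: below 10⁻² the penalty is
numerically negligible at standardized scale, and at 10² and beyond DQ²
collapses, so the omitted decades are flat extensions of the endpoints.
Problem sizes throughout the suite are the full default design (d = 1500,
n = 100, T = 4) for generator and comparison checks, and small dense
problems (d ≤ 40) for oracle-level solver checks.

## Known limitations

* IRLS is a fixed-point scheme for a convex but nonsmooth problem;
  convergence to `tol` can take thousands of iterations when strong
  penalties push coefficients to the ε floor. Accelerated first-order or
  proximal solvers are out of scope by design.
* CE_AUC saturates at 1 well before models differ meaningfully (the
  comparison experiments therefore arbitrate on DQ², which remains
  discriminating).
* DQ² under LPOCV is computed from pooled per-pair predictions, so each
  sample contributes once per opposite-class partner; with balanced
  classes this coincides with the per-sample version.
* The generator's class profiles are a documented reconstruction; the
  printed design numbers pin the counts but not the exact trajectories of
  the multi-period profile types.
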