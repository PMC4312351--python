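# Methods

## Model

Region-level envelope samples are modelled as zero-mean multivariate
Gaussian with precision matrix Θ; a zero off-diagonal entry encodes a
vanishing partial correlation, i.e. no direct functional connection.
The estimator maximises the penalized log-likelihood

    log det Θ − tr(S Θ) − λ Σ_{i≠j} W_ij |Θ_ij|

with S = XᵀX/T the maximum-likelihood sample covariance of the centered
T×p envelope matrix. Three weight constructions are supported: constant
weights (GL), inverse absolute sample covariances (GLa), and inverse
fiber densities from tractography (GLd). The Gaussian assumption means
all dependence is second-order; the model is cross-sectional — no
time-lagged or spectral precision is estimated, and no source-leakage
correction is applied.

### Penalty weights

* The diagonal of Θ is never penalized (W_ii = 0). The weights are
  derived from pairwise connectivity; penalizing variances has no
  structural meaning.
* GLa uses 1/|S_ij|. Covariances can be negative and a negative penalty
  is ill-posed; the absolute value is the standard adaptive-lasso
  convention.
* Zero denominators (S_ij = 0, or absent tracts FD_ij = 0) receive a
  finite cap of 10× the largest finite raw weight. An infinite weight
  would turn the structural prior into a hard support constraint; the
  intent is guidance, not constraint. The factor 10 makes an absent
  tract roughly an order of magnitude more expensive than the weakest
  present one.
* Weights are rescaled so the mean off-diagonal weight is 1. Without
  this, the BIC-selected λ ranges differ by orders of magnitude between
  GL/GLa/GLd (raw 1/FD weights are O(10²–10⁴)) and λ values could not
  be compared or averaged across modes and subjects. A constant weight
  matrix therefore reduces GLa/GLd exactly to GL.

### Solver

Block coordinate descent on the working covariance with per-entry
penalties, the column subproblems solved by cyclic soft-thresholding
coordinate descent (numba-compiled). Sweep order is lexicographic and
deterministic. Convergence is declared when the relative max-norm
change of Θ between sweeps falls below `tol = 1e−6` (at most 500
sweeps; exhaustion returns the iterate with `converged=False` and a
warning). λ-grid searches warm-start each fit from the previous grid
point's working covariance and regression coefficients; warm and cold
fits agree to ~1e−7 entrywise. Solutions are verified in the test suite
against an independent proximal-gradient solver
(`scglasso.reference`, backtracking line search preserving positive
definiteness) to 1e−4 entrywise, and against the closed forms at the
two ends of the path (Θ̂ = S⁻¹ at λ = 0; Θ̂ = diag(1/S_ii) beyond the
full-shrinkage λ). Network density counts strictly-upper-triangular
entries with |Θ_ij| > 1e−8 · max_i Θ_ii — coordinate descent produces
exact zeros, the tolerance only guards round-off.

## Model selection

BIC = −2·loglik(Θ̂; S, n_eff) + m·log(n_eff) with
m = p + #{nonzero upper-triangle entries}, the standard Gaussian
graphical-model parameter count. Envelope samples are strongly
autocorrelated, so n_eff = n / (1 + 2 Σ_{k≤K} ρ̂_k) replaces n; the sum
runs to the first nonpositive sample autocorrelation (capped at n/4),
the initial-positive-sequence rule. Channels are combined by the median
of per-channel values — robust to a few strongly autocorrelated
channels. A constant channel returns n with a warning, and n_eff is
clipped into [1, n].

The λ search uses 20 log-spaced candidates from
λ_max = max_{i≠j} |S_ij|/W_ij (the smallest λ with a fully diagonal
solution) down to λ_max/1000, then up to three refinements, each
re-gridding 20 points over one grid step either side of the running
minimiser. Candidates whose density exceeds the cap (default 20 %;
`group_density_threshold` computes the data-driven value as the density
of the group-average structural network) are excluded from selection,
and BIC ties break toward larger λ (the sparser model). The selected λ
attains the minimum BIC among *all* evaluated admissible candidates.

Cross-validated comparison splits the time axis into k = 10 contiguous
blocks rather than random samples, respecting autocorrelation; within
each fold λ is selected by BIC on the training covariance only (GLa
weights likewise), and the fitted precision is scored by Gaussian
log-likelihood on the held-out block. Final, classification-ready
networks can be fit either at the per-subject BIC-selected λ (default,
`strategy="bic"`) or at the mean fold λ (`strategy="cv_mean_lambda"`,
ten times the cost); the default keeps the test suite and the
reproduction script fast and gave indistinguishable classification
results in development.

## Classification

Features are the strictly-upper-triangular precision entries in
row-major label order, standardized per feature using training-fold
statistics (mean/sd) — raw entries rather than partial correlations,
a recorded choice. Screening ranks features by two-sided Mann-Whitney
p-values computed on training rows only (vectorized normal
approximation with continuity and tie corrections; the single-pair
`mann_whitney_rank` uses exact enumeration for tie-free groups of up
to 8). Classifiers:

* **LDA** with the pooled covariance shrunk toward its diagonal,
  (1−γ)Σ̂ + γ·diag(Σ̂), γ ∈ [0,1]; γ = 1 is the diagonal (naive
  Gaussian) discriminant. Zero-variance features (precision entries
  that are exactly zero in every training subject) get a floored
  variance so the diagonal target stays positive definite; genuine
  collinearity at γ = 0 is rejected with advice to raise γ.
* **kNN**, Euclidean, k ∈ [2,10]; vote ties go to the class with the
  smaller mean neighbour distance, then the lower class index.
* **SVM** (cost fixed at 1) with the un-normalized polynomial kernel
  (1+⟨x,x′⟩)^d, d ∈ 1..6, and the RBF kernel exp(−‖x−x′‖²/2σ²),
  σ ∈ 10^{−5..5}.

Validation is outer stratified 10-fold CV with a fixed, logged seed;
for each outer fold an inner 10-fold loop over the training rows
jointly selects the feature count m ∈ {10, 25, 50, 100, 200, 310, 385,
all} and the family hyperparameter by mean inner accuracy (ties prefer
fewer features, then the earlier grid value). Outer predictions
aggregate into a single confusion matrix; sensitivity is the second
group's correct-classification rate and specificity the first's.
Feature stability reports, per feature, the number of outer folds that
selected it and the median absolute LDA weight across those folds;
features in ≥9 of 10 folds are flagged, and the top 1 % of features by
median weight among the flagged are marked for display.

## Synthetic cohorts

The generator emulates the statistical regime the estimator targets,
not the physiology: a random structural network at 20 % density with
log-uniform fiber densities in [1e−4, 1e−2] (the scale of
volume-normalized streamline counts), a sparse ground-truth precision
at 15 % density whose edges lie on the structural support with
probability 0.9 (off-diagonal magnitudes uniform in [0.2, 0.4] with
random signs, diagonal inflated to absolute row sum + 0.1, which
guarantees positive definiteness by diagonal dominance), and AR(1)
envelope series with φ = 0.5. The innovation covariance is scaled by
(1−φ²) so the stationary cross-sectional covariance is exactly Θ⁻¹ —
ground truth is usable in tests without deconvolving the filter. A
burn-in of 10/(1−φ) samples is discarded. Per-subject fiber densities
get multiplicative log-normal jitter (σ = 0.2) with fixed support,
mimicking between-subject tractography variability without changing
topology. Cohorts are bit-reproducible from their seed. Group B
multiplies 8 structurally supported precision edges
by 1.3, re-inflating the diagonal; this effect size was calibrated once
so that an ideal observer separates the groups with ≈0.95 accuracy —
strong enough for a meaningful classification benchmark, weak enough
that the problem is not degenerate.

What the generator does **not** emulate: oscillatory dynamics,
band-pass filtering and Hilbert envelopes (series are generated at the
envelope level directly), source leakage/cross-talk, non-Gaussian
heavy tails, and nonstationarity. Passing tests therefore demonstrate
correctness of the estimation and validation machinery under the
model's own assumptions, not robustness to real MEG artifacts.

## Problem sizes and numerical choices

Tests and the reproduction script run at p = 20 regions, 20 subjects
per group and T = 1200 samples per subject (T = 2000 for support
recovery, n = 20 000 for the ESS checks) — sizes chosen so the full
suite completes in a few minutes while keeping every qualitative
comparison well-powered (paired sign tests over 20 subjects, 50-
permutation nulls, 20-seed F1 averages). The real-data regime the
package is designed for (66 cortical Desikan regions; the reference
label list ships in `scglasso.io.desikan_66_labels`) is supported but
not exercised in the default suite.

Degenerate inputs are handled explicitly: constant series (ESS → n with
a warning), all-zero fiber densities (rejected — no structural
information), singular S at λ = 0 (rejected), every λ candidate over
the density cap (rejected with a diagnostic), identical pooled values
in the Mann-Whitney test (p = 1), and folds that cannot be stratified
(rejected).

## Known limitations

* The cross-sectional Gaussian model ignores spectral structure; the
  autocorrelation enters only through the effective sample size.
* When the true network density equals the search cap, the selected λ
  sits at the cap boundary and the estimate retains shrinkage bias that
  does not vanish with T; the likelihood-recovery test therefore uses a
  truth safely inside the cap.
* The adaptive weights are plug-in (single-stage); no iterated
  re-weighting is performed.
* Mann-Whitney screening is univariate and can miss jointly informative
  feature sets.
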