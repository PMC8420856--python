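# Methods

## Model

Antigen-specific serology measurements form a three-mode tensor
X ∈ ℝ^{I×J×K} (subjects × receptors × antigens) with an observation mask;
antigen-generic measurements form a matrix Y ∈ ℝ^{I×G} (subjects ×
glycans) sharing the subject mode.  The coupled factorization approximates

    X ≈ Σ_{r=1..R} a_r ∘ b_r ∘ c_r ,   Y ≈ Σ_{r=1..R} a_r ∘ d_r

with shared subject factors a_r.  The loss is the summed squared residual
over *observed* entries of both blocks.  Variance and R2X are defined as

    v_total = ‖X‖² + ‖Y‖²  (observed entries only)
    R2X = 1 − (‖X − X̂‖² + ‖Y − Ŷ‖²) / v_total

Q2X is the same quantity restricted to deliberately held-out entries.

Model assumptions: measurements are additively separable into a small
number of multilinear patterns after log-transformation and
per-measurement centering; missingness is ignorable in the least-squares
sense (entries are excluded from the loss, not modeled); tensor and matrix
blocks are comparable after variance balancing.

## Preprocessing

Raw values are clipped from below at an assay noise floor (defaults:
1.0 for the tensor block, 0.1 for glycan fractions; both configurable —
high-background panels may need 10.0), log-transformed (base 10 by
default; the base only shifts a global scale that centering and the factor
magnitudes absorb), and centered per measurement — each receptor–antigen
fiber and each glycan column — across observed subjects.  The matrix is
then rescaled so that ‖Y‖² = ratio × ‖X‖² over observed entries
(ratio 1 by default).  Equal variance keeps the factorization responsive
to both blocks; the ratio is exposed because the balance is a genuine
trade-off (raising it buys matrix R2X at the expense of tensor R2X).
Scaling happens after centering; the applied constant is recorded in the
dataset provenance for back-transformation.

## Fitting

**Censored least squares.** Each ALS update solves, per target column,
the least-squares problem using only rows where the target is observed.
Implementation: per-column normal equations batched with einsum — with
R ≤ ~10 components the Gram systems are tiny and the squared conditioning
is harmless.  Columns with no observed rows get zero solutions (needed
when entire fibers are deliberately deleted); exactly singular systems
fall back to the minimum-norm solution.

**Initialization.** Each mode's factors start as the leading R left
singular vectors of that mode's unfolding, with missing entries imputed
by a one-component EM-PCA model and entirely missing columns removed
(their rows zero-filled).  The subject mode uses the unfolding of the
tensor concatenated with the matrix, mirroring the coupled update.  SVD
sign indeterminacy is fixed deterministically (largest-magnitude entry of
each singular vector positive).  If R exceeds a mode size the extra
columns are zero-padded.

**ALS sweep.** A from [X₁ Y] against [(C⊙B)ᵀ Dᵀ]; B from X₂ against
C⊙A; C from X₃ against B⊙A; D from Y against A (⊙ = Khatri–Rao;
unfoldings use Fortran-order column indexing so these normal equations
hold verbatim).  Each update is an exact coordinate minimization, so R2X
is monotone non-decreasing across sweeps.  R2X is checked every 2 sweeps
and the fit stops when the absolute change drops below 1e-5 (the change
measure is absolute on the [0, 1] scale) or after 2,000 sweeps.

**Multi-start.** On exactly-low-rank data with heavy missingness,
single-start ALS can stall in a degenerate basin in which two components
collapse onto nearly collinear subject directions (observed persisting
beyond 3,000 sweeps, i.e. a stationary point rather than slow
convergence).  `FitConfig(n_starts=k)` supplements the SVD start with
k−1 seeded random starts and keeps the fit with the highest final R2X.
The default remains the single SVD-initialized fit; the exact-rank
recovery benchmarks use n_starts=4.

**Standardization for display.** Components are ordered by descending
explained variance (squared Frobenius norm of each rank-1 term, summed
over blocks).  Signs are flipped pairwise — (A,B) then (A,C), with D
following every A flip — so receptor and antigen columns have
non-negative mean while both reconstructions stay bit-identical.
Subject, receptor and antigen columns are divided by their max-abs value,
the removed tensor-block product recorded per component in `scale`;
glycan columns are not normalized per component (their relative scale is
informative) but absorb the subject-column scale so Y = A Dᵀ is exact.

## Imputation benchmarking

Two hold-out schemes: **chord** removes whole receptor–antigen pairs
across all subjects (default 15 pairs, 20 trials) — the structurally hard
task a flattened-matrix method cannot attempt, since it deletes entire
flattened columns; **entry** removes individual observed values (default
15 values, 10 trials).  Chord pairs are drawn from pairs with at least
one observation (on fully observed pairs, 15 pairs × 181 subjects = 2,715
held-out values).  Each trial masks the removals, refits at each R, and
scores Q2X on them; trials whose removal would empty a mode slice are
resampled.  Chord trials also score two naive baselines (observed mean
along the receptor or antigen dimension); entry trials also score
flattened EM-PCA completion.

The EM-PCA baseline iterates {fill missing with the rank-R SVD
reconstruction; refit} until the change in the imputed-value sum of
squares is below 1e-5 or 100 iterations; the monitored quantity is a
design choice (the convergence tolerance was fixed first).  No
re-centering is applied inside the loop, so on complete data the result
is exactly one truncated SVD.

## Supervised layer

Subject component weights are centered and variance-normalized, then:
continuous responses use elastic net (L1 fraction 0.8, 50-point
regularization grid auto-scaled from the data, strength by inner 10-fold
CV); binary classes use elastic-net-penalized logistic regression (same
L1 fraction, SAGA solver).  Performance comes from an outer 10-fold CV
whose folds are assigned independently of the inner folds (sharing them
systematically overfits); outer folds are stratified for classification
to avoid single-class folds.  Accuracy is the Pearson correlation of
held-out predictions (regression) or the fraction correct at probability
0.5 (classification; ROC/AUC available threshold-free).  The scheme is
repeated with reshuffled folds (default 10×) for a spread.  Reported
weights are rescaled to the original feature scale so they are comparable
across bootstrap resamples; weight stability is the standard deviation
across bootstraps of subjects drawn with replacement (default 20).
Subjects with a missing response are dropped per response.

Temporal component trajectories are summarized by
y = A/[1 + exp(−k(x − x0))] + C, fit by Levenberg–Marquardt from a fixed
initial point: A = 0.6 × range(y), C = min(y), x0 = median(x), k = ±0.5
with the sign chosen by comparing the means of the first and second half
of the time-ordered y values.  Non-convergence returns the initial-point
parameters flagged unconverged.

## Synthetic data

The generator draws all factor entries i.i.d. standard normal (a
heavier-tailed t(3) option exists for robustness checks), builds X and Y
as the Kruskal sums, adds homoscedastic Gaussian noise scaled relative to
the signal RMS (a per-fiber heteroscedastic option emulates assay
dynamic-range differences), applies entry-wise missingness and optional
whole-chord removal, and links outcomes linearly to the subject factors
(continuous: A·w + noise; binary: median/logistic threshold).  The
cohort-shaped presets fix sizes 181 × 22 × 39 + 181 × 25 (six components,
40% tensor missingness, glycan rows for half the subjects — matching the
~60% observed fill of the structure they emulate) and 438 × 6 × 11
(complete, two components, sampling times over ~4 weeks, severity groups
with group-specific sigmoid trajectories chosen so severe cases start and
end above moderate ones — illustrative, not calibrated).

What the generator does *not* emulate: real assays' marginal
distributions, batch effects, correlated (non-ignorable) missingness
patterns, or measurement-specific noise floors.  Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not performance claims about any particular cohort.

## Numerical choices and problem sizes

Convergence tolerances: ALS ΔR2X < 1e-5 (absolute); EM-PCA Δ(imputed
SSQ) < 1e-5; elastic-net coordinate descent and SAGA at library defaults
(tol 1e-3 for the logistic path).  Reconstruction invariance of
standardization holds to 1e-12; oracle-equivalence tests use 1e-8.
Benchmarks and the acceptance script run the cohort-shaped presets at
rank 3 (imputation, 20/10 trials) and rank 6 (recovery), the supervised
layer at 120 subjects with 3 fold-reshuffle repeats, and sigmoid recovery
on an 80-point curve — sizes chosen so a full run completes in minutes on
one CPU while staying at the shapes the method targets.

## Known limitations

- CP/CMTF degeneracy: ALS can stall with collapsed components on
  exactly-low-rank missing-data instances (see Multi-start).  On noisy
  real-scale data we have not observed this, but `n_starts > 1` is cheap
  insurance.
- The stopping rule is an absolute R2X change; very slowly converging
  fits (small modes with large R) can halt early.  Tighten `tol` when
  mode sizes are small relative to R.
- Censored normal equations square the condition number; for very
  ill-conditioned designs at large R a QR-based path would be preferable.
- The chord scheme assumes removals leave every mode slice with at least
  one observation; datasets already near that boundary will trigger
  resampling.
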