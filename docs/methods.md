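# Methods

`sparseconn` implements a sparse network-based discriminative pipeline for
two-group classification from regional time-series (typically BOLD fMRI),
with the hyperparameters selected jointly for predictive accuracy and
pattern reproducibility, and permutation-based inference on the resulting
connectivity pattern. This note records the model, the numerical choices,
and what the synthetic benchmark does and does not establish.

## Preprocessing

A subject's data is an `n_t × n_p` matrix of regional mean signals (when
voxel data are supplied, regional means are spatial averages over an integer
parcellation). Confounds are removed sequentially, each step a
residual-forming projection `R = I − C (C'C)⁺ C'`:

1. the six rigid-body motion parameters plus an intercept (the intercept is
   always included, so every cleaned column has zero mean — covariance
   estimation needs a mean convention);
2. a discrete-cosine drift basis with periods above a cutoff (default
   128 s), `K = floor(2 n_t TR / cutoff)` regressors. For a 180-scan, TR 2 s
   run this gives the conventional five regressors; `dct_k` forces a
   specific count for other geometries.

Because the two projections are applied sequentially (motion first), exact
orthogonality to the motion columns holds after step 1 and is only
approximate after step 2; the joint projector would differ by the overlap of
the two spans. Tests pin the exact property at the motion stage and bound
the residual leakage after drift removal. Global signal and task regressors
are deliberately not removed.

## Connectivity features

Per subject, from the cleaned series:

* covariance `Σ` (maximum-likelihood `1/n_t` scaling so that the Gaussian
  log-likelihood used below is exact; `1/(n_t−1)` by flag),
* Pearson correlation `Φ`,
* full inverse covariance `Π = Σ⁻¹` (requires `n_t > n_p` and a
  well-conditioned `Σ`),
* partial correlation `Θ_ij = −Π_ij / √(Π_ii Π_jj)`,
* sparse inverse covariance `Ω`, the positive-definite maximizer of
  `log det Ω − tr(ΩΣ) − λ‖Ω‖₁` with the L1 norm over **all** entries,
  diagonal included.

The graphical-LASSO solver is block coordinate descent. The full-entry
penalty has the same stationarity conditions as the off-diagonal-only
problem applied to `Σ + λI` (the optimal working covariance has diagonal
`σ_ii + λ`), which is how the solver is invoked; the equivalence is verified
in tests against an independent ADMM solver and the 2×2 closed form.
Sparsity comes from exact zeros of coordinate descent — never from
thresholding. Convergence is monitored by the duality gap (default
tolerance 1e-4, 100 iterations); non-convergence warns by default
(`on_nonconvergence="raise"` to escalate), since a modest residual gap does
not invalidate the downstream support-based statistics.

`λ` is selected on the grid {0.1, 0.01, 0.001} by the Bayesian Information
Criterion `BIC(λ) = −2L(Ω) + d log n_t` with `d = m(m−1)/2`, where `m`
counts nonzero entries over the lower triangle including the diagonal
(counting both symmetric copies is available by flag; the quadratic `d`
makes the criterion strongly sparsity-favoring either way). Selection runs
per group on time-concatenated training subjects in every inner fold; each
group's winner is the modal λ across folds, and the pooled λ is the
arithmetic mean of the two winners snapped to the nearest grid value on the
log10 scale (the grid is log-spaced; linear snapping would make the mean of
0.1 and 0.001 land on 0.01, which misrepresents its magnitude), ties toward
the larger (sparser) value.

Features are the `q = n_p(n_p−1)/2` strictly-lower-triangle entries in the
canonical order (column index ascending, then row index), identical across
subjects.

## Classification

The sparse classifier minimizes `‖w‖₁ + C Σᵢ max(1 − yᵢ w'xᵢ, 0)²` (squared
hinge); the dense comparator is the usual `½‖w‖² + C Σᵢ max(1 − yᵢ w'xᵢ, 0)`.
Both are bias-free — the decision function is `sign(w'x)`, with `sign(0)`
mapped to +1 so predictions are total — and solved by LIBLINEAR coordinate
descent. No feature standardization is applied by default (a z-scoring flag
exists and is fit on training folds only). The L1 support uses exact zeros
with a guard threshold of 1e-8; for the dense model an "effective support"
is obtained by zeroing the largest ascending-magnitude prefix of weights
whose cumulative sum stays within 1% of `‖w‖₁`.

## Nested cross-validation and stability

The outer loop is leave-one-subject-per-group-out: with `n_s` subjects per
group there are `n_s` folds, each holding out one patient and one control.
Pairing is by within-group position after sorting subject identifiers —
arbitrary but fixed and logged. Each outer fold runs an inner LOSGO loop
over the remaining `n_s − 1` pairs.

Stability of a set of supports is the mean chance-corrected pairwise
overlap `O(s,s') = (|I_s ∩ I_s'| − E) / max(|I_s|, |I_s'|)` with
`E = |I_s||I_s'| / q`, the hypergeometric expectation of the intersection of
two random supports of those sizes (this count-scale form is the
dimensionally consistent reading of the fraction-scale expression
`S(s)S(s')/q`). Two empty supports overlap 0 by convention (warned).

For every C on the grid (default 11 decade steps, 1e-5…1e5), each inner
fold yields a held-out accuracy and a support; `Ō(C)` aggregates the
supports across inner folds. Each inner fold votes for the C minimizing
`D = √((1−Acc)² + (1−Ō)²)` — its own accuracy against the shared `Ō` — and
the modal vote wins, ties toward the smaller (sparser) C. The alternative
"aggregate accuracy first, then argmin D" rule is available by flag
(`aggregate_inner`). With a single inner fold stability is undefined and
selection falls back to accuracy alone; with a single training pair the
inner evaluation degenerates to resubstitution.

The final model retrains on all subjects at the median of the per-fold
parameters, snapping an off-grid median toward the sparser grid point
(down for C, up for λ).

## Permutation inference

Accuracy significance: labels are uniformly permuted (group sizes are
preserved by construction; a within-pair stratified option exists), the
entire nested cross-validation is rerun per permutation, and
`p = max(1/n_perm, n_ge/n_perm)` where ties count as "equal or higher".
Permutation `b` uses seed `base + b + 1`, logged for exact replay.

Per-connection inference: each permutation additionally reruns the
median-parameter refit, giving a null sample of every weight. P-values are
two-sided (discriminative relevance is sign-agnostic), so an observed zero
weight has p = 1. The default test statistic is the *relative* weight
`|w_e| / ‖w‖₁` rather than the raw magnitude: the decision function
`sign(w'x)` identifies only the direction of `w`, and refits on permuted
labels carry systematically larger norms (less separable data pushes the
squared-hinge solution outward), so raw-magnitude comparisons confound
pattern with scale and lose power at moderate feature counts. Raw
comparison is available via `statistic="raw"`; at large feature counts with
small supports the two coincide, because a null refit almost never places
weight on any given connection. Benjamini–Hochberg FDR at q = 0.05 is
applied over the refit support (the set of connections actually under
test); correcting over all q connections is available by flag but, with
p-values floored at 1/n_perm, is so conservative that no edge can survive
at practical permutation counts. Significant edges and per-region degrees
(number of incident significant edges) form the discriminative network.

Because the per-subject connectivity features depend only on that subject's
own time-series, they are computed once and shared across permutations and
folds — a pure speed-up with no train/test leakage.

## Synthetic benchmark

The generator draws each group's subjects i.i.d. from a zero-mean Gaussian
whose precision matrix is a jittered copy of a group template. The base
template has a random sparse support (default 10% of pairs), off-diagonal
magnitudes U(0.25, 0.55) with random signs, and diagonal 0.6 plus the
absolute row sum (strict diagonal dominance ⇒ positive definite). The
magnitudes were calibrated once, during design, so that the implied partial
correlations are strong enough for BIC-path support recovery (F1 ≥ 0.8 at
n_t = 800) while remaining fMRI-plausible; they were then frozen. The
patient template differs on `n_diff_edges` planted entries (±`effect` on
currently-zero pairs, so the conditional-independence graph itself
differs). Positive definiteness after planting or jitter is restored by
diagonal inflation to a safe floor (minimum eigenvalue 0.2 for templates,
0.05 for per-subject jitter); inflating only to machine precision would
produce wildly ill-conditioned covariances.

Default study conditions mirror the event-related geometry at reduced
region count: 19 + 19 subjects, `n_t = 180`, TR 2 s, `n_p = 20` (q = 190),
5 planted edges of magnitude 0.5 — roughly a 3σ per-edge difference at this
series length — and subject jitter 0.02. Optional low-frequency cosine
drifts and motion-correlated random-walk components (with a matching
six-column motion record) exercise the preprocessing stage.

What the benchmark does *not* emulate: temporal autocorrelation of BOLD
(an AR-free i.i.d. default matches the estimators' likelihood; an
autocorrelated stress test can be built from the same pieces), hemodynamic
convolution, physiological noise spectra, inter-subject registration error,
and atlas geometry. Passing tests therefore demonstrate correctness of the
estimation and selection machinery under its own assumptions, not clinical
performance.

A known small-sample/fixed-penalty effect, visible in the tests: at fixed
λ = 0.01 the graphical LASSO recovers every true edge at large `n_t` but
retains a handful of small compensating false positives (soft-threshold
bias), so support F1 plateaus near 0.85–0.9 rather than 1.

## Problem sizes used in the shipped checks

The end-to-end checks run the full pipeline at the default study geometry
with a reduced hyperparameter search — C ∈ {0.1, 1, 10} (the mid-decades of
the full grid), λ fixed at 0.01 (the value the BIC selection picks on this
generator), SVM tolerance 1e-4 — and 50 label permutations; the null
calibration repeats a 10 + 10, 12-region, 120-time-point, zero-effect
version of the same generator over ten seeds with 20 permutations each.
These sizes keep the whole suite desk-scale while exercising every stage.
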