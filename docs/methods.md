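# Methods

## The model

`bantor` relates *distances between brain networks* to *differences in
covariates*. The data are repeated weighted networks: each subject *i*
contributes one symmetric correlation matrix **C**_ijk_ per task *j* and
repetition *k* (a "scan"), with unit diagonal and entries in [−1, 1]. For a
chosen metric, the response is the distance between two scans of **distinct**
subjects *a*, *d* on the **same** task *b*, for every combination of their
repetitions *c*, *f*:

    Dist_abc,dbf = x'_abc,dbf β_b + α_abc + α_dbf + b_{a,b;d,b} + ε_abc,dbf

* `x` holds a per-task intercept, absolute differences |x_a − x_d| of
  continuous covariates, and difference indicators 1{x_a ≠ x_d} of
  categorical covariates; each task gets its own coefficient vector β_b.
* `α` are scan-level fixed effects — one indicator per scan, two per row —
  absorbing scan-specific distance shifts.
* `b_{a,b;d,b} ~ N(0, g_b)` is a random intercept per **dyad** (unordered
  subject pair) and task, with a task-specific variance; it carries the
  correlation among the n_r² rows that compare the same two subjects.
* `ε ~ N(0, σ²)` iid; a single residual variance is shared across tasks
  (`task_specific_residual=True` relaxes this).

Because distances sharing a subject are correlated, ordinary least squares
(`fit_f_test`) and OLS with scan effects (`fit_f_test_sle`) are
anticonservative with repeated measures; they are provided for comparison
and for the degenerate single-scan case, where the mixed model provably
reduces to the scan-level-effects fit (and `fit_3m_bantor` falls back to it
automatically whenever every dyad-task group has a single row, which
happens exactly when there is one repetition per task).

## Distance metrics

All metrics act on the off-diagonal upper triangle; all but the
log-Euclidean metric also accept nodal degree vectors.

* **KS** — natural log of the two-sample Kolmogorov–Smirnov statistic
  between the two edge-weight ECDFs, computed exactly by evaluating both
  ECDFs at every pooled point. Identical multisets give a raw statistic of
  0; the log is then floored at log(1/n_edges) — the smallest nonzero value
  attainable at that sample size — and the pair flagged degenerate.
* **Jaccard** — (M01 + M10)/(M11 + M01 + M10) over key-edge indicators.
  Key edges come from `threshold_top_fraction`: exactly
  k = round(f · n_edges) edges, ranked by signed weight, ties broken by
  ascending row-major edge index so results are bit-reproducible. No
  positivity filter is applied: if fewer than k edges are positive the key
  set still has size k, keeping the Jaccard denominator logic intact.
* **EUC** — Euclidean norm of the edge-weight difference.
* **PCD** — (1 − r)/2 with r the Pearson correlation of the two edge
  vectors, mapping r ∈ [−1, 1] onto [0, 1].
* **LERM** — Frobenius norm of the difference of matrix logarithms,
  computed by symmetric eigendecomposition; any eigenvalue ≤ 1e−10 raises
  an error naming the offending scan (upstream smoothing targets 1e−6, so
  a healthy input clears this floor by four orders of magnitude).

## REML estimation

Every design row belongs to exactly one (dyad, task) group, so the marginal
covariance V = σ²I + ZGZ' is block compound-symmetric: per group of size m,
V_g = σ²I + g_b J. Both V⁻¹ and log|V| then have closed forms, and the
whole REML criterion reduces to a handful of dense p×p matrices
(p = covariate columns + scan indicators) precomputed once from the sparse
design — blocks of groups sharing (task, group size) contribute Gram
matrices A_b A_b' with A = X'Z. This is what lets the fit scale to the full
design (~2.4e5 rows, ~1.5e4 random effects) in seconds per evaluation.

With a shared residual variance the criterion is profiled over σ² and
optimized over log variance ratios λ_b = g_b/σ² by bounded L-BFGS-B
(relative tolerance 1e−8, at most 500 iterations, bounds e^±18.4 — the
lower bound acts as a zero floor and sets a boundary flag). The optimizer's
iterate history is retained so the monotone decrease of the criterion can
be monitored. The reported REML log-likelihood follows the lme4 convention
(including the (n−p)log 2π term), which the test suite exploits by
cross-checking an entire fit — estimates, standard errors, variance
components, log-likelihood and Satterthwaite p-values — against
lme4/lmerTest via Rscript, and the pooled-variance option against
statsmodels MixedLM.

**Inference.** Fixed-effect p-values use Satterthwaite's approximation
df = 2(l'Ĉl)² / (d'Ŵd), with Ĉ = (X'V̂⁻¹X)⁻¹, d the gradient of l'C(θ)l in
the variance parameters θ = (g_1..g_B, σ²) by central differences with step
1e−5(1+|θ|), and Ŵ the inverse observed REML information, computed as a
central-difference Hessian with step 2e−4(1+|θ|) plus one Richardson
extrapolation (the larger step with extrapolation balances round-off
against truncation; in a balanced two-level toy design this reproduces the
classical between-group df to 1e−6). Degrees of freedom are clamped to
[1, n−p]; at a variance boundary the clamp returns the residual df of the
scan-level-effects fit, which is the correct limit. No multiplicity
adjustment is applied by default.

**Identification.** Scan indicators are exactly collinear with the
per-task intercepts (the task-b indicators sum to twice the intercept), so
one reference scan per task is dropped up front; any remaining dependence
is resolved by an in-order greedy pivoted Cholesky that scans covariate
columns first, guaranteeing that only scan columns are ever dropped and
that covariate inference is invariant to the identification (tested by
relabeling subjects, which changes the reference scans). If a covariate
column itself lies in the span of the scan indicators — e.g. a categorical
level held by a single subject — the model is genuinely unidentifiable and
an error names the column.

## Permutation MDMR baseline

`mdmr_permutation` implements distance-matrix regression on the complete
per-task scan distance matrix (within-individual pairs included, as the
method requires): G = −½H(D∘D)H with H the centering matrix; each
predictor's pseudo-F compares tr(H_j G) (hat matrix of the full predictor
set minus the set without predictor j) to the residual trace; p-values use
the add-one permutation estimator (default 5,000 permutations), permuting
rows and columns of G jointly. On a univariate response with Euclidean
distances the pseudo-F reproduces the classical regression F exactly, which
the tests verify. The method ignores the correlation between scans of one
subject and is included only as a baseline; a random-effects variant of
MDMR is out of scope.

## The simulator

The generator emulates repeated-measures fMRI connectivity with a known,
tunable covariate signal; it is the ground truth against which type-I error
and power are measured.

* **Covariates.** SEX and TRT are fair coin flips; IQ and AGE are
  round(N(100, 15²)). Only IQ and TRT enter the generative process, through
  a = clip(0.15(IQ−100) + 2·1{TRT=Treatment} − 2·1{TRT=Placebo}, ±5.95);
  AGE and SEX are null covariates by construction. The clamp keeps both
  parameters of the signal distribution Beta(7+a, 7−a) strictly positive.
* **Background noise.** Σ1 is a random correlation matrix built from a
  Haar-distributed orthogonal Q (QR of a Gaussian matrix, sign-corrected):
  A = Q'DQ with D = diag(50·Beta(34, 2)), rescaled to unit diagonal and
  smoothed. Its off-diagonal entries concentrate near zero — the
  "low-connectivity" regime — and their absolute values form the noise
  pool of the signal mixture.
* **Correlation smoothing.** Eigenvalues floored at the tolerance
  (default 1e−6), matrix reconstructed and rescaled to unit diagonal,
  iterated at most 5 times; inputs already at tolerance are returned
  bitwise unchanged. Every emitted scan passes validation and is SPD, so
  the log-Euclidean metric is always defined.
* **Regions.** Each network carries three 15-node regions with
  compound-symmetric correlation: a single value r fills all 105
  off-diagonal cells of a region block per scan. Task 1 has one
  covariate-dependent (signal) region, task 2 two, task 3 three; the
  remaining regions are "high-connectivity noise" with r ~ Beta(5, 5).
  The signal edges are therefore 105/210/315 of the 35,778 edges at 268
  nodes — 0.3%, 0.6%, 0.9% per task.
* **Coupling.** Per subject and region, one latent 12-vector (3 tasks × 4
  repetitions) is drawn from a Gaussian copula with correlation 0.7
  within-task and 0.3 within-repetition. That matrix equals
  0.7·I⊗J + 0.3·J⊗I and is positive *semi*-definite (a 6-dimensional null
  space), so sampling goes through an eigenvalue factor rather than a
  Cholesky. Copula quantiles u are pushed through the target
  distributions, preserving rank correlation across scans.
* **Signal mixture.** A signal region's level at quantile u is the
  comonotone combination (1−s_p)·F_pool⁻¹(u) + s_p·F_Beta(7+a,7−a)⁻¹(u),
  where F_pool is the ECDF of |off-diagonal(Σ1)| and s_p ∈ [0, 1] the
  signal percentage. At s_p = 0 signal regions are exchangeable with noise
  draws (covariates carry no information — the basis of the type-I
  experiment); at s_p = 1 levels are pure Beta(7+a, 7−a), whose mean
  (7+a)/14 increases with IQ. Comonotone mixing keeps each level a
  monotone function of its quantile, so the copula's rank correlation
  survives the transform; an alternative that inverts the mixture CDF
  itself is available via `mixture="mixture-cdf"`.
* **Realization.** Each scan draws n_time = 2,500 points (an fMRI BOLD
  series length) of a 0-mean normal with covariance Σ1, overwrites each
  region's 15 columns with an independent compound-symmetric draw at that
  scan's level, takes the sample Pearson correlation matrix, and smooths.
  Overwriting a full-dimension draw (rather than composing block
  covariances) leaves non-region nodes with the exact Σ1 marginal while
  the sample correlations bordering regions absorb realistic edge effects.
* **Seeding.** master seed → per-subject stream → per-scan stream via
  `numpy` SeedSequence spawning, so any single scan is reproducible in
  isolation and datasets are bit-identical across runs.

## The study harness

`run_study` crosses signal percentage × metric × method, simulating a fresh
dataset per replicate (per-replicate seeds derive from the master seed,
signal level and replicate index, so any cell reruns in isolation and the
result is independent of the parallelism degree). Rejection rates at
α = 0.05 come with binomial Monte-Carlo standard errors; `power_crossing`
reports the first grid value reaching the power threshold (default 80%)
and flags curves that dip back below it.

**Problem sizes.** The package's default study profile is a reduced one —
30 subjects, 60 nodes, 200 replicates — chosen so a full type-I-error run
completes on a single CPU in minutes while preserving the qualitative
structure (three tasks, four repetitions, 15-node regions, 2,500-point
series). `StudyConfig.paper_scale()` switches to the full factorial design
(100 subjects, 268 nodes, 2,500 replicates, all metrics and methods, the
0–100% signal grid), which is cluster-scale work: reproducing the published
80%-power crossings per metric and task requires that configuration and
long parallel runs. At the reduced scale the tests verify type-I error
control, the anticonservativeness of the F-test alternatives, and that
power increases with signal percentage and with the number of signal
regions.

**A reduced-scale caveat.** With 60 nodes and 0% signal, task 3 (whose
three regions are all low-connectivity pool draws under the null) yields
nearly constant distances; the dyad variance estimate then sits on the
zero boundary and all methods become conservative for that task — its
contribution to pooled type-I error is below nominal, while tasks 1 and 2
calibrate tightly around 0.05. This is a property of the scaled-down
condition, not of the estimator: the signal-free contrast between
high-connectivity noise regions and the pool is what generates dyad-level
variance, and task 3 has no such regions.

## What the generator does and does not emulate

Passing tests show correct calibration and power behavior *under the
generative model*: Gaussian series, compound-symmetric regions, a single
global noise field, and exchangeable repetitions. Real fMRI violates all
of these in degree — temporal autocorrelation, heavy-tailed motion
artifacts, spatially structured noise, session drift — so empirical type-I
control on real data additionally depends on the scan-level effects and
dyad intercepts capturing those structures, which the tests cannot
establish. Directed networks, metrics beyond the five implemented,
geodesic means and other manifold statistics, and random-effects MDMR are
out of scope.
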