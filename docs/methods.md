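# Methods

## Data model and harmonization

A cohort is a genes × samples matrix of log-scale normalized expression
paired with a survival table (`time` > 0 in one declared unit per run,
default months; `event` ∈ {0,1}; optional covariates).  Cohorts are aligned
on the exact string intersection of their gene identifiers (no symbol
aliasing, no probe collapsing); missing expression values are rejected at
read time because every downstream solver assumes complete matrices.
Before modelling, each gene row is z-scored *within* its cohort (sample SD,
ddof = 1); constant genes are zeroed and flagged.  Coefficients of linear
models are therefore per-SD log-hazard ratios.

The pooled "Meta" cohort is built by per-cohort gene-wise z-scoring
followed by sample concatenation, dropping repeated sample ids (first
occurrence in cohort order wins).  Z-scoring is a location/scale batch
adjustment: it is deterministic, testable (per-cohort per-gene means are
zero by construction), and removes additive/multiplicative cohort effects,
but it is *not* an empirical-Bayes batch correction and does not address
covariance-level batch structure.

## Cox machinery

`fit_cox` maximizes the Cox partial likelihood by Newton–Raphson with
step-halving; Efron tie handling is the default (Breslow available), the
gradient max-norm tolerance is 1e-8 with at most 50 iterations, and
monotone likelihoods (separation) are capped at |β| ≤ 20 and flagged
non-converged.  P-values are Wald, (β/SE)² against χ²₁.  The likelihood,
gradient and Hessian are vectorized over tied-event groups so the
consensus screen (one univariate fit per gene per cohort; 20 000 fits on
the benchmark) runs in seconds.

The consensus rule selects a gene when it reaches Wald p < `p_threshold`
(default 0.05) in at least `min_cohorts` (default 8) of the K cohorts with
a consistent hazard direction *over the qualifying cohorts*.  Evaluating
direction only over qualifying cohorts keeps the rule well-defined when a
cohort's fit fails (a failed fit marks that cohort non-qualifying and never
aborts the screen).  "At least 8" is one reading of a rule that is stated
ambiguously in the motivating literature ("more than 8/10" vs "at least
8/10"); the integer is configurable.  No multiple-testing correction is
applied: replication across cohorts is the error control.

Absolute survival probabilities use the Breslow cumulative baseline hazard,
S(t|x) = S0(t)^exp(lp); with all coefficients zero this reduces exactly to
the Nelson–Aalen-based survival of the pooled sample.

## Penalized solvers

LASSO / ridge / elastic net are fitted by the package's own glmnet-style
solver: IRLS on the Breslow weighted-least-squares approximation with
cyclic coordinate descent and soft-thresholding (numba-compiled inner
sweeps), objective −(1/n)·pl(β) + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), a warm-started
descending λ path (100 values by default, λ_max zeroing all coefficients,
λ_min ratio 1e-4 when n > p), and fold-wise path evaluation during CV.  At
λ = 0 the iteration is plain IRLS and agrees with the Newton solver to
1e-4; ridge agrees with scikit-survival's penalized Cox to machine
precision (with the penalty convention λ_ours = alpha_sksurv / n).

CoxBoost is componentwise likelihood boosting: at each of M steps every
coordinate's penalized one-step Newton update U_j/(I_j + λ_pen) is
evaluated and only the coordinate with the largest penalized score
statistic U_j²/(I_j + λ_pen) is applied; ties break to the lowest index.
The penalty default is 9 × n_events (the canonical default of the
referenced boosting method); CV tunes only M (default grid 0…100 step 5).
With λ_pen = 0 and M large it converges to the unpenalized MLE.

## The ten learner families

All families sit behind one contract: `fit_learner(spec, cohort, cv)` →
`FittedLearner` with `predict`, a declared score orientation
(`higher_is_risk` for all Cox-flavoured families and the tree ensembles;
`higher_is_protective` for the survival SVM, whose regression formulation
predicts toward longer survival), and `select_features` for the four
selector-capable families (RSF, LASSO, CoxBoost, StepCox).  Hyperparameters
maximize the mean out-of-fold Harrell C-index over the grid (10 folds,
seeded shuffled K-fold; folds reduced with a warning if they exceed the
event count); ties go to the smallest-complexity grid entry; singleton
grids skip CV.  Selected genes are ordered by descending |coefficient| or
importance with lexicographic tie-breaks.

Backends: RSF, GBM (Cox partial-likelihood loss, depth-3 trees, shrinkage
0.1) and the linear survival SVM (regularization 1.0, regression
formulation) are scikit-survival estimators behind the module surface;
penalized Cox, CoxBoost, stepwise AIC Cox (forward from the null model,
backward/bidirectional from the full model), SuperPC (univariate-z
screening at a CV-chosen quantile threshold of |z|, PCA of the screened
submatrix with sign-fixed loadings, Cox on k ∈ {1,2,3} components) and
plsRcox (sequential components weighted by covariance with the current
martingale residuals, design deflation, Cox on the components, CV-chosen
component count) are implemented in-package.

RSF gene selection uses positive permutation importance measured on a
seeded internal 25 % holdout (the forest for importance is refit on the
remaining 75 %): training-set importance of deep trees is inflated on pure
noise, and the holdout keeps the "positive importance" threshold
meaningful.  The deployed RSF model is refit on the full training cohort.

Fitted learners serialize to a versioned archive (JSON metadata; TSV
coefficient tables written with %.17g and read back with round-trip float
parsing for linear families; a joblib state blob for tree/kernel models);
loading reproduces `predict_scores` bit-identically.

## Combination sweep

The default roster ships 76 combinations built by a documented rule — 20
standalone models (RSF, LASSO, CoxBoost, StepCox in its three directions,
GBM, SurvSVM, SuperPC, Ridge, plsRcox, and the nine elastic-net α
variants) plus the 4 selectors × 14 pure-modeler variants (GBM, SurvSVM,
SuperPC, Ridge, plsRcox, Enet × 9) = 56 pairs; the stepwise selector uses
bidirectional search.  A second "remodel" roster holds the 18 single-model
variants.  The engine itself is roster-agnostic: any explicit combination
list with unique labels runs.

`run_combination` fits the selector (if any) on the training cohort
restricted to the input genes, reduces to the selected genes, fits the
modeler, and only then scores the testing cohorts; testing outcomes can
never influence fitting (asserted in tests by poisoning testing outcomes).
Selector failures ("selector returned no genes") skip the row rather than
aborting the sweep — under a null outcome CoxBoost legitimately tunes to
M = 0.  The leaderboard ranks by mean testing C-index (training C is
reported, never ranked), ties broken by fewer genes then label; each
combination derives its own RNG stream from the master seed plus a CRC of
its label, so results are independent of execution order.  User-facing
signature scores are protective (higher = better outcome); concordance is
always computed on the negated, risk-oriented scores.  Median
stratification sends samples exactly at the median to the "high" group.

## Evaluation estimators

* Harrell's C with the usable-pair convention (the earlier time must be an
  event; equal-time both-event pairs are unusable; score ties count 0.5)
  and a pair-count SE, sqrt(C(1−C)/n_pairs).
* Paired C-index comparison: leave-one-out jackknife of ΔC (rows and
  columns of the pair matrices removed per subject), z = ΔC/SE_jack,
  two-sided normal p.  The jackknife is deterministic, unlike a bootstrap;
  degenerate variance returns p = 1 with a warning.
* Time-dependent AUC: IPCW cumulative-case / dynamic-control estimator
  with Kaplan–Meier censoring weights (cases weighted by 1/G(T⁻)); with no
  censoring it equals the plain empirical ROC AUC exactly.  Horizons with
  no cases or no controls are reported NaN and flagged.
* KM / log-rank: product-limit curves with Greenwood variance and the
  k-group log-rank χ²_{k−1} (generalized inverse when the variance matrix
  is singular).
* Calibration: samples binned by predicted-probability quantiles (default
  4); observed survival is the within-bin KM at the horizon with a
  Greenwood CI.  Because most learners emit only relative scores, absolute
  probabilities come from a univariate Cox of the outcome on the score plus
  the Breslow baseline — recorded in the report notes so curves are not
  misread as learner-native probabilities.
* External signatures are gene → coefficient tables applied as linear risk
  scores; missing genes are dropped (with a coverage report) or raise,
  per policy.

## Drug screen

Compounds with more than 20 % missing AUC or fewer than 10 observed lines
are excluded; remaining missing entries are excluded pairwise (no
imputation).  Ridge λ is chosen per compound by 10-fold CV over a fixed
grid, implemented with one SVD per fold shared across the λ grid; patient
expression is standardized with the cell-line panel's per-gene mean/SD.
The fold-change gate is log2(mean AUC in the low-score decile / mean AUC
in the high-score decile) > 0.2 — computed on means of raw AUC — together
with a two-sided Wilcoxon rank-sum p < 0.05; the correlation gate is
Spearman r < −0.4 over all patients with no p-value threshold.  Hits are
the intersection, sorted by r.

## Synthetic generator

Expression is block-equicorrelated Gaussian (default block size 10,
correlation 0.35 — co-expression-module-like collinearity); planted genes
carry per-SD log-hazard ratios.  Event times follow a Weibull
proportional-hazards model via the inverse CDF, t = scale·(−log U ·
exp(−lp))^{1/shape} (defaults shape 1.2, scale 30 months — a
median-survival-around-two-years, increasing-hazard regime typical of
aggressive tumours).  Censoring is an independent uniform(0, c_max) with
c_max found by bisection on E[min(T/c, 1)] so the realized censored
fraction matches the target; the default target 0.3 (0.25 in the
benchmarks) reflects the high event rates of pancreatic-cancer cohorts.
Cohort batch effects are a per-gene additive shift N(0, 0.5) and
multiplicative scale U(0.8, 1.25).  All draws descend from one
`SeedSequence`, so identical configs are bit-identical.

The generator emulates location/scale batch structure, module-level
collinearity and proportional hazards.  It does **not** emulate RNA-seq
count noise, non-proportional or time-varying effects, informative
censoring, or platform-specific normalization artifacts — so passing tests
demonstrate correctness of the machinery under the PH model, not
performance on real cohorts.

## Frozen benchmarks and their design

The self-contained claims are measured under conditions fixed a priori by
power analysis (`consurv.benchmarks`):

* **Screen benchmark** — 10 cohorts × 150 samples × 2000 genes, censoring
  0.25, twenty planted genes of |log HR| = 0.5 arranged as one hazardous
  and one protective 10-gene co-expressed module (block correlation 0.35),
  each module occupying its own correlation block.  The module structure
  matters: twenty *independent* effects of this size generate a composite
  linear predictor whose omitted-covariate attenuation pushes every
  marginal univariate z below the per-cohort power needed for an 8-of-10
  consensus, whereas co-expressed prognostic programs — the realistic
  configuration, and exactly what consensus screens find in practice —
  boost each member's marginal association without creating hitchhiker
  false positives outside the modules.
* **Sweep benchmark** — the same planted modules in a training cohort of
  160 plus nine testing cohorts of 120 (400 genes); the sweep receives 32
  input genes (the 20 planted + 12 nulls), mirroring a post-screen
  consensus panel.  Full-roster sweeps use reduced hyper-grids (30/20 λ
  values, CoxBoost M ≤ 50, 100-tree forests, two GBM sizes, four SuperPC
  thresholds) — problem sizes chosen so a two-sweep run (signal + permuted
  null) completes in minutes on one CPU.
* The null sweep permutes (time, event) jointly within every cohort; the
  best-of-76 mean testing C-index bounds the selection bias of the
  leaderboard (< 0.58 under the null).

## Numerical conventions and edge cases

Gradient tolerance 1e-8 (Newton), coordinate-descent tolerance 1e-7,
λ = 0 allowed; exp(η) clipped at e^±500; diagonal IRLS weights floored at
1e-10; empty screened set in SuperPC falls back to the single best gene;
constant genes z-score to zero; samples exactly at the median stratify
"high"; score ties in concordance count 0.5; lexicographic tie-breaks for
selected-gene ordering and leaderboard labels.  Degenerate inputs (no
events, all-censored concordance, zero gene overlap, decile groups < 5)
raise typed errors.

## Known limitations

The meta-cohort adjustment is location/scale only.  The consensus screen's
HR magnitudes depend on whether expression was standardized (the default)
— direction and p-values do not.  The 76-combination roster is shipped
configuration reproducing a published enumeration count whose generating
rule is not stated anywhere authoritative; the rule used here is
documented above.  The SVM is linear only; stepwise Cox is O(p²) model
fits and intended for post-screen gene counts (tens), not genome-wide
input.  The jackknife variance of ΔC and the pair-count SE of C are
first-order approximations; for small n or heavy censoring prefer the
comparison test over the marginal SE.
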