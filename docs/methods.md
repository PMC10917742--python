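# Methods

This note records what `evtgraph` computes, the assumptions behind it, and
the choices made where the design was genuinely open. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohorts

The generator emulates a single-center EVT registry of 220 anterior-
circulation stroke patients through group-conditional sampling: the 3-month
mRS level is drawn first (class mix 81/220 good, 97/220 poor-but-alive,
42/220 dead, spread over the seven mRS levels), then every variable is drawn
conditionally on the patient's outcome group.

* **Three outcome groups.** Published univariate tables give two overlapping
  binary splits (good/poor and alive/dead). Sampling conditionally on
  {good, poor-alive, dead} respects both: dead is a sub-event of poor
  (mRS = 6 ⊂ mRS > 2). Continuous poor-alive means are recovered from the
  mixture identity 178·alive = 81·good + 97·poor-alive; the poor-group SD is
  reused for poor-alive. For ordinal scores the printed poor column is
  reused for poor-alive (inverting a mixture of medians is not well posed),
  so the alive/dead margins of ordinal variables are approximate.
* **Ordinal scores** (NIHSS, ASPECTS, TAN, COVES, clot burden, TICI,
  pre-stroke mRS) are discretized normals matched to the printed median and
  IQR: μ = median, σ = IQR/1.349 floored at 0.5 so degenerate IQRs like
  0 [0–0] stay proper distributions. Realized medians land within one level
  of the target (tested).
* **Conditional independence.** Only group-conditional marginals are
  published, so variables are conditionally independent given the outcome
  group by default. An optional shared latent severity factor
  (`severity_corr` ∈ [0, 1)) correlates the continuous and ordinal variables
  within patients for sensitivity analyses; binary variables stay
  independent.
* **Missingness is MCAR**, applied per cell at each variable's rate. Rates
  are small (2–5%) except one filler lab variable at 15% that exercises the
  cleaning rule. Real registries likely miss informatively; nothing here
  models that.
* **What passing tests show.** Moment recovery, class balance, determinism
  and pipeline behavior on cohorts *with this structure*. They do not show
  performance on real data: real cohorts have correlated predictors,
  informative missingness, and effect sizes that need not match the printed
  summaries.
* `planted_spec` builds cohorts with controllable per-timepoint-block effect
  sizes (continuous signal variables with a chosen good/poor mean gap, dead
  shifted 1.5× further) for recovery and monotonicity tests.

## Preprocessing

Fixed order: drop variables with **strictly more than 10%** missing cells →
impute → encode → restrict to a timepoint → normalize.

* Imputation and normalization statistics are fitted on training rows only
  and applied everywhere (median for continuous, nearest level to the median
  for ordinal, mode for binary/nominal). A leakage test asserts fit
  statistics are bit-identical under test-row perturbation.
* Ordinal encoding is cumulative ("thermometer": level k of L → first k+1
  slots set), preserving order elementwise; nominal is one-hot; binary a
  single 0/1 column.
* Continuous columns are z-scored with the **sample** SD (ddof = 1);
  encoded 0/1 columns pass through unscaled (preserves sparsity and
  interpretability; `scale_encoded=True` overrides). Columns constant on
  the fit rows are dropped with a logged warning.
* Timepoint blocks are **cumulative** (admission ⊂ post-EVT ⊂ follow-up),
  matching the progressive-information design.

## Feature selection

Greedy mRMR with one-way ANOVA F relevance and mean |Pearson r| redundancy
against the selected set, k = 10, re-run per fold on train+validation rows.
The first pick maximizes relevance alone; later picks maximize
relevance − redundancy after min-max scaling both terms over the remaining
candidates (difference/MID form; quotient behind `scheme="quotient"`). Ties
break lexicographically by feature name. Two degeneracy rules: a perfectly
separating feature's F is capped at 10¹²; and a candidate whose |r| with any
selected feature exceeds 0.999 ranks behind every genuine candidate — an
exact copy adds no information, and without this rule the scaled difference
scheme can prefer duplicates over uncorrelated noise once all informative
directions are covered. Constant columns are excluded from the pool.

## Population graph

Edge weight = gate × similarity. The meta fields are standardized
cohort-wide before the correlation so age (scale: decades) cannot dominate
the 4-vector; gate thresholds apply to raw values (years). "Correlation
distance" is mapped to the affinity 1 − d_corr/2 = (1 + r)/2 ∈ [0, 1] so
that similar patients get *heavy* edges, which is what a convolution over
neighbors requires; the raw distance is available via `mode="distance"`.
Zero-variance meta-vectors get similarity 0 with a warning. Self-loops are
not stored — the spectral filter contributes its own self-term. The gating
grid search enumerates conjunctions of at most two conditions over
{age 1–10 y, pre-mRS 1–3 levels, NIHSS 2–10 points, sex equality}, rated by
mean validation AUC of a pluggable downstream trainer; the default is a
weighted neighbor-vote scorer (cheap, monotone in graph quality), and
`make_gcn_trainer` rates graphs with the actual network when the grid is
small. Ties resolve to the first rule in the grid.

## Graph network and uncertainty

Three ChebConv layers (input → 40 → 20 → 2; the output layer is also graph
convolutional), K = 3 (polynomial orders 0..3), ReLU between layers,
dropout p = 0.1 after each hidden activation (not on inputs), Glorot-uniform
initialization from the run seed, Adam lr 10⁻³ with weight decay 10⁻³
applied to weights only, masked cross-entropy over training nodes,
max 500 epochs with patience 30 on validation loss and best-weight restore.
λ_max of the normalized Laplacian is computed exactly (dense symmetric
eigensolve; graphs here are a few hundred nodes). Isolated nodes contribute
identity rows, keeping the spectrum of L̃ inside [−1, 1]. Forward, backprop
and the optimizer are hand-written in numpy; a dense-polynomial
eigendecomposition oracle checks the convolution to 10⁻⁸ on small
instances, and training is bit-reproducible given the config seed.

Uncertainty is the entropy (natural log) of the mean over T = 100
dropout-enabled passes — the printed formula read as its negated sum, since
entropy is non-negative and its binary ceiling ln 2 ≈ 0.693 matches the
stated 0-to-0.7 scale. The pass-to-pass SD of the positive-class
probability (population convention) is exposed as the spread-based
alternative. Neither is calibrated to error probability.

## Baselines and evaluation

LR (l2, C ∈ {1000, 100, 10}, newton-cholesky/liblinear), RF (trees
{2, 5, 10, 100}, max-features {log2, sqrt, 2, 5, 10, 100} with values
exceeding the matrix width filtered per fit, depth {5, 10, ∞}, bootstrap,
gini/entropy), FCN (fixed hidden sizes 128/64/32/16/8 — read as five hidden
layers plus output — solver sgd/adam, lr {0.1…10⁻⁴}; sklearn MLP), XGBoost
(depth {2, 4, 6}, subsample {0.6, 0.8, 1}, colsample {0.4–1}, γ
{0.5, 1, 1.5, 2.5}, 200 rounds with validation early stopping). Exhaustive
grid search maximizes validation AUC; ties take the first configuration in
deterministic grid order.

Stratified 5-fold plans keep per-fold class counts within one patient; a
stratified 20% of each fold's training rows forms the validation split, and
duplicate patient ids are forced into a common fold (group-aware variant).
Metrics: AUC, accuracy and balanced accuracy at a 0.5 probability cut.
Algorithms are compared by two-sided paired t-tests on per-fold AUC
(zero-variance differences report p = 1 with a warning). The univariate
table uses Student's t for continuous and plain Pearson χ² (no continuity
correction) for categorical variables, switching to Fisher's exact for 2×2
tables with an expected count below 5 (larger sparse tables keep χ² and are
flagged), with Benjamini–Hochberg adjustment across variables. The
uncertainty sweep uses the strict rule certain = {u < th} on the grid
0.1–0.7 (step 0.1); AUC is recorded as missing on single-class subsets.
Reported performance is the mean over fold-wise test metrics, not pooled
predictions.

## Problem sizes

Tests and the experiment examples run scaled-down configurations chosen to
exercise every code path at desk scale: cohorts of 120–300 patients (2000+
only for moment-recovery checks), 3 folds, reduced hyperparameter grids,
and 10-seed repetitions for the stochastic recovery and directionality
claims (pass marks at ≥ 8/10, or a mean AUC band for the permutation null).
The full published design — 220 patients, 5 folds, both tasks, all three
timepoints, five algorithms with full grids — is the default
`ExperimentConfig` and runs unchanged, just longer.

## Known limitations

* Synthetic cohorts cannot validate clinical performance claims; they
  validate machinery and qualitative behavior.
* Conditional independence given outcome group understates real predictor
  collinearity unless the severity factor is enabled.
* The FCN baseline is an sklearn MLP; optimizer schedules differ in detail
  from a hand-built torch network.
* The gating grid search's default scorer is a neighbor-vote proxy, not the
  full network; rules that help only through higher-order convolution
  effects could be under-rated.
* MC-dropout uncertainty is uncalibrated and is known to degrade out of
  distribution (e.g., cohorts from other centers).
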