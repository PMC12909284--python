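# Methods

`gsoelm` couples a glowworm swarm optimizer (GSO) to a ridge-regularized
extreme learning machine (ELM) for wrapper feature selection and
hyperparameter tuning on mixed-type screening tables. This note records
the model, its assumptions, the defaults and why, the numerical choices,
and what the synthetic-data experiments do and do not demonstrate.

## Preprocessing

A raw table is declared by a role schema (numeric / categorical / boolean
feature columns plus exactly one binary label with a declared yes/no
pair). The pipeline order is fixed: **impute → encode → scale**.

* Numeric imputation uses the mean of non-missing *training* entries;
  categorical imputation uses the modal training category with ties
  broken lexicographically (determinism). Imputation statistics, like
  scaler statistics, are refit inside every cross-validation fold, so a
  held-out row can never influence a statistic used to transform it.
* Categoricals one-hot encode against a vocabulary — by default the
  sorted set of observed training values, optionally pinned in the
  schema. Unseen categories at transform time are a hard error by
  default; a lenient all-zeros mode exists behind the `strict` flag.
  Yes/no history flags in the default screening schema are treated as
  two-column categoricals (No, Yes), matching the published encoded
  layout of the sample table; the single-column indicator encoder is
  used for the class label.
* Scaling kinds: `minmax` ((x−min)/(max−min), training extremes, no
  clipping of out-of-range test rows), `zscore` (population standard
  deviation), `robust` (median/IQR), and `unitnorm` (each encoded feature
  row divided by its Euclidean norm; no column statistics; all-zero rows
  left untouched). One-hot columns are never scaled column-wise — a
  z-score would destroy the {0,1} semantics of sparse indicators.
  Constant columns are an error under minmax/zscore/robust, naming the
  column. Numeric columns may declare known bounds (e.g. a 0–10 item
  score) used instead of observed extremes under min-max. The scaling
  kind is itself a tunable hyperparameter (see tuning).
* SMOTE-style oversampling (off by default) is applied only to the
  training design matrix after the train/test split: synthetic minority
  rows interpolate k-nearest minority neighbors; interpolated one-hot
  blocks are snapped back to a valid pattern by within-group argmax and
  boolean columns are rounded. If the minority class has ≤ k members, k
  is reduced with a logged warning.

The fitted `FeatureSchema` (vocabularies, group structure, imputation and
scaling statistics) serializes to JSON for exact round-trip.

## Extreme learning machine

A single hidden layer of L units with fixed random parameters:

* **sigmoid** — `H = g(XWᵀ + 1bᵀ)`, `g(z) = 1/(1+e^(−z))`, with W and b
  i.i.d. uniform on [−a, a] (default a = 1). The logistic is evaluated in
  its overflow-safe split form.
* **RBF** — `H_ij = exp(−‖x_i − c_j‖² / (2σ_j²))`, centers drawn
  uniformly inside the training-data column ranges. Squared distances are
  computed by the Gram decomposition `D = r1ᵀ + 1sᵀ − 2XCᵀ`; tiny
  negative entries from rounding are clamped to zero before the
  exponential. Widths default to the median pairwise center distance (a
  standard heuristic; no width rule is otherwise implied by the model)
  and are exposed in the config.

Output weights solve the ridge system `(HᵀH + λI)B = HᵀT` by Cholesky
factorization — never an explicit inverse, whose error is governed by
κ(HᵀH) rather than the much smaller κ of the triangular solves. When
L > N the algebraically identical dual form `B = Hᵀ(HHᵀ + λI)⁻¹T` is used
so the factorized system is always the smaller of L×L and N×N. Sample
weights (the `balanced` option sets w_c = N/(2N_c)) enter through the
square-root trick H̃ = Ω^{1/2}H. Regularization bounds the smallest
eigenvalue of the system from below by λ; `conditioning_report` returns
κ(HᵀH) and κ(HᵀH + λI) as diagnostics and asserts the λ floor up to
eigensolver rounding (which scales with ‖HᵀH‖). All computation is double
precision.

**Decision rule.** Binary problems regress a single {0,1} target column
(two-column one-hot targets are supported and give identical labels).
The decision score is the *class margin* of the regression output —
`t̂ − ½` for one column, `t̂₁ − t̂₀` for one-hot — so a margin of zero
lies exactly between the two target values; the probability is the
logistic of the margin and a label is 1 iff probability ≥ τ (non-strict,
default τ = 0.5). Thresholding the raw output's logistic instead would
put the boundary at raw output 0, i.e. below virtually every prediction
when targets are {0,1}, and degenerate to the majority class; the margin
form makes τ = 0.5 the natural operating point while preserving the
score-0 ↦ probability-0.5 ↦ positive-label boundary behavior.

## Glowworm swarm optimization

Agents in R^d carry position s, luciferin l and neighborhood radius r.
Per iteration each agent's objective is evaluated once, then
`l ← (1−ρ)l + γJ`; neighbors are the strictly brighter agents within
Euclidean distance r (non-strict radius, strict brightness); an agent
follows neighbor j with probability proportional to the luciferin excess
`l_j − l_i`, stepping β toward it plus uniform noise on
[−ε_scale, ε_scale]^d; the radius adapts by
`r ← clamp(r + α_r(n_t − |N|), 0, r_s)`.

Defaults follow the practitioner ranges of the method: G = 20 agents
(range 20–50), T_max = 50 (30–100), ρ = 0.4 (0.3–0.5), γ = 0.6
(0.4–0.8), β = 0.1 (0.03–0.2), n_t = 5 (3–7), r_s = 1. Choices the
method leaves open, fixed here:

* positions initialize uniformly on [−1, 1]^d so sigmoid-decoded masks
  start diverse (σ spans ≈ 0.27–0.73);
* luciferin initializes at 0 (the first update seeds it from fitness);
* an agent with no brighter neighbor — common early on — takes a pure
  noise step and keeps its luciferin;
* ε_scale defaults to 0.01 ("small" noise made concrete);
* r0 defaults to 0.1·√d: the space diagonal scales with √d, and a radius
  proportional to d itself would exceed r_s for d > 10; the literal
  0.1·d remains configurable;
* β anneals linearly from β to β/3 over T_max, an elite archive keeps
  the best `elite_count` positions ever evaluated (so best-so-far is
  non-decreasing), and the search stops after `patience` (default 20)
  iterations without best-objective improvement — the standard
  convergence practices for this optimizer family;
* non-finite objective values are treated as −∞ fitness with a warning;
* probabilistic ties are resolved by the seeded sampler.

`position_to_mask` uses the strict inequality σ(s_j) > τ as defined for
the transfer function (so the all-zero position decodes to the empty
mask), while the ELM label rule is non-strict ≥ τ; the two thresholds
are unrelated and each follows its own definition.

## Wrapper selection and tuning

Fitness of a mask m is `J(m) = Score_CV(m) − α‖m‖₁/d` with α = 0.1 by
default and Score_CV the mean validation metric (AUC by default —
imbalance-aware; balanced accuracy and plain accuracy are options) over
k stratified folds (default 5; 3 in the reduced-scale pipeline). An
alternative score-per-size ratio form `Score/(1 + α‖m‖₁/d)` is available
behind `penalty_form="ratio"`. The empty mask scores −1 without
training; if a run's best decoded mask is empty it is repaired by
enabling the most-frequently-selected unit so far (seeded random unit if
none). Fitness evaluations are memoized per mask — the swarm revisits
masks constantly, and the objective is deterministic given the fold
seed.

Group-level search (default for raw tables) works in R^G over original
variables and expands each selected group to its whole encoded block, so
one-hot blocks are never split. When the problem wraps a raw table, fold
matrices are rebuilt per fold with train-fitted statistics; category
vocabularies are pinned from the full table first, because a fold-varying
vocabulary would change the encoded width and scramble mask indexing —
vocabularies are table structure, not leakage-bearing statistics. A
single-class validation fold triggers one re-stratification with a new
seed, then an error.

The outer protocol in `run_pipeline` is a stratified 80/20 holdout
around the inner k-fold search; the holdout is scored once, after
selection and tuning. When noise injection or SMOTE intervene (both
operate on the encoded matrix), the inner folds reuse the outer-train
encoding rather than refitting per fold.

Hyperparameter tuning reuses the same swarm in a 4-dimensional space
whose unit-interval coordinates decode to L = round(20 + 180p),
λ = 10^(−6+8p), activation (sigmoid/rbf by half), and scaling kind (by
quartile); out-of-range coordinates clip. Neighbor/luciferin rules are
reused unchanged in this space. Tuning the L·d′ hidden weights
themselves by swarm is dimensionally explosive; it exists as an opt-in
(`tune_hidden_weights`) restricted to L ≤ 10 toy cases, and the default
tunes (L, λ, activation, scaling) only.

## Synthetic data

The generator emulates a majority-positive mobile screening sample:
class Bernoulli(0.69); ten binary items at class-conditional rates
0.7 (positive) / 0.15 (negative) whose sum is the 0–10 score; age
uniform on 12–36 months; sex 50/50; a six-category ethnicity prior
(0.30/0.20/0.15/0.15/0.10/0.10) echoing the published sample's
composition; jaundice (base 0.30) and family history (base 0.15) with a
1.5 odds multiplier in the positive class so they carry weak signal;
test completer 90% family member. Label noise flips labels
independently; missingness is MCAR over feature cells. The conventional
item-score cut-off (≥ 4) is available to re-derive labels from the
score. A separate planted-signal Gaussian generator
(`generate_planted`) provides known informative columns for recovery
experiments. `noise_inject` defines the noise-level sweep mechanism —
flip binary cells with probability p, perturb other numerics by uniform
noise of half-width p × column range — as a package convention, since
"noise level" otherwise has no operational definition.

What passing tests on this generator show: the pipeline recovers planted
signal, respects leakage discipline, and degrades under label/feature
noise in the expected direction. What they do not show: performance on
real screening populations — the generator's items are conditionally
independent given the class, demographics carry only the configured
signal, and missingness is MCAR, none of which hold in field data. The
published 20-row sample table ships as a fixture and is reproduced
cell-exactly through preprocessing; its printed class column has 14
positives among 20 rows (the accompanying prose describes 13/19 — the
fixture keeps the printed rows and the discrepancy is noted, not
reconciled).

## Evaluation and experiment sizes

AUC is the Mann-Whitney rank statistic with averaged ties (equal to
trapezoidal ROC integration); ROC/PR points are reported at every unique
score threshold; F1 uses the zero convention; a single-class truth makes
AUC NaN with a warning while threshold metrics are still returned.
Timing is recorded but never asserted.

Sweeps rerun the pipeline over one axis. The sample-size sweep is a
proper learning curve with common random numbers: per replicate one
super-sample is generated, each grid value trains on a *nested* subset of
the same training pool, and all of them are scored on the same 400-row
held-out block. Independently resampled cells with holdouts shrinking
with n would bury the curve's small slope under dataset-resampling noise
and make small-n accuracy too granular to order. Acceptance-scale experiments use:
100 random instances (N, L ≤ 20) for the solver property; 10 seeds of
G = 20, T = 50 for sphere recovery; 10 selection runs at G = 20, T = 30,
3 folds on 300×20 planted data; and 3 replicates per grid point for the
sample-size {100, 500, 1000} and noise {0, 0.05, 0.25} sweeps with a
light selection budget (G = 10, T = 10). Directional claims (accuracy
non-decreasing in sample size up to one 0.01 inversion; 25% noise
strictly below 0–5%) are asserted on these synthetic conditions;
absolute benchmark figures from external data are out of scope.

## Known limitations

* The ELM's random hidden layer makes small-sample scores seed-dependent;
  multi-run aggregation (selection frequencies, mean ± sd) is the
  supported remedy, not variance reduction inside a single run.
* Group-level selection assumes the schema's group structure is correct;
  column-level search on one-hot data can select semantically invalid
  partial blocks and is off by default for raw tables.
* The swarm is a stochastic local-search heuristic: no global-optimum
  guarantee; elitism plus annealing only stabilize what it finds.
* Multi-class labels, free-text fields, date parsing and non-MCAR
  missingness models are out of scope.
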