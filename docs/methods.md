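# Methods

`decliner` implements an explainable machine-learning screen for
biomarkers of rapid kidney-function decline in diabetic kidney disease
(DKD) cohorts: small samples (~135 patients, ~10 % positives), very wide
non-targeted metabolomics (thousands of features), and heavy,
informative missingness. This note records the model, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Outcome definition

Each patient contributes an eGFR series over four visits (months 0, 10,
20, 30). The annual change rate is the ordinary least-squares slope of
eGFR on month (units/month), annualised and expressed as a percentage of
the baseline (month-0) eGFR:

    rate = slope * 12 / eGFR(0) * 100   [%/yr]

Patients partition into four decline groups; group 4, `rate < -10 %/yr`,
is the *rapid decliner* — the binary target. Boundary convention: the
rapid cut is strict and every interval is closed on its right edge
(-10 → group 3, -3.3 → group 2, 0 → group 1). The label uses the single
full-period slope over all four visits; per-window slopes are exposed as
a diagnostic (`outcomes.window_rates`) but do not drive labelling.

## Encoding and the three-state missing flag

Binary variables map to ±1, multi-categorical variables of K levels to K
columns (+1 member, -1 others), ordinal variables to integer ranks, and
quantitative variables to z-scores over their observed entries
(population SD, divide by n — fixed so the documented examples are
exact). Every missing cell encodes to exactly 0, which contributes
nothing to a weighted sum — the invariant all downstream models rely on.
Each metabolite column carries a companion three-state flag: +1 when the
value fell below the assay sensitivity (type-1), 0 when it was not
measured (type-2), -1 when observed. Only metabolomic quantitative
variables get flags; clinical variables do not. Degenerate (constant)
columns are dropped with a logged warning; a metabolite's flag survives
even when its value column is degenerate.

## Point-wise linear classifier

The prediction is `sigmoid( sum_j w_j(x) x_j + b(x) )` where the weight
vector `w(x)` and bias `b(x)` are produced by a small densely
skip-connected network: hidden layer l receives the raw input
concatenated with all previous hidden outputs; the weight/bias heads
read the concatenation of all hidden outputs plus a free constant term.
With zero hidden layers `w` cannot depend on `x` and the model is
exactly L2-penalised logistic regression (`weight_decay` λ ↔ C = 1/λ,
biases unpenalised) — the oracle used in tests. Defaults: 3 hidden
layers of width 32, ReLU, weight decay 1e-3, full-batch Adam
(lr 0.01), positive class reweighted by inverse prevalence, early
stopping with patience 20 on the unpenalised cross-entropy of an
internal 20 % split. Implemented in numpy with hand-written gradients;
training is deterministic for a fixed seed.

Because the logit is point-wise linear in the inputs, each feature owns
an exact signed contribution `c_ij = w_j(x_i) x_ij`, and
`sum_j c_ij + b_i` reconstructs the logit to ~1e-8.

### Importance score

Per sample, a feature is *top-decile* when its weight magnitude
|w_j(x_i)| reaches the 90th percentile of that sample's weight
magnitudes (ties inclusive). With f_c(j) the fraction of class-c samples
ranking j top-decile, the unsigned score is (f_rapid + f_non)/2 — so a
feature top-decile in exactly half of one class and never in the other
scores 0.25, the auto-selection threshold. The sign is the direction of
the feature's mean signed contribution to the logit.

The decile ranks weight magnitudes, not contributions w·x: ranking
contributions lets constant-magnitude columns (flags are ±1 for every
sample) crowd the decile purely through their input scale, and planted
single-feature markers then fail to surface. The weight is what the
network itself computes as a feature's importance; the contribution
supplies the direction.

The explanation fit runs to convergence on the full data
(`validation_fraction=0` in the pipeline's train stage). At n=135 an
internal validation split holds ~3 positives; its CE is dominated by
noise and early stopping returns a nearly untrained model. Held-out
performance estimation is the cross-validation harness's job, not the
explanation fit's.

Selection: all features with |score| > 0.25, plus curated (biologically
motivated) names with |score| > 0.06, ranked by |score| and capped at 50.

## Double cross-validation

Ten random (unstratified) outer folds — for n=135 that is five training
sets of 121/test 14 and five of 122/test 13 — with a 5-fold inner grid
search maximising AUC on the training rows only. Encoding
standardisation statistics are refit inside each outer training fold
(`EncodedMatrix.values_for_rows`); a test fold that drew no positives
has undefined AUC and is skipped with a warning, and the fold maker
redraws once if any test fold lacks positives. Baselines: sklearn
logistic regression, random forest, and an RBF SVM whose probabilities
come from an explicit logistic (Platt) calibration of the training
margins — the library's internal cross-validated estimate can come out
anti-calibrated on cohorts this small. All four model families share
one fold plan per seed. Secondary metrics
(F1, accuracy, precision, recall, FPR, FNR) are computed at the
threshold maximising F1 over the observed probabilities (ties → lowest
threshold; `p >= t` is called positive).

## Exhaustive two-feature search

*PWL* models classify over a pair of continuous features with 2–4
boundary lines: `sigmoid(v0 + sum_k v_k relu(a_k x1 + b_k x2 + c_k))`,
fit by Adam on class-weighted CE with 3 seeded restarts per K ∈ {2,3,4},
best K by in-sample AUC. Flags and other discrete columns are
ineligible (of a 50-feature candidate set with 20 flags, 30 enter PWL).

*HCLR* models are 2-input logistic regressions over a handcrafted pool:
for every unordered feature pair {A,B} the five derived columns A+B,
A−B, A×B, A÷B, B÷A (A−B and B−A are collinear under a logistic
coefficient; the quotients are not), plus optionally the raw features.
Pool size is `n·[raw] + 5·C(n,2)` and the candidate-model count
`C(pool, 2)` — 4.12e14 at the full 3388-feature scale, which is why the
search runs on the ~50 selected candidates. Quotient columns are
clamp-guarded (denominator `sign(d)·max(|d|, 1e-3)`) and winsorised at
the 0.5/99.5 percentiles because z-scored inputs cross zero. Each fit is
an in-package damped-Newton solver (ridge 1e-8 for separable pairs),
~0.3 ms per model; coefficients agree with an unpenalised reference ML
fit to 1e-6. AUCs are in-sample — faithful to a screen that scores "all
possible" models, and optimistic in the usual in-sample sense.

Per-feature aggregates stream during the search: the *single frequency*
(number of high-AUC models containing the feature; thresholds 0.8 PWL /
0.9 HCLR), the mean AUC over all of the feature's models (PWL), and the
mean of the top 10 % of the feature's model AUCs (HCLR — a good
difference marker A−B necessarily spawns a bad sibling A+B, which would
drag a plain mean down). The interaction graph weights feature pairs by
high-AUC co-occurrence count (HCLR) or by the unique pair model's AUC
(PWL), prunes below threshold (500 / 0.8 at study scale), drops isolated
nodes, and reports the node of maximal weighted degree as the hub.

## Synthetic cohorts

The generator emulates the cohort the analysis assumes: 135 samples,
14/135 rapid fraction, eGFR baselines ~45 ± 8 (clipped to the 30–60
inclusion window), noise SD 1.5 on visits, log-normal metabolite
abundances (per-feature log-mean ~N(10,1), log-SD ~U(0.4,1.2)),
per-feature missing rates Beta-distributed around the configured means
(defaults 0.25 type-1, 0.05 type-2). Type-1 missingness censors the
latent log-abundance below the per-feature quantile of its target rate,
so every censored cell is genuinely below every observed one; type-2
strikes uncensored cells at rate r2/(1−r1), putting both marginal rates
on target in expectation. Clinical tables mix binary, one 4-level
multi-categorical, one ordinal, and continuous variables so every
encoding branch is exercised.

Planted effects act on the latent (pre-censoring) scale:

* `univariate_shift` — a mean shift of `effect_size` latent SDs in the
  rapid class;
* `ratio` / `difference` — the two features share a strong latent
  confounder (loading k=5) so each is individually weak (univariate
  Cohen's d = es/√(2(k²+1)), i.e. design AUC ≈ 0.64 at es = 3.5) while
  their standardized latent contrast separates the classes at
  `effect_size` SDs. Pair controls are generated as well-detected
  (type-1 rate 0) and moderately dispersed (log-SD 0.4) features: a
  value-combination marker planted in a heavily censored or extremely
  skewed feature is erased by the missing→0 z-score encoding before any
  search sees it, and would test nothing;
* `missingness_shift` — a downward latent shift in the rapid class, so
  the signal expresses itself chiefly through the censoring (flag)
  channel.

What the synthetic experiments show: the pipeline's own machinery
re-finds planted single markers (top-3 importance in ≥9/10 seeds) and
planted pair markers invisible to univariate screening (top-5 HCLR
frequency and a retained high-AUC pair model in ≥8–9/10 seeds), and is
calibrated under the null (permuted labels give outer-fold test AUC
within [0.35, 0.65] for all four model families; ≤5 % of features reach
q<0.05). What they do not show: performance on real metabolomics, whose
batch effects, correlated pathways, longitudinal drift and non-MCAR
type-2 missingness the generator deliberately omits.

## Problem sizes and numerical conventions

Desk-scale defaults keep every stage inside interactive budgets: ~40–60
metabolite features in pipeline runs, pair searches over ≤12 selected
features (pool ≤ 342, ≤ ~58k HCLR models at ~0.3 ms each), DCV with
compact inner grids. The 3311/3388-column study scale is reachable by
configuration; the exhaustive search cost is governed by `C(pool, 2)`
and guarded by a configurable model-count ceiling (default 2e6).

Other fixed conventions: binary levels take +1/-1 by lexicographic label
order; ties at the 90th weight percentile count as top-decile; the
max-F1 threshold resolves ties to the lowest candidate; Mann-Whitney p
is exact by enumeration when min(n1,n2) ≤ 7 with no ties and a
tie/continuity-corrected normal approximation otherwise; q-values are
Benjamini-Hochberg over the tested feature set; single-marker AUC is the
rank AUC (U/(n1·n2)) oriented ≥ 0.5.

## Known limitations

* HCLR AUCs are in-sample; an optional CV mode is not implemented.
* The PWL pair fit is non-convex; 3 restarts make it reproducible, not
  provably optimal, so the "PWL ≥ linear" hierarchy holds to a small
  tolerance rather than exactly.
* The weight network architecture is one reasonable realisation of a
  densely skip-connected design; importance scores depend on the fitted
  model and are meaningful only after convergence.
* With 14 positives, unstratified outer folds occasionally lack
  positives; such folds are skipped, which slightly reduces the
  effective fold count.
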