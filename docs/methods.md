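# Methods

This note records the statistical procedures implemented in `fairselect`,
the modelling assumptions behind them, and the design choices made where
the problem was genuinely open.

## The task

Given a flat cohort table (one row per participant; binary 5-year outcome
columns, categorical protected attributes, mixed numeric/categorical
predictors, possibly missing cells), choose among candidate binary
classifiers while weighing predictive accuracy against performance parity
across demographic subgroups, and explain the chosen model.

## Preprocessing

* **Complete-case analysis.** Rows with any missing value in a role column
  (outcome, protected, predictor) are dropped; no imputation. Missingness
  in columns without a declared role is ignored. With a 6% row-level
  incomplete rate this loses little data while keeping the estimand simple.
* **Reference dummy coding.** A categorical predictor with k declared
  levels becomes k−1 indicators named `feature=level`, against the first
  listed level. Reference coding (rather than full one-hot) makes single
  coefficients such as `gender=women` directly interpretable as contrasts;
  tree ensembles are insensitive to the choice.
* **Split.** Unstratified uniform 70/30 train/test partition; train size is
  round-half-up of `0.7·n` (9635 → 6745/2890). Stratification is exposed as
  an option but off by default, since the reference procedure is a plain
  random split.
* **Class weights.** Events are rare (9.1% MI, 2% stroke), so all model
  fits use balanced inverse-frequency sample weights
  `w(c) = n/(2·n_c)`, which equalise the aggregate weight of the classes.

## Model zoo

All candidate families sit behind one adapter contract: risk scores in
[0, 1] and margins equal to `logit(risk)` with risk clamped to
`[1e-12, 1−1e-12]` (risk and margin are a bijection on (0,1); downstream
stages never branch on family). Hyperparameters are chosen by mean
10-fold cross-validated AUC over a declared grid (unstratified folds,
deterministic given the seed; ties go to the earlier grid point), then the
model is refit on the full training matrix.

Specific choices:

* The penalized logistic family standardizes features inside the estimator
  (as glmnet does internally) so the elastic-net penalty is scale-free;
  `linear_coefficients()` back-transforms to the raw encoded scale.
* Mixed-integer optimal trees and exact sparse logistic formulations
  require proprietary solvers; the interpretable-model slots are filled by
  greedy trees limited to depth 3–4 and elastic-net logistic regression,
  behind the same adapter.
* SVM decision values are converted to probabilities by Platt-style
  sigmoid calibration inside the adapter so the risk contract holds.

## Assessment

* **AUC** is computed in rank-statistic (Mann–Whitney) form, ties counted
  1/2 — identical to the trapezoidal ROC area.
* **Operating threshold.** Candidate thresholds are the unique observed
  scores under the rule "positive iff score ≥ t"; the chosen t maximizes
  `u·sens + (1−u)·spec` with u = 2/3 by default, and objective ties break
  toward the lower threshold, i.e. higher sensitivity, matching the
  clinical preference for catching true events.
* **RPPS** `= 1 − max_s |AUC_s − AUC|/AUC` over the subgroups of one
  protected attribute, evaluated on the test set and threshold-free. It is
  deliberately not clamped at zero. A subgroup whose test rows carry a
  single outcome class has no AUC; it is excluded from the max with a
  warning rather than failing the whole report (silently dropping it would
  hide the problem; erroring would make small subgroups fatal). The base
  metric is AUC but the function accepts any per-subgroup metric map.
* All subgroups present in the data are evaluated unless the configuration
  restricts them.

## Selection

Scores `w·accuracy + (1−w)·RPPS` are affine in w, so each model is a line
and the best model at each w is the upper envelope. Accuracy here is the
threshold-dependent overall accuracy at the u-optimized operating point,
i.e. the same number the assessment stage reports. The grid default is
w = 0, 0.05, …, 1; ties are all reported rather than broken (the output is
advisory); crossovers between consecutive leaders are solved exactly as
rational line intersections, never grid-snapped.

## Explanation

* **Bootstrapped permutation importance** (default 100 replicates):
  resample training rows with replacement, refit the model, compute a
  baseline AUC on the out-of-bag rows, then permute each predictor's
  encoded column block (jointly, so a multi-level categorical moves as one
  unit) and record the AUC drop. Reported per feature: mean and percentile
  95% CI across replicates. Out-of-bag rows are used for the baseline
  because in-bag AUC is optimistically biased. Replicates with single-class
  out-of-bag rows are skipped (error if more than half are). Negative
  importances are preserved — they typically indicate the model fit noise
  on that predictor. Permuting a constant column is the identity, so its
  importance is exactly 0.
* **Shapley values** are computed on the margin (log-odds) scale with the
  training set as interventional background: additivity is exact there for
  linear models, and log-odds are the natural additive scale for risk
  models. For linear margins the closed form
  `phi_i = beta_i (x_i − E_bg[x_i])` is used. Otherwise a
  permutation-sampling estimator draws (feature ordering, background row)
  pairs and accumulates margin changes as the explained row's values are
  switched in; because contributions telescope and the base value is the
  mean margin over the *sampled* background rows, the efficiency identity
  `sum_i phi_i + base = margin(x)` holds exactly for every row, and the
  estimator reports a per-cell Monte-Carlo standard error. When the sample
  budget covers all pairs the enumeration is exhaustive and exact.
* **Relative Shapley values** divide each row by its total attribution
  `sum_j phi_j` (= margin − base), so relative contributions sum to 1 per
  row; rows with near-zero total attribution are flagged and excluded from
  the per-feature summary means. Normalizing by the total attribution
  (rather than by the raw prediction or by `sum |phi|`) is a documented
  convention choice: it is the only denominator under which the values are
  exact shares of the explained quantity.
* **Partial dependence**: the feature column is set to each grid value in
  every row and the model output averaged; grids are the observed unique
  values for (near-)binary columns and 50 equally spaced points over the
  observed range otherwise. Curves are emitted on both scales — mean risk
  and mean log-odds (the average of per-row margins, not the logit of the
  mean risk; for a linear model the log-odds curve is exactly affine with
  slope equal to the feature's coefficient). A histogram of observed
  values accompanies each curve so that regions of data scarcity are
  visible.
* `explain_model` composes the three, with partial dependence drawn for
  the top-k (default 3) features by mean permutation importance.

## Synthetic cohort generator

The generator emulates the structure of a large type 2 diabetes CVD trial
cohort so the framework can be exercised and tested without the
access-restricted data:

* Numeric biomarkers are independent normals with the published baseline
  means/SDs (age 62.8 (6.66), BMI 32.2 (5.4), SBP 136.5 (17.1), HbA1c 8.3
  (1.1), …); categorical variables are multinomial with the published
  fractions (38% women; 19%/7%/74% Black/Hispanic/White; 36% CVD history).
  A correlation hook exists for the numeric block but defaults to identity:
  the framework's correctness does not depend on realistic correlation,
  whereas a known-truth logistic structure is what the tests require.
* Outcomes are Bernoulli with logistic probabilities over reference-coded
  features; MI and stroke are conditionally independent given features,
  mirroring their treatment as separate classification tasks. Intercepts
  are calibrated by monotone bisection on a large fixed feature sample
  (n = 200 000, tolerance 1e-4) to hit the published prevalences (9.1% MI,
  2% stroke).
* The default coefficients are the generator's own ground truth (the real
  study's fitted values are data-dependent and unpublished beyond a few
  signs): CVD history dominates MI risk, HbA1c and systolic blood pressure
  drive stroke, and women and Black participants carry modestly negative
  MI coefficients (−0.32, −0.19) consistent in sign with the reported
  contrasts. Magnitudes were set once, scaled to the features' units, to
  give moderate discrimination (test AUC around 0.65–0.70 at realistic n).
* Missingness is MCAR: each row is flagged with probability 6% and one
  uniformly chosen predictor cell is blanked; outcomes and protected
  attributes are never blanked. Only a row-level incomplete rate is
  published, so a one-cell-per-row mechanism is the minimal model
  reproducing it.

What the generator does **not** emulate: feature correlations, survival
time / competing risks, treatment-arm effects, non-logistic outcome
mechanisms, and structured (non-MCAR) missingness. Passing tests therefore
demonstrate the correctness of the framework's mechanics on known-truth
data, not the clinical performance of any model on real trial data.

## Numerical and testing notes

* All randomness flows from explicit integer seeds; a single global seed
  fans out to stage-specific streams by fixed offsets (all derived seeds
  stay below 2^31). Identical spec + seed yields byte-identical cohorts
  and reports.
* Risks are clamped to `[1e-12, 1−1e-12]` before any logit.
* Test problem sizes: parameter recovery uses n = 50 000 (coefficients
  within 3 Wald SEs) and n = 100 000 (prevalences within 3 binomial SEs);
  oracle-equivalence property tests run on instances with n ≤ 50 against
  brute-force enumeration; bootstrap-importance checks use small cohorts
  with a fast linear refit so the full suite stays around a minute.
* Published parity-table cells are reproduced to the 3 printed decimals
  from the printed AUC inputs — all 28 (model, task, attribute) cells.
* Known limitations: RPPS is reported without a confidence interval (a
  natural extension, out of scope here); calibration metrics are not
  assessed; the selection stage scalarizes exactly two objectives
  (accuracy and one attribute's RPPS) and does not enumerate Pareto fronts
  across multiple attributes simultaneously.
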