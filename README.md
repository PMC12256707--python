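# fairselect

Fairness-aware **assessment, selection, and explanation** of clinical risk
classifiers on tabular cohorts.

Clinical risk models — e.g. classifiers predicting 5-year myocardial
infarction (MI) or stroke among people with type 2 diabetes — are usually
chosen by predictive accuracy alone, yet a model with a strong overall AUC
can discriminate much better for one demographic subgroup than another.
`fairselect` implements a three-stage workflow for choosing among candidate
binary classifiers with fairness and explainability on equal footing with
accuracy:

1. **Assessment.** Each model is scored on the test set by AUC and by
   sensitivity/specificity/accuracy at a threshold maximizing
   `u·sensitivity + (1−u)·specificity` (default `u = 2/3`, leaning toward
   sensitivity — missing a true cardiovascular event costs more than a
   false alarm). Fairness per protected attribute (gender, race, …) is
   summarised by the **relative performance parity score**

   ```
   RPPS = 1 − max_s |AUC_s − AUC| / AUC
   ```

   where `AUC_s` is the AUC conditional on subgroup `s`. RPPS = 1 means
   every subgroup matches the overall AUC; it is threshold-free, relative
   to each model's own AUC (hence comparable across models), and not
   clamped below zero.

2. **Selection.** Models are ranked by the weighted sum
   `w·Accuracy + (1−w)·RPPS` swept over `w ∈ [0, 1]`. The result is a
   trade-off curve per model, the best model at each `w`, and exact
   (rational, not grid-snapped) crossover points between dominance regions
   — an advisory map from a user's accuracy/fairness preference to a model
   choice.

3. **Explanation.** The chosen model is explained by three complementary
   views: bootstrapped permutation importance (resample → refit →
   out-of-bag AUC drop per feature, with 95% percentile CIs, 100 replicates
   by default), Shapley values on the log-odds scale (exact closed form for
   linear models, a permutation-sampling estimator otherwise) normalized to
   per-row **relative** Shapley values, and partial dependence curves on
   both the risk and log-odds scales with a data-density histogram.

Because real trial cohorts of this kind are access-restricted, the package
ships a synthetic cohort generator (`fairselect.cohort`) that mirrors the
published baseline characteristics of a large type 2 diabetes CVD trial
(N = 9635; 38% women; 19%/7%/74% Black/Hispanic/White; 36% CVD history;
MI prevalence 9.1%, stroke 2%; ~6% incomplete rows) with a known logistic
outcome mechanism — so every stage is testable against ground truth.

## Worked example

```python
from pathlib import Path
from fairselect.cli import run_assess, run_select

cfg = {
    "seed": 42,
    "data": {"synthetic": {"n": 9635, "missing_rate": 0.06}},
    "outcome": "mi",
    "protected": ["gender", "race"],
    "models": {
        "glmnet-like": {"family": "penalized-logistic", "grid": {"C": [0.1, 1.0]}},
        "cart-like":   {"family": "decision-tree",      "grid": {"max_depth": [3, 4]}},
        "naive-bayes": {"family": "naive-bayes"},
    },
}
frame = run_assess(cfg, Path("out"), seed=42)
curve = run_select(cfg, Path("out"), seed=42)
```

prints (abridged):

```
      model   auc  sensitivity  specificity  accuracy  auc[gender=men]  auc[gender=women]  rpps[gender]  rpps[race]
glmnet-like 0.670        0.875        0.300     0.356            0.698              0.631         0.943       0.946
  cart-like 0.653        0.868        0.272     0.330            0.671              0.623         0.953       0.996
naive-bayes 0.654        0.936        0.155     0.231            0.681              0.620         0.949       0.932
```

and the gender trade-off regions:

```
[{"w_lo": 0.0, "w_hi": 0.278, "best": ["cart-like"]},
 {"w_lo": 0.278, "w_hi": 1.0,  "best": ["glmnet-like"]}]
```

Reading: the depth-limited tree has the best gender parity (RPPS 0.953),
so it leads while fairness dominates the criterion (`w < 0.278`); beyond
that the penalized logistic model's higher accuracy takes over. The
crossover 0.278 is the exact intersection of the two models' score lines.
All three stages are also available from a shell:

```
fairselect synth|assess|select|explain --config run.yaml [--out DIR] [--seed N]
```

Every run writes a `manifest.json` (config hash, seed, library versions)
sufficient to reproduce its outputs exactly.

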