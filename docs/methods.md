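# Methods

## Problem setting

Given a cohort `D` of participants with predictor vector `x_i` and a set
`Y_i ⊆ L` of chronic conditions (|L| = 10 by default), the task is
multilabel classification: predict the condition subset `Z_i` for new
participants. Multimorbidity is the event |Y_i| ≥ 2. Three features of
such cohorts drive the design: conditions co-occur (so label dependence
carries signal), their prevalences are strongly imbalanced, and the
practical value of a model grows as the predictor set shrinks.

## Evaluation metrics

All metrics are example-based (averaged per instance, then over
instances). Precision divides the per-instance overlap by |Y_i| and
recall by |Z_i|; this is swapped relative to the usual
information-retrieval convention but is kept deliberately — the F-measure,
a harmonic mean, is unaffected by the swap. Zero-denominator instances
contribute 1 when both the true and predicted sets are empty and 0
otherwise; this convention keeps every metric total and inside [0, 1] and
preserves `subset_accuracy ≤ accuracy`. F is computed from the
dataset-level precision/recall averages, not per instance. All
definitions are tested to 1e-12 against an independent per-instance
set-arithmetic oracle.

## Imbalance and oversampling

Cardinality, density, IRLbl and MeanIR follow the standard definitions;
a label with zero occurrences raises an explicit error rather than a
silent infinity. ML-ROS oversampling clones uniformly chosen carriers of
minority labels (IRLbl above the current MeanIR), updating label counts
after every clone so stopping is exact, and re-deriving the minority set
each sweep. The clone budget defaults to 25% of n — the resampling
literature's usual default; the source reports applying IRLbl-based
oversampling but not its percentage. Clones are exact copies and the
original rows are always retained, so MeanIR can only move toward balance
(property-tested over random datasets).

## Classifiers

BR, CC and DBR share a base-learner contract (`fit`, probabilistic
`score`), implemented over scikit-learn random forests and RBF SVMs
(standardized inputs, Platt-scaled probabilities). CC trains each label
on the *true* values of its chain predecessors and predicts sequentially
on thresholded predictions; the chain order defaults to the dataset's
label-column order and is stored on the model because results depend on
it. DBR is the standard two-stage form: stage 2 trains on all *other*
true labels as features, and an internal BR stage supplies those label
estimates at prediction time. The probability threshold is 0.5 with ties
predicting positive. A label constant in a training partition is handled
by a constant-rate predictor instead of failing the fold.

The multivariate random forest adapts the tree itself: a split's score is
`Σ_l w_l · ΔGini_l / Gini_l(parent)` over labels not already pure at the
parent. Normalizing per-label decreases by parent impurity puts rare and
common conditions on a comparable scale before pooling. The default
weight structure is uniform (identity covariance); a compound-symmetry
option weights each label by its mean absolute correlation with the
others, so strongly co-occurring conditions steer splits. An
autoregressive structure is not offered — it presumes an ordering, which
unordered disease labels do not have. On single-label data with uniform
weights the criterion reduces exactly to the classical normalized Gini
decrease (tested against a scalar oracle).

Numeric splits are placed at midpoints of adjacent sorted values;
categorical levels are ordered once per forest by pooled positive-label
rate and then treated as ordered (the classical ordered-level reduction).
Defaults: 500 trees, mtry = ⌈√p⌉, min node size 5 — standard forest
practice. Permutation importance permutes a feature across the
out-of-bag-covered rows, recomputes out-of-bag predictions, and reports
the mean increase of the selected multilabel loss (Hamming by default)
over the configured number of runs (default 100).

## Feature selection

BR+IG computes information gain (bits, base-2, 0·log 0 := 0) for every
(feature, label) pair on the binary-relevance decomposition. Numeric
features are discretized into 10 equal-frequency bins; missing values
form their own bin, so selection never depends on imputation.
Aggregation across labels is the unweighted mean (max available by
config); ties break lexicographically for determinism.

## Cross-validation harness

Folds come from iterative stratification: labels are processed rarest
first and carriers assigned to the fold with the largest remaining demand
for that label, with fold-capacity enforcement so sizes stay within one
instance. Per outer fold the harness (1) fits a median/mode imputer on
the training partition (by default applied to both partitions; a
"separate" mode fits the test partition its own imputer), (2) optionally
oversamples the training partition, (3) tunes hyperparameters by inner
3-fold CV minimizing Hamming loss over a small grid (forests:
mtry ∈ {⌈√p⌉, p/3}, min node size ∈ {5, 20}; SVMs: C ∈ {0.1, 1, 10},
γ ∈ {1/p, 4/p}), and (4) fits and scores. In feature-curve runs the BR+IG
ranking is recomputed on each training partition by default; a global
single-ranking mode exists for comparability with workflows that rank
once. A master seed spawns per-repeat/per-fold child seeds, making whole
experiments bit-reproducible. An optional audit trail records the row
indices consumed by imputation, oversampling, selection and tuning, and
the tests assert that no test-partition row ever appears there.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
joint distribution. Thirty-one predictors (age, sex, education, race,
marital status, income, children, maternal education, smoking, alcohol,
physical activity and days, sleep flags, fruit/vegetable/coffee
consumption, BMI, systolic/diastolic BP, heart rate, waist–hip ratio and
nine family-history flags) are drawn with mild realistic dependence (age
drifts blood pressure and BMI; sex shifts the waist–hip ratio; income is
log-normal). Each condition follows a logistic model on named
standardized covariates plus two shared standard-normal latent factors: a
cardio-metabolic factor loading on the dyslipidemia, diabetes, heart- and
kidney-disease analogs and a musculoskeletal-mental factor loading on the
common-mental-disorder, migraine and joint-problem analogs. The factors
create label co-occurrence beyond what the predictors explain — exactly
the signal that CC, DBR and the multivariate forest can exploit and BR
cannot.

Default prevalence targets: the three largest are the published cohort's
printed values (0.442, 0.295, 0.267); the remaining seven (0.216, 0.198,
0.143, 0.112, 0.085, 0.058, 0.044) are plausible values chosen once so
the target cardinality is 1.86 and the implied MeanIR ≈ 3.83. Effect
sizes are set so the BMI analog carries the largest aggregate signal,
followed by blood pressure, age and sex. Missingness is 2% completely at
random on features only. Intercepts are calibrated by Brent root-finding
on the expected prevalence `mean_i sigmoid(α + η_i)` over a fixed
reference sample of 40,000 linear predictors, which is deterministic,
monotone and accurate to the Monte-Carlo error of the generated cohort
(~0.4 pp at n ≈ 15,000 for the most prevalent label).

What passing tests do *not* show: the generator is conditionally
independent across participants, has no center effects, no survey
weights, no measurement error model, and its categorical distributions
are stylized. Results on it demonstrate that the pipeline recovers
structure it is known to contain, not that the same accuracy would hold
on a real cohort.

## Problem sizes used in the test suite

The scientific checks are run at sizes where their conclusions are
stable: metric/imbalance oracles use thousands of small random matrices;
dependence recovery uses 4-label latent-factor cohorts of n = 2,000 over
20 seeds with strong loadings (2.0) — a regime where dependence-aware
methods must pay off — with a 2-percentage-point bound (an order below
the observed effect) defining "indistinguishable" in the zero-loading
null; structure recovery uses 20 default cohorts of n = 900 with 40-tree
forests of minimum node size 40 (shallow trees stabilize permutation
importance at this n) and 5 permutation runs. The acceptance script uses
the full default n = 14836.

## Known limitations

* CC uses a single chain order; ensembles of chains are out of scope.
* The forest has no surrogate splits; predictors must be imputed first.
* SVM probabilities come from Platt scaling inside scikit-learn and can
  be poorly calibrated on small folds.
* Information gain with many-level categoricals is biased upward; the
  equal-frequency binning bounds this for numeric features only.
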