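# caseadapt

Retrieval-driven, case-adaptive classification with Gaussian-prior
regularization, for computer-aided diagnosis (CADx) feature vectors.

## The problem

A CADx classifier for breast lesions is typically a logistic-regression
model pretrained offline on a fixed training set: it maps a vector of
image-derived features (e.g. nine morphology and intensity statistics of a
cluster of microcalcifications) to a probability of malignancy.  A single
global linear model, however, cannot follow a decision boundary that bends
across feature space.  When a reference library of cases with known
pathology is available, one can do better *per query*: retrieve the
library cases most similar to the lesion at hand and refit the classifier
locally — anchored to the global model so that a handful of retrieved
cases cannot drag it into overfitting.

`caseadapt` implements this scheme end to end for users who have tabular
case libraries (CSV, one row per lesion: d features + a benign/malignant
label): baseline training, similarity retrieval, the regularized per-query
refit in several variants, ROC/AUC bootstrap evaluation, cross-validated
hyperparameter selection, a synthetic benchmark generator, and experiment
runners — all exposed as scikit-learn-style estimators plus a thin CLI.

## The model

The baseline discriminant w̄ (bias absorbed via an augmented input
x̃ = [1, x]) maximizes the logistic log-likelihood over the N training
cases

    L(w) = Σᵢ log p(yᵢ | xᵢ; w),      p(y=1 | x; w) = σ(wᵀx̃),

solved by damped Newton–Raphson.  For a query x, the N_r nearest library
cases (Euclidean distance in z-scored feature space) are retrieved and
weighted by normalized Gaussian similarity

    βⱼ = γⱼ / Σₖ γₖ,      γⱼ = exp(−‖xⱼ⁽ʳ⁾ − x‖² / σ²),

with bandwidth σ set to the 10th percentile of pairwise training
distances.  The adaptive discriminant maximizes the retrieved,
similarity-weighted likelihood under a Gaussian prior centered at the
baseline:

    L_Uni(w) = Σⱼ βⱼ log p(yⱼ⁽ʳ⁾ | xⱼ⁽ʳ⁾; w) − (C/2)‖w − w̄‖².

This is a MAP estimate: a second-order expansion of L about w̄ yields the
exact prior N(w̄, [−∇²L(w̄)]⁻¹) (available as `method="full_hessian"`);
the isotropic approximation above is the default.  C interpolates between
retraining on the retrieved cases alone (C = 0, the overfitting-prone
ablation) and returning the baseline unchanged (C → ∞); it is chosen by
10-fold cross-validated AUC over the grid
{0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1, 5, 10, 100}.

A query-varying prior is also provided: one adaptive vector wᵢ per
training case is pretrained by maximizing the coupled objective

    L̃(w₁, …, w_N) = Σᵢ log p(yᵢ | xᵢ; wᵢ) − (C′/2) Σᵢ ‖wᵢ − w̄ᵢ‖²,

where w̄ᵢ is the similarity-kernel average of the other cases' vectors;
at query time the prior mean w̄_Var = Σᵢ cᵢ wᵢ is interpolated with the
same kernel and substituted for w̄ in L_Uni.  The earlier full-retrain
adaptive classifier (training set plus emphasized retrieved cases, weights
greater than 1) is included as a comparison arm.

Evaluation uses the empirical (Mann–Whitney) AUC with percentile bootstrap
confidence intervals (2000 case resamples) and paired-bootstrap p-values
for classifier differences.

## Worked example

Real CADx case libraries are not public, so the package ships a generator
that emulates the study regime: 9 features, a 175-case training set
(100 benign / 75 malignant), an equally sized test set, and a 656-case
retrieval library (446 / 210), with a class boundary that varies across
feature-space regions so that local adaptation genuinely helps.

```python
from caseadapt import (
    SyntheticSpec, generate, BaselineLogistic, AdaptiveUniformClassifier,
    ScoredTestSet, bootstrap_auc,
)

train, test, library, meta = generate(SyntheticSpec(seed=1))

baseline = BaselineLogistic().fit(train.features, train.labels)
print(f"baseline: converged in {baseline.n_iter_} Newton iterations, "
      f"sigma = {baseline.sigma_:.3f}")

adaptive = AdaptiveUniformClassifier(n_r=50, C=0.2).fit(
    train.features, train.labels,
    library=(library.features, library.labels),
)

for name, clf in [("baseline LR", baseline), ("Ada-Reg-Uni", adaptive)]:
    scores = clf.predict_proba(test.features)[:, 1]
    report = bootstrap_auc(ScoredTestSet(scores, test.labels), seed=0)
    lo, hi = report.bootstrap_ci
    print(f"{name:12s} AUC = {report.auc:.4f}  (95% CI {lo:.4f}-{hi:.4f})")
```

Output:

```
baseline: converged in 5 Newton iterations, sigma = 2.888
baseline LR  AUC = 0.6947  (95% CI 0.6192-0.7700)
Ada-Reg-Uni  AUC = 0.8121  (95% CI 0.7464-0.8712)
```

The baseline's global linear boundary reaches AUC 0.69 on this data while
the per-query adaptive refit reaches 0.81 — the gap is exactly the local
boundary structure a single linear model cannot express (the generator's
Bayes-optimal scorer attains 0.92 here, an upper reference).

The same pipeline is available from a shell:

```sh
caseadapt generate --seed 1 --out data/
caseadapt fit-baseline --train data/train.csv --out model.json
caseadapt classify --baseline model.json --library data/library.csv \
    --query data/test.csv --nr 50 --C 0.2 --out predictions.csv
caseadapt nr-sweep --seed 1 --out sweep/     # all arms vs N_r
caseadapt c-sweep  --seed 1 --out csweep/    # AUC vs C at fixed N_r
```

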