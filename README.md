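# radbench

Benchmarking class-resampling methods on high-dimensional, correlated,
imbalanced feature tables of the kind produced by radiomics pipelines
(quantitative shape/intensity/texture features extracted from medical
images, hundreds to thousands of columns, tens to hundreds of rows).

Radiomic datasets are frequently class-imbalanced — the positive class can
be several times smaller than the negative one — and resampling methods
(SMOTE and friends) are routinely applied to "fix" this before model
training. `radbench` provides the machinery to measure what resampling
actually does, both to predictive performance and to the *set of selected
features*, under a leakage-safe protocol:

- **datasets** — a `FeatureTable` data model (numeric matrix + binary
  labels), CSV/manifest I/O, and preprocessing: named-feature removal,
  mean imputation, z-scoring.
- **synthdata** — a generator of radiomics-like tables: equicorrelated
  Gaussian feature blocks (pairwise correlation ρ within a block),
  class-conditional mean shifts δ on informative features, exact class
  counts from 15 built-in dataset profiles (n ∈ [51, 922],
  d ∈ [118, 7106], majority/minority balance B ∈ [1.0, 4.0]), and MCAR
  missingness. The analytic oracle AUC for k informative features is
  Φ(δ√k/√2).
- **resampling** — nine methods from first principles: random under/over,
  SMOTE (k ∈ {3,5,7}), SVM-SMOTE, Edited NN (k=3), All k-NN, Tomek links,
  SMOTE+ENN, SMOTE+Tomek. Pure functions of `(table, spec)`; Euclidean
  distances; lowest-index tie-breaking.
- **feature_selection** — four filter scorers (ANOVA F, Gaussian
  Bhattacharyya distance, extra-trees importance, L1-logistic
  coefficients) and top-N selection over N ∈ {1, 2, 4, …, 64}.
- **classifiers** — kNN, logistic regression, Gaussian naive Bayes,
  random forest (250 trees), RBF-SVM with γ = 1 / mean pairwise distance;
  regularization grids 2⁻¹⁰ … 2¹⁰.
- **harness** — 5-fold stratified CV × 30 repeats where resampling,
  selection and training happen strictly inside training folds; Mann–Whitney
  AUC, sensitivity/specificity; best-model selection per resampling method
  by macro-averaged AUC.
- **set_similarity** — Jaccard and Ochiai agreement, the symmetrized
  max-correlation similarity ½[s(A→B) + s(B→A)] with
  s(A→B) = mean over a∈A of max over b∈B of |R(a,b)|, and the Zucknick
  correlation-corrected Jaccard measure.
- **benchstats** — gains vs. not resampling (mean and per-dataset max),
  mean ranks, pairwise win–loss with 0.5-point draws, the Friedman rank
  test with tie correction, and the Nemenyi post hoc on the Studentized
  range distribution.

## Worked example

Generate an imbalanced table with one informative correlated block, run a
small model grid through the leakage-safe harness, and compare against the
analytic oracle:

```python
import radbench as rb

profile = rb.DatasetProfile("demo", n=200, d=200, n_pos=60, n_neg=140,
                            balance=2.3)
spec = rb.SynthSpec(profile, n_informative=1, effect_size=2.0,
                    block_size=10, within_block_corr=0.8, seed=11)
table, _ = rb.preprocess(rb.generate(spec))

print(f"oracle AUC {rb.bayes_auc(spec):.4f}")
for method in (rb.ResamplerSpec("none"), rb.ResamplerSpec("smote", k=5)):
    cfg = rb.ModelConfig(method, "anova", 4, rb.ClassifierSpec("naive_bayes"))
    res = rb.run_config(table, cfg, folds=5, repeats=5, master_seed=23)
    print(f"{cfg.label}: macro AUC {res.macro_auc:.4f}")
```

Output:

```
oracle AUC 0.9214
none|anova|N=4|naive_bayes: macro AUC 0.9160
smote(k=5)|anova|N=4|naive_bayes: macro AUC 0.9107
```

The oracle is the AUC attainable from the informative coordinates alone;
both pipelines recover it to within CV noise, and oversampling neither
helps nor hurts much here because ANOVA scores and naive Bayes are nearly
balance-insensitive on this geometry — exactly the kind of effect the
benchmark is built to expose and quantify across many datasets.

The same study runs from the shell:

```bash
radbench simulate --profile custom --n 200 --d 200 --n-pos 60 \
    --delta 2 --rho 0.8 --seed 11 --out demo.csv
radbench run --config run.yaml --out results/
radbench agreement --feature-sets results/feature_sets.jsonl \
    --metric jaccard --out agreement.csv
radbench report --cv-results results/cv_results.csv --baseline none --out report/
```

`run.yaml` lists datasets (CSV paths or synthetic profiles) and optionally
overrides the grids; absent keys keep the full defaults (19 resampler
variants × 4 selectors × 7 values of N × 29 classifier configurations,
5×30 CV).

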