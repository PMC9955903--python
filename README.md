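# genefs

Hybrid filter + metaheuristic wrapper feature selection for two-class
gene-expression microarray data.

## The problem

Microarray cohorts routinely measure tens of thousands of gene probes on a
few dozen to a few hundred samples, often with strong class imbalance
(e.g. 176 primary breast tumor samples vs 10 normal breast samples). To
find a small, stable panel of candidate gene biomarkers that separates the
two classes, `genefs` chains:

1. **Quasi-constant filter** — remove genes with sample variance < 0.01.
2. **SMOTE** — balance the minority class by interpolating toward minority
   nearest neighbors (`x + u·(x_nn − x)`, `u ~ U(0,1)`, k = 5).
3. **mRMR (FCQ)** — greedy minimum-redundancy / maximum-relevance
   selection. Relevance of gene *g* is the one-way ANOVA F-statistic
   against the class label *h* (for two classes, F = t²); redundancy is
   the mean absolute Pearson correlation with already-selected genes *S*;
   each greedy step maximizes the quotient

   ```
   F(g, h) / [ (1/|S|) Σ_{j∈S} |c(g, j)| ]
   ```

4. **t-test screen** — keep the mRMR genes whose two-tailed unpaired
   t-test p-value falls below α = 0.05.
5. **Binary metaheuristic search** — five optimizers (Binary Bat
   Algorithm, Genetic Algorithm, Equilibrium Optimizer, Cuckoo Search,
   Red Deer Algorithm) maximize one wrapper fitness over subset masks *m*:

   ```
   fitness(m) = ω · CV-accuracy(m) + (1 − ω) · (1 − |m|/n),   ω = 0.9
   ```

   with a 5-NN classifier under stratified 5-fold internal CV, plus an
   exhaustive-search oracle for verification on small pools.
6. **Evaluation harness** — seven classifiers (LR, XGBoost, Gaussian NB,
   decision tree, k-NN, linear SVM, random forest) scored by accuracy, F1
   and ROC-AUC under stratified k-fold CV on an 80/20 stratified split.

A synthetic-data generator reproduces the statistical shape of the curated
benchmarks (log-scale expression, imbalanced classes, planted mean-shift
genes), so the whole pipeline runs and is tested without any download.
Real data in the CuMiDa CSV dialect (samples as rows, a `type` class
column, gene-accession columns) can be supplied instead.

## Worked example

```
genefs run-all --config examples/demo.yaml --out demo_run --verbose
```

runs the full pipeline on a synthetic 186-sample × 500-gene cohort
(176 tumor / 10 normal, 6 planted informative genes) and prints:

```
start: genefs=0.1.0, numpy=2.4.6, sklearn=1.9.0, master_seed=0
load: source=synthetic, n_samples=186, n_genes=500, class_counts={0: 10, 1: 176}
preprocess: input={0: 10, 1: 176}, after_filter_genes=500, after_smote={0: 176, 1: 176}, train={0: 141, 1: 141}, test={0: 35, 1: 35}, train_total=282, test_total=70, removed_genes=0
mrmr: k=20, top=G000412
ttest_screen: alpha=0.05, candidates=20
optimize:bba: n_selected=5, best_fitness=0.975
optimize:ga: n_selected=4, best_fitness=0.98
optimize:eo: n_selected=5, best_fitness=0.975
optimize:csa: n_selected=7, best_fitness=0.965
optimize:rda: n_selected=7, best_fitness=0.965
evaluate: pairs=35, folds=10, best=bba/GaussianNB, best_test_cv_accuracy=1.0
```

Reading the log: SMOTE raises the 10 normal samples to 176 per class; the
stratified 80/20 split yields 282 training (141 + 141) and 70 test
(35 + 35) samples; mRMR keeps 20 candidate genes and the t-test screen
passes them to the optimizers; each optimizer reports the size and wrapper
fitness of its best subset (e.g. GA finds 4 genes at fitness 0.98 =
0.9·accuracy + 0.1·parsimony); the harness then scores all 5 subsets × 7
classifiers (35 pairs). Per-stage artifacts (gene lists, the t-test table,
convergence traces, the evaluation report) are written to the run
directory as re-readable JSON/CSV.

The same stages are available as a library of scikit-learn-style
estimators:

```python
from genefs import MRMRSelector, TTestScreen, BinaryBatSelector

panel = MRMRSelector(k=20).fit(X, y)            # X: samples x genes
screened = TTestScreen(alpha=0.05).fit(X, y)
best = BinaryBatSelector(random_state=0).fit(X[:, screened.support_], y)
```

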