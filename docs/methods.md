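# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical choices, and the design decisions behind
`genefs`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline model

The pipeline treats biomarker discovery as a three-stage hybrid feature
selection problem on an `n_samples × n_genes` matrix of log-scale
expression values with binary labels (0 = normal, 1 = primary tumor):

1. a **filter** stage (variance filter, mRMR-FCQ) that is classifier-free,
2. a **statistical screen** (two-tailed unpaired t-test, per-gene α), and
3. a **wrapper** stage (binary metaheuristics) guided by cross-validated
   classifier accuracy.

The default stage order mirrors the published protocol: variance filter →
SMOTE → feature selection on the full balanced data → stratified 80/20
split → evaluation. Selecting features on balanced data that includes
synthetic minority samples, before splitting, leaks information into the
test partition; `PipelineConfig.split_before_selection` switches to the
leakage-safe order (split first, select on training data only). The
default reproduces the published counts (282 train / 70 test, 141/141 and
35/35 per class from a 176/10 input); the flag exists because the
conventional order is what a practitioner should prefer on real data.

## Stage details and parameters

**Quasi-constant filter** — removes genes with unbiased sample variance
(denominator n − 1) strictly below the threshold (default 0.01, expression
units²). Strict `<` makes threshold 0 a no-op and the filter idempotent.

**SMOTE** (implemented in-package) — raises the minority count to the
majority count. Each synthetic sample is `x + u (x_nn − x)` with
`u ~ U(0,1)`, `x` a uniformly drawn minority sample and `x_nn` one of its
`k = 5` nearest minority neighbors (Euclidean over all genes; `k` capped
at minority size − 1). Neighbor ties break toward the lower sample index;
per synthetic sample the RNG is consumed in the order sample → neighbor →
interpolation coefficient, so runs are bit-reproducible. Original rows are
never modified.

**Stratified split** — per class, the test count is
`round(test_fraction × class size)` (half-up) with a guard of ≥ 1 test
sample when the fraction is positive. This reproduces 35/35 test samples
from 176/176 at 20%.

**mRMR-FCQ** — relevance is the one-way ANOVA F-statistic (two classes:
F = t² with the pooled t); redundancy the mean absolute Pearson
correlation with already-selected genes; the greedy step maximizes their
quotient. The denominator is floored at 1e-5 (the configured minimum
correlation of the filter stage), which also covers degenerate
zero-variance partners. Ties break toward the lower column index. A
constant gene gets relevance 0 with a warning rather than +∞ — the
variance filter should already have removed it. Default panel size k = 20.

**t-test screen** — two-tailed unpaired t-test per gene; the `student`
variant (pooled variance, df = n1 + n0 − 2) is the default because
"unpaired t-test" classically denotes it; Welch (Satterthwaite df) is
available by flag. Selection keeps genes with p < α (default 0.05), with
no multiplicity correction: the screen is specified at a per-gene 5%
level. Two constant equal groups give (t, p) = (0, 1) by convention; zero
pooled variance with unequal means is an error.

**Wrapper fitness** — the published objective ("compute fitness") is not
defined beyond its name, so the package uses the convention standard in
the binary-metaheuristic feature-selection literature:
`ω · CV-accuracy + (1 − ω) · (1 − |mask|/n)` with ω = 0.9, a 5-nearest-
neighbor wrapper classifier and stratified 5-fold internal CV. The folds
are unshuffled, so fitness is a pure function of (data, mask) and is
memoized per mask; a cache can be shared across optimizers on the same
data. Empty masks are repaired by setting one uniformly chosen bit.

**Optimizers** — all five use 20 agents × 100 iterations by default and
the reported algorithm constants (BBA: A = 1.0, r = 0.15, α = 0.95,
γ = 0.5, f ∈ [0, 2]; GA: crossover 0.4, mutation 0.3, roulette-wheel
selection, elitism 1; EO: pool 4, a1 = 2, a2 = 1, GP = 0.5; CSA:
pa = 0.25, Lévy exponent 1.5 via Mantegna sampling; RDA: γ = 0.5, α = 0.2,
β = 0.1, bounds ±5). BBA, GA, EO and CSA binarize continuous positions
with the sigmoid transfer `S(v) = 1/(1 + e^{−v})` against a fresh U(0,1)
threshold; RDA thresholds its continuous coordinates at 0.5
deterministically, which is the only reading under which the mating
recombinant of two identical parents with c = 0 reproduces the parent
mask. Every optimizer keeps best-ever elitist bookkeeping (ties resolved
like the exhaustive oracle: smaller subset, then lexicographic), so
convergence traces are non-decreasing and the returned fitness is
re-derived from the returned mask, never read from run-time state.

Optimizer-specific choices made where the published description is silent
or misprinted:

- The bat frequency uses the canonical `f = f_min + (f_max − f_min) β`;
  the printed sign variant can never reach `f_max`.
- The RDA roaring offset uses `r1 ((UB − LB) r2 + LB)` — a symmetric
  random move; the printed parenthesization pushes every move toward the
  lower bound.
- RDA positions are folded back into the search box by *reflection*, not
  clipping: with a 0.5 threshold and bounded moves, a clipped boundary
  coordinate could never change its bit again, stalling the search.
- RDA elitist truncation keeps *distinct* masks first; duplicate copies of
  the incumbent otherwise collapse population diversity within a few
  generations.
- RDA fights breed two contender recombinants per commander–stag duel and
  the best contender takes the commander slot (the canonical component).
- The RDA male fraction (not among the reported settings) is the canonical
  0.25; commanders are γ = 0.5 of males.
- CSA initializes positions in U(−4, 4): near 0 the sigmoid transfer makes
  every binarization a coin flip and the search cannot retain structure.
- The EO "Omega = 0.9" setting is carried as a parameter for parity with
  the reported configuration but has no effect on the binary dynamics; it
  is undefined in both the publication and the cited EO source.

**Evaluation harness** — seven classifiers with the reported
hyperparameters (XGBoost: depth 4, learning rate 0.2, λ = 1, 150 rounds,
subsample/colsample 0.9, random_state 1; RF: 100 trees, depth 4; DT depth
4; k-NN k = 5; linear SVM with squared hinge, C = 1; logistic regression
lbfgs/L2; Gaussian NB). Where the reported roster conflicts (an abstract
mentions a neural net; the settings table lists a random forest), the
settings table wins and the registry is pluggable. AUC uses each
classifier's predicted probability, or its decision margin for the linear
SVM, which has no native probabilities. Metrics (accuracy, F1, TPR, FPR,
rank-based AUC with ties counted ½) are implemented from their definitions
and verified against scikit-learn to 1e-9 in tests. The harness reports,
per (subset × classifier): stratified k-fold CV on the training partition
(default k = 10; 5 is the other protocol in circulation — the report
records the value used), the same CV protocol applied to the test
partition (reproducing the published, unconventional "CV on the test set"
analysis), and a clearly separated conventional fit-on-train /
score-on-test evaluation with confusion counts. F1/precision/recall are 0
when undefined (zero denominators).

## Synthetic-data generator

`SyntheticSpec` defaults emulate the curated breast-cancer benchmark: 176
tumor / 10 normal samples, many more genes than samples, per-gene base
means uniform in [4, 13] and SDs uniform in [0.1, 1.3] (the ranges spanned
by the published per-gene group statistics), and a small planted set of
genes (default 6) whose tumor-class mean is shifted by a configurable
effect (default 0.8 expression units, i.e. roughly 1 SD at the mean SD).
Genes are independent Gaussians given the class.

What this does *not* emulate: gene–gene correlation structure
(co-expression modules), heavy-tailed and probe-specific noise, batch
effects, and any real biological signal. Tests passing on this generator
therefore demonstrate that the algorithms are implemented correctly and
recover planted signal under idealized conditions — not that the selected
genes of any real dataset are biologically meaningful. Probe accessions
are synthetic (`G000001`, …); no probe-to-gene-symbol annotation is
implemented or implied.

## Numerical and degenerate-input conventions

- The sigmoid transfer uses `scipy.special.expit` (overflow-safe).
- The Pearson correlation is clipped into [−1, 1] against rounding.
- Repair of an all-zero mask sets one uniformly chosen bit, keeping the
  fitness total; returned masks are never empty.
- Each run consumes a single seeded `numpy` Generator in documented order;
  pipeline stages derive their seeds as `sha256(master_seed:stage)`
  (mod 2³¹), so stages can be re-run in isolation and whole runs are
  byte-identical under a fixed master seed.
- Duplicate gene ids at CSV ingest are suffixed with an occurrence index
  (`NM_152426_2`), keeping columns addressable while flagging the
  duplication; the class-label mapping defaults to "normal" → 0, anything
  else → 1, and is configurable.

## Verification problem sizes

The oracle-equivalence checks run each optimizer at its full default
budget on 10-candidate pools with 2 planted genes (2-SD effects,
n = 60/60) over 20 instances, against exhaustive evaluation of all 1023
subsets. Screen calibration uses 200 null replicates of 100 genes at
n = 50/50 (type-I error against the 99% binomial band) and 100 replicates
with 3-SD planted shifts (power). The shipped demonstration pipeline uses
186 × 500 with reduced optimizer budgets (10 agents × 15 iterations),
chosen because its post-screen candidate pool is small enough that the
search converges well within that budget.

## Known limitations

- The t-test screen applied after relevance-based pre-selection on the
  same data is circular (selection bias inflates significance); on
  balanced synthetic data most mRMR picks pass the screen. This mirrors
  the published protocol; the screen earns its keep on real data with
  weaker, correlated features.
- SMOTE before splitting (the default, published order) places
  interpolated copies of minority samples on both sides of the split;
  held-out metrics under this order are optimistic. Use
  `split_before_selection` for honest generalization estimates.
- Exhaustive verification is limited to pools of ≤ 15 candidates (2¹⁵
  masks); beyond that only the metaheuristics are available.
- The generator's independence assumption makes mRMR's redundancy term
  nearly inert on synthetic data (planted genes correlate only through the
  class label); the duplicated-gene tests exercise it directly.
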