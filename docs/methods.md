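# Methods

## The comparison problem and the experimental design

Screening-model selection compares many descriptor-set / method (D–M)
combinations on the same compounds.  A single k-fold cross-validation
gives each combination one number, but that number depends on the random
fold assignment; rerunning with a different assignment can reorder the
ranking.  `qsarlab` treats the exercise as a designed experiment:

- **Splits** are independent repetitions of k-fold cross-validation,
  each with its own seeded fold assignment.
- Within a split, **every D–M combination uses the identical fold
  assignment**.  The split is therefore a *block*: whatever a particular
  fold assignment does to performance, it does it to all combinations
  equally.
- Each combination's measure is computed once per split on the pooled
  n out-of-fold predictions (never per fold, which sidesteps degenerate
  folds that contain no actives).

The resulting s × c table (s splits, c combinations) is analysed with
the additive fixed-effects model

    Y_ij = μ + α_i + β_j + ε_ij,

α_i the split (block) effect, β_j the combination effect.  With one
observation per cell an interaction is not estimable, so none is fitted;
both factors are fixed effects.  The balanced closed-form decomposition
is used (SS_split = c·Σ_i(ȳ_i·−ȳ··)², SS_combo = s·Σ_j(ȳ·j−ȳ··)²,
SS_error by subtraction, df_error = (s−1)(c−1)); its agreement with a
direct least-squares fit is verified in the test suite against
statsmodels.  Tables with undefined cells are refused: columns containing
any NaN are dropped with a warning (`PerformanceTable.drop_incomplete`)
rather than fitting an unbalanced model, which keeps both the closed-form
decomposition and the pairwise standard error below exact.

## Tukey–Kramer pairwise comparisons and the MCS matrix

All c(c−1)/2 differences of combination means are tested at once.  For a
pair (j, j′): d = ȳ·j − ȳ·j′, SE = √(MS_error/s), q = |d|/SE, and the
adjusted p-value is P(Q_{c, df_error} ≥ q) under the studentized range
distribution (scipy's `studentized_range`, evaluated vectorized over all
pairs).  With two groups this reduces exactly to the two-sided paired
t-test (Q_{2,ν} = √2·|t_ν|), which the tests verify numerically.  When
MS_error = 0 (a perfectly additive table) nonzero differences are
assigned p = 0 and zero differences p = 1, with a warning.

Significance is reported in three bands — p ≤ 0.01, 0.01 < p ≤ 0.05,
p > 0.05 — with configurable edges.  The MCS matrix is symmetric, has
"self" on the diagonal, and orders combinations best→worst by mean
measure; orientation is a property of the measure (descending for IE,
AUC, sensitivity, specificity, PPV, F1, R², Spearman; ascending for
error rate and RMSE).

Simulation behaviour, measured by the test suite at c=5, s=3: the
familywise any-pair false-positive rate at the 0.05 level stays at or
below its nominal value within Monte-Carlo error, and a combination
elevated by 6σ is ranked first in essentially every run.  The power to
additionally push **all** of the elevated combination's pairwise
comparisons below p = 0.01 in this small design (df_error = 8) is about
92% — a property of the design size, not of the implementation; larger
s or c raises it.

## Cross-validation engine

- Defaults: 3 splits × 10 folds.  Three is the smallest split count
  giving a usable error df for the ANOVA; both are configurable.
- Seeds: split i defaults to 11111·i (11111, 22222, …).
- Fold assignment: a seeded uniform permutation of the observations is
  dealt round-robin into k folds, guaranteeing fold sizes of ⌊n/k⌋ or
  ⌈n/k⌉.  Assignment is *not* stratified by response; with very few
  actives a fold may contain none, which is harmless because measures
  are pooled per split.
- Model-internal randomness (random forest, neural net, SVM probability
  calibration, penalty-grid CV) is seeded from one deterministic
  per-split stream keyed by the split seed and consumed in
  (descriptor set, method, fold) loop order, so reruns are bit-identical
  and skipping one method does not perturb another's seeds.
- Leakage control: centering/scaling statistics and penalty selection
  are computed inside each training fold only; the suite spot-checks
  that deleting a test fold and refitting reproduces its stored
  predictions exactly.

## The model suite

Thirteen methods behind one contract (`fit_predict` returns "higher =
more active" scores).  Response handling:

| group | methods | binary response | continuous |
|---|---|---|---|
| native | Tree, RPart, RF, KNN, NNet, SVM | class-1 probability in [0,1] | prediction |
| least-squares | Lasso, LAR, Ridge, ENet, PCR, PLS | treated as continuous; unbounded scores, never clipped | prediction |
| discriminant | PLSLDA | class-1 probability | refused (dichotomize first) |

Thresholding of scores happens only in the measures layer (default
threshold 0.5, user-overridable — which matters for the unbounded
least-squares scores).

Defaults (all overridable through the parameter registry): KNN k=10;
RF 100 trees, √p features per split; SVM radial kernel, cost 1,
gamma="scale"; NNet one hidden layer of 2 units, weight decay 1e-3;
Lasso/ENet a 20-point penalty grid chosen by 3-fold CV on the training
fold (ENet l1_ratio 0.5); Ridge grid {0.01, 0.1, 1, 10, 100}; LAR a
least-angle path truncated by 3-fold CV; PCR/PLS min(10, rank)
components; PLSLDA 5 PLS components followed by LDA on the scores;
Tree a deep, unpruned recursive partition; RPart a conservative variant
(min split 20, min leaf 7, cost-complexity pruning α=0.01) so the two
tree entries genuinely differ.  All learners are scikit-learn estimators
or thin compositions of them.  Degenerate fits (constant training
response, numerical failure) fall back to predicting the training mean
with a warning so a long run never dies mid-way.

Standardization applies to every non-tree method, uses training-fold
mean and sample SD (ddof=1), and leaves zero-variance training columns
centered with scale factor 1.

## Measures

- Binary (on pooled out-of-fold scores): error rate, sensitivity,
  specificity, PPV, F1 from the confusion matrix after thresholding;
  AUC as the Mann–Whitney probability (ties count one half); initial
  enhancement IE = (h/m)/(p/n) with h the positives among the m
  top-scored observations.  Default m = 300 (capped at n); 0/0 ratios
  become NaN markers, not exceptions.
- Continuous: RMSE, R² = 1 − SS_res/SS_tot, Spearman's ρ.
- Tie rule for top-m selection and accumulation ordering: stable sort by
  descending score, original row order breaking ties.  Fractional tie
  sharing would be a defensible alternative; the stable rule was chosen
  because it is deterministic and makes IE exactly invariant under
  strictly monotone score transformations.

## Accumulation curves

Testing order is decreasing predicted score; the curve is the cumulative
response over the first m tests, m = 1..max_select with
max_select = ⌊min(300, n/4)⌋ by default.  The ideal curve sorts the
response itself in decreasing order (min(m, p) for binary y); the random
curve is the *expectation* line m·Σy/n — deterministic and testable,
rather than one sampled ordering.  Panels come in a "descriptors" series
(one panel per split × descriptor set, methods overlaid) and a "methods"
series (one panel per split × method, descriptor sets overlaid).
Monotonicity of the curve is guaranteed only for nonnegative responses.

## Applicability domain

T² = (x − x̄)ᵀ S⁻¹ (x − x̄) with x̄, S the training descriptor mean and
sample covariance (ddof = 1, no shrinkage by default; a ridge term is an
explicit opt-in for near-singular covariances).  The control limit is
the phase-II limit for future individual observations,
UCL = p(n+1)(n−1)/(n(n−p)) · F₁₋α(p, n−p); points above it are flagged
as extrapolations.  The statistic is affine-invariant, so the raw
descriptor matrix is used without standardization.  n > p is required;
high-dimensional descriptor sets need dimension reduction first.

## Synthetic data

The binary generator emulates the *shape* of a small screening subset —
500 compounds with exactly 50 actives, a 24-column continuous descriptor
set and a 147-column binary (presence/absence) descriptor set.  Signal:
a fraction (default 25%) of columns is informative; actives get a mean
shift of `effect` SDs on informative continuous columns and a
+0.2·effect success-probability shift (capped) on informative binary
columns over a 0.2 base rate.  Default effect = 1.0, a mid-strength,
clearly learnable but imperfect signal.  `effect = 0` yields an exact
null.  The continuous generator produces y as a sparse linear
combination of descriptors plus Gaussian noise (default n = 277, the
size of a small physical-property series).  The performance-table
generator draws directly from the additive ANOVA model with optional
single-combination elevation.

What these fixtures do **not** emulate: real descriptor correlation
structure, activity cliffs, assay noise heteroscedasticity, or chemical
series structure.  Passing tests demonstrate the statistical machinery
is correct, not that any method is good at real chemistry.

## Problem sizes used in the automated checks

Unit and acceptance checks run on deliberately small instances — tens to
a few hundred compounds, 2–3 splits, 4–10 folds, 200-table simulation
batches — chosen so the whole suite completes in well under a minute per
module while still exercising every code path and invariant.

## Known limitations

- Balanced (complete-table) ANOVA only; incomplete columns are dropped,
  not modelled.
- No stratified or grouped (e.g. leave-series-out) fold assignment.
- No parallel execution; runs are single-process and deterministic.
- Tukey–Kramer p-values assume the balanced blocked design; with
  dropped columns the comparison set shrinks accordingly.
- The 13 learners are faithful *in contract* (response handling,
  preprocessing, defaults documented here); they are not numerical
  clones of any other software's fits.
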