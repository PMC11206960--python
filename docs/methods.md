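# Methods

`cacoperm` implements a QSPR (quantitative structure–property
relationship) workflow for apparent permeability across Caco-2 cell
monolayers, modelled as log10 Papp (cm s⁻¹). This note documents the
models, the choices made where the design was genuinely open, and what
the synthetic data do and do not establish.

## The modelling problem

Given a table of compounds with measured log Papp and a matrix of
numeric molecular descriptors computed by external engines
(PaDEL-Descriptor, alvaDesc or similar), the pipeline learns a regression
from descriptors to log Papp and then predicts the permeability of new
compounds, flagging those outside the model's applicability domain.
Raw transport measurements convert to the response via
Papp = (dQ/dt) / (C₀ · A), with dQ/dt in µmol s⁻¹, C₀ in µmol cm⁻³ and
A in cm²; the model works on log10 Papp.

## Preprocessing

Fitted on the training rows only and applied unchanged everywhere else:

1. **Median imputation.** Missing descriptor cells take the training
   median; columns that are entirely missing are dropped (their median is
   undefined).
2. **Near-zero-variance removal** (caret-style): a column is dropped when
   it has a single distinct value, or when the frequency ratio of its two
   most common values exceeds 19 and its distinct-value percentage is
   below 10 %. The cutoffs are conventional, not data-derived.
3. **Pairwise correlation filter** at |r| > 0.70: repeatedly find the
   surviving pair with the largest |r|, and drop the member with the
   larger mean absolute correlation against all remaining columns (ties:
   the later column in input order). The victim rule follows the caret
   convention; the guarantee is that no surviving pair exceeds the
   threshold. Note that within a group of near-duplicate columns exactly
   one member survives, and the rule does not identify *which*.
4. **Centering and unit-variance scaling** (sd with denominator n−1).

The stage order (impute → variance → correlation → scale) makes the
variance and correlation computations well defined; it is a pipeline
choice, as is treating imputation statistics as training-only to avoid
test-set leakage.

**Split.** 80:20 train/test, stratified on five response-quantile bins;
within each bin round(0.8 · bin size) compounds go to training. The
split is seeded and is a partition by construction.

## Feature selection

**RFE (recursive feature elimination).** Under repeated k-fold
resampling (defaults 5 folds × 20 repeats), a random forest fitted on
all candidates is ranked by permutation importance — scored on the
held-out fold, which is cheaper and less biased than in-sample
permutation — and nested subsets at a grid of sizes (default 1–200) are
refitted and scored out-of-fold by RMSE. The winning size minimizes the
mean RMSE (ties: the smaller size); the final subset is the top-k ranking
of a forest refitted on all training rows. Evaluating a size grid rather
than literally removing one feature at a time is the only computationally
coherent reading of backward elimination at hundreds of descriptors and
changes nothing about the winner definition.

**GA (genetic algorithm).** Bit-string chromosomes over the RFE
survivors; fitness is the mean 5-fold CV RMSE of a random forest on the
active subset (empty chromosomes score +∞). Operators: tournament
selection of size 2, uniform crossover with probability 0.8, independent
per-bit mutation with probability 0.1, no elitism, population 50, 100
generations (all configurable). The per-bit mutation rate makes the
search aggressive; the result is therefore the **best chromosome ever
evaluated**, not the final population's best. Initialization sets each
bit with probability ½. Fitness values are cached by chromosome, and the
CV folds are fixed per run, so fitness is a deterministic function of the
chromosome and the search is exactly reproducible under a seed.

## Regressors

| kind | implementation | defaults |
|---|---|---|
| mlr | ordinary least squares | — |
| pls | PLS regression | ncomp = 11 |
| svm_rbf | ε-SVR, RBF kernel | σ = 0.015, C = 2, ε = 0.1 |
| rf | random forest | mtry = 18, 500 trees |
| gbm | gradient boosting (squared error) | 100 trees, depth 16, shrinkage 0.1, ≥ 10 obs/leaf |

σ is the kernlab `rbfdot` parameter in k(x,y) = exp(−σ‖x−y‖²), which is
numerically identical to the scikit-learn RBF `gamma`. `mtry` and
`ncomp` are clamped to the selected-feature count by the orchestrator.
Two PLS component counts circulate for this workflow (11 and 40); 11 is
the default and 40 remains available via configuration.

**Stacking ensemble (SVM–RF–GBM).** A linear meta-model
ŷ = β₀ + β₁·ŷ_svm + β₂·ŷ_rf + β₃·ŷ_gbm fitted by least squares of y on
**out-of-fold** base predictions (repeated k-fold; resubstitution
predictions would let the meta-model reward overfit bases). The bases are
then refitted on all training rows. Collinear or constant base
predictions fall back to the minimum-norm (pseudo-inverse) solution and
are flagged.

**Metrics.** RMSE, and R² defined as the squared Pearson correlation of
observed and predicted values — not 1 − SS_res/SS_tot; the two differ
whenever predictions are biased or mis-scaled. R² is reported as
undefined when either vector has zero variance. Internal validation is
5-fold CV repeated five times (configurable); fold assignment is a
seeded random partition per repeat.

## Applicability domain

Leverage-based. With the intercept-augmented training design
A = [1 X] (the +1 in the h* formula counts the intercept), the hat
matrix is H = A(AᵀA)⁻¹Aᵀ; a new intercept-augmented row u has leverage
h = uᵀ(AᵀA)⁻¹u. The inverse is a pseudo-inverse so collinear selections
degrade gracefully. The warning leverage is h* = 3(p+1)/n; standardized
residuals are residual / sd(training residuals) (denominator n−1, a
convention this package fixes since several circulate). A compound is
outside the domain when h > h* or |standardized residual| > 3 (the
Williams-plot convention). Screening of new compounds is done in the
preprocessed (training-scaled) descriptor space — the space the model
actually operates in. Outside-domain compounds keep their predictions in
the report but are withheld from the permeability-class summary.

For a full-rank design, Σ training leverages = p + 1 and each training
leverage lies in [1/n, 1]; the tests assert both, plus the identity of
the new-sample formula with the training hat diagonal.

## Permeability classes and drug-likeness

Predicted log Papp is binned: high > −5; medium −6…−5 (boundaries
inclusive, following the literal class wording "greater than −5" /
"below −6"); low < −6.

Each drug-likeness score is DLS = nRules/tRules, the fraction of
satisfied rules in a rule set; all bounds are inclusive. Seven rule sets
are built in (DLS_01…DLS_07, with 4/6/6/7/2/6/2 rules), and DLS_cons is
their arithmetic mean — the eighth score. DLS_01 is the modified
rule-of-five form using MlogP ≤ 4.15 rather than ClogP ≤ 5, because the
pipeline's property set computes MlogP. The unsaturation ratio
(`unsat_p`) and the atom-ratio properties are **supplied** inputs; no
defining formula is imposed, and a rule whose property is undefined
(e.g. (N+O)/C_sp3 with no sp3 carbons) counts as violated. Custom rule
sets can be loaded from JSON.

## Synthetic data

The generator emulates only the *statistical* structure the pipeline
assumes — it makes no attempt at chemistry-aware simulation or real
descriptor marginals, so passing tests demonstrate pipeline correctness
and recoverability of planted structure, not predictive accuracy on real
compounds.

A dataset has `n_informative` standard-normal columns feeding the fixed
response map

    f(z) = 1.2 z₁ + 1.0 z₂ + 0.8 z₃ + 0.7 z₄ + 0.6 z₅ + 0.8 z₄z₅ + 0.6 (z₃² − 1)

(every informative column has a marginal term, as real descriptors show
marginal correlations with log Papp; the interaction and the squared
term put roughly a quarter of the signal variance beyond a linear fit,
so kernel/tree models and the ensemble should beat MLR). The noiseless
response is rescaled so its sample range width equals the requested
width (default 3.92, i.e. −7.70…−3.78) and its sample mean equals the
requested mean (default −5.34) exactly — an affine map cannot pin mean
*and* both endpoints, and the mean is the quantity the invariants check.
Gaussian noise (default sd 0.4) is added after rescaling, so 0.4 is the
irreducible test RMSE. Redundant columns are affine copies of
informative ones plus jitter of sd 0.05 × source sd (|r| ≈ 0.999, safely
above both the 0.95 detectability bound and the 0.70 filter);
near-constant columns differ in at most 0.5 % of rows; missingness is
completely at random in the descriptor matrix only. Identical spec ⇒
bit-identical output.

Because the correlation filter keeps exactly one member per
near-duplicate group, recovery of planted signal is measured on signal
identity: an informative column counts as recovered when the selection
contains it **or one of its planted duplicates** (`informative_recovery`
resolves this via the generated redundant map).

Property-profile generation has three scenarios: `all_pass` draws inside
the intersection of every rule interval, `all_fail` strictly above every
upper bound (all rules are simultaneously violable from above), and
`mixed` uniformly over ranges straddling each threshold.

## Problem sizes used by the test suite

The end-to-end study runs at 800 compounds (5 informative, 10 redundant,
85 noise, 2 near-constant columns; 2 % missing; noise sd 0.4), RFE sizes
1–30 with 5 folds × 2 repeats, GA population 20 over 15 generations,
selection forests of 60 trees, across seeds {1, 2, 3} — sizes chosen so
the whole suite runs comfortably on a single CPU while leaving the
planted-signal recovery and model-ordering conclusions unchanged. The
reference-scale settings (sizes 1–200, 5×20 resampling, GA 50×100, 500
trees) remain the configuration defaults.

## Known limitations

- The GA searches the RFE survivors only; whether a wider candidate pool
  would do better is untested.
- R² as squared correlation can flatter a biased predictor; both metrics
  are computable from the stored predictions if needed.
- The leverage domain is convex-ellipsoidal; it cannot flag interpolation
  gaps inside the training cloud, and no distance-to-model or density
  variant is provided.
- Duplicate removal keeps the first record of each canonical structure;
  conflicting measurements among duplicates are not merged.
- The near-zero-variance and correlation cutoffs, split stratification
  (5 quantile bins) and fold construction are fixed conventions; none is
  estimated from data.
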