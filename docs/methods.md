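# Methods

`qsarpipe` builds binary-classification and continuous-regression QSAR
models for enzyme-inhibition data (the motivating target is human
dipeptidyl peptidase 4, DPP4) and applies them to virtual screening.
This note records the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic test data do and do
not establish.

## Data curation

Input records are compound–IC50 pairs (nM) with a relation qualifier
(`=`, `>`, `<`, `>=`, `<=`). Structures are standardized by keeping the
largest organic fragment (salts, counter-ions and waters are dropped);
the duplicate key is the canonical SMILES of that fragment — after
salt stripping it is the only structural identity available.

Duplicate groups are resolved per task:

* identical response values collapse to one entry;
* regression groups with coefficient of variation sd/mean < 0.2 over
  their IC50 values collapse to the **geometric mean** (potencies are
  log-normally distributed, so the geometric mean is the natural
  average); groups at or above the threshold are rejected wholesale as
  discordant;
* classification groups whose members straddle the activity cutoff are
  rejected — collapsing them would fabricate a label.

The sd in the sd/mean rule uses the sample convention (n−1); it is
configurable (`sd_mode="population"`).

Classification labels use the lead-likeness potency cutoff: *active*
iff IC50 ≤ 50 nM, boundary included. Classification admits all
relation qualifiers; regression admits only exact (`=`) measurements,
because a qualified value bounds, rather than measures, the response.
pIC50 = −log10(IC50 in molar) = 9 − log10(IC50 in nM); the inverse
transform is exact to floating tolerance.

## Descriptors

Descriptor computation sits behind a provider registry so the pipeline
is descriptor-agnostic. The shipped providers are backed by RDKit:
`rdkit2d` (the full RDKit 2D list, ~210 descriptors) and `rdkit2d3d`
(adds 3D shape descriptors on a single ETKDG conformer embedded with a
fixed seed, so recomputation is bitwise identical). Every column is
tagged with one of a fixed 20-label category vocabulary (autocorrelations,
connectivity indexes, E-state, Burden eigenvalues, MOE-type surface
areas, functional-group counts, ...). Individual descriptor failures
yield NaN cells and never abort a batch. The registry accepts
additional providers; nothing downstream hard-codes descriptor names.

## Preprocessing

Fixed order, fitted on training data only and frozen for prediction:

1. drop columns that are constant over observed entries or contain any
   non-finite value;
2. correlation filter at |Pearson r| > 0.90, computed on
   pairwise-complete observations, greedy left-to-right (the earlier
   column in matrix order is kept — deterministic and order-dependent);
3. kNN imputation with k = 3 and uniform weights (NaN-aware Euclidean
   distance on mutually observed columns);
4. standard scaling to zero mean / unit variance, population (n)
   standard deviation.

Fitting scaling statistics on the training split only avoids
information leaking from validation compounds into the model. The
fitted state (retained columns, imputer donor rows, means/sds)
serializes to a versioned JSON archive, so prediction-time application
is bit-reproducible.

Train/validation splitting is semi-random: k-means clusters the
preprocessed descriptor space (default k = round(√(n/2)), a standard
rule of thumb; the split is insensitive to the exact value) and each
cluster is split at the global train fraction (default 75%) with
largest-remainder rounding. Clusters smaller than 2 go entirely to
training. This keeps every region of chemical space represented in
both sets.

## GA feature selection

A wrapper genetic algorithm evolves descriptor subsets. Fitness is the
mean five-fold cross-validated score (F1 for classification, R² for
regression) of a model trained on the subset, minus a linear penalty
`penalty_per_descriptor × |subset|` (default 0.001). Linear is the
simplest monotone penalty; it guarantees that for equal raw score a
smaller subset always wins.

Defaults: population 50, 200 generations, top 50% kept as parents,
mutation probability 0.3 (swap one descriptor for a random outsider),
deletion probability 0.3 (drop one descriptor, floor size 1), both
applied independently to each child in that order. The initial
population includes each pool descriptor independently with
probability 0.5; a config switch (`restrict_initial_pool`) instead
restricts the whole initial population to one random half of the pool.
Parents survive into the next generation (elitism), which makes the
best-fitness trace provably non-decreasing; the next population is
parents + children truncated to the population size by fitness.

The scoring estimator inside the wrapper CV is pluggable. The default
is a regularized linear model (logistic regression / ridge): wrapper
selection evaluates thousands of subsets, so the inner model must be
cheap, and a linear scorer ranks subsets reliably on monotone signal.
Tree ensembles can be passed via `estimator_factory` when the extra
cost is warranted. The GA is run once per ensemble algorithm (three
classification runs plus one regression run) with offset seeds.

The planted-signal recovery study (60 descriptors, 8 informative with
a logistic effect of 2.0 at n = 300, population 24, 30 generations, 10
seeded runs) recovers at least 6 of the 8 planted descriptors in ≥70%
of runs. These problem sizes were chosen once as a realistic
desk-scale recovery setting and frozen.

## Models and ensembles

Base classifiers: random forest, extra trees, AdaBoost; regression uses
an extra-trees regressor. Hyperparameters are tuned by exhaustive grid
search scored by mean 10-fold cross-validation (F1 / R²), ties going to
the first combination in grid order, winner refitted on the full
training data. The default grids are compact (tree counts, depth,
leaf size) so the exhaustive search stays tractable on one core; any
grid can be supplied.

Hard voting takes the majority of the three predicted labels (three
voters, no ties). Soft voting computes P(active) = Σ wᵢpᵢ / Σ wᵢ —
invariant to positive rescaling of the weights — and labels active at
P ≥ 0.5 (the conventional threshold; configurable). Weights are
optimized by exhaustive scan of the lattice {0, 0.1, …, 2.0}³ minus
the all-zero triple (9,260 candidates), maximizing F1 on out-of-fold
cross-validated probabilities from the training set; tuning on
held-out data would leak the validation set into the model. Ties are
broken by lowest total weight, then lexicographically.

## Applicability domain

Per-model kNN-density AD: for each training compound compute the mean
distance to its k nearest training neighbours (default k = 5, self
excluded); the global reference width is a percentile of that
distribution (default: median). A compound's threshold is its own mean
kNN distance when that is below the reference (dense regions get
tighter thresholds) and the reference width otherwise; thresholds are
floored at 1e-12 so duplicated training points keep a positive
threshold. A query is inside a model's AD if it lies within at least
one training compound's threshold. Distances are Euclidean on the
scaled subset space (configurable metric).

For the three-model soft-voting ensemble, each model contributes a
reliability score of 0.33 when the query is inside its AD; the query
is inside the ensemble AD iff the summed score exceeds 0.6 —
equivalently, iff at least two of the three models agree. The
regression model uses the identical single-model rule without
aggregation.

## Single-point assay analysis

Enzymatic activity is the slope of the fluorescence trace between
minutes 10 and 20, (FLU₂₀ − FLU₁₀)/10; readings not exactly at the
window edges are linearly interpolated from bracketing timepoints.
Percent inhibition is 100 · (slope_control − slope_sample)/slope_control,
invariant to rescaling all fluorescence by a common factor; negative
values (activation) are reported as-is, not clamped. Hits are called
at strictly greater than 15% inhibition (the boundary value is
inactive), the usual single-point triage cutoff at low test
concentrations (default 1.5 µM). Replicate traces are analyzed
separately and their slopes averaged per compound; control slopes are
pooled. `score_screen` treats the experimental hit calls as truth and
reports the confusion matrix with PPV, NPV, TPR, TNR and ACC.

## Synthetic data and what the tests show

`make_synthetic_classification` draws standard-normal features, plants
a logistic signal on a known informative subset, and optionally adds
near-duplicate column blocks (for the correlation filter) and missing
cells (for the imputer). `make_synthetic_regression` uses a linear
signal with alternating ±coef coefficients plus Gaussian noise, with a
closed-form population R² ceiling for oracle checks. The ~30-molecule
fixture (`toy_molecule_set`) carries hand-assigned synthetic IC50s
spanning 1–10,000 nM with planted concordant and discordant
duplicates, a salt, a hydrate and one invalid SMILES, enabling the
full curate → train → predict path without any download.

Passing on these data establishes algorithmic correctness —
deduplication rules, filter/imputer/scaler oracles, GA recovery of a
planted signal, voting algebra, AD geometry — not predictive
performance on real bioactivity data. Real descriptor matrices are
heavier-tailed and far more collinear than the generator's Gaussian
features, real activity data carry assay and inter-lab noise, and a
fixture of ~30 molecules cannot measure generalization; training a
production model requires a curated target-specific dataset of
thousands of compounds.

## Numerical conventions and degenerate inputs

* Metrics with zero denominators are reported as explicit `None`
  (undefined), never as 0, and fold aggregation skips them while
  recording how many folds contributed.
* FPR and FNR are computed as exact complements (1 − specificity,
  1 − recall) so the identities hold bitwise.
* MCC uses the four-factor denominator √((TP+FN)(TP+FP)(TN+FN)(TN+FP)).
* Grid-search and GA randomness is fully seeded; identical inputs and
  seeds reproduce identical models, traces and predictions.
* Problem sizes in the test suite and the acceptance script are
  desk-scale (hundreds of rows, tens of descriptors, tiny grids for
  the smoke run) — chosen so the whole suite runs in minutes on one
  core while still exercising every code path at non-trivial size.

## Known limitations

* The RDKit 2D provider computes ~210 descriptors — far fewer than a
  full multi-library descriptor stack; named descriptors from other
  packages (Dragon/Mordred-style block names) are simply absent, and
  the pipeline never assumes them.
* No probability calibration, stacking, stereochemistry enumeration,
  tautomer canonicalization beyond the standardizer defaults, or
  dose–response fitting.
* The AD method's percentile and k defaults are reasonable choices,
  not values asserted from any reference dataset; both are logged in
  the model manifest.
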