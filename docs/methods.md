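# Methods

This note records the modeling choices behind varselbench: what each
component assumes, which parameters matter, what the synthetic generator
does and does not emulate, and the numerical conventions adopted where
more than one reasonable convention exists.

## Preprocessing

- **Split.** `n_train = floor(0.7·n + 0.5)` (symmetric half-up rounding;
  the 70/30 proportion only fixes a fraction, not a rounding rule). The
  permutation comes from `numpy.random.default_rng(seed)`.
- **Same-value filter.** A column is dropped when the relative frequency
  of its most common *training* value is ≥ 0.8, using exact value
  equality (no binning): the criterion targets near-constant discrete
  descriptors (e.g. fingerprint counts), for which exact ties are the
  natural notion of "same value".
- **Perfect-correlation dedup.** |Pearson r| ≥ 1 − 1e-12 on the training
  partition counts as perfectly correlated; exact equality to 1 is
  fragile in floating point. The scan is left-to-right and keeps the
  first occurrence, making the result order-stable and idempotent.
- **Probe spiking.** One uniform(0,1) column per surviving original
  descriptor, drawn independently for train and test from one seeded
  generator. Test-partition probes are required because the regression
  suite must be able to evaluate models that (wrongly) include probes.
- **Autoscaling** (train mean/SD applied to both partitions, y included)
  is on by default: LASSO, PLS and SVR are scale-sensitive, and the λ/C/γ
  default ranges assume standardized inputs. Predictions are mapped back
  through the stored train y statistics, so every reported MAE is in
  original response units.
- All column decisions are made on the training partition only; the test
  set never influences which columns survive.

## LASSO selector

The penalty grid is 2⁻¹⁵ … 2⁻¹ (15 values). The grid value is passed
directly as the `alpha` of scikit-learn's coordinate-descent `Lasso`,
whose objective is `(1/2m)‖y − Xb‖² + alpha·‖b‖₁`; on autoscaled data
this span covers essentially-unpenalized through strongly-sparse fits,
and cross-validation picks the operating point, so the distinction
between the per-sample-scaled and unscaled penalty parameterizations is
absorbed by the grid search. CV folds are shuffled, seeded 5-fold; the
score is the **pooled out-of-fold r²** (one number computed from the
concatenated out-of-fold predictions, no per-fold averaging). Ties break
toward the smaller λ — less shrinkage, i.e. toward *not* deleting
y-related columns. Selection tests coefficients against exactly zero,
which coordinate descent produces.

## GA selectors

Chromosomes are real vectors in [0,1]; a column enters the model iff its
gene ≥ 0.5 (the binarization rule is a design choice; continuous
weighting is a plausible alternative but makes the selected set
ill-defined). GASVR appends three genes mapped by `2^(lo + g·(hi−lo))`
to C (log₂ range [−5, 10]), ε (the ε-insensitive tube width, [−10, 0])
and γ ([−20, 10]) — wide log-uniform ranges standard for SVR searches on
standardized data.

The engine is a generational GA: tournament selection (size 3), uniform
crossover (probability 0.9), per-gene uniform-reset mutation (probability
1/length), elitism of one. Elitism makes the best-fitness trajectory
monotone non-decreasing, which is asserted in tests. Defaults are
population 100 × 50 generations; benchmark-scale runs in this repository
use smaller populations/generations (stated below) because the fitness
cache already covers the mask space of interest at those sizes.

Fitness is the pooled out-of-fold 5-fold-CV r² of the wrapped model on
the masked columns; empty masks score −∞. For GAPLS the PLS component
count is chosen internally by evaluating every count from 1 up to
min(30, #masked columns, fold size − 1) on the same folds and taking the
best — a single-level search rather than a nested CV, accepted because
the component count is a one-dimensional, strongly unimodal parameter.
Fitness values are cached by decoded mask (plus decoded SVR parameters),
which changes nothing in the results but avoids re-evaluating duplicate
masks.

## Boruta and r-Boruta

Shadows are **re-shuffled at every iteration** (the canonical algorithm;
shuffling once would make the reference a fixed draw rather than a null
distribution). The importance engine is a regression random forest
(default 500 trees, `max_features = 1/3`, the regression-forest
convention) using impurity-based importances. Each iteration the
reference is the p-th percentile of the shadow importances — linear
interpolation between order statistics, which at p = 100 is exactly the
shadow maximum — and an original column is a *hit* only if its importance
is **strictly greater** than the reference (boundary equality is not a
hit). Decisions use the exact two-sided Binomial(trials, ½) test at
α = 0.05, split evenly across tails: confirmed when P[H ≥ hits] < α/2,
rejected when P[H ≤ hits] < α/2. Rejected columns are removed from the
design matrix and their hit counts freeze; confirmed columns stay in the
matrix (they shape the forest) with frozen status. The loop stops when
no column is tentative or after `max_iter` (default 100) iterations;
tentative columns are excluded from the selection by default
(`tentative_policy="exclude"`), since the protocol treats "not shown
important" as deleted. No multiple-testing correction is applied across
columns.

r-Boruta draws `n_random = 10 000` standard-normal columns (normal, not
uniform: the calibration models chance *correlation*, and |r| against
normal nulls is the standard chance-correlation reference), computes
their absolute Pearson correlations with y, and sets
p = 100 × max|r|, clipped to (0, 100]. At n = 140 training samples this
gives p ≈ 30–40: the hit bar drops well below the shadow maximum, more
columns (including some probes) are confirmed, and weakly relevant
descriptors survive — the intended trade-off. The calibration draw uses
a generator seeded independently of the Boruta loop, so with the
percentile overridden to 100 r-Boruta reproduces Boruta bit-for-bit; the
tests assert this equivalence.

## Regression suite

24 configurations: PLS, ridge, LASSO, elastic net, SVR (linear,
Gaussian), decision tree, random forest, GPR with 11 registered kernels
(linear; RBF; Matérn 3/2; Matérn 5/2; rational quadratic; each of those
five plus a white-noise component; linear + RBF sum), gradient-boosted
trees, XGBoost, LightGBM, a histogram gradient-boosted tree config, and
a two-hidden-layer (64×64) multilayer perceptron. Each config carries a
small hyperparameter grid tuned by seeded shuffled 5-fold CV (r²
scoring) before a full-train refit; GPR (internal marginal-likelihood
optimization) and the MLP (fixed architecture) carry no grid. The grids
are deliberately small — the suite's job is to span model families, not
to squeeze each family's optimum. A `fast` profile (the 8 non-GPR,
non-boosting, non-MLP configs) exists for repeated benchmark runs; the
10th-percentile reduction is profile-agnostic. The percentile uses
linear interpolation between order statistics (so for 24 sorted MAEs it
interpolates at index 2.3). A configuration whose backend fails is
logged and excluded from the percentile rather than voiding the run.

## Synthetic generator

Informative columns are equicorrelated multivariate normal (one-factor
construction, ρ = 0.3 by default — always positive definite for ρ < 1
and controlled by a single parameter); noise columns are i.i.d. standard
normal; y = Xβ (+ the product of the first two informative columns for
the `quadratic_interaction` response) + N(0, noise_sd). The default
fixture is 200 samples, 10 informative + 65 noise columns (close to a
75-descriptor small-molecule table), coefficients decaying geometrically
from 3 to 0.3, noise SD 1 — so the weakest informative variable carries
roughly 1 % of the signal variance and selectors are genuinely stressed.

What the generator does **not** emulate: heavy-tailed or discrete
descriptor distributions, blockwise spectra-like correlation along a
wavelength axis, train/test distribution shift, and outliers. Passing
tests therefore demonstrate correct protocol behavior and recoverable
signal under Gaussian conditions, not performance on real descriptor
tables.

## Run sizes

Benchmark-scale runs (the repeated-seed tests and
`scripts/acceptance.py`) use 150-tree forests with `max_iter` 60 for the
Boruta variants, GA populations of 20–30 over 10–30 generations with PLS
components capped at 10, the `fast` suite profile, and 3–10 repeats;
these sizes were chosen as the package's standard quick-benchmark
configuration and are stated in the relevant code. Library defaults
(500 trees, `max_iter` 100, population 100 × 50 generations, the full
24-config suite) remain the recommended settings for one-off analyses.

## Known limitations

- The GA fitness landscape is evaluated by CV r², which is itself noisy;
  two GA runs with different seeds can legitimately return different
  masks (the benchmark records this run-to-run variability rather than
  hiding it).
- Boruta's binomial test treats iterations as independent Bernoulli
  trials, which is approximate because the forest sees the surviving
  columns jointly.
- The selection-ratio metrics divide by the number of original columns,
  so `ratio_random` is comparable across methods only when the probe
  count equals the original count — which the spiking step guarantees.
- `recovery_metrics` scores membership only; it does not credit a
  selector for ranking informative columns higher within its selection.
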