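# Methods

## The classifier

`mdem` implements a family of minimum-perturbation classifiers for
numeric tabular data.  Each class *c* with *N_c* training points is
summarized by a moment vector over the attributes: its mean (order
*n* = 1) or its population *n*-th central moment (*n* = 2, 3, 4 —
variance, non-normalized skewness, non-normalized kurtosis).  To
classify a point *x*, each class *pseudo-includes* it — the class's
moment vector is recomputed as if *x* belonged to it — and the raw
displacement

d_c(x) = ‖ m_c(x included) − m_c ‖₂

is multiplied by the class cardinality, wd_c(x) = d_c(x) · N_c.  The
point is assigned to argmin_c wd_c(x), ties broken toward the lowest
class position.  The cardinality weight is essential: the mean shift
from one inclusion is (x − μ)/(N + 1) and the central-moment shift
likewise decays as 1/(N + 1), so without the weight a large class would
absorb every new point regardless of fit.  The weight uses the current
count N_c; a `weight_on_new_count` switch offers N_c + 1 instead, which
matches the 1/(N + 1) shrinkage rate exactly but is not the default
behaviour of the reference pseudocode the default follows.

In *evolve* mode (the default), every prediction is committed: the
chosen class absorbs the point, so the model drifts with the test
stream and batch predictions are order-dependent by contract.  With
`evolve=False` the model is frozen and predictions are a pure function
of (model, point).

## Incremental moment bookkeeping

Each class state stores only its count and the powered sums
S_l = Σᵢ xᵢˡ for l = 1..L_max per attribute (L_max defaults to
max(order, 4)).  These are sufficient statistics: with raw moments
E[Xˡ] = S_l/N,

μ_n = Σ_{k=0}^{n} C(n,k) · E[X^{n−k}] · (−μ)^k,

which reproduces the familiar specializations μ₂ = E[X²] − μ²,
μ₃ = E[X³] − 3E[X²]μ + 2μ³, μ₄ = E[X⁴] − 4μE[X³] + 6E[X²]μ² − 3μ⁴.
All moments are population moments (divide by N, never N − 1); the
worked five-point example (mean 11.6, third moment 58.752 = 293.76/5)
fixes this convention.  Absorbing a point updates each S_l in O(1), so
training is one pass over the rows and scoring a point costs
O(M · n · d), independent of how many points have been absorbed — the
basis of the constant-per-prediction cost contract.

A closed-form identity gives the post-inclusion moment directly from
the pre-inclusion state: with δ = x − x̄_N and h = δ/(N+1),

μ_n(N+1) = 1/(N+1) · [ Σ_{k=0}^{n} C(n,k) · N · μ_{n−k}(N) · (−h)^k
                       + (δ·N/(N+1))^n ],

with conventions μ₀ = 1, μ₁ = 0.  A variant of this identity sometimes
quoted with an extra N/(N+1) prefactor over the whole bracket is
algebraically inconsistent with the term-by-term derivation and with
direct recomputation (the worked update {5,10,15,8,20} ∪ {17.6} gives
μ₂ = 171.2/6 under the form above and not under the prefactored one);
the package implements the form above and tests it against two-pass
recomputation at 1e-9 absolute tolerance.

**Numerical caveat.**  Deriving central moments from raw powered sums
cancels catastrophically when |μ| is large relative to the spread.  The
pipeline therefore min-max scales attributes to [0, 1] before
classification; on unscaled data the derivation carries only a 1e-6
relative-error expectation, which is documented rather than defended.

## Margin diagnostic

`margin_diagnostic(x)` returns the gap between the winning and
runner-up weighted displacements.  A positive margin certifies a unique
argmin: any estimation error smaller than half the margin, uniformly
over classes, cannot change the decision.  Only this empirical margin
is computed; the population displacement it approximates has no
estimator here.

## Preprocessing

The cleansing pipeline is impute → IQR filter → min-max scale.

- **Imputation** replaces declared missing cells (NaN and/or per-column
  sentinel codes such as the zero coding common in clinical tables) by
  the column mean of the non-missing values.  Zero-as-missing is
  strictly opt-in per column.
- **IQR filtering** flags cells outside [Q1 − f·IQR, Q3 + f·IQR];
  default factors are 3 (outlier) and 6 (extreme value), and rows with
  either flag are removed.  Quartiles use linear interpolation between
  order statistics (numpy's default), configurable via
  `quantile_method`; other toolchains' quartile rules differ, so
  flagged-row counts on a given table are rule-dependent and no exact
  count is asserted anywhere.
- **Scaling** maps each attribute affinely onto [0, 1]; constant
  attributes map to 0.  Scaling parameters are recorded for reuse.

Scaling on the full table before cross-validation leaks the global
min/max into training folds.  This matches the whole-dataset filter
workflow these clinical benchmarks are usually run under and is the
default; a per-fold mode is exposed in `RunConfig` for leakage-free
studies.

## Evaluation

`cross_validate` runs k-fold or stratified k-fold CV of any estimator
exposing `fit`/`predict` (the moment models, or scikit-learn baselines
behind `SklearnAdapter`).  A fresh model is built per fold, so evolved
class states never leak across folds.  Plain k-fold permutes rows with
a seeded generator and deals folds of size ⌊n/k⌋ or ⌈n/k⌉; stratified
k-fold shuffles within class and deals round-robin, keeping every
fold's class count within one row of its fair share.  Accuracy is the
mean of per-fold accuracies; precision, recall, F1 and MCC come from
the confusion matrix pooled over folds (stabler for small folds than
averaging ratios), with per-fold matrices also reported.  The positive
class defaults to the minority label.  Undefined metric denominators
yield 0 with the metric name flagged, never an exception.

## Synthetic data generator

`mdem.synthetic.generate` draws each class from a sinh-arcsinh-
transformed Gaussian, S = sinh((asinh(Z) + ε)/τ): ε tilts skewness, τ
controls tail weight, independently.  The transform is standardized
analytically — its first two moments are computed by 201-point
probabilists' Gauss–Hermite quadrature — before location and scale are
applied, so every class realizes its requested population mean and
standard deviation exactly regardless of shape.  That is what makes
shape-only separation scenarios well-posed: classes can share mean and
variance exactly while differing in skewness.  Missing-value sentinels
and additive outliers are injected element-wise at specified rates.
All randomness flows through one seeded generator per call.

What the generator does *not* emulate: correlated attributes, mixed
attribute scales, label noise, and the particular marginals of real
clinical tables.  Passing tests on this data demonstrate the mechanics
and the moment-separation regimes, not clinical performance.

### Study conditions

The regime experiments use two classes of 200 rows each, two
attributes, evaluated by 5-fold CV over 5 seeds after [0, 1] scaling:

- *variance regime*: equal means (0.5), standard deviations 0.05 vs
  0.2 — the order-2 rule beats the order-1 rule (which sits near
  chance, as both classes share a mean);
- *skew regime*: equal mean (0.5) and standard deviation (0.12),
  skewness parameter ±0.9 — the order-3 rule beats order-1;
- *separation check*: two unit-variance Gaussian classes 6σ apart,
  where the order-1 rule scores ≥ 0.99.

These sizes were chosen once as typical benchmark-scale conditions; the
comparisons are asserted as majorities over the 5 seeds, not as fixed
accuracy values.

## Cost contracts

Training is linear in rows; prediction is constant in training-set
size.  Both are asserted empirically: fitting 15,000 rows must take at
most 20× the time of 1,500 (2× linear headroom), and a 400-point
prediction batch against 5,000 training rows must take at most 2× its
time against 500 rows (min-of-repeats timings to suppress scheduler
noise).  These sizes are the package's own measurement design, large
enough to dominate constant overheads.

## Degenerate inputs and tie-breaking

- Every declared class must have at least one training row; an empty
  class has undefined displacement and is an error.
- A singleton class has all central moments exactly zero; with order
  ≥ 2 and all classes singleton, weighted displacements can tie at the
  temporary-moment magnitude and the lowest-position tie-break applies.
  This is documented behaviour, not an error.
- `derive_moments` on an empty state, moment orders above L_max,
  dimension mismatches and non-finite attribute values raise
  `ValueError` with explicit expected/actual detail.

## Known limitations

- No downdating (point removal), no weighted points, no merging of two
  class states.
- Classification uses a single moment order at a time, never a
  concatenation across orders.
- Binary metrics only (one-vs-rest via a declared positive class);
  multiclass prediction is native but macro/micro metric variants are
  out of scope.
- No probability outputs or calibration.
- ARFF support covers numeric and nominal attributes only.
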