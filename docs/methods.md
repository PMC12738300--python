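# Methods

## The classifier

`PAVGaussianNB` is an ensemble of `T` Gaussian naive Bayes (GNB) base
learners combined by **posterior averaging**. Learner `t`:

1. draws a **class-stratified bootstrap** of the training rows — sampling
   with replacement *within* each class, so per-class counts (and hence the
   estimated priors) match the training proportions exactly;
2. draws a uniform random subset `F_t` of `m = min(max(⌊αp⌋, 1), p)` feature
   columns without replacement (`α` = `feature_fraction`);
3. estimates, for each class `k` and feature `j ∈ F_t`, the sample mean
   `μ_kj`, the **unbiased** sample variance `σ²_kj` (denominator `n_k − 1`)
   and the prior `π_k = n_k / n`;
4. scores a query `x` by the log-joint
   `log π_k + Σ_{j∈F_t} [−½ log(2πσ²_kj) − (x_j − μ_kj)² / (2σ²_kj)]`, and
5. converts scores to posteriors with the log-sum-exp trick (subtract the
   row maximum before exponentiating), which is exact and immune to
   underflow for scores as extreme as ±10⁴.

The ensemble posterior is the arithmetic mean of the member posterior
matrices — an average of probability-simplex points, so it is already
normalized and no second normalization is applied. The predicted label is
the row argmax; exact ties resolve to the lowest class index. The class
axis is ordered by **first appearance in the training labels**, not sorted,
so the fitted model's probability columns follow the data's own vocabulary
order.

Soft voting is preferred to majority voting because the mean of member
posteriors is the Brier-score-optimal equal-weight mixture when members are
exchangeable with equal variance and covariance; it also keeps the
aggregate usable as a calibrated probability rather than a vote count.

### Reproducibility and parallelism

Each member's randomness comes from an independent substream keyed by
`(base_seed, t)` (`numpy.random.SeedSequence` spawn keys). Consequently
`n_jobs` is purely an execution hint: any worker count and any execution
order produce a bit-identical ensemble, and serialized models are
byte-identical across `n_jobs ∈ {1, 2, 4}` (for the same reason `n_jobs` is
not part of the serialized model state). Within one member the draw order
is fixed: bootstrap indices first, then the feature subset.

### Numerical choices

- **Variance floor.** Per-(class, feature) variances are floored at
  `var_smoothing · (mean global feature variance + 1)` (default
  `var_smoothing = 1e-9`) so a feature that is constant within a class
  still yields finite log-densities. The `+ 1` keeps the floor positive
  even for all-constant data.
- **Degenerate strata.** Under exact per-class-count stratification a class
  with at least one training row always appears in every bootstrap, so a
  singleton stratum can only arise from externally supplied data with a
  one-member class; in that case the member falls back to the pooled
  within-class variance for that feature and emits a warning. An empty
  class is an error.
- **Fast fit path.** The estimator computes member moments through
  bootstrap *multiplicity weights* (`bincount` of the bootstrap indices)
  instead of materializing the resampled matrix; this is identical to the
  materialized computation up to float summation order (verified to ~1e-16
  in the tests). Columns are centered before the second-moment pass so the
  `E[x²] − μ²` form cannot cancel catastrophically. Large inputs are
  converted to column-major layout once per fit, making each member's
  column gather a contiguous copy.
- **Scoring.** The per-member log-joint is evaluated as two
  `(n, m) @ (m, K)` products by expanding the quadratic, rather than a loop
  over classes.
- **Defaults.** `n_iter = 100` and `feature_fraction = 0.5` follow the
  reference interface defaults; the simulation benchmarks use
  `feature_fraction = 0.25` throughout, matching their published designs.

## Variance identity and margin bound (`pavgnb.theory`)

For member posteriors at a fixed query with common marginal variance `σ²`
and average pairwise correlation `ρ`,

    Var[mean of T members] = σ² (1 + ρ(T − 1)) / T,

which equals `σ²/T` at `ρ = 0`, `σ²` at `ρ = 1`, and tends to `ρσ²` as
`T → ∞`. `simulate_equicorrelated_members` verifies this by Monte Carlo
using a single-common-factor construction `√ρ·Z₀ + √(1−ρ)·Z_t`; any
construction with the stated first two moments would do, since the identity
depends on moments only.

With a positive Bayes margin `γ(x)` and true-class bias `b(x)`
(`E[P_t(Y|x)] = p*(Y|x) + b(x)`), a Cantelli-type argument gives the
pointwise misclassification bound

    Pr[pred ≠ Y | x] ≤ Var[mean] / [γ(x)/2 − |b(x)|]₊²,

reported as `+inf` when the denominator collapses. The bound is evaluated
pointwise in `x`; no integration over the feature distribution is
attempted. `empirical_bound_check` estimates `σ²`, `ρ` and `b` from
repeated ensemble fits on independent training draws (the expectations are
over training-data plus resampling randomness; members within one fit are
conditionally independent given the data, so `ρ` must be estimated *across*
fits), computes the exact posterior and margin from the generating model's
closed-form equicorrelation inverse, and reports the fraction of evaluable
points where the empirical error respects the bound. `b(x)` is the bias of
the **true-class** posterior only, matching the assumption's statement; `ρ`
is the average pairwise Pearson correlation of member true-class
posteriors, the natural estimator where none is prescribed.

## Synthetic scenarios (`pavgnb.synthdata`)

Every scenario draws `x | y = k ~ N(μ_k, Σ)` with the equicorrelation
covariance `Σ = (1 − ρ) I_p + ρ 11ᵀ` shared across classes (one structure
per overlap level). `Σ` has eigenvalues `1 + ρ(p − 1)` (direction **1**)
and `1 − ρ`; its square root has the closed form `aI + b11ᵀ` with
`a = √(1 − ρ)`, `b = (√(1 + ρ(p−1)) − a)/p`, so sampling costs `O(np)`
rather than a dense matrix product — this is what makes the
100 000 × 1 000 scenarios tractable.

Overlap presets map a level to a spacing `d` and correlation `ρ`:
none `(5, 0)`, low `(3.5, 0.1)`, moderate `(2, 0.5)`, high `(1, 0.9)`.

**Mean layout.** The default layout is **collinear**: `μ_k = k·d·1_p`, i.e.
adjacent classes are shifted by `d` in every feature along the all-ones
direction. This choice is deliberate and load-bearing: with equicorrelated
features the naive-Bayes boundary statistic between adjacent collinear
classes has the closed-form z-value `z = (d/2)·√(m / (1 + ρ(m − 1)))` for a
member using `m` features, giving per-boundary accuracy `Φ(z)` and K-class
accuracy `(2Φ(z) + (K−2)(2Φ(z) − 1))/K`; these closed forms reproduce the
published benchmark accuracies across all overlap levels and class counts
to three decimals, including the exact 1.0 results for the well-separated
levels (the large per-feature shift makes member error probabilities of
order 1e-5 or smaller). Note that at high `ρ` the adjacent Mahalanobis
distance `d·√(p/(1 + ρ(p−1)))` is approximately the preset value `d`
itself. An alternative **simplex** layout is provided
(`simplex_class_means`): class means form a regular simplex in the
Mahalanobis metric so *every* pairwise Mahalanobis distance equals `d`
exactly (requires `K ≤ p + 1`); it is useful when the overlap knob must be
the Mahalanobis separation by definition, but it concentrates the signal in
`K − 1` directions, which interacts very differently with random feature
subsets.

Labels are uniform over classes by default (`class_balance` overrides).

**What the generator does and does not emulate.** It produces exactly
Gaussian, homoscedastic, equicorrelated features with linear class
structure. Real data exhibit skewness, heavy tails, heteroscedastic and
block-structured dependence, label noise and class imbalance — none of
which the presets contain. Passing the benchmark reproductions therefore
validates the implementation and its behavior under the stated model, not
robustness on arbitrary real data; the Pima workflow (below) is the
real-data sanity check.

## Benchmarks (`pavgnb.bench`)

Seven named experiment families (baseline, scalability, dimensionality,
sample-size, feature-fraction, complexity, iterations) mirror the published
designs. Every cell is repeated `R = 10` times (3 for the largest
configuration in the acceptance script); each replicate draws an
independent **train** set and an independent **held-out test** set of
`n_test = max(2000, n/5)` rows from the same scenario, fits the ensemble,
and records accuracy (fraction of exact matches) plus fit/predict
wall-times. All replicate randomness is keyed by
`(base_seed, cell index, replicate index)`, so results are invariant to
execution order and core count. Wall-clock times are informational only:
they depend on hardware and are exported, never asserted. Scalability
efficiency is `E_S = T₁/(c·T_c)`. Each preset accepts a `scale` multiplier
that shrinks `n`, `p` and `T` proportionally (replicates preserved) for
desk-sized runs.

Problem sizes used by the acceptance script: the published configurations
at full size (baseline n=1000/p=50; sweeps at n=5000–10000/p=100–500; the
high-complexity cell at n=100000/p=1000 with R=3).

The feature-fraction sweep includes `α = √p/p` (subset size `⌊√p⌋`); at
`p = 100` this numerically coincides with `p/10`, and the two cells differ
only in their random draws. Two-way ANOVA/Tukey analyses of the benchmark
outputs are out of scope; the harness exports tidy long-format CSV so any
statistics package can run them.

## Known limitations

- GNB's conditional-independence assumption is wrong under `ρ > 0` by
  construction; the ensemble reduces variance but cannot remove the model
  bias, which is why high-overlap accuracies sit near the naive-Bayes
  (not the Bayes-optimal) boundary performance.
- The margin bound is often loose (Cantelli) and is reported pointwise;
  points with `γ/2 ≤ |b|` are unbounded and excluded from coverage
  statistics.
- Model files store every member densely as JSON text; they are exact but
  not compact (a T=100, p=1000 model is tens of MB).
- `scalability_efficiency` is measured on whatever hardware runs it;
  published runtime tables cannot be reproduced numerically, only their
  arithmetic can.
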