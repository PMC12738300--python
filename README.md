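# pavgnb — posterior-averaging Gaussian naive Bayes ensembles

`pavgnb` implements the **PAV-GNB** classifier: an ensemble of `T` Gaussian
naive Bayes (GNB) base learners, each fitted on a *class-stratified
bootstrap* of the rows and a *uniform random subspace* of
`m = ⌊α·p⌋` feature columns, aggregated by **averaging the member posterior
probabilities** (soft voting) rather than majority vote:

    P̄_T(C_k | x) = (1/T) Σ_t P_t(C_k | x),      Ĉ(x) = argmax_k P̄_T(C_k | x)

Each member scores queries by
`log π_k + Σ_{j∈F_t} log N(x_j ; μ_kj, σ²_kj)` with unbiased (`n_k − 1`)
variance estimates, normalized with the log-sum-exp trick so posteriors are
underflow-free. When members have posterior variance σ²(x) and average
pairwise correlation ρ(x), the averaged posterior has variance
`σ²(x)(1 + ρ(x)(T−1))/T` — near-1/T reduction when resampling and random
subspaces keep members weakly correlated — and a positive Bayes margin γ(x)
yields the pointwise error bound
`Pr[Ĉ(x) ≠ Y] ≤ Var[P̄_T] / [γ(x)/2 − |b(x)|]₊²`. The package is aimed at
statisticians and applied-ML practitioners who want an interpretable,
probability-calibrated, embarrassingly parallel ensemble for continuous
tabular data (clinical, epidemiological, omics-style feature matrices).

The package provides:

- `PAVGaussianNB` — a scikit-learn-compatible estimator
  (`fit` / `predict` / `predict_proba`, `get_params`/`set_params`), with
  bit-reproducible fits for any worker count;
- `pavgnb.theory` — the variance identity and margin bound above, plus
  Monte-Carlo harnesses that verify them;
- `pavgnb.synthdata` — equicorrelated Gaussian scenario generator
  (`Σ = (1−ρ)I + ρ11ᵀ`) with controlled class overlap;
- `pavgnb.bench` — the benchmark harness (accuracy, runtime, scalability
  efficiency `E_S = T₁/(c·T_c)`) with named experiment presets;
- a `pavgnb` command line (`train`, `predict`, `simulate`, `bench`,
  `theory`).

## Worked example

```python
import numpy as np
from pavgnb import PAVGaussianNB, generate_dataset, preset_scenario
from pavgnb.bench import accuracy

train = generate_dataset(preset_scenario("moderate", n=1000, p=50, K=3, seed=7))
test  = generate_dataset(preset_scenario("moderate", n=2000, p=50, K=3, seed=8))

model = PAVGaussianNB(n_iter=100, feature_fraction=0.25, random_state=0)
model.fit(train.X, train.y)

print(model.classes_)                      # [1 2 0]  (first-appearance order)
np.set_printoptions(precision=3, suppress=True)
print(model.predict_proba(test.X[:3]))     # [[0. 0. 1.]
                                           #  [0. 1. 0.]
                                           #  [0. 0. 1.]]
print(model.predict(test.X[:3]))           # [0 2 0]   (matches test.y[:3])
print(accuracy(model.predict(test.X), test.y))   # 0.893
```

The "moderate" preset draws three Gaussian classes with equicorrelation
ρ = 0.5 and adjacent per-feature mean spacing d = 2; the ensemble of 100
members, each seeing 12 of the 50 features, recovers ~89% held-out accuracy
— close to the closed-form naive-Bayes boundary performance for this
geometry (see `docs/methods.md`). The posterior rows are probability
vectors over `model.classes_`; here the test points are classified with
near-certain posteriors.

The same workflow from the shell:

```bash
pavgnb simulate --level moderate --n 1000 --p 50 --k 3 --seed 7 --out train.csv
pavgnb train --data train.csv --response class --n-iter 100 \
             --feature-fraction 0.25 --cores 2 --seed 0 --out model.json
pavgnb predict --model model.json --data new.csv --type prob
```

For real data (e.g. the Pima Indians Diabetes CSV with a `diabetes`
response), `pavgnb.bench.pima_workflow(frame, response="diabetes")` runs the
70/30 split protocol; that dataset is third-party and not redistributed
here — place it at `data/pima_indians_diabetes.csv` to enable the
corresponding test.

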