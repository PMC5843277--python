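# abcinfer

Approximate Bayesian computation (ABC) for model comparison and parameter
estimation when likelihoods are intractable or inconvenient — with a focus
on approximate Bayes factors for psychological and biostatistical models.

Many interesting model comparisons (non-nested models, non-standard priors,
simulation-defined models such as multinomial processing trees) have no
closed-form Bayes factor. ABC sidesteps the likelihood entirely: if a model
is a good account of the observed data `D0`, data simulated from it will
tend to resemble `D0`. The rejection algorithm implemented here is

1. draw a model `m* ~ P(m)`,
2. draw parameters `θ* ~ P(θ | m*)`,
3. simulate `D* ~ f(D | θ*, m*)`,
4. accept the particle `(m*, θ*)` if `d(s(D0), s(D*)) ≤ ε`,

repeated for a fixed budget of `N` particles collected in a *reference
table* (model index, summary statistics `s(D*)`, parameters, distance).
The tolerance `ε` is the k-th percentile of the simulated distances
(nearest rank, `k` small, e.g. 1 or 5). Accepted counts estimate posterior
model probabilities,

    P(m' | D0) ≈ #accepted(m', ·) / N,

and pairwise approximate Bayes factors follow from posterior over prior
odds:

    BF_ij = [P(m_i | D0) / P(m_j | D0)] · [P(m_j) / P(m_i)],

capped at 10 000 when the denominator model never crosses the threshold.
The default distance is the Euclidean distance with each summary dimension
scaled by its median absolute deviation (MAD); a random-forest classifier
trained on the reference table is available as an alternative estimator of
the posterior model probabilities, and leave-one-out cross-validation
(confusion matrix, prediction error `E_pred = Σ_i (θ̃_i − θ_i)² / Var(θ)`)
quantifies how well models and parameters can be recovered at all.

Three worked suites ship with the package and double as validation cases:

- **Bayesian two-sample t-test** — H0: equal means; H1: Cauchy(0, 0.707)
  prior on Cohen's d; summary = empirical Cohen's d; distance = squared
  difference. Validated against the exact JZS default Bayes factor
  (numerical quadrature, `ttest.jzs_bf10`).
- **Bayesian Levene test** — H0: equal variances; H1: Gamma(8, 0.125) prior
  (mean exactly 1) on the variance ratio; summary = sample variance ratio;
  the classical Levene test is included for comparison.
- **Multinomial processing trees** — the process-dissociation and Stroop
  accounts of the weapon-identification task (16-cell design, 11 free
  parameters each, Beta priors), compared by approximate Bayes factor.

## Worked example

```python
import numpy as np
from abcinfer import ABCModelComparison
from abcinfer.examples import ttest

rng = np.random.default_rng(0)
data = ttest.simulate("H1", 50, 50, rng, d=0.5)   # two groups, true d = 0.5

comp = ABCModelComparison.from_data(data, ttest.suite(50, 50))
res = comp.fit(n_simulations=100_000, percentile=1, seed=7)
print(res.summary())
print("ln BF10 =", round(res.log_bf("H1", "H0"), 3))
print("ln JZS  =", round(np.log(ttest.jzs_bf10(ttest.cohens_d(data), 50, 50)), 3))
```

prints

```
ABC model comparison
====================
method:       rejection
N simulated:  100000
epsilon:      0.00133077 (1% percentile)
accepted:     1000

Posterior model probabilities:
H0    0.087
H1    0.913

Approximate Bayes factors (row over column):
         H0      H1
H0   1.0000  0.0953
H1  10.4943  1.0000
ln BF10 = 2.351
ln JZS  = 2.516
```

The accepted particles split 87:913 between H0 and H1, so the data update
equal prior odds by a factor ≈ 10 in favor of a real group difference —
within Monte-Carlo error of the exact default Bayes factor (ln BF 2.52).

The same analyses run from the shell via a declarative YAML project file:

```
abcinfer run project.yaml --seed 7 --output-dir results/
```

which writes the reference table, model probabilities, Bayes factors and a
run log (all CSV/text) to the output directory. `--modeltest H1 --param
d=0.8` generates pseudo-observed data instead of reading a file; `--cv 100`
adds leave-one-out cross-validation.

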