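# Methods

## The rejection algorithm and its estimates

`abcinfer` implements fixed-budget rejection ABC. A run simulates exactly
`N` particles: for each, a model index is drawn from the prior model
probabilities `P(m)`, parameters from that model's priors `P(θ | m)`, a
dataset from the model's simulator, and the dataset is reduced to a summary
vector `s(D*)` of fixed length `k`. The distance of every simulated summary
to the observed summary is computed, the tolerance `ε` is chosen as a low
percentile of those `N` distances, and the particles with `d ≤ ε` are
accepted. (The alternative formulation — keep simulating until `k`
particles are accepted — is equivalent in distribution but has an unbounded
runtime; the fixed-`N` reference-table formulation is what the engine,
cross-validation and the CSV import/export all operate on, so it is the one
implemented.)

Two readings of the posterior model probability are reported.
`ModelPosterior.raw_fraction` is `accepted_m / N`, the literal
acceptance-fraction estimate; its sum over models is the overall acceptance
rate, not 1. `ModelPosterior.probabilities` renormalizes by the total
number of accepted particles and is a proper probability vector. The Bayes
factor uses the ratio of posterior to prior odds, where the normalization
cancels, so the choice does not affect `BF_ij`.

**Zero-acceptance cap.** If the denominator model of a Bayes factor never
crosses the threshold, the ratio is undefined; the cell is set to the cap
(default 10 000, `ln 10 000 = 9.21`) and flagged. The cap is applied
symmetrically — a zero-numerator cell becomes `1/cap` — and all cells are
clipped to `[1/cap, cap]`, so `BF_ij · BF_ji = 1` holds wherever neither
cell was capped. The cap value is an arbitrary stand-in for "very large";
it should be read as a floor/ceiling, not an estimate.

## Distances, scales, thresholds

The default distance is the MAD-scaled Euclidean distance: each summary
dimension is divided by the median absolute deviation of that dimension
*across the simulated summaries of the current reference table* (the
observed summary is not included in the scale computation), then ordinary
Euclidean distance is taken. A dimension whose simulated summaries are
constant has MAD 0 and receives scale 1, which keeps the distance defined
while effectively weighting that dimension by its raw deviation. Because
the scales depend on all `N` summaries, table construction is two-pass:
simulate everything, then compute scales and distances.

`ε` uses the nearest-rank order statistic: the `⌈(k/100)·N⌉`-th smallest
distance for acceptance percentile `k`. This makes the accepted count exact
(barring ties) rather than interpolation-dependent. Percentile and absolute
`ε` are mutually exclusive settings; `ε = 0` gives exact-match ABC, which
is only useful for discrete summaries.

Custom distance functions receive the full `(N, k)` matrix of simulated
summaries plus the observed summary and the MAD scales, and return `N`
distances; this keeps user-defined distances vectorized. The t-test suite
uses the squared difference of effect sizes and ignores the scales.

## Reproducibility and vectorization

A run is driven by one master seed. The generator is consumed in a fixed
order — model-index draws, then per-model parameter draws, then per-model
simulation — so a fixed seed yields a bit-identical reference table. Models
may provide, alongside the one-dataset simulator the engine contract
requires, a fused `simulate_summaries(params, n, rng)` that maps parameter
arrays straight to an `(n, k)` summary matrix; all bundled suites do, which
is what makes 10^6-row tables take seconds rather than hours. The fused
path must agree in distribution with summary∘simulate (tested per suite).
Per-particle independent substreams were considered and rejected: they
would make row-level parallelism order-independent, but at the cost of
generator setup dominating the vectorized simulators; the engine promises
determinism for a fixed seed and execution order instead.

## Random-forest model choice

As an alternative to distance-based acceptance, a random-forest classifier
(500 trees by default, bootstrap aggregation, sqrt-feature subsampling;
scikit-learn's `RandomForestClassifier`) is trained to map simulated
summaries to model indices and evaluated at the observed summary. The
reported probabilities are soft votes — the forest's mean of per-tree leaf
class frequencies — rather than hard majority fractions. Forest size,
depth and feature rule are declared defaults, not calibrated values; the
refinement of regressing the posterior error on out-of-bag predictions is
deliberately not implemented.

## Cross-validation

Leave-one-out cross-validation treats one simulated particle at a time as
pseudo-observed: distances and `ε` are recomputed on the remaining rows
(including the MAD scales, which change slightly with each removal).
For model comparison the selected model is the one with the highest
normalized posterior probability; tallies form a confusion matrix. For
parameter estimation the point prediction is the posterior mean of the
accepted draws of the target model, and the prediction error is

    E_pred = Σ_i (θ̃_i − θ_i)² / Var(θ),

with `Var(θ)` the empirical variance of the true held-out values, computed
once per parameter. This makes `E_pred` invariant under affine rescaling of
the parameter and comparable across parameters. A variant that also divides
by the number of replicates (matching the convention of some ABC software)
is available as `per_replicate=True`. Held-out rows are sampled without
replacement.

## The bundled suites

**t-test.** H0 draws both groups from N(0, 1); H1 draws group 1 from
N(d, 1) with `d ~ Cauchy(0, 0.707)`. Means and the common σ are fixed at
0/1 because the summary, Cohen's d, is location- and scale-free — the
models are only identified through the standardized mean difference, so
this parameterization loses nothing. The shift is applied to group 1 so
that the generating `d` and the empirical `(mean1 − mean2)/s_pooled` have
the same sign. The JZS reference Bayes factor integrates the noncentral-t
density of the observed t statistic against the Cauchy prior by adaptive
quadrature (`scipy.integrate.quad`, tolerance ~1e−10) and divides by the
central-t density; at an observed effect of exactly zero it reproduces the
known lower limits ln BF10 ≈ −1.26 (25 per group) and −1.87 (100 per
group).

**Levene.** H0 fixes both variances to 1; H1 draws the variance ratio
`r = σ2²/σ1²` from Gamma(shape 8, scale 0.125) — strictly positive, mean
exactly 1, comfortably covering ratios between about 0.3 and 2.5. The
summary statistic is the sample variance ratio `s2²/s1²` — sufficient for
the single contrast the two models encode. The ratio is read as a ratio of
*variances*, matching the homogeneity statement σ1² = σ2² the H0 encodes.
The classical comparison test uses the W statistic on absolute deviations
from the group means with an F(1, N−2) reference distribution
(`scipy.stats.levene(center="mean")`).

**MPT.** The weapon-identification design crosses condition (private /
anticipated-public) × prime race (white/black) × prime gender
(female/male) × target (gun/tool) into 16 cells with a fixed number of
trials per cell (default 50 — a plausible per-cell trial count for this
two-session paradigm; the original behavioral counts are not reproduced
here). The automatic-bias parameter A varies by condition × prime × gender
(8 values), control C by condition (2), and one guessing parameter G is
shared: 11 free parameters. G is the probability of *responding "gun"*
when guessing, so a guess is correct with probability G for gun targets
and 1 − G for tool targets. Cell accuracies follow the two trees (s = 1
when the stereotype-consistent response is correct, i.e. black+gun or
white+tool):

    PD:     P(correct) = C + (1 − C)(A·s + (1 − A)·g)
    Stroop: P(correct) = A·s + (1 − A)(C + (1 − C)·g)

Counts are Binomial(trials, P) per cell; the summary is the 16-vector of
correct proportions and the distance the MAD-scaled Euclidean default.
Fitting priors are A ~ Beta(2, 10), C ~ Beta(3, 3), G ~ Beta(10, 10); the
recovery study draws generating parameters from the tighter, empirically
motivated A ~ Beta(2, 10), C ~ Beta(60, 40), G ~ Beta(50, 50). The
recovery acceptance percentile is 5% — deliberately loose, which is also
why Stroop-generated data are occasionally misattributed to the PD tree
(the two trees make similar predictions when C is high and A low).

## What the synthetic data do and do not show

All validation inputs are simulated from the models themselves (or fixed
printed values). Passing tests therefore demonstrate that the engine's
estimates converge to the right quantities *when the model family contains
the generating process* — internal consistency, oracle agreement, and
recovery under correct specification. They say nothing about
summary-statistic sufficiency for real data, model misspecification, or
non-normal group data in the t-test/Levene suites; those are properties of
a user's analysis, not of the engine.

## Problem sizes and numerical choices

Validation runs use reference tables of 4×10^6 rows at the 0.1% acceptance
percentile for the Bayes-factor limit checks (≈4 000 accepted particles,
Monte-Carlo standard error of ln BF ≈ 0.04), 10^5 rows at 5% for the MPT
recovery study (50 pseudo-observed datasets per generating model), 10^5
rows at 1% for the 200-dataset comparison with the JZS factor, and 10^5
rows with `ε = 0` for the exact-match Bernoulli oracle. The unit-test
suite uses smaller tables of the same structure.

Degenerate inputs fail loudly rather than silently: zero total acceptance
raises "threshold too strict"; a simulator whose output shape disagrees
with the observed data raises at table-construction time; a zero pooled
variance (Cohen's d), zero first-group variance (variance ratio), or zero
truth variance (E_pred) is an error. Reference-table CSVs are written with
full round-trip float precision and re-parsed with pandas'
`float_precision="round_trip"`, so write-then-read is bit-exact.

## Known limitations

- Only rejection and random-forest model choice, and rejection parameter
  estimation, are implemented; sequential/adaptive schemes and MCMC-based
  parameter estimation are out of scope.
- The acceptance-fraction Bayes factor degrades in the extreme-evidence
  regime (few or zero denominator particles), where only the capped bound
  is reported.
- The random-forest probabilities depend on forest hyper-parameters; no
  out-of-bag calibration is applied.
- Leave-one-out cross-validation recomputes all distances per replicate;
  it is O(reps × N) and meant for diagnostic table sizes, not 10^6-row
  production tables.
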