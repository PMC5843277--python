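"""ABC version of a Bayesian Levene test for two samples.

H0 fixes both population variances to 1; H1 carries one parameter, the
variance ratio r = var2/var1, with a Gamma(shape 8, scale 0.125) prior —
strictly positive with mean exactly 1, as befits a ratio that is 1 under
homogeneity.  The summary statistic is the sample variance ratio
s2^2/s1^2; the classical Levene test (W statistic on absolute deviations
from the group means) is the frequentist baseline the approximate Bayes
factor is contrasted with.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import stats

from ..inference import ModelSuite
from ..model import ModelSet, ModelSpec
from ..priors import Prior
from .ttest import split_groups, two_group_array

__all__ = [
    "simulate",
    "variance_ratio",
    "classical_pvalue",
    "variance_ratio_prior",
    "suite",
]

_CHUNK = 200_000


def variance_ratio_prior() -> Prior:
    """Gamma(shape 8, scale 0.125) prior on the variance ratio (mean 1)."""
    return Prior("gamma", shape=8.0, scale=0.125)


def simulate(
    hypothesis: str,
    n1: int,
    n2: int,
    rng: np.random.Generator,
    r: Optional[float] = None,
) -> np.ndarray:
    """group1 ~ N(0, 1); group2 ~ N(0, sqrt(r)) under H1, N(0, 1) under H0."""
    if hypothesis == "H0":
        sd2 = 1.0
    elif hypothesis == "H1":
        if r is None or not r > 0:
            raise ValueError("H1 requires a variance ratio r > 0")
        sd2 = float(np.sqrt(r))
    else:
        raise ValueError(f"hypothesis must be 'H0' or 'H1', got {hypothesis!r}")
    g1 = rng.normal(0.0, 1.0, size=n1)
    g2 = rng.normal(0.0, sd2, size=n2)
    return two_group_array(g1, g2)


def variance_ratio(data: np.ndarray) -> float:
    """Sample variance ratio s2^2 / s1^2 (same orientation as the prior)."""
    g1, g2 = split_groups(data)
    v1 = g1.var(ddof=1)
    if v1 == 0:
        raise ValueError("first group has zero variance; the ratio is undefined")
    return float(g2.var(ddof=1) / v1)


def classical_pvalue(data: np.ndarray) -> float:
    """p-value of the classical Levene test (absolute deviations from group
    means, F(k-1, N-k) reference distribution)."""
    g1, g2 = split_groups(data)
    _, p = stats.levene(g1, g2, center="mean")
    return float(p)


def suite(n1: int, n2: int) -> ModelSuite:
    """Two-model Levene suite: equal variances vs Gamma-distributed ratio."""

    def sim_h0(params, rng):
        return simulate("H0", n1, n2, rng)

    def sim_h1(params, rng):
        return simulate("H1", n1, n2, rng, r=params["r"])

    def _batch_ratio(sd2_rows: np.ndarray, n: int, rng) -> np.ndarray:
        out = np.empty(n)
        for lo in range(0, n, _CHUNK):
            hi = min(lo + _CHUNK, n)
            v1 = rng.normal(0.0, 1.0, size=(hi - lo, n1)).var(axis=1, ddof=1)
            g2 = rng.normal(0.0, 1.0, size=(hi - lo, n2)) * sd2_rows[lo:hi, None]
            out[lo:hi] = g2.var(axis=1, ddof=1) / v1
        return out[:, None]

    def batch_h0(params, n, rng):
        return _batch_ratio(np.ones(n), n, rng)

    def batch_h1(params, n, rng):
        return _batch_ratio(np.sqrt(np.asarray(params["r"], dtype=float)), n, rng)

    models = ModelSet(
        [
            ModelSpec("H0", priors={}, simulate=sim_h0, simulate_summaries=batch_h0),
            ModelSpec(
                "H1",
                priors={"r": variance_ratio_prior()},
                simulate=sim_h1,
                simulate_summaries=batch_h1,
            ),
        ]
    )
    # MAD-scaled Euclidean default distance on the 1-D summary
    return ModelSuite(models=models, summary=variance_ratio, distance=None)
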