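"""ABC version of the Bayesian two-sample t-test.

Two candidate models for two-group data: H0 simulates both groups from the
same normal distribution; H1 places a Cauchy(0, 0.707) prior on the
population effect size d and shifts the first group by d standard
deviations.  Both simulators fix sigma = 1 — the summary statistic
(Cohen's d) is location- and scale-free, so nothing is lost.  The distance
between summaries is the squared difference of the empirical effect sizes.

The JZS default Bayes factor (numerical integration of the Cauchy-prior
marginal likelihood ratio) serves as the exact reference the ABC
approximation is validated against.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import integrate, stats

from ..inference import ModelSuite
from ..model import ModelSet, ModelSpec
from ..priors import Prior

__all__ = [
    "simulate",
    "cohens_d",
    "squared_difference",
    "suite",
    "jzs_bf10",
    "two_group_array",
    "split_groups",
    "DEFAULT_PRIOR_SCALE",
]

DEFAULT_PRIOR_SCALE = 0.707

_CHUNK = 200_000  # rows per block in the vectorized simulators


def two_group_array(group1: np.ndarray, group2: np.ndarray) -> np.ndarray:
    """Stack two samples into the canonical (n, 2) [value, group] layout."""
    g1 = np.asarray(group1, dtype=float).ravel()
    g2 = np.asarray(group2, dtype=float).ravel()
    values = np.concatenate([g1, g2])
    labels = np.concatenate([np.zeros(g1.size), np.ones(g2.size)])
    return np.column_stack([values, labels])


def split_groups(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`two_group_array`."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("two-group data must be an (n, 2) [value, group] array")
    labels = data[:, 1]
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"expected exactly 2 group labels, got {groups}")
    return data[labels == groups[0], 0], data[labels == groups[1], 0]


def simulate(
    hypothesis: str,
    n1: int,
    n2: int,
    rng: np.random.Generator,
    d: Optional[float] = None,
) -> np.ndarray:
    """One two-group dataset: group1 ~ N(delta, 1), group2 ~ N(0, 1), with
    delta = 0 under H0 and delta = d under H1."""
    if hypothesis == "H0":
        delta = 0.0
    elif hypothesis == "H1":
        if d is None:
            raise ValueError("H1 requires an effect size d")
        delta = float(d)
    else:
        raise ValueError(f"hypothesis must be 'H0' or 'H1', got {hypothesis!r}")
    g1 = rng.normal(delta, 1.0, size=n1)
    g2 = rng.normal(0.0, 1.0, size=n2)
    return two_group_array(g1, g2)


def cohens_d(data: np.ndarray) -> float:
    """Empirical effect size (mean1 - mean2) / pooled SD."""
    g1, g2 = split_groups(data)
    return _cohens_d_from_groups(g1, g2)


def _cohens_d_from_groups(g1: np.ndarray, g2: np.ndarray) -> float:
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("pooled variance is zero; Cohen's d is undefined")
    return float((g1.mean() - g2.mean()) / np.sqrt(pooled_var))


def squared_difference(d_sim, d_obs):
    """Distance between two effect sizes: (d_sim - d_obs)^2."""
    return (np.asarray(d_sim, dtype=float) - np.asarray(d_obs, dtype=float)) ** 2


def _squared_difference_distance(s_sim: np.ndarray, s_obs: np.ndarray, scales) -> np.ndarray:
    # engine distance contract: (n, 1) summary matrix vs length-1 observed
    return squared_difference(np.atleast_2d(s_sim)[:, 0], s_obs[0])


def _batch_cohens_d(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Row-wise Cohen's d for (n, n1) and (n, n2) group matrices."""
    n1, n2 = g1.shape[1], g2.shape[1]
    pooled_var = ((n1 - 1) * g1.var(axis=1, ddof=1) + (n2 - 1) * g2.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    return (g1.mean(axis=1) - g2.mean(axis=1)) / np.sqrt(pooled_var)


def suite(n1: int, n2: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> ModelSuite:
    """The two-model t-test suite for groups of size ``n1`` and ``n2``."""

    def sim_h0(params, rng):
        return simulate("H0", n1, n2, rng)

    def sim_h1(params, rng):
        return simulate("H1", n1, n2, rng, d=params["d"])

    def batch_h0(params, n, rng):
        out = np.empty(n)
        for lo in range(0, n, _CHUNK):
            hi = min(lo + _CHUNK, n)
            g1 = rng.normal(0.0, 1.0, size=(hi - lo, n1))
            g2 = rng.normal(0.0, 1.0, size=(hi - lo, n2))
            out[lo:hi] = _batch_cohens_d(g1, g2)
        return out[:, None]

    def batch_h1(params, n, rng):
        d = np.asarray(params["d"], dtype=float)
        out = np.empty(n)
        for lo in range(0, n, _CHUNK):
            hi = min(lo + _CHUNK, n)
            g1 = rng.normal(0.0, 1.0, size=(hi - lo, n1)) + d[lo:hi, None]
            g2 = rng.normal(0.0, 1.0, size=(hi - lo, n2))
            out[lo:hi] = _batch_cohens_d(g1, g2)
        return out[:, None]

    models = ModelSet(
        [
            ModelSpec("H0", priors={}, simulate=sim_h0, simulate_summaries=batch_h0),
            ModelSpec(
                "H1",
                priors={"d": Prior("cauchy", loc=0.0, scale=prior_scale)},
                simulate=sim_h1,
                simulate_summaries=batch_h1,
            ),
        ]
    )
    return ModelSuite(models=models, summary=cohens_d, distance=_squared_difference_distance)


# ---------------------------------------------------------------------------
# JZS default Bayes factor (exact reference)
# ---------------------------------------------------------------------------


def jzs_bf10(
    d_obs: float, n1: int, n2: int, scale: float = DEFAULT_PRIOR_SCALE
) -> float:
    """Default two-sample Bayes factor BF10 under a Cauchy(0, scale) prior
    on the standardized effect size.

    The marginal likelihood under H1 integrates the noncentral-t density of
    the observed t statistic over the Cauchy prior; under H0 it is the
    central-t density.  Deterministic to quadrature tolerance ~1e-8.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if not scale > 0:
        raise ValueError("prior scale must be > 0")
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    t = float(d_obs) * np.sqrt(n_eff)

    def integrand(d):
        return stats.nct.pdf(t, nu, np.sqrt(n_eff) * d) * stats.cauchy.pdf(d, 0.0, scale)

    m1, err = integrate.quad(
        integrand, -np.inf, np.inf, epsabs=1e-12, epsrel=1e-10, limit=200
    )
    if not np.isfinite(m1) or err > 1e-6 * max(m1, 1e-300):
        raise RuntimeError("quadrature for the JZS marginal likelihood did not converge")
    m0 = stats.t.pdf(t, nu)
    return float(m1 / m0)
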