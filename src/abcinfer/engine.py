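"""Rejection-ABC engine: prior-predictive simulation, distances, acceptance.

The workflow fixes a total simulation budget N, builds a reference table of
N particles (model index, parameter draw, simulated summary, distance to
the observed summary), chooses the tolerance epsilon as a low percentile of
the simulated distances, and estimates posterior model probabilities and
Bayes factors (or parameter posteriors) from the accepted particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelSet, ModelSpec, validate_dataset
from .reference_table import ReferenceTable

__all__ = [
    "ABCSettings",
    "ModelPosterior",
    "BayesFactorMatrix",
    "PosteriorSample",
    "mad_scales",
    "mad_scaled_euclidean",
    "select_epsilon",
    "reject",
    "build_reference_table",
    "model_posterior",
    "bayes_factor_matrix",
    "estimate_posterior",
    "generate_pseudo_observed",
]

#: distance contract: (simulated summaries, observed summary, scales) -> distances.
#: Called with the full (n, k) summary matrix; must return (n,) distances.
DistanceFunction = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]

DEFAULT_BF_CAP = 10_000.0


@dataclass
class ABCSettings:
    """Run settings for a rejection/random-forest ABC analysis.

    Parameters
    ----------
    n_simulations : int
        Total number of particles N in the reference table.
    percentile : float, optional
        Acceptance percentile in (0, 100]; epsilon is chosen as this
        percentile of the simulated distances (nearest rank).  Mutually
        exclusive with ``epsilon``.
    epsilon : float, optional
        Absolute acceptance threshold >= 0.
    objective : {"comparison", "estimation"}
    method : {"rejection", "random_forest"}
    seed : int, optional
        Master seed; a fixed seed makes the whole run bit-reproducible.
    bf_cap : float
        Cap applied to approximate Bayes factors when a model has zero
        accepted particles (default 10000).
    """

    n_simulations: int
    percentile: Optional[float] = 1.0
    epsilon: Optional[float] = None
    objective: str = "comparison"
    method: str = "rejection"
    seed: Optional[int] = None
    bf_cap: float = DEFAULT_BF_CAP

    def __post_init__(self):
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.epsilon is not None:
            if self.epsilon < 0:
                raise ValueError("epsilon must be >= 0")
            self.percentile = None
        elif self.percentile is None or not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")
        if self.objective not in ("comparison", "estimation"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.method not in ("rejection", "random_forest"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.bf_cap > 0:
            raise ValueError("bf_cap must be > 0")

    def resolve_epsilon(self, distances: np.ndarray) -> float:
        if self.epsilon is not None:
            return float(self.epsilon)
        return select_epsilon(distances, self.percentile)


# ---------------------------------------------------------------------------
# distances and thresholds
# ---------------------------------------------------------------------------


def mad_scales(summaries: np.ndarray) -> np.ndarray:
    """Per-dimension median absolute deviation of simulated summaries.

    Dimensions with MAD exactly zero (constant summaries) get scale 1 so
    that the scaled distance stays defined.
    """
    s = np.atleast_2d(np.asarray(summaries, dtype=float))
    if s.size == 0:
        raise ValueError("mad_scales requires at least one summary vector")
    med = np.median(s, axis=0)
    mad = np.median(np.abs(s - med), axis=0)
    mad[mad == 0] = 1.0
    return mad


def mad_scaled_euclidean(s_sim: np.ndarray, s_obs: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Euclidean distance between summaries after dividing each dimension by
    its MAD scale.  ``s_sim`` may be a single summary vector or an (n, k)
    matrix of summaries; the result is a scalar or an (n,) vector."""
    s_sim = np.asarray(s_sim, dtype=float)
    s_obs = np.asarray(s_obs, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if s_sim.shape[-1] != s_obs.shape[-1]:
        raise ValueError(
            f"summary length mismatch: {s_sim.shape[-1]} vs {s_obs.shape[-1]}"
        )
    z = (s_sim - s_obs) / scales
    return np.sqrt(np.sum(z * z, axis=-1))


def select_epsilon(distances: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile of the simulated distances.

    Returns the ceil(percentile/100 * N)-th smallest distance, so that
    accepting ``d <= epsilon`` keeps (at least) that share of particles.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("select_epsilon requires at least one distance")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    rank = int(np.ceil(percentile / 100.0 * d.size))
    return float(np.sort(d)[rank - 1])


def reject(table: ReferenceTable, epsilon: float) -> ReferenceTable:
    """Particles with distance <= epsilon, original order preserved."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return table.accepted(epsilon)


# ---------------------------------------------------------------------------
# reference-table construction
# ---------------------------------------------------------------------------


def _as_distance_matrix_fn(distance_fn: Optional[DistanceFunction]) -> DistanceFunction:
    if distance_fn is None:
        return mad_scaled_euclidean
    return distance_fn


def _simulate_summaries_loop(
    model: ModelSpec,
    params: Mapping[str, np.ndarray],
    n: int,
    k: int,
    summary_fn: Callable[[np.ndarray], np.ndarray],
    observed_shape: Optional[tuple],
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty((n, k))
    names = list(params)
    for i in range(n):
        theta = {name: params[name][i] for name in names}
        data = np.asarray(model.simulate(theta, rng))
        if observed_shape is not None and data.shape != observed_shape:
            raise ValueError(
                f"model {model.name!r} simulated data of shape {data.shape}, "
                f"but the observed data has shape {observed_shape}"
            )
        s = np.atleast_1d(np.asarray(summary_fn(data), dtype=float))
        if s.shape != (k,):
            raise ValueError(
                f"summary of model {model.name!r} has length {s.size}, expected {k}"
            )
        if not np.all(np.isfinite(s)):
            raise ValueError(f"non-finite summary from model {model.name!r}")
        out[i] = s
    return out


def build_reference_table(
    models: ModelSet,
    observed_summary: np.ndarray,
    settings: ABCSettings,
    summary_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    distance_fn: Optional[DistanceFunction] = None,
    observed_shape: Optional[tuple] = None,
    rng: Optional[np.random.Generator] = None,
) -> ReferenceTable:
    """Simulate N particles and compute their distances to the observed summary.

    Construction is two-pass: all N summaries are simulated first, then the
    MAD scales of the simulated summaries are computed and passed to the
    distance function, so that scaled distances use the final scales.

    Model indices are drawn from P(m); each model's parameters are drawn
    from its priors; each particle is summarized by ``summary_fn`` (or by
    the model's fused ``simulate_summaries`` when every model provides one).

    Parameters not present in a particle's model are NaN in that row.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    obs = np.atleast_1d(np.asarray(observed_summary, dtype=float))
    k = obs.shape[0]
    n = settings.n_simulations

    # step 1: model indicator draws m* ~ P(m)
    model_idx = rng.choice(len(models), size=n, p=models.prior_probabilities)

    all_param_names = models.parameter_names
    summaries = np.empty((n, k))
    param_cols = {name: np.full(n, np.nan) for name in all_param_names}

    fused = all(m.simulate_summaries is not None for m in models) and summary_fn is None
    for mi, model in enumerate(models):
        rows = np.flatnonzero(model_idx == mi)
        if rows.size == 0:
            continue
        # step 2: theta* ~ P(theta | m*), vectorized per model
        params = model.draw_parameters(rng, size=rows.size)
        for name, values in params.items():
            param_cols[name][rows] = values
        # step 3: D* ~ f(D | theta*, m*), then s(D*)
        if fused:
            s = np.atleast_2d(
                np.asarray(model.simulate_summaries(params, rows.size, rng), dtype=float)
            )
            if s.shape != (rows.size, k):
                raise ValueError(
                    f"simulate_summaries of model {model.name!r} returned shape "
                    f"{s.shape}, expected {(rows.size, k)}"
                )
            if not np.all(np.isfinite(s)):
                raise ValueError(f"non-finite summary from model {model.name!r}")
        else:
            if summary_fn is None:
                raise ValueError(
                    "summary_fn is required unless every model provides simulate_summaries"
                )
            if model.simulate is None:
                raise ValueError(f"model {model.name!r} has no simulator")
            s = _simulate_summaries_loop(
                model, params, rows.size, k, summary_fn, observed_shape, rng
            )
        summaries[rows] = s

    # step 4: distances with the final MAD scales of the simulated summaries
    scales = mad_scales(summaries)
    dist = _as_distance_matrix_fn(distance_fn)(summaries, obs, scales)
    dist = np.asarray(dist, dtype=float).reshape(n)
    if np.any(dist < 0) or not np.all(np.isfinite(dist)):
        raise ValueError("distance function returned negative or non-finite values")

    return ReferenceTable(model_idx, summaries, param_cols, dist)


# ---------------------------------------------------------------------------
# model comparison estimates
# ---------------------------------------------------------------------------


@dataclass
class ModelPosterior:
    """Approximate posterior model probabilities from accepted particles.

    ``raw_fraction`` is accepted_m / N (the literal acceptance-fraction
    estimate, which sums to the overall acceptance rate across models);
    ``probabilities`` renormalizes over accepted particles so the entries
    sum to one.
    """

    model_names: list[str]
    accepted_counts: np.ndarray
    n_simulations: int

    def __post_init__(self):
        self.accepted_counts = np.asarray(self.accepted_counts, dtype=int)
        if self.accepted_counts.sum() == 0:
            raise ValueError(
                "no particles were accepted for any model: the threshold is too strict"
            )

    @property
    def raw_fraction(self) -> np.ndarray:
        return self.accepted_counts / self.n_simulations

    @property
    def probabilities(self) -> np.ndarray:
        return self.accepted_counts / self.accepted_counts.sum()

    @classmethod
    def from_probabilities(cls, model_names, probabilities, n_effective=1_000_000):
        """Build from an externally estimated probability vector (e.g. the
        random-forest classifier), quantized on a large virtual count."""
        probs = np.asarray(probabilities, dtype=float)
        counts = np.round(probs * n_effective).astype(int)
        return cls(list(model_names), counts, n_effective)

    def to_series(self) -> pd.Series:
        return pd.Series(self.probabilities, index=self.model_names, name="probability")


@dataclass
class BayesFactorMatrix:
    """Pairwise approximate Bayes factors BF_ij between all model pairs.

    BF_ij multiplies the prior odds of model i over model j into posterior
    odds.  Cells whose denominator model had zero accepted particles are set
    to the cap (and flagged); zero-numerator cells get 1/cap.
    """

    model_names: list[str]
    values: np.ndarray
    capped: np.ndarray
    cap: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.model_names, columns=self.model_names)

    def __getitem__(self, pair) -> float:
        i, j = pair
        if isinstance(i, str):
            i = self.model_names.index(i)
        if isinstance(j, str):
            j = self.model_names.index(j)
        return float(self.values[i, j])


def model_posterior(
    accepted: ReferenceTable, settings: ABCSettings, models: ModelSet
) -> ModelPosterior:
    """Eq.-style acceptance-fraction estimate of P(m | D0) per model."""
    counts = accepted.model_counts(len(models))
    return ModelPosterior(models.names, counts, settings.n_simulations)


def bayes_factor_matrix(
    posterior: ModelPosterior,
    models: ModelSet,
    cap: float = DEFAULT_BF_CAP,
) -> BayesFactorMatrix:
    """Pairwise BF_ij = (P(m_i|D0)/P(m_j|D0)) * (P(m_j)/P(m_i)).

    Zero accepted particles for the denominator model indicate extreme
    support for the numerator model; such cells are set to ``cap``
    (numerator-zero cells to ``1/cap``) and flagged.  All cells are clipped
    to [1/cap, cap].
    """
    if not cap > 0:
        raise ValueError("cap must be > 0")
    post = posterior.probabilities
    prior = models.prior_probabilities
    m = len(models)
    values = np.ones((m, m))
    capped = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            if post[j] == 0:
                values[i, j] = cap
                capped[i, j] = True
            elif post[i] == 0:
                values[i, j] = 1.0 / cap
                capped[i, j] = True
            else:
                bf = (post[i] / post[j]) * (prior[j] / prior[i])
                values[i, j] = float(np.clip(bf, 1.0 / cap, cap))
                capped[i, j] = bf > cap or bf < 1.0 / cap
    return BayesFactorMatrix(models.names, values, capped, cap)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass
class PosteriorSample:
    """Accepted parameter draws of one model plus per-parameter summaries."""

    model_name: str
    draws: pd.DataFrame
    epsilon: float = field(default=np.nan)

    def __post_init__(self):
        if len(self.draws) == 0:
            raise ValueError(
                f"no accepted particles for model {self.model_name!r}: "
                "the threshold is too strict"
            )

    @property
    def n_accepted(self) -> int:
        return len(self.draws)

    def summary(self) -> pd.DataFrame:
        """mean, median, sd and central quantiles per parameter."""
        rows = {}
        for name in self.draws.columns:
            x = self.draws[name].to_numpy(dtype=float)
            q = np.quantile(x, _QUANTILES)
            rows[name] = {
                "mean": x.mean(),
                "median": q[2],
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "q2.5%": q[0],
                "q25%": q[1],
                "q75%": q[3],
                "q97.5%": q[4],
            }
        return pd.DataFrame(rows).T

    def mean(self) -> pd.Series:
        return self.draws.mean()


def estimate_posterior(
    table: ReferenceTable, model_index: int, epsilon: float, model_name: str | None = None
) -> PosteriorSample:
    """Accepted parameter draws of ``model_index`` at threshold ``epsilon``."""
    accepted = table.accepted(epsilon)
    mask = accepted.model_indices == model_index
    draws = accepted.parameters.iloc[np.flatnonzero(mask)].dropna(axis=1, how="all")
    draws = draws.reset_index(drop=True)
    return PosteriorSample(model_name or f"model_{model_index}", draws, epsilon)


# ---------------------------------------------------------------------------
# pseudo-observed data ("model test" mode)
# ---------------------------------------------------------------------------


def generate_pseudo_observed(
    model: ModelSpec,
    fixed_params: Mapping[str, float] | None = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """One dataset simulated from ``model`` at fixed parameter values.

    Used instead of importing observed data, to check whether the analysis
    recovers the generating model or its parameters.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fixed_params = dict(fixed_params or {})
    expected = set(model.parameter_names)
    given = set(fixed_params)
    if given != expected:
        raise ValueError(
            f"fixed parameters {sorted(given)} do not match model "
            f"{model.name!r} parameters {sorted(expected)}"
        )
    if model.simulate is None:
        raise ValueError(f"model {model.name!r} has no simulator")
    return validate_dataset(model.simulate(fixed_params, rng), f"simulated data from {model.name!r}")
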