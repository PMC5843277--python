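"""Model-comparison and parameter-estimation front ends.

These classes wrap the functional engine in the familiar model/results
idiom: construct the analysis object from the observed data (or an observed
summary) and the candidate models, call :meth:`fit`, and read estimates and
diagnostics off the returned results object.

Example
-------
>>> from abcinfer.examples import ttest
>>> suite = ttest.suite()
>>> comp = ABCModelComparison.from_data(obs, suite)        # doctest: +SKIP
>>> res = comp.fit(n_simulations=100_000, percentile=1, seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from . import engine
from .engine import (
    ABCSettings,
    BayesFactorMatrix,
    ModelPosterior,
    PosteriorSample,
    bayes_factor_matrix,
    build_reference_table,
    estimate_posterior,
    model_posterior,
    reject,
)
from .model import ModelSet, validate_dataset
from .reference_table import ReferenceTable

__all__ = [
    "ModelSuite",
    "ABCModelComparison",
    "ABCParameterEstimation",
    "ComparisonResults",
    "EstimationResults",
]


@dataclass
class ModelSuite:
    """A pluggable analysis definition: candidate models plus the shared
    summary function and (optional) distance function.

    ``distance`` follows the engine contract — it receives the full
    ``(n, k)`` matrix of simulated summaries, the observed summary and the
    MAD scales, and returns ``(n,)`` distances.  When None, the MAD-scaled
    Euclidean default is used.
    """

    models: ModelSet
    summary: Optional[Callable[[np.ndarray], np.ndarray]] = None
    distance: Optional[engine.DistanceFunction] = None

    def observed_summary(self, data: np.ndarray) -> np.ndarray:
        if self.summary is None:
            raise ValueError("suite has no summary function to apply to observed data")
        return np.atleast_1d(np.asarray(self.summary(validate_dataset(data)), dtype=float))


class _ABCAnalysis:
    """Shared plumbing for comparison and estimation front ends."""

    def __init__(
        self,
        observed_summary: np.ndarray,
        models: ModelSet,
        summary: Optional[Callable] = None,
        distance: Optional[engine.DistanceFunction] = None,
        observed_shape: Optional[tuple] = None,
    ):
        self.observed_summary = np.atleast_1d(np.asarray(observed_summary, dtype=float))
        if not np.all(np.isfinite(self.observed_summary)):
            raise ValueError("observed summary contains non-finite values")
        self.models = models
        self.summary = summary
        self.distance = distance
        self.observed_shape = observed_shape

    @classmethod
    def from_data(cls, observed_data: np.ndarray, suite: ModelSuite, **kwargs):
        """Build the analysis from raw observed data and a model suite."""
        data = validate_dataset(observed_data, "observed data")
        return cls(
            suite.observed_summary(data),
            suite.models,
            summary=suite.summary,
            distance=suite.distance,
            observed_shape=data.shape,
            **kwargs,
        )

    @classmethod
    def from_suite(cls, observed_summary: np.ndarray, suite: ModelSuite, **kwargs):
        """Build from a precomputed observed summary and a model suite."""
        return cls(
            observed_summary,
            suite.models,
            summary=suite.summary,
            distance=suite.distance,
            **kwargs,
        )

    def build_table(self, settings: ABCSettings, rng=None) -> ReferenceTable:
        return build_reference_table(
            self.models,
            self.observed_summary,
            settings,
            summary_fn=self.summary if not self._fused() else None,
            distance_fn=self.distance,
            observed_shape=self.observed_shape,
            rng=rng,
        )

    def _fused(self) -> bool:
        return all(m.simulate_summaries is not None for m in self.models)


class ABCModelComparison(_ABCAnalysis):
    """Approximate Bayesian model comparison by rejection sampling or a
    random-forest classifier on the reference table."""

    def fit(
        self,
        n_simulations: int = 100_000,
        percentile: Optional[float] = 1.0,
        epsilon: Optional[float] = None,
        method: str = "rejection",
        seed: Optional[int] = None,
        bf_cap: float = engine.DEFAULT_BF_CAP,
        table: Optional[ReferenceTable] = None,
        n_trees: int = 500,
    ) -> "ComparisonResults":
        """Run the analysis and return a :class:`ComparisonResults`.

        With ``method="rejection"`` the results carry the acceptance-based
        posterior model probabilities and the Bayes-factor matrix; with
        ``method="random_forest"`` the probabilities come from a classifier
        trained on (summary -> model index) pairs of the reference table.
        A prebuilt ``table`` (e.g. imported from CSV) can be supplied.
        """
        settings = ABCSettings(
            n_simulations=n_simulations,
            percentile=percentile,
            epsilon=epsilon,
            objective="comparison",
            method=method,
            seed=seed,
            bf_cap=bf_cap,
        )
        if table is None:
            table = self.build_table(settings)
        else:
            settings.n_simulations = table.n_rows
        eps = settings.resolve_epsilon(table.distances)
        accepted = reject(table, eps)
        if method == "rejection":
            posterior = model_posterior(accepted, settings, self.models)
        else:
            from .rf import RFSettings, rf_model_probabilities

            posterior = rf_model_probabilities(
                table,
                self.observed_summary,
                RFSettings(n_trees=n_trees, seed=seed),
                model_names=self.models.names,
            )
        bf = bayes_factor_matrix(posterior, self.models, cap=bf_cap)
        return ComparisonResults(self, settings, table, eps, posterior, bf)


class ABCParameterEstimation(_ABCAnalysis):
    """Rejection-ABC posterior sampling for the parameters of one model."""

    def fit(
        self,
        model: int | str = 0,
        n_simulations: int = 100_000,
        percentile: Optional[float] = 1.0,
        epsilon: Optional[float] = None,
        seed: Optional[int] = None,
        table: Optional[ReferenceTable] = None,
    ) -> "EstimationResults":
        if isinstance(model, str):
            model = self.models.index_of(model)
        settings = ABCSettings(
            n_simulations=n_simulations,
            percentile=percentile,
            epsilon=epsilon,
            objective="estimation",
            seed=seed,
        )
        if table is None:
            table = self.build_table(settings)
        else:
            settings.n_simulations = table.n_rows
        eps = settings.resolve_epsilon(table.distances)
        sample = estimate_posterior(table, model, eps, self.models[model].name)
        return EstimationResults(self, settings, table, eps, model, sample)


@dataclass
class ComparisonResults:
    """Results of an ABC model comparison."""

    analysis: ABCModelComparison
    settings: ABCSettings
    reference_table: ReferenceTable
    epsilon: float
    posterior: ModelPosterior
    bayes_factors: BayesFactorMatrix

    @property
    def model_probabilities(self) -> pd.Series:
        return self.posterior.to_series()

    def bf(self, numerator: int | str, denominator: int | str) -> float:
        """Approximate Bayes factor of one model over another."""
        return self.bayes_factors[numerator, denominator]

    def log_bf(self, numerator: int | str, denominator: int | str) -> float:
        return float(np.log(self.bf(numerator, denominator)))

    def summary(self) -> str:
        lines = [
            "ABC model comparison",
            "====================",
            f"method:       {self.settings.method}",
            f"N simulated:  {self.settings.n_simulations}",
            f"epsilon:      {self.epsilon:.6g}"
            + (
                f" ({self.settings.percentile}% percentile)"
                if self.settings.percentile is not None
                else ""
            ),
            f"accepted:     {int(self.posterior.accepted_counts.sum())}"
            if self.settings.method == "rejection"
            else "accepted:     (random-forest probabilities)",
            "",
            "Posterior model probabilities:",
            self.model_probabilities.round(4).to_string(),
            "",
            "Approximate Bayes factors (row over column):",
            self.bayes_factors.to_frame().round(4).to_string(),
        ]
        return "\n".join(lines)


@dataclass
class EstimationResults:
    """Results of ABC parameter estimation for one model."""

    analysis: ABCParameterEstimation
    settings: ABCSettings
    reference_table: ReferenceTable
    epsilon: float
    model_index: int
    posterior: PosteriorSample

    @property
    def draws(self) -> pd.DataFrame:
        """All accepted posterior parameter draws."""
        return self.posterior.draws

    def summary(self) -> pd.DataFrame:
        return self.posterior.summary()

    def __str__(self) -> str:
        return (
            f"ABC posterior for model {self.posterior.model_name!r} "
            f"({self.posterior.n_accepted} accepted particles, "
            f"epsilon={self.epsilon:.6g})\n"
            + self.summary().round(4).to_string()
        )
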