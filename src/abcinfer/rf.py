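"""Random-forest model comparison on the ABC reference table.

Instead of accepting particles by distance, a random-forest classifier is
trained to map simulated summary statistics to the index of the generating
model; its aggregated class-probability vector evaluated at the observed
summary is reported as the posterior model probability.  Class probabilities
are soft votes: the forest averages the class frequencies of the leaves each
tree routes the observed summary to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .engine import ModelPosterior
from .reference_table import ReferenceTable

__all__ = ["RFSettings", "rf_model_probabilities", "fit_rf_classifier"]


@dataclass
class RFSettings:
    """Forest hyper-parameters.

    n_trees defaults to 500; max_features follows the usual classification
    rule (sqrt of the number of summary statistics).
    """

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def fit_rf_classifier(table: ReferenceTable, settings: RFSettings) -> RandomForestClassifier:
    """Train the bootstrap-aggregated forest on (summary -> model index)."""
    labels = table.model_indices
    if len(np.unique(labels)) < 2:
        raise ValueError("random-forest model choice needs >= 2 models in the table")
    if table.k == 0:
        raise ValueError("reference table has no summary statistics")
    clf = RandomForestClassifier(
        n_estimators=settings.n_trees,
        max_features=settings.max_features,
        bootstrap=True,
        random_state=settings.seed,
        n_jobs=1,
    )
    clf.fit(table.summaries, labels)
    return clf


def rf_model_probabilities(
    table: ReferenceTable,
    observed_summary: np.ndarray,
    settings: RFSettings | None = None,
    model_names: Optional[Sequence[str]] = None,
) -> ModelPosterior:
    """Posterior model probabilities at the observed summary.

    The returned vector sums to one.  Models absent from the reference
    table (never drawn) get probability zero.
    """
    settings = settings or RFSettings()
    clf = fit_rf_classifier(table, settings)
    obs = np.atleast_2d(np.asarray(observed_summary, dtype=float))
    proba = clf.predict_proba(obs)[0]
    n_models = (
        len(model_names) if model_names is not None else int(table.model_indices.max()) + 1
    )
    full = np.zeros(n_models)
    full[clf.classes_] = proba
    names = (
        list(model_names) if model_names is not None else [f"model_{i}" for i in range(n_models)]
    )
    return ModelPosterior.from_probabilities(names, full)
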