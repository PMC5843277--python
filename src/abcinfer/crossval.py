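"""Leave-one-out cross-validation on the reference table.

One simulated particle at a time is treated as pseudo-observed: its summary
replaces the observed summary, distances and the acceptance threshold are
recomputed on the remaining particles, and the ABC estimate is compared with
the held-out particle's truth.  For model comparison this yields a confusion
matrix of generating vs selected model; for parameter estimation it yields
the prediction error

    E_pred = sum_i (theta_hat_i - theta_i)^2 / Var(theta),

with Var(theta) the empirical variance of the true held-out values (one
variance per parameter).  Dividing additionally by the number of replicates
is available via ``per_replicate=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import ABCSettings, DistanceFunction, mad_scaled_euclidean, mad_scales
from .reference_table import ReferenceTable

__all__ = [
    "ConfusionMatrix",
    "PredictionError",
    "loo_model_cv",
    "loo_param_cv",
    "prediction_error",
    "plot_confusion_matrix",
    "plot_true_vs_predicted",
]


@dataclass
class ConfusionMatrix:
    """counts[g, p]: held-out particles generated by model g and classified
    as model p."""

    counts: np.ndarray
    model_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.model_names, name="generated"),
            columns=pd.Index(self.model_names, name="selected"),
        )

    @property
    def n_reps(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Share of held-out particles assigned to their generating model."""
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass
class PredictionError:
    """Eq-style prediction error per parameter plus the (true, predicted)
    pairs it was computed from."""

    e_pred: pd.Series
    pairs: pd.DataFrame  # columns: parameter, true, predicted

    def pairs_for(self, parameter: str) -> pd.DataFrame:
        return self.pairs[self.pairs["parameter"] == parameter]


def prediction_error(
    theta_true: Sequence[float],
    theta_pred: Sequence[float],
    variance: Optional[float] = None,
    per_replicate: bool = False,
) -> float:
    """Scaled squared prediction error for one parameter.

    ``variance`` defaults to the empirical variance of ``theta_true``; the
    error is invariant under affine rescaling of the parameter when the
    default is used.
    """
    t = np.asarray(theta_true, dtype=float)
    p = np.asarray(theta_pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError("true and predicted arrays must have equal length")
    if variance is None:
        variance = float(np.var(t, ddof=1))
    if variance == 0:
        raise ValueError("variance of the true parameter values is zero")
    err = float(np.sum((p - t) ** 2) / variance)
    if per_replicate:
        err /= t.size
    return err


def _loo_distances(
    summaries: np.ndarray, pseudo_obs: np.ndarray, distance_fn: DistanceFunction
) -> np.ndarray:
    scales = mad_scales(summaries)
    return np.asarray(distance_fn(summaries, pseudo_obs, scales), dtype=float)


def loo_model_cv(
    table: ReferenceTable,
    n_reps: int,
    settings: ABCSettings,
    rng: Optional[np.random.Generator] = None,
    distance_fn: Optional[DistanceFunction] = None,
    model_names: Optional[Sequence[str]] = None,
) -> ConfusionMatrix:
    """Confusion matrix of generating vs rejection-selected model.

    Held-out rows are sampled without replacement; the selected model is the
    one with the highest normalized posterior probability among the
    particles accepted at the configured threshold.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_reps > table.n_rows:
        raise ValueError(f"n_reps={n_reps} exceeds the table size {table.n_rows}")
    n_models = int(table.model_indices.max()) + 1
    if n_models < 2:
        raise ValueError("model cross-validation needs >= 2 models")
    distance_fn = distance_fn or mad_scaled_euclidean
    names = list(model_names) if model_names is not None else [f"model_{i}" for i in range(n_models)]

    held_out = rng.choice(table.n_rows, size=n_reps, replace=False)
    counts = np.zeros((n_models, n_models), dtype=int)
    keep = np.ones(table.n_rows, dtype=bool)
    for i in held_out:
        keep[i] = False
        summaries = table.summaries[keep]
        labels = table.model_indices[keep]
        dist = _loo_distances(summaries, table.summaries[i], distance_fn)
        eps = settings.resolve_epsilon(dist)
        acc_labels = labels[dist <= eps]
        acc_counts = np.bincount(acc_labels, minlength=n_models)
        selected = int(np.argmax(acc_counts))
        counts[table.model_indices[i], selected] += 1
        keep[i] = True
    return ConfusionMatrix(counts, names)


def loo_param_cv(
    table: ReferenceTable,
    model_index: int,
    n_reps: int,
    settings: ABCSettings,
    rng: Optional[np.random.Generator] = None,
    distance_fn: Optional[DistanceFunction] = None,
    per_replicate: bool = False,
) -> PredictionError:
    """Prediction error of the ABC posterior-mean point estimate.

    Held-out rows are drawn (without replacement) from the particles of
    ``model_index``; for each, the posterior mean over the accepted
    particles of that model (excluding the held-out row) is the point
    prediction.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 so the truth variance is defined")
    distance_fn = distance_fn or mad_scaled_euclidean
    candidate_rows = np.flatnonzero(table.model_indices == model_index)
    if candidate_rows.size < n_reps:
        raise ValueError(
            f"model {model_index} has only {candidate_rows.size} particles, "
            f"fewer than n_reps={n_reps}"
        )
    param_names = [
        c for c in table.parameter_names
        if table.parameters[c].iloc[candidate_rows].notna().all()
    ]
    if not param_names:
        raise ValueError(f"model {model_index} has no parameters to cross-validate")

    held_out = rng.choice(candidate_rows, size=n_reps, replace=False)
    records = []
    keep = np.ones(table.n_rows, dtype=bool)
    for i in held_out:
        keep[i] = False
        summaries = table.summaries[keep]
        dist = _loo_distances(summaries, table.summaries[i], distance_fn)
        eps = settings.resolve_epsilon(dist)
        rows_kept = np.flatnonzero(keep)
        acc_rows = rows_kept[dist <= eps]
        acc_rows = acc_rows[table.model_indices[acc_rows] == model_index]
        keep[i] = True
        if acc_rows.size == 0:
            raise ValueError(
                "no accepted particles of the target model for a held-out row; "
                "loosen the threshold"
            )
        pred = table.parameters[param_names].iloc[acc_rows].mean()
        for name in param_names:
            records.append(
                {
                    "parameter": name,
                    "true": float(table.parameters[name].iloc[i]),
                    "predicted": float(pred[name]),
                }
            )
    pairs = pd.DataFrame(records)
    errors = {}
    for name in param_names:
        sub = pairs[pairs["parameter"] == name]
        errors[name] = prediction_error(
            sub["true"], sub["predicted"], per_replicate=per_replicate
        )
    return PredictionError(pd.Series(errors, name="E_pred"), pairs)


# ---------------------------------------------------------------------------
# optional plotting hooks
# ---------------------------------------------------------------------------


def plot_confusion_matrix(cm: ConfusionMatrix, ax=None):
    """Heatmap of the confusion matrix (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = cm.to_frame()
    im = ax.imshow(frame.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(cm.model_names)), cm.model_names)
    ax.set_yticks(range(len(cm.model_names)), cm.model_names)
    ax.set_xlabel("selected model")
    ax.set_ylabel("generating model")
    for (g, p), v in np.ndenumerate(cm.counts):
        ax.text(p, g, str(v), ha="center", va="center")
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_true_vs_predicted(pe: PredictionError, parameter: str, ax=None):
    """Scatter of true vs ABC-predicted parameter values (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = pe.pairs_for(parameter)
    ax.scatter(sub["true"], sub["predicted"], s=12, alpha=0.7)
    lo = min(sub["true"].min(), sub["predicted"].min())
    hi = max(sub["true"].max(), sub["predicted"].max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel(f"true {parameter}")
    ax.set_ylabel(f"predicted {parameter}")
    ax.set_title(f"E_pred = {pe.e_pred[parameter]:.3g}")
    return ax
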