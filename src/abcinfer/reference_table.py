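"""The ABC reference table.

The reference table is the central data structure of rejection ABC: one row
per simulated particle holding the model index, the k summary statistics of
the simulated dataset, the parameter values used to simulate it, and the
distance to the observed summary.  Parameters a model does not have are
stored as NaN in that model's rows.

Column layout (also the on-disk CSV dialect, see :mod:`abcinfer.io`):
``idx, s_1 .. s_k, p_<name> ..., distance``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ReferenceTable"]


class ReferenceTable:
    """Particles from the prior-predictive sweep, one per row.

    Parameters
    ----------
    model_indices : (N,) int array
        Index of the generating model per particle.
    summaries : (N, k) float array
        Summary statistics of each simulated dataset.
    parameters : DataFrame or mapping of str to (N,) arrays
        Parameter values per particle; NaN where the particle's model does
        not have that parameter.
    distances : (N,) float array
        Distance of each simulated summary to the observed summary.
    """

    def __init__(self, model_indices, summaries, parameters, distances):
        idx = np.asarray(model_indices, dtype=int)
        s = np.atleast_2d(np.asarray(summaries, dtype=float))
        if s.shape[0] != idx.shape[0] and s.shape[1] == idx.shape[0]:
            s = s.T
        d = np.asarray(distances, dtype=float)
        params = pd.DataFrame(parameters)
        n = idx.shape[0]
        if params.shape[1] == 0:
            params = pd.DataFrame(index=pd.RangeIndex(n))
        if s.shape[0] != n or d.shape[0] != n or len(params) != n:
            raise ValueError("model_indices, summaries, parameters and distances disagree in length")
        if np.any(idx < 0):
            raise ValueError("model indices must be >= 0")
        if np.any(d < 0):
            raise ValueError("distances must be >= 0")
        if not np.all(np.isfinite(s)):
            raise ValueError("summaries contain non-finite values")
        self.model_indices = idx
        self.summaries = s
        self.parameters = params.reset_index(drop=True)
        self.distances = d

    # -- basic properties -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.model_indices.shape[0]

    @property
    def k(self) -> int:
        """Number of summary statistics."""
        return self.summaries.shape[1]

    @property
    def parameter_names(self) -> list[str]:
        return list(self.parameters.columns)

    def __len__(self) -> int:
        return self.n_rows

    def __repr__(self) -> str:
        return (
            f"<ReferenceTable: {self.n_rows} particles, k={self.k}, "
            f"params={self.parameter_names}, models={sorted(set(self.model_indices))}>"
        )

    # -- subsetting -------------------------------------------------------

    def subset(self, mask) -> "ReferenceTable":
        """Row subset (order preserved)."""
        mask = np.asarray(mask)
        return ReferenceTable(
            self.model_indices[mask],
            self.summaries[mask],
            self.parameters.iloc[np.flatnonzero(mask)] if mask.dtype == bool else self.parameters.iloc[mask],
            self.distances[mask],
        )

    def drop_row(self, i: int) -> "ReferenceTable":
        mask = np.ones(self.n_rows, dtype=bool)
        mask[i] = False
        return self.subset(mask)

    def accepted(self, epsilon: float) -> "ReferenceTable":
        """Particles with distance <= epsilon (may be empty)."""
        return self.subset(self.distances <= epsilon)

    def model_counts(self, n_models: int) -> np.ndarray:
        return np.bincount(self.model_indices, minlength=n_models)

    # -- DataFrame round trip ---------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame in the canonical idx, s_*, p_*, distance layout."""
        data = {"idx": self.model_indices}
        for j in range(self.k):
            data[f"s_{j + 1}"] = self.summaries[:, j]
        for name in self.parameter_names:
            data[f"p_{name}"] = self.parameters[name].to_numpy()
        data["distance"] = self.distances
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceTable":
        """Build from a DataFrame in the canonical column layout."""
        for col in ("idx", "distance"):
            if col not in df.columns:
                raise ValueError(f"reference table is missing required column {col!r}")
        s_cols = sorted(
            (c for c in df.columns if c.startswith("s_")),
            key=lambda c: int(c[2:]),
        )
        if not s_cols:
            raise ValueError("reference table has no summary columns (s_1 .. s_k)")
        expected = [f"s_{j}" for j in range(1, len(s_cols) + 1)]
        if s_cols != expected:
            raise ValueError(
                f"summary columns must be numbered contiguously from s_1; got {s_cols}"
            )
        p_cols = [c for c in df.columns if c.startswith("p_")]
        params = {c[2:]: df[c].to_numpy(dtype=float) for c in p_cols}
        return cls(
            df["idx"].to_numpy(dtype=int),
            df[s_cols].to_numpy(dtype=float),
            params,
            df["distance"].to_numpy(dtype=float),
        )

    def equals(self, other: "ReferenceTable") -> bool:
        return (
            np.array_equal(self.model_indices, other.model_indices)
            and np.array_equal(self.summaries, other.summaries)
            and np.array_equal(self.distances, other.distances)
            and self.parameter_names == other.parameter_names
            and np.allclose(
                self.parameters.to_numpy(dtype=float),
                other.parameters.to_numpy(dtype=float),
                equal_nan=True,
                rtol=0,
                atol=0,
            )
        )
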