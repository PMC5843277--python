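"""Model specifications for likelihood-free inference.

A :class:`ModelSpec` bundles a model's name, its prior model probability
P(m), an ordered mapping of parameter priors P(theta | m), and a simulator
f(D | theta, m).  A :class:`ModelSet` is the ordered collection of candidate
models whose prior probabilities sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .priors import Prior

__all__ = ["ModelSpec", "ModelSet", "validate_dataset"]

#: simulator contract: params mapping (name -> scalar) and RNG in, dataset out
Simulator = Callable[[Mapping[str, float], np.random.Generator], np.ndarray]

#: optional fused fast path: (params mapping of name -> length-n arrays,
#: n, RNG) in, (n, k) summary matrix out; must agree with the project's
#: summary function applied to the per-particle simulator output
BatchSummarySimulator = Callable[
    [Mapping[str, np.ndarray], int, np.random.Generator], np.ndarray
]


def validate_dataset(data: np.ndarray, context: str = "dataset") -> np.ndarray:
    """Check that a dataset is a nonempty finite 1-D or 2-D numeric array."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim not in (1, 2):
        raise ValueError(f"{context} must be 1-D or 2-D, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError(f"{context} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{context} contains non-finite values")
    return arr


@dataclass
class ModelSpec:
    """One candidate model: name, parameter priors, simulator, P(m).

    Parameters
    ----------
    name : str
        Unique model identifier.
    priors : mapping of str to Prior
        Ordered parameter priors; empty for parameter-free models.
    simulate : callable(params, rng) -> ndarray
        Draws one dataset given a realized parameter mapping.  The output
        shape must match the observed data.
    prior_probability : float, optional
        P(m).  If omitted, the owning :class:`ModelSet` assigns equal
        probabilities.
    simulate_summaries : callable, optional
        Vectorized shortcut mapping per-particle parameter arrays directly
        to an ``(n, k)`` summary matrix; used by the engine when every model
        in the set provides it.
    """

    name: str
    priors: Mapping[str, Prior] = field(default_factory=dict)
    simulate: Optional[Simulator] = None
    prior_probability: Optional[float] = None
    simulate_summaries: Optional[BatchSummarySimulator] = None

    def __post_init__(self):
        self.priors = dict(self.priors)
        for pname, prior in self.priors.items():
            if not isinstance(prior, Prior):
                raise TypeError(f"prior for {pname!r} must be a Prior, got {type(prior)}")
        if self.prior_probability is not None and not 0 <= self.prior_probability <= 1:
            raise ValueError(f"prior_probability must lie in [0, 1], got {self.prior_probability}")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.priors)

    def draw_parameters(self, rng: np.random.Generator, size: int | None = None) -> dict:
        """Draw parameters from the model's priors (scalars, or arrays of ``size``)."""
        return {name: prior.sample(rng, size=size) for name, prior in self.priors.items()}


class ModelSet:
    """Ordered set of candidate models with prior model probabilities.

    Models without an explicit ``prior_probability`` share the probability
    mass left over by those that declare one (equal split; all-equal when
    none declares one).
    """

    def __init__(self, models: Sequence[ModelSpec]):
        models = list(models)
        if not models:
            raise ValueError("ModelSet requires at least one model")
        names = [m.name for m in models]
        if len(set(names)) != len(names):
            raise ValueError(f"model names must be unique, got {names}")
        self.models = models
        self.prior_probabilities = self._resolve_probabilities(models)

    @staticmethod
    def _resolve_probabilities(models: Sequence[ModelSpec]) -> np.ndarray:
        fixed = np.array([m.prior_probability for m in models], dtype=object)
        free = [i for i, p in enumerate(fixed) if p is None]
        probs = np.zeros(len(models))
        declared = sum(p for p in fixed if p is not None)
        if declared > 1 + 1e-9:
            raise ValueError(f"declared prior model probabilities sum to {declared} > 1")
        for i, p in enumerate(fixed):
            if p is not None:
                probs[i] = p
        if free:
            probs[free] = (1.0 - declared) / len(free)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"prior model probabilities must sum to 1, got {probs.sum()}")
        return probs

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i: int) -> ModelSpec:
        return self.models[i]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.models]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no model named {name!r}; have {self.names}") from None

    @property
    def parameter_names(self) -> list[str]:
        """Union of parameter names across models, in first-seen order."""
        seen: dict[str, None] = {}
        for m in self.models:
            for p in m.parameter_names:
                seen.setdefault(p, None)
        return list(seen)
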