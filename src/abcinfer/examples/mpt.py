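"""Multinomial-processing-tree models of the weapon-identification task.

Participants classify a target as gun or tool after a white or black face
prime, under private or anticipated-public instructions, with female or
male primes — a 2 x 2 x 2 x 2 design of 16 cells, each yielding a count of
correct responses out of ``trials_per_cell``.

Two trees compete.  The process-dissociation (PD) account puts control
first: a response is correct with probability C; only when control fails
(1 - C) does the automatic stereotype response A, or guessing, decide.
The Stroop account reverses the order: the automatic response fires first
with probability A, and control (then guessing) only matters when it does
not.  With s = 1 in cells where the stereotype-consistent response is
correct (black prime + gun, or white prime + tool) and g the probability
that a guess is correct (g = G for gun targets, 1 - G for tools):

    PD:     P(correct) = C + (1 - C) * (A * s + (1 - A) * g)
    Stroop: P(correct) = A * s + (1 - A) * (C + (1 - C) * g)

A varies by condition x prime x gender (8 parameters), C by condition (2),
and a single G is shared — 11 free parameters per tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np

from ..inference import ModelSuite
from ..model import ModelSet, ModelSpec
from ..priors import Prior

__all__ = [
    "Cell",
    "MPTDesign",
    "MODEL_NAMES",
    "parameter_names",
    "default_priors",
    "recovery_priors",
    "cell_probability",
    "cell_probabilities",
    "simulate_counts",
    "suite",
]

CONDITIONS = ("private", "public")
PRIMES = ("white", "black")
GENDERS = ("female", "male")
TARGETS = ("gun", "tool")

MODEL_NAMES = ("process_dissociation", "stroop")


@dataclass(frozen=True)
class Cell:
    condition: str
    prime: str
    gender: str
    target: str

    @property
    def stereotype_consistent_correct(self) -> bool:
        """True when the stereotype-consistent response is the correct one."""
        return (self.prime == "black") == (self.target == "gun")


@dataclass
class MPTDesign:
    """The 16-cell factorial design with a fixed trial count per cell."""

    trials_per_cell: int = 50
    cells: tuple[Cell, ...] = field(init=False)

    def __post_init__(self):
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        self.cells = tuple(
            Cell(c, p, g, t) for c, p, g, t in product(CONDITIONS, PRIMES, GENDERS, TARGETS)
        )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_labels(self) -> list[str]:
        return [f"{c.condition}_{c.prime}_{c.gender}_{c.target}" for c in self.cells]


def parameter_names() -> list[str]:
    """The 11 free parameters: A per condition x prime x gender, C per
    condition, and one G."""
    names = [f"A_{c}_{p}_{g}" for c, p, g in product(CONDITIONS, PRIMES, GENDERS)]
    names += [f"C_{c}" for c in CONDITIONS]
    names.append("G")
    return names


def default_priors() -> dict[str, Prior]:
    """Mildly informed fitting priors: A ~ Beta(2, 10) (automatic responses
    are rare), C ~ Beta(3, 3) (control succeeds about half the time, with
    uncertainty), G ~ Beta(10, 10) (guessing near one half)."""
    priors: dict[str, Prior] = {}
    for name in parameter_names():
        if name.startswith("A_"):
            priors[name] = Prior("beta", alpha=2, beta=10)
        elif name.startswith("C_"):
            priors[name] = Prior("beta", alpha=3, beta=3)
        else:
            priors[name] = Prior("beta", alpha=10, beta=10)
    return priors


def recovery_priors() -> dict[str, Prior]:
    """Generating distributions for the recovery study, mimicking common
    empirical estimates: A ~ Beta(2, 10), C ~ Beta(60, 40), G ~ Beta(50, 50)."""
    priors: dict[str, Prior] = {}
    for name in parameter_names():
        if name.startswith("A_"):
            priors[name] = Prior("beta", alpha=2, beta=10)
        elif name.startswith("C_"):
            priors[name] = Prior("beta", alpha=60, beta=40)
        else:
            priors[name] = Prior("beta", alpha=50, beta=50)
    return priors


def _resolve_acg(params: Mapping[str, np.ndarray], cell: Cell):
    a = np.asarray(params[f"A_{cell.condition}_{cell.prime}_{cell.gender}"], dtype=float)
    c = np.asarray(params[f"C_{cell.condition}"], dtype=float)
    g_gun = np.asarray(params["G"], dtype=float)
    g = g_gun if cell.target == "gun" else 1.0 - g_gun
    return a, c, g


def cell_probability(model: str, params: Mapping[str, float], cell: Cell) -> float:
    """P(correct) in one design cell under one tree."""
    return float(cell_probabilities(model, params, MPTDesign(), [cell])[..., 0])


def cell_probabilities(
    model: str,
    params: Mapping[str, np.ndarray],
    design: MPTDesign,
    cells=None,
) -> np.ndarray:
    """P(correct) for every cell; vectorizes over parameter arrays.

    Returns shape ``(n_cells,)`` for scalar parameters or ``(n, n_cells)``
    for length-n parameter arrays.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"model must be one of {MODEL_NAMES}, got {model!r}")
    cells = design.cells if cells is None else list(cells)
    for name in parameter_names():
        v = np.asarray(params[name], dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"parameter {name} out of [0, 1]")
    cols = []
    for cell in cells:
        a, c, g = _resolve_acg(params, cell)
        s = 1.0 if cell.stereotype_consistent_correct else 0.0
        if model == "process_dissociation":
            p = c + (1.0 - c) * (a * s + (1.0 - a) * g)
        else:  # stroop
            p = a * s + (1.0 - a) * (c + (1.0 - c) * g)
        cols.append(p)
    return np.stack(cols, axis=-1)


def simulate_counts(
    model: str,
    params: Mapping[str, float],
    design: MPTDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correct-response counts per cell: Binomial(trials_per_cell, P(correct))."""
    p = cell_probabilities(model, params, design)
    return rng.binomial(design.trials_per_cell, p).astype(float)


def suite(design: MPTDesign | None = None) -> ModelSuite:
    """PD-vs-Stroop comparison suite.

    Datasets are length-16 count vectors; the summary statistic is the
    vector of correct-response proportions per cell; the distance is the
    engine's MAD-scaled Euclidean default.
    """
    design = design or MPTDesign()

    def summary(counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(counts, dtype=float).ravel()
        if counts.shape != (design.n_cells,):
            raise ValueError(
                f"MPT data must have {design.n_cells} cell counts, got shape {counts.shape}"
            )
        return counts / design.trials_per_cell

    def make_model(name: str) -> ModelSpec:
        def sim(params, rng, _name=name):
            return simulate_counts(_name, params, design, rng)

        def batch(params, n, rng, _name=name):
            p = cell_probabilities(_name, params, design)  # (n, 16)
            counts = rng.binomial(design.trials_per_cell, p)
            return counts / design.trials_per_cell

        return ModelSpec(name, priors=default_priors(), simulate=sim, simulate_summaries=batch)

    models = ModelSet([make_model(name) for name in MODEL_NAMES])
    return ModelSuite(models=models, summary=summary, distance=None)
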