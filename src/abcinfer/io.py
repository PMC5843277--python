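"""CSV dialects, declarative project configuration and run orchestration.

Reference-table files are plain CSV with the header
``idx, s_1 .. s_k, p_<name> ..., distance`` — one row per particle.
Observed data are numeric CSV tables.  A project is described by a YAML
file naming a model suite, the analysis objective and method, the run
settings, and either an observed-data file or a model-test block that
generates pseudo-observed data from one of the models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .crossval import ConfusionMatrix, loo_model_cv
from .engine import ABCSettings, generate_pseudo_observed
from .inference import (
    ABCModelComparison,
    ABCParameterEstimation,
    ComparisonResults,
    EstimationResults,
    ModelSuite,
)
from .reference_table import ReferenceTable

__all__ = [
    "write_reference_table",
    "read_reference_table",
    "read_observed_data",
    "ProjectConfig",
    "ProjectError",
    "run_project",
    "SUITE_REGISTRY",
]


class ProjectError(RuntimeError):
    """A project-level failure, tagged with the stage it occurred in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# reference-table CSV dialect
# ---------------------------------------------------------------------------


def write_reference_table(table: ReferenceTable, path) -> None:
    """Write the canonical idx, s_1..s_k, p_*, distance CSV.

    Floats are serialized with full round-trip precision, so reading the
    file back reproduces the table bit for bit.
    """
    df = table.to_frame()
    df.to_csv(path, index=False, float_format=None)


def read_reference_table(path) -> ReferenceTable:
    """Parse the reference-table dialect, inferring k from the ``s_*``
    columns and parameter names from the ``p_*`` columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"reference table column {col!r} contains non-numeric cells")
    return ReferenceTable.from_frame(df)


def read_observed_data(path) -> np.ndarray:
    """Numeric CSV (with or without a header row) as a 1-D or 2-D array."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"observed-data file {path} is empty") from None
    # a non-numeric first row is taken to be a header
    first = df.iloc[0]
    if first.map(lambda v: _is_number(v)).all():
        data = df
    else:
        data = pd.read_csv(path, float_precision="round_trip")
    arr = data.to_numpy()
    try:
        arr = arr.astype(float)
    except (TypeError, ValueError):
        bad = [
            str(c)
            for c in data.columns
            if not pd.api.types.is_numeric_dtype(pd.to_numeric(data[c], errors="coerce"))
            or pd.to_numeric(data[c], errors="coerce").isna().any()
        ]
        raise ValueError(f"observed data contains non-numeric cells in columns {bad}") from None
    if not np.all(np.isfinite(arr)):
        raise ValueError("observed data contains missing or non-finite cells")
    if arr.shape[1] == 1:
        arr = arr[:, 0]
    return arr


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# suite registry (plug-in identifiers used by project files)
# ---------------------------------------------------------------------------


def _build_ttest(args: Mapping[str, Any]) -> ModelSuite:
    from .examples import ttest

    return ttest.suite(**args)


def _build_levene(args: Mapping[str, Any]) -> ModelSuite:
    from .examples import levene

    return levene.suite(**args)


def _build_mpt(args: Mapping[str, Any]) -> ModelSuite:
    from .examples import mpt

    design = mpt.MPTDesign(trials_per_cell=int(args.get("trials_per_cell", 50)))
    return mpt.suite(design)


SUITE_REGISTRY: dict[str, Callable[[Mapping[str, Any]], ModelSuite]] = {
    "ttest": _build_ttest,
    "levene": _build_levene,
    "mpt": _build_mpt,
}


# ---------------------------------------------------------------------------
# project configuration
# ---------------------------------------------------------------------------


@dataclass
class ProjectConfig:
    """Declarative description of one analysis run."""

    suite: str
    suite_args: dict = field(default_factory=dict)
    objective: str = "comparison"
    method: str = "rejection"
    n_simulations: int = 100_000
    percentile: Optional[float] = 1.0
    epsilon: Optional[float] = None
    seed: Optional[int] = None
    bf_cap: float = 10_000.0
    data_file: Optional[str] = None
    model_test: Optional[dict] = None  # {"model": name, "params": {...}}
    estimation_model: Optional[str] = None
    cv_reps: Optional[int] = None
    output_dir: Optional[str] = None

    def __post_init__(self):
        if (self.data_file is None) == (self.model_test is None):
            raise ProjectError(
                "config", "exactly one of data_file and model_test must be given"
            )
        if self.suite not in SUITE_REGISTRY:
            raise ProjectError(
                "config",
                f"unknown suite {self.suite!r}; available: {sorted(SUITE_REGISTRY)}",
            )
        if self.objective == "estimation" and self.estimation_model is None:
            raise ProjectError("config", "estimation requires an estimation model name")

    @classmethod
    def from_yaml(cls, path) -> "ProjectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ProjectError("config", f"project file {path} is not a mapping")
        suite = raw.get("suite") or {}
        settings = raw.get("settings") or {}
        analysis = raw.get("analysis") or {}
        known = {
            "suite": suite.get("name"),
            "suite_args": suite.get("args") or {},
            "objective": analysis.get("objective", "comparison"),
            "method": analysis.get("method", "rejection"),
            "n_simulations": int(settings.get("n_simulations", 100_000)),
            "percentile": settings.get("percentile", 1.0),
            "epsilon": settings.get("epsilon"),
            "seed": settings.get("seed"),
            "bf_cap": float(settings.get("bf_cap", 10_000.0)),
            "data_file": raw.get("data"),
            "model_test": raw.get("model_test"),
            "estimation_model": (raw.get("estimation") or {}).get("model"),
            "cv_reps": raw.get("cv"),
            "output_dir": raw.get("output_dir"),
        }
        if known["suite"] is None:
            raise ProjectError("config", "project file must name a suite (suite: name: ...)")
        return cls(**known)

    def to_yaml(self, path) -> None:
        doc = {
            "suite": {"name": self.suite, "args": self.suite_args},
            "analysis": {"objective": self.objective, "method": self.method},
            "settings": {
                "n_simulations": self.n_simulations,
                "percentile": self.percentile,
                "epsilon": self.epsilon,
                "seed": self.seed,
                "bf_cap": self.bf_cap,
            },
            "data": self.data_file,
            "model_test": self.model_test,
            "estimation": {"model": self.estimation_model} if self.estimation_model else None,
            "cv": self.cv_reps,
            "output_dir": self.output_dir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump({k: v for k, v in doc.items() if v is not None}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# run orchestration
# ---------------------------------------------------------------------------


@dataclass
class ProjectResults:
    """Everything one run produced, plus where it was written."""

    config: ProjectConfig
    observed_data: np.ndarray
    results: ComparisonResults | EstimationResults
    confusion: Optional[ConfusionMatrix] = None
    output_dir: Optional[Path] = None


def _observed_data(config: ProjectConfig, suite: ModelSuite) -> np.ndarray:
    if config.data_file is not None:
        try:
            return read_observed_data(config.data_file)
        except (OSError, ValueError) as exc:
            raise ProjectError("data-import", str(exc)) from exc
    block = config.model_test
    name = block.get("model")
    params = block.get("params") or {}
    try:
        idx = suite.models.index_of(name)
        rng = np.random.default_rng(
            None if config.seed is None else config.seed + 1_000_003
        )
        return generate_pseudo_observed(suite.models[idx], params, rng=rng)
    except (KeyError, ValueError) as exc:
        raise ProjectError("model-test", str(exc)) from exc


def run_project(config: ProjectConfig) -> ProjectResults:
    """Execute a configured analysis end to end.

    Dispatches to model comparison (Bayes-factor matrix from rejection, or
    model probabilities from the random forest) or parameter estimation
    (posterior summary and full sample export), optionally followed by
    leave-one-out cross-validation, and writes all outputs plus a log to
    the configured output directory.
    """
    try:
        suite = SUITE_REGISTRY[config.suite](config.suite_args)
    except (TypeError, ValueError) as exc:
        raise ProjectError("suite", str(exc)) from exc

    observed = _observed_data(config, suite)

    try:
        if config.objective == "comparison":
            analysis = ABCModelComparison.from_data(observed, suite)
            results = analysis.fit(
                n_simulations=config.n_simulations,
                percentile=config.percentile,
                epsilon=config.epsilon,
                method=config.method,
                seed=config.seed,
                bf_cap=config.bf_cap,
            )
        else:
            analysis = ABCParameterEstimation.from_data(observed, suite)
            results = analysis.fit(
                model=config.estimation_model,
                n_simulations=config.n_simulations,
                percentile=config.percentile,
                epsilon=config.epsilon,
                seed=config.seed,
            )
    except ValueError as exc:
        raise ProjectError("inference", str(exc)) from exc

    confusion = None
    if config.cv_reps:
        try:
            settings = ABCSettings(
                n_simulations=config.n_simulations,
                percentile=config.percentile,
                epsilon=config.epsilon,
                seed=None if config.seed is None else config.seed + 2_000_003,
            )
            confusion = loo_model_cv(
                results.reference_table,
                config.cv_reps,
                settings,
                distance_fn=suite.distance,
                model_names=suite.models.names,
            )
        except ValueError as exc:
            raise ProjectError("cross-validation", str(exc)) from exc

    out = ProjectResults(config, observed, results, confusion)
    if config.output_dir is not None:
        out.output_dir = _write_outputs(out)
    return out


def _write_outputs(out: ProjectResults) -> Path:
    config = out.config
    outdir = Path(config.output_dir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        write_reference_table(out.results.reference_table, outdir / "reference_table.csv")
        results = out.results
        if isinstance(results, ComparisonResults):
            results.model_probabilities.to_csv(outdir / "model_probabilities.csv")
            results.bayes_factors.to_frame().to_csv(outdir / "bayes_factors.csv")
        else:
            results.summary().to_csv(outdir / "posterior_summary.csv")
            results.draws.to_csv(outdir / "posterior_samples.csv", index=False)
        if out.confusion is not None:
            out.confusion.to_frame().to_csv(outdir / "confusion_matrix.csv")
        _write_log(out, outdir / "run_log.txt")
    except OSError as exc:
        raise ProjectError("output", str(exc)) from exc
    return outdir


def _write_log(out: ProjectResults, path: Path) -> None:
    config = out.config
    lines = [
        "abcinfer run log",
        f"suite: {config.suite} {config.suite_args}",
        f"objective: {config.objective}  method: {config.method}",
        f"n_simulations: {config.n_simulations}",
        f"threshold: "
        + (
            f"epsilon={config.epsilon}"
            if config.epsilon is not None
            else f"percentile={config.percentile}"
        ),
        f"seed: {config.seed}",
        f"bf_cap: {config.bf_cap}",
        f"data: "
        + (
            config.data_file
            if config.data_file is not None
            else f"model_test {config.model_test}"
        ),
        f"epsilon (resolved): {out.results.epsilon!r}",
    ]
    if isinstance(out.results, ComparisonResults):
        lines.append("")
        lines.append(out.results.summary())
    else:
        lines.append("")
        lines.append(str(out.results))
    path.write_text("\n".join(lines) + "\n")
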