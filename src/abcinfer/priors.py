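"""Univariate prior distributions for ABC model parameters.

A :class:`Prior` names one of the supported distribution families together
with its family-specific parameters and can produce reproducible draws from
a :class:`numpy.random.Generator`.  Supported families:

========================  =============================================
family                    parameters
========================  =============================================
``uniform``               ``lower``, ``upper``
``normal``                ``loc``, ``scale``
``truncated_normal``      ``loc``, ``scale``, ``lower``, ``upper``
``cauchy``                ``loc``, ``scale``
``gamma``                 ``shape``, ``scale``
``inverse_gamma``         ``shape``, ``scale``
``beta``                  ``alpha``, ``beta``
``exponential``           ``scale``
``lognormal``             ``mu``, ``sigma``  (mean/sd of log-values)
========================  =============================================
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import stats

__all__ = ["Prior", "SUPPORTED_FAMILIES"]


def _positive(params: Mapping[str, float], *names: str) -> None:
    for name in names:
        if not params[name] > 0:
            raise ValueError(f"prior parameter {name!r} must be > 0, got {params[name]!r}")


def _build_uniform(p):
    if not p["lower"] < p["upper"]:
        raise ValueError("uniform prior requires lower < upper")
    return stats.uniform(loc=p["lower"], scale=p["upper"] - p["lower"])


def _build_normal(p):
    _positive(p, "scale")
    return stats.norm(loc=p["loc"], scale=p["scale"])


def _build_truncated_normal(p):
    _positive(p, "scale")
    if not p["lower"] < p["upper"]:
        raise ValueError("truncated_normal prior requires lower < upper")
    a = (p["lower"] - p["loc"]) / p["scale"]
    b = (p["upper"] - p["loc"]) / p["scale"]
    return stats.truncnorm(a, b, loc=p["loc"], scale=p["scale"])


def _build_cauchy(p):
    _positive(p, "scale")
    return stats.cauchy(loc=p["loc"], scale=p["scale"])


def _build_gamma(p):
    _positive(p, "shape", "scale")
    return stats.gamma(a=p["shape"], scale=p["scale"])


def _build_inverse_gamma(p):
    _positive(p, "shape", "scale")
    return stats.invgamma(a=p["shape"], scale=p["scale"])


def _build_beta(p):
    _positive(p, "alpha", "beta")
    return stats.beta(a=p["alpha"], b=p["beta"])


def _build_exponential(p):
    _positive(p, "scale")
    return stats.expon(scale=p["scale"])


def _build_lognormal(p):
    _positive(p, "sigma")
    return stats.lognorm(s=p["sigma"], scale=float(np.exp(p["mu"])))


_FAMILIES = {
    "uniform": (_build_uniform, ("lower", "upper")),
    "normal": (_build_normal, ("loc", "scale")),
    "truncated_normal": (_build_truncated_normal, ("loc", "scale", "lower", "upper")),
    "cauchy": (_build_cauchy, ("loc", "scale")),
    "gamma": (_build_gamma, ("shape", "scale")),
    "inverse_gamma": (_build_inverse_gamma, ("shape", "scale")),
    "beta": (_build_beta, ("alpha", "beta")),
    "exponential": (_build_exponential, ("scale",)),
    "lognormal": (_build_lognormal, ("mu", "sigma")),
}

SUPPORTED_FAMILIES = tuple(_FAMILIES)


class Prior:
    """A named univariate prior distribution.

    Parameters
    ----------
    family : str
        One of :data:`SUPPORTED_FAMILIES`.
    **params
        Family-specific parameters, e.g. ``Prior("beta", alpha=2, beta=10)``
        or ``Prior("cauchy", loc=0.0, scale=0.707)``.

    Examples
    --------
    >>> rng = np.random.default_rng(0)
    >>> Prior("uniform", lower=0, upper=1).sample(rng)  # doctest: +SKIP
    0.636...
    """

    def __init__(self, family: str, **params: float):
        if family not in _FAMILIES:
            raise ValueError(
                f"unknown prior family {family!r}; supported: {sorted(_FAMILIES)}"
            )
        builder, required = _FAMILIES[family]
        missing = set(required) - set(params)
        extra = set(params) - set(required)
        if missing or extra:
            raise ValueError(
                f"{family} prior takes parameters {required}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        self.family = family
        self.params = {k: float(params[k]) for k in required}
        self._dist = builder(self.params)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw ``size`` values (a scalar if ``size`` is None)."""
        return self._dist.rvs(size=size, random_state=rng)

    def pdf(self, x):
        return self._dist.pdf(x)

    def mean(self) -> float:
        return float(self._dist.mean())

    @property
    def support(self) -> tuple[float, float]:
        return tuple(float(v) for v in self._dist.support())

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"Prior({self.family!r}, {args})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Prior)
            and self.family == other.family
            and self.params == other.params
        )
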