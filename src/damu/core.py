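"""Binormal measurand model for a binary screening or diagnostic test.

The measurand (a log-transformed analyte concentration, or any quantity
that is normal after a suitable transform) is assumed normally distributed
within each of the diseased and non-diseased populations, with known
parameters.  A measurement carries normal, homoscedastic error summarised
by the standard measurement uncertainty ``u`` (an SD-scale parameter), so
the *observed* value in a population with biological SD ``sigma_p`` has SD
``sqrt(sigma_p**2 + u**2)``.

The classification rule is fixed: a measurement strictly above the
diagnostic threshold ``d`` is test-positive.  The opposite orientation is
obtained by swapping the two populations, not by a flag.

Every normal CDF / survival / quantile evaluation in the package routes
through the erf/erfc-based primitives in this module, so all closed forms
agree with each other to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "PopulationPair",
    "TestModel",
    "effective_sigma",
    "sensitivity",
    "specificity",
    "se_given_sp",
    "sp_given_se",
]

_SQRT2 = math.sqrt(2.0)


def _maybe_float(x):
    """Return a Python float for 0-d results, pass arrays through."""
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


def norm_cdf(x, mu=0.0, sigma=1.0):
    """Normal CDF via erfc (accurate in both tails); accepts ±inf."""
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return _maybe_float(0.5 * special.erfc(-z / _SQRT2))


def norm_sf(x, mu=0.0, sigma=1.0):
    """Normal survival function via erfc."""
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return _maybe_float(0.5 * special.erfc(z / _SQRT2))


def norm_pdf(x, mu=0.0, sigma=1.0):
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return _maybe_float(np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi)))


def norm_quantile(p, mu=0.0, sigma=1.0):
    """Inverse normal CDF via erfcinv; p=0 and p=1 map to ∓inf."""
    p = np.asarray(p, dtype=float)
    return _maybe_float(mu - sigma * _SQRT2 * special.erfcinv(2.0 * p))


@dataclass(frozen=True)
class PopulationPair:
    """Measurand distribution parameters in both populations plus prevalence.

    Parameters
    ----------
    mu_d, sigma_d
        Mean and SD of the measurand in the diseased population
        (``sigma_d > 0``).
    mu_nd, sigma_nd
        Mean and SD in the non-diseased population (``sigma_nd > 0``).
    v
        Disease prevalence, a probability in ``[0, 1]``.
    """

    mu_d: float
    sigma_d: float
    mu_nd: float
    sigma_nd: float
    v: float

    def __post_init__(self) -> None:
        if not self.sigma_d > 0:
            raise ValueError(f"sigma_d must be > 0, got {self.sigma_d}")
        if not self.sigma_nd > 0:
            raise ValueError(f"sigma_nd must be > 0, got {self.sigma_nd}")
        if not 0.0 <= self.v <= 1.0:
            raise ValueError(f"v (prevalence) must be in [0, 1], got {self.v}")


@dataclass(frozen=True)
class TestModel:
    """One test: a population pair plus its standard measurement uncertainty."""

    pop: PopulationPair
    u: float

    def __post_init__(self) -> None:
        if not self.u >= 0:
            raise ValueError(f"u (standard uncertainty) must be >= 0, got {self.u}")

    @property
    def sigma_d_eff(self) -> float:
        """Observed SD in the diseased population."""
        return effective_sigma(self.pop.sigma_d, self.u)

    @property
    def sigma_nd_eff(self) -> float:
        """Observed SD in the non-diseased population."""
        return effective_sigma(self.pop.sigma_nd, self.u)


def effective_sigma(sigma_p: float, u: float) -> float:
    """SD of observed measurements: biological SD and uncertainty combined
    in quadrature, ``sqrt(sigma_p**2 + u**2)``.
    """
    if not sigma_p > 0:
        raise ValueError(f"sigma_p must be > 0, got {sigma_p}")
    if not u >= 0:
        raise ValueError(f"u must be >= 0, got {u}")
    return math.hypot(sigma_p, u)


def sensitivity(d, model: TestModel):
    """P(measurement > d | diseased); strictly decreasing in ``d``.

    Accepts scalar or array thresholds, including ±inf (limits 0 and 1).
    """
    return norm_sf(d, model.pop.mu_d, model.sigma_d_eff)


def specificity(d, model: TestModel):
    """P(measurement <= d | non-diseased); strictly increasing in ``d``."""
    return norm_cdf(d, model.pop.mu_nd, model.sigma_nd_eff)


def threshold_for_specificity(z, model: TestModel):
    """Threshold d with specificity(d) = z (z in [0, 1], endpoints → ∓inf)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("specificity must be in [0, 1]")
    return norm_quantile(z, model.pop.mu_nd, model.sigma_nd_eff)


def threshold_for_sensitivity(y, model: TestModel):
    """Threshold d with sensitivity(d) = y (y in [0, 1], endpoints → ±inf)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("sensitivity must be in [0, 1]")
    # Se(d) = 1 - CDF_D(d)  =>  d = quantile_D(1 - y)
    return norm_quantile(1.0 - y, model.pop.mu_d, model.sigma_d_eff)


def se_given_sp(z, model: TestModel):
    """Sensitivity at the threshold whose specificity equals ``z``.

    ``z`` in ``[0, 1]``; the endpoints return the limits 1 and 0.
    """
    return sensitivity(threshold_for_specificity(z, model), model)


def sp_given_se(y, model: TestModel):
    """Specificity at the threshold whose sensitivity equals ``y``."""
    return specificity(threshold_for_sensitivity(y, model), model)
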