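"""Uncertainty sensitivity, two-test comparison and threshold optimization.

Three tools on top of the measure table:

* partial derivatives of every measure with respect to the standard
  measurement uncertainty u, analytic by default (chain rule through the
  normal-CDF forms of Se and Sp) with a central finite-difference fallback;
* comparison of two tests that share a population and differ only in u
  (difference, relative difference, ratio — test 1 in the numerator);
* deterministic optimal-threshold solvers for the four objective / loss
  functions: maximize Youden's J or the concordance probability CZ,
  minimize the Euclidean distance ED or the expected-loss risk R.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .core import PopulationPair, TestModel, norm_pdf, norm_cdf, norm_sf
from .measures import (
    MEASURES,
    DamTable,
    LossSpec,
    MeasureBoundaryWarning,
    dam_table,
    evaluate,
)

__all__ = [
    "TestPair",
    "OptResult",
    "CompareResult",
    "OBJECTIVES",
    "d_measure_du",
    "compare",
    "optimize_threshold",
]

#: objective name -> (measure key, optimization sense)
OBJECTIVES = {"J": ("j", "maximize"), "ED": ("ed", "minimize"),
              "CZ": ("cz", "maximize"), "R": ("r", "minimize")}


@dataclass(frozen=True)
class TestPair:
    """Two tests of the same measurand differing only in uncertainty."""

    test1: TestModel
    test2: TestModel

    def __post_init__(self) -> None:
        if self.test1.pop != self.test2.pop:
            raise ValueError("both tests of a TestPair must share the same PopulationPair")


class CompareResult(NamedTuple):
    difference: Union[float, np.ndarray]
    relative_difference: Union[float, np.ndarray]
    ratio: Union[float, np.ndarray]


@dataclass(frozen=True)
class OptResult:
    """Optimal threshold for one objective plus the full measure table there."""

    objective: str
    d_opt: float
    table: DamTable
    sense: str
    non_unique: bool = False


def _se_sp_at(d, pop: PopulationPair, u):
    """Se and Sp as even functions of u (only u² enters), vectorized.

    Accepts negative u so that symmetric finite differences are valid
    at u = 0.
    """
    sd = math.hypot(pop.sigma_d, u) if np.isscalar(u) else np.hypot(pop.sigma_d, u)
    sn = math.hypot(pop.sigma_nd, u) if np.isscalar(u) else np.hypot(pop.sigma_nd, u)
    se = norm_sf((np.asarray(d, float) - pop.mu_d) / sd)
    sp = norm_cdf((np.asarray(d, float) - pop.mu_nd) / sn)
    return se, sp


def measure_at(name: str, d, model: TestModel, loss: Optional[LossSpec] = None,
               v: Optional[float] = None):
    """Named measure of ``model`` at threshold(s) ``d``; vectorized.

    ``v`` overrides the population prevalence (used for prevalence sweeps).
    """
    se, sp = _se_sp_at(d, model.pop, model.u)
    return evaluate(name, se, sp, v=model.pop.v if v is None else v, loss=loss)


def _partials_se_sp(name: str, se, sp, v, loss: Optional[LossSpec]):
    """(∂m/∂Se, ∂m/∂Sp) for each measure, as closed forms."""
    se = np.asarray(se, float)
    sp = np.asarray(sp, float)
    one = np.ones_like(se * sp)
    with np.errstate(divide="ignore", invalid="ignore"):
        if name == "se":
            return one, 0.0 * one
        if name == "sp":
            return 0.0 * one, one
        if name == "ppv":
            a, b = se * v, (1.0 - sp) * (1.0 - v)
            den = (a + b) ** 2
            return v * b / den, a * (1.0 - v) / den
        if name == "npv":
            c, e = sp * (1.0 - v), (1.0 - se) * v
            den = (c + e) ** 2
            return c * v / den, (1.0 - v) * e / den
        if name == "oda":
            return v * one, (1.0 - v) * one
        if name == "dor":
            return (sp / ((1.0 - se) ** 2 * (1.0 - sp)),
                    se / ((1.0 - se) * (1.0 - sp) ** 2))
        if name == "lr_pos":
            return 1.0 / (1.0 - sp) * one, se / (1.0 - sp) ** 2
        if name == "lr_neg":
            return -1.0 / sp * one, -(1.0 - se) / sp**2
        if name == "j":
            return one, one
        if name == "ed":
            ed = np.hypot(1.0 - se, 1.0 - sp)
            return -(1.0 - se) / ed, -(1.0 - sp) / ed
        if name == "cz":
            return sp, se
        if name == "r":
            if loss is None:
                raise ValueError("risk derivative requires a LossSpec")
            return ((loss.l_tp - loss.l_fn) * v * one,
                    (loss.l_tn - loss.l_fp) * (1.0 - v) * one)
    raise ValueError(f"unknown measure {name!r}; valid: {', '.join(MEASURES)}")


def _d_se_sp_du(d, model: TestModel):
    """Analytic (∂Se/∂u, ∂Sp/∂u) at fixed threshold.

    With z = (μ − d)/σ_eff and σ_eff = sqrt(σ_p² + u²),
    ∂Φ(z)/∂u = −φ(z)·z·u/σ_eff².
    """
    d = np.asarray(d, float)
    p, u = model.pop, model.u
    sd, sn = model.sigma_d_eff, model.sigma_nd_eff
    z_d = (p.mu_d - d) / sd       # Se = Φ(z_d)
    z_n = (d - p.mu_nd) / sn      # Sp = Φ(z_n)
    with np.errstate(invalid="ignore"):  # 0·inf at d = ±inf
        dse = -norm_pdf(z_d) * z_d * u / sd**2
        dsp = -norm_pdf(z_n) * z_n * u / sn**2
    return dse, dsp


def d_measure_du(measure: str, d, model: TestModel, loss: Optional[LossSpec] = None,
                 h: Union[str, float] = "analytic"):
    """∂measure/∂u at fixed threshold ``d``.

    ``h="analytic"`` (default) uses the chain rule through the closed
    forms; a numeric ``h`` (or ``h=None`` for an automatic step) uses a
    central finite difference with one Richardson extrapolation level.
    Boundary evaluations where a ratio measure is infinite yield NaN with
    a warning rather than raising.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; valid: {', '.join(MEASURES)}")
    if h == "analytic":
        se, sp = _se_sp_at(d, model.pop, model.u)
        dse, dsp = _d_se_sp_du(d, model)
        p_se, p_sp = _partials_se_sp(measure, se, sp, model.pop.v, loss)
        out = np.asarray(p_se * dse + p_sp * dsp, float)
        if np.any(~np.isfinite(out)):
            warnings.warn(
                f"derivative of {measure} undefined at a boundary; returning NaN",
                MeasureBoundaryWarning, stacklevel=2)
            out = np.where(np.isfinite(out), out, np.nan)
        return float(out) if out.ndim == 0 else out

    step = float(h) if h is not None else max(1e-6, 1e-3 * model.u)

    def central(s):
        lo = evaluate(measure, *_se_sp_at(d, model.pop, model.u - s),
                      v=model.pop.v, loss=loss)
        hi = evaluate(measure, *_se_sp_at(d, model.pop, model.u + s),
                      v=model.pop.v, loss=loss)
        return (np.asarray(hi, float) - np.asarray(lo, float)) / (2.0 * s)

    d1, d2 = central(step), central(step / 2.0)
    out = (4.0 * d2 - d1) / 3.0  # one Richardson level
    out = np.asarray(out, float)
    return float(out) if out.ndim == 0 else out


def compare(measure: str, pair: TestPair, d, loss: Optional[LossSpec] = None,
            v: Optional[float] = None) -> CompareResult:
    """Difference m1−m2, relative difference (m1−m2)/m1 and ratio m1/m2.

    Test 1 (the lower-uncertainty test in the bundled case study) is the
    reference in the numerator.  ``d`` may be an array for threshold
    sweeps; ``v`` may be an array for prevalence sweeps at fixed ``d``.
    m1 = 0 leaves the relative difference and ratio NaN with a warning.
    """
    m1 = np.asarray(measure_at(measure, d, pair.test1, loss=loss, v=v), float)
    m2 = np.asarray(measure_at(measure, d, pair.test2, loss=loss, v=v), float)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = diff / m1
        ratio = m1 / m2
    if np.any(m1 == 0):
        warnings.warn(
            f"relative difference/ratio of {measure} undefined where the "
            "reference value is 0; returning NaN",
            MeasureBoundaryWarning, stacklevel=2)
        rel = np.where(m1 == 0, np.nan, rel)
        ratio = np.where(m1 == 0, np.nan, ratio)

    def out(x):
        x = np.asarray(x)
        return float(x) if x.ndim == 0 else x

    return CompareResult(out(diff), out(rel), out(ratio))


def optimize_threshold(objective: str, model: TestModel,
                       loss: Optional[LossSpec] = None, *,
                       grid_n: int = 1001, xatol: float = 1e-8) -> OptResult:
    """Optimal diagnostic threshold for one objective or loss function.

    Deterministic derivative-free search: a coarse grid over
    [min μ − 6σ_eff, max μ + 6σ_eff] locates the global basin (guarding
    against multimodality of risk under extreme loss ratios), then bounded
    scalar minimization refines the threshold well below 1e-6.

    A flat objective (e.g. J when the two populations coincide) is
    reported as the midpoint of the search interval with
    ``non_unique=True`` instead of failing.
    """
    if objective not in OBJECTIVES:
        raise ValueError(
            f"unknown objective {objective!r}; valid: {', '.join(OBJECTIVES)}")
    key, sense = OBJECTIVES[objective]
    if key == "r" and loss is None:
        raise ValueError("objective 'R' requires a LossSpec")
    sign = -1.0 if sense == "maximize" else 1.0

    s = max(model.sigma_d_eff, model.sigma_nd_eff)
    lo = min(model.pop.mu_d, model.pop.mu_nd) - 6.0 * s
    hi = max(model.pop.mu_d, model.pop.mu_nd) + 6.0 * s

    def f(d):
        return sign * np.asarray(measure_at(key, d, model, loss=loss), float)

    grid = np.linspace(lo, hi, grid_n)
    vals = f(grid)
    span = float(np.nanmax(vals) - np.nanmin(vals))
    if span <= 1e-12 * max(1.0, float(np.nanmax(np.abs(vals)))):
        d_opt = 0.5 * (lo + hi)
        return OptResult(objective, d_opt, dam_table(d_opt, model, loss),
                         sense, non_unique=True)

    i = int(np.nanargmin(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid_n - 1)]
    res = minimize_scalar(lambda d: float(f(d)), bounds=(a, b), method="bounded",
                          options={"xatol": xatol})
    d_opt = float(res.x)
    return OptResult(objective, d_opt, dam_table(d_opt, model, loss), sense)
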