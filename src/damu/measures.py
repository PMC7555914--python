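"""Diagnostic accuracy measures and expected-loss risk.

All measures are explicit functions of sensitivity (Se), specificity (Sp),
prevalence (v) and, for risk, five loss constants — so the whole table can
be evaluated for known population parameters without any sample counts.

Boundary policy: ratio measures at their singularities return ``inf``
(e.g. LR+ when Sp = 1 and Se > 0) and genuine 0/0 indeterminacies return
NaN together with a :class:`MeasureBoundaryWarning`; exceptions are never
raised, because threshold sweeps for plotting and optimization routinely
pass through the boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import TestModel, sensitivity, specificity

__all__ = [
    "LossSpec",
    "DamTable",
    "MeasureBoundaryWarning",
    "MEASURES",
    "predictive_values",
    "ratio_measures",
    "objective_measures",
    "oda",
    "risk",
    "evaluate",
    "dam_table",
]

#: Canonical measure order used by tables, sweeps and derivatives.
MEASURES = (
    "se", "sp", "ppv", "npv", "oda",
    "dor", "lr_pos", "lr_neg", "j", "ed", "cz", "r",
)


class MeasureBoundaryWarning(RuntimeWarning):
    """A measure was evaluated at a boundary where it is undefined (0/0)."""


@dataclass(frozen=True)
class LossSpec:
    """Expected losses on one common scale.

    ``l0`` is the loss of the testing procedure itself; the other four are
    per-outcome expected losses (true/false negative, true/false positive).
    No sign constraint is imposed — only finiteness.
    """

    l0: float
    l_tn: float
    l_fn: float
    l_tp: float
    l_fp: float

    def __post_init__(self) -> None:
        for name in ("l0", "l_tn", "l_fn", "l_tp", "l_fp"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val}")


def _warn_nan(name: str, arr) -> None:
    if np.any(np.isnan(arr)):
        warnings.warn(
            f"{name} undefined (0/0) at a boundary; returning NaN",
            MeasureBoundaryWarning,
            stacklevel=3,
        )


def predictive_values(se, sp, v):
    """Positive and negative predictive value (prevalence-dependent).

    PPV = Se·v / (Se·v + (1−Sp)(1−v)); NPV = Sp(1−v) / (Sp(1−v) + (1−Se)v).
    A zero denominator (e.g. v = 0 with Sp = 1) yields NaN with a warning.
    """
    se, sp, v = np.asarray(se, float), np.asarray(sp, float), np.asarray(v, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = se * v / (se * v + (1.0 - sp) * (1.0 - v))
        npv = sp * (1.0 - v) / (sp * (1.0 - v) + (1.0 - se) * v)
    _warn_nan("PPV", ppv)
    _warn_nan("NPV", npv)
    return _scal(ppv), _scal(npv)


def ratio_measures(se, sp):
    """Diagnostic odds ratio and likelihood ratios.

    LR+ = Se/(1−Sp), LR− = (1−Se)/Sp, DOR = odds(Se)·odds(Sp).
    Sp = 1 gives LR+ = DOR = +inf; Se = 1 gives LR− = 0 and DOR = +inf;
    indeterminate combinations (e.g. Se = 1 with Sp = 0) give NaN.
    """
    se, sp = np.asarray(se, float), np.asarray(sp, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr_pos = se / (1.0 - sp)
        lr_neg = (1.0 - se) / sp
        dor = (se / (1.0 - se)) * (sp / (1.0 - sp))
    _warn_nan("LR+", lr_pos)
    _warn_nan("LR-", lr_neg)
    _warn_nan("DOR", dor)
    return _scal(dor), _scal(lr_pos), _scal(lr_neg)


def objective_measures(se, sp):
    """Youden's index J = Se+Sp−1, Euclidean distance from the perfect
    point ED = sqrt((1−Se)²+(1−Sp)²), concordance probability CZ = Se·Sp."""
    se, sp = np.asarray(se, float), np.asarray(sp, float)
    j = se + sp - 1.0
    ed = np.hypot(1.0 - se, 1.0 - sp)
    cz = se * sp
    return _scal(j), _scal(ed), _scal(cz)


def oda(se, sp, v):
    """Overall diagnostic accuracy, Se·v + Sp·(1−v)."""
    se, sp, v = np.asarray(se, float), np.asarray(sp, float), np.asarray(v, float)
    return _scal(se * v + sp * (1.0 - v))


def risk(se, sp, v, loss: LossSpec):
    """Expected loss of the test:

    R = l0 + lTN·Sp(1−v) + lFN(1−Se)v + lTP·Se·v + lFP(1−Sp)(1−v).

    Linear in every loss constant; lower is better.
    """
    se, sp, v = np.asarray(se, float), np.asarray(sp, float), np.asarray(v, float)
    r = (
        loss.l0
        + loss.l_tn * sp * (1.0 - v)
        + loss.l_fn * (1.0 - se) * v
        + loss.l_tp * se * v
        + loss.l_fp * (1.0 - sp) * (1.0 - v)
    )
    return _scal(r)


def _scal(x):
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


def evaluate(name: str, se, sp, v=None, loss: Optional[LossSpec] = None):
    """Evaluate one named measure from (Se, Sp[, v, loss]); vectorized.

    ``name`` is one of :data:`MEASURES`.  ``v`` is required for the
    prevalence-dependent measures (ppv, npv, oda, r) and ``loss`` for r;
    ``r`` with ``loss=None`` returns NaN.
    """
    if name not in MEASURES:
        raise ValueError(f"unknown measure {name!r}; valid: {', '.join(MEASURES)}")
    if name == "se":
        return _scal(np.asarray(se, float) + 0.0)
    if name == "sp":
        return _scal(np.asarray(sp, float) + 0.0)
    if name in ("ppv", "npv"):
        if v is None:
            raise ValueError(f"{name} requires a prevalence v")
        ppv, npv = predictive_values(se, sp, v)
        return ppv if name == "ppv" else npv
    if name == "oda":
        if v is None:
            raise ValueError("oda requires a prevalence v")
        return oda(se, sp, v)
    if name in ("dor", "lr_pos", "lr_neg"):
        dor, lr_pos, lr_neg = ratio_measures(se, sp)
        return {"dor": dor, "lr_pos": lr_pos, "lr_neg": lr_neg}[name]
    if name in ("j", "ed", "cz"):
        j, ed, cz = objective_measures(se, sp)
        return {"j": j, "ed": ed, "cz": cz}[name]
    # risk
    if v is None:
        raise ValueError("r requires a prevalence v")
    if loss is None:
        return _scal(np.full(np.broadcast(np.asarray(se), np.asarray(sp)).shape, np.nan))
    return risk(se, sp, v, loss)


@dataclass(frozen=True)
class DamTable:
    """All measure values for one test at one threshold (a calculator row)."""

    d: float
    se: float
    sp: float
    ppv: float
    npv: float
    oda: float
    dor: float
    lr_pos: float
    lr_neg: float
    j: float
    ed: float
    cz: float
    r: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("d",) + MEASURES}

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_dict())


def dam_table(d: float, model: TestModel, loss: Optional[LossSpec] = None) -> DamTable:
    """Evaluate every measure of ``model`` at threshold ``d``.

    ``loss=None`` leaves the risk entry NaN (without a warning).
    """
    v = model.pop.v
    se = sensitivity(d, model)
    sp = specificity(d, model)
    ppv, npv = predictive_values(se, sp, v)
    dor, lr_pos, lr_neg = ratio_measures(se, sp)
    j, ed, cz = objective_measures(se, sp)
    r = risk(se, sp, v, loss) if loss is not None else float("nan")
    return DamTable(
        d=float(d), se=se, sp=sp, ppv=ppv, npv=npv, oda=oda(se, sp, v),
        dor=dor, lr_pos=lr_pos, lr_neg=lr_neg, j=j, ed=ed, cz=cz, r=r,
    )
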