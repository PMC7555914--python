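"""ROC and predictive ROC (PROC) curves for the binormal model.

The ROC curve plots Se against 1−Sp and has the closed binormal form
``roc(t) = S_D(S_ND^{-1}(t))`` with the normal survival function S; its
area under the curve is

    AUC = Φ( (μ_D − μ_ND) / sqrt(σ_ND² + σ_D² + 2u²) )

because the measurement uncertainty u inflates both population SDs in
quadrature.  The PROC curve plots PPV against 1−NPV; it has no elementary
closed form, so it is traced by sweeping the threshold.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    TestModel,
    norm_cdf,
    norm_quantile,
    sensitivity,
    specificity,
    threshold_for_specificity,
)
from .measures import predictive_values

__all__ = [
    "roc",
    "auc",
    "aoc",
    "ed_on_roc",
    "roc_points",
    "proc_points",
    "npv_inverse",
    "threshold_grid",
]


def threshold_grid(model: TestModel, n: int = 512) -> np.ndarray:
    """Threshold grid spanning both populations to beyond six observed SDs.

    Wide enough that the traced ROC endpoints reach the corners to ~1e-9.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    s = max(model.sigma_d_eff, model.sigma_nd_eff)
    lo = min(model.pop.mu_d, model.pop.mu_nd) - 6.0 * s
    hi = max(model.pop.mu_d, model.pop.mu_nd) + 6.0 * s
    return np.linspace(lo, hi, n)


def roc(t, model: TestModel):
    """True-positive fraction at false-positive fraction ``t`` in [0, 1].

    Endpoints return the exact limits roc(0)=0 and roc(1)=1 rather than
    evaluating the normal quantile at its singularities.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("t (false-positive fraction) must be in [0, 1]")
    d = threshold_for_specificity(1.0 - t_arr, model)
    y = np.asarray(sensitivity(d, model), dtype=float)
    y = np.where(t_arr == 0.0, 0.0, y)
    y = np.where(t_arr == 1.0, 1.0, y)
    return float(y) if y.ndim == 0 else y


def auc(model: TestModel) -> float:
    """Area under the ROC curve, closed binormal form."""
    p = model.pop
    denom = np.sqrt(p.sigma_nd**2 + p.sigma_d**2 + 2.0 * model.u**2)
    return norm_cdf((p.mu_d - p.mu_nd) / denom)


def aoc(model: TestModel) -> float:
    """Area over the ROC curve, 1 − AUC (a summary of diagnostic inaccuracy)."""
    return 1.0 - auc(model)


def ed_on_roc(t, model: TestModel):
    """Euclidean distance of the ROC point (t, roc(t)) from the corner (0, 1)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("t must be in [0, 1]")
    y = roc(t, model)
    out = np.hypot(t_arr, 1.0 - np.asarray(y, float))
    return float(out) if out.ndim == 0 else out


def roc_points(model: TestModel, n: int = 512) -> pd.DataFrame:
    """ROC curve traced over a threshold grid: columns d, t (=1−Sp), y (=Se)."""
    d = threshold_grid(model, n)[::-1]  # t increasing as d decreases
    t = 1.0 - np.asarray(specificity(d, model), float)
    y = np.asarray(sensitivity(d, model), float)
    return pd.DataFrame({"d": d, "t": t, "y": y})


def proc_points(model: TestModel, n: int = 512) -> pd.DataFrame:
    """PROC curve, threshold-parametrized: columns d, t (=1−NPV), y (=PPV).

    Requires 0 < v < 1 — the predictive values are degenerate otherwise.
    """
    v = model.pop.v
    if not 0.0 < v < 1.0:
        raise ValueError("PROC requires a prevalence strictly inside (0, 1)")
    d = threshold_grid(model, n)
    se = np.asarray(sensitivity(d, model), float)
    sp = np.asarray(specificity(d, model), float)
    ppv, npv = predictive_values(se, sp, v)
    return pd.DataFrame({"d": d, "t": 1.0 - np.asarray(npv, float), "y": np.asarray(ppv, float)})


def npv_inverse(target: float, model: TestModel, bracket: Optional[tuple] = None) -> float:
    """Threshold at which NPV equals ``target``, by bracketed root-finding.

    Provided to validate the composition form PPV(NPV^{-1}(1−t)) of the
    PROC curve on stretches where NPV is monotone in d; the curve itself
    is traced by threshold parametrization, which needs no branch choice.
    """
    v = model.pop.v
    if not 0.0 < v < 1.0:
        raise ValueError("NPV is degenerate unless 0 < v < 1")

    def f(d: float) -> float:
        se = sensitivity(d, model)
        sp = specificity(d, model)
        _, npv = predictive_values(se, sp, v)
        return npv - target

    if bracket is None:
        grid = threshold_grid(model, 1024)
        bracket = (grid[0], grid[-1])
    return brentq(f, bracket[0], bracket[1], xtol=1e-12)
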