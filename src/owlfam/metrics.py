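"""Spatial conspecific indices and body-condition covariates.

The two bespoke covariates of the family-living analyses are

* the conspecific aggregation index ``S_i = sum_{j != i} exp(-d_ij)``,
  a density proxy where ``d_ij`` is the planar distance between nests
  *i* and *j* (kilometres by default — in metres the kernel underflows
  for any realistic nest spacing);
* the conspecific productivity residual: the productivity-weighted
  version of the same index, residualised by OLS on the plain index so
  that it measures neighbourhood productivity *beyond* what density
  alone predicts.

Body condition is the residual of a log10–log10 regression of body mass
(g) on wing length (mm); the reference line is ``1.45 + 0.37*log10(wing)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ConditionCoefficients",
    "aggregation_index",
    "productivity_weighted_index",
    "residual_conspecific_productivity",
    "center_covariates",
    "body_condition",
    "fit_condition_regression",
]

_UNIT_SCALE = {"km": 1.0, "m": 1000.0}


@dataclass(frozen=True)
class ConditionCoefficients:
    """Intercept and slope of the log10(mass) ~ log10(wing) reference line."""

    intercept: float = 1.45
    slope: float = 0.37
    log_base: float = 10.0


def _coords(nests: pd.DataFrame) -> np.ndarray:
    if len(nests) == 0:
        raise ValueError("no nests supplied")
    return np.column_stack([nests["x_km"].to_numpy(float), nests["y_km"].to_numpy(float)])


def aggregation_index(nests: pd.DataFrame, distance_unit: str = "km") -> pd.DataFrame:
    """Per-nest conspecific aggregation index S_i = sum_{j != i} exp(-d_ij).

    ``nests`` needs columns nest_id, x_km, y_km. Coincident nests are
    legal (d = 0 contributes exp(0) = 1). Returns nest_id with an ``S``
    column, in input order.
    """
    if distance_unit not in _UNIT_SCALE:
        raise ValueError(f"distance_unit must be 'km' or 'm', got {distance_unit!r}")
    xy = _coords(nests) * _UNIT_SCALE[distance_unit]
    d = cdist(xy, xy)
    kernel = np.exp(-d)
    np.fill_diagonal(kernel, 0.0)
    return pd.DataFrame({"nest_id": nests["nest_id"].to_numpy(), "S": kernel.sum(axis=1)})


def productivity_weighted_index(
    nests: pd.DataFrame, productivities: np.ndarray, distance_unit: str = "km"
) -> pd.DataFrame:
    """Productivity-weighted aggregation index P_i = sum_{j != i} prod_j * exp(-d_ij)."""
    if distance_unit not in _UNIT_SCALE:
        raise ValueError(f"distance_unit must be 'km' or 'm', got {distance_unit!r}")
    prod = np.asarray(productivities, dtype=float)
    if len(prod) != len(nests):
        raise ValueError("one productivity per nest required")
    if np.any(prod < 0):
        raise ValueError("negative productivity")
    xy = _coords(nests) * _UNIT_SCALE[distance_unit]
    kernel = np.exp(-cdist(xy, xy))
    np.fill_diagonal(kernel, 0.0)
    # row-wise reduction (not a BLAS matvec) so that unit productivities
    # reproduce the aggregation index bit for bit
    P = (kernel * prod[None, :]).sum(axis=1)
    return pd.DataFrame({"nest_id": nests["nest_id"].to_numpy(), "P": P})


def residual_conspecific_productivity(table: pd.DataFrame) -> pd.DataFrame:
    """Residualise P on S by OLS (with intercept); adds a ``P_resid`` column.

    Raises on fewer than 3 nests or a constant S column (collinear design).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 nests to residualise")
    S = table["S"].to_numpy(float)
    P = table["P"].to_numpy(float)
    if np.ptp(S) == 0:
        raise ValueError("aggregation index is constant; residual regression is collinear")
    X = np.column_stack([np.ones_like(S), S])
    beta, *_ = np.linalg.lstsq(X, P, rcond=None)
    out = table.copy()
    out["P_resid"] = P - X @ beta
    return out


def center_covariates(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean-centre a covariate; returns (centered, mean) for back-transform."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty covariate vector")
    m = float(v.mean())
    return v - m, m


def body_condition(
    mass_g, wing_mm, coefficients: ConditionCoefficients | None = None
) -> np.ndarray:
    """Condition residual: log10(mass) - (intercept + slope*log10(wing))."""
    c = coefficients or ConditionCoefficients()
    mass = np.asarray(mass_g, dtype=float)
    wing = np.asarray(wing_mm, dtype=float)
    if np.any(mass <= 0) or np.any(wing <= 0):
        raise ValueError("mass and wing length must be positive")
    lb = np.log(c.log_base)
    return np.log(mass) / lb - (c.intercept + c.slope * np.log(wing) / lb)


def fit_condition_regression(chicks: pd.DataFrame) -> ConditionCoefficients:
    """OLS of log10(mass_g) on log10(wing_mm) over a chick cohort."""
    if len(chicks) < 3:
        raise ValueError("need at least 3 chicks")
    wing = chicks["wing_mm"].to_numpy(float)
    mass = chicks["mass_g"].to_numpy(float)
    if np.any(wing <= 0) or np.any(mass <= 0):
        raise ValueError("mass and wing length must be positive")
    lw = np.log10(wing)
    lm = np.log10(mass)
    if np.ptp(lw) == 0:
        raise ValueError("constant wing lengths: slope unidentifiable")
    X = np.column_stack([np.ones_like(lw), lw])
    beta, *_ = np.linalg.lstsq(X, lm, rcond=None)
    return ConditionCoefficients(intercept=float(beta[0]), slope=float(beta[1]))
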