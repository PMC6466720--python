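"""Tank-level regression of feed conversion ratio on indicator traits.

FCR is only observable per tank, so the predictive value of the isotope
indicator traits is assessed by ordinary least squares of tank FCR on
sampling day plus tank means of candidate covariates, judged by
leave-one-out cross-validation:

    PRESS  = sum_t (y_t - yhat_(t))^2          (yhat_(t) fit without tank t)
    R^2hat = 1 - PRESS / SS_tot
    bias   = mean(y_t - yhat_(t))

Backward elimination repeatedly removes the covariate whose removal most
reduces PRESS (sampling day is never removed) until no removal helps.
The leave-one-out residuals come from the exact leverage identity
``e_t / (1 - h_tt)`` of the hat matrix rather than n refits.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "fit_tank_model",
    "loo_press",
    "backward_eliminate",
    "single_covariate_scan",
]


@dataclasses.dataclass
class RegressionResult:
    """OLS fit of tank FCR with its cross-validation summary."""

    covariates: list[str]
    coefficients: pd.Series
    se: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    press: float
    r2_hat: float
    bias_loo: float
    bias_insample: float
    loo_predictions: np.ndarray
    n: int
    elimination_trace: list[dict] = dataclasses.field(default_factory=list)


def _design_frame(
    day: np.ndarray, covariates: pd.DataFrame | None, interactions: bool
) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(day.size)})
    day = np.asarray(day, float)
    if np.unique(day).size > 1:  # constant day is absorbed by the intercept
        X["day"] = day
    if covariates is not None and covariates.shape[1]:
        for c in covariates.columns:
            X[c] = covariates[c].to_numpy(float)
        if interactions:
            for a, b in itertools.combinations(covariates.columns, 2):
                X[f"{a}:{b}"] = X[a] * X[b]
    return X


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # identify offending columns by greedy inclusion
        bad = []
        kept: list[str] = []
        for c in X.columns:
            cand = X[kept + [c]].to_numpy(float)
            if np.linalg.matrix_rank(cand) < len(kept) + 1:
                bad.append(c)
            else:
                kept.append(c)
        raise ValueError(f"rank-deficient design; offending columns: {bad}")


def fit_tank_model(
    fcr: Sequence[float],
    day: Sequence[float],
    covariates: pd.DataFrame | None = None,
    *,
    interactions: bool = False,
) -> RegressionResult:
    """OLS of tank FCR on sampling day and the given tank-mean covariates.

    Day is always part of the model.  Raises on rank deficiency, naming
    the offending columns.  The returned result carries the full
    leave-one-out summary from :func:`loo_press`.
    """
    y = np.asarray(fcr, dtype=float)
    X = _design_frame(np.asarray(day, float), covariates, interactions)
    if y.size <= X.shape[1] + 1:
        raise ValueError("need more tanks than parameters + 1")
    _check_rank(X)
    model = sm.OLS(y, X)
    fit = model.fit()
    press, r2_hat, bias_loo, yhat_loo = loo_press(fit)
    return RegressionResult(
        covariates=[c for c in X.columns if c not in ("intercept", "day")],
        coefficients=fit.params,
        se=fit.bse,
        pvalues=fit.pvalues,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        press=press,
        r2_hat=r2_hat,
        bias_loo=bias_loo,
        bias_insample=float(np.mean(fit.resid)),
        loo_predictions=yhat_loo,
        n=int(y.size),
    )


def loo_press(fit) -> tuple[float, float, float, np.ndarray]:
    """Leave-one-out PRESS, predictive R^2 and bias from an OLS fit.

    Uses the hat-matrix identity ``e_(t) = e_t / (1 - h_tt)``, exact for
    OLS.  ``R^2hat = 1 - PRESS/SS_tot`` with SS_tot the total sum of
    squares of the response about its mean; bias is the mean leave-one-out
    prediction error.
    """
    y = np.asarray(fit.model.endog, float)
    resid = np.asarray(fit.resid, float)
    h = fit.get_influence().hat_matrix_diag
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("a leave-one-out subset is rank-deficient (leverage 1)")
    e_loo = resid / (1.0 - h)
    press = float(np.sum(e_loo**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_hat = 1.0 - press / ss_tot
    return press, r2_hat, float(np.mean(e_loo)), y - e_loo


def backward_eliminate(
    fcr: Sequence[float],
    day: Sequence[float],
    candidates: pd.DataFrame,
    *,
    interactions: bool = False,
) -> RegressionResult:
    """PRESS-minimizing backward elimination over candidate covariates.

    Starting from the model with every candidate (plus day, which is
    never eliminated), repeatedly drop the single covariate whose removal
    most reduces PRESS; stop when no removal reduces it.  Ties are broken
    toward the first-listed covariate, so the procedure is deterministic
    in column order.  The elimination trace (step, dropped column, PRESS)
    is attached to the result.
    """
    cols = list(candidates.columns)
    if interactions:
        base = _design_frame(np.asarray(day, float), candidates, True)
        candidates = base.drop(columns=["intercept", "day"])
        cols = list(candidates.columns)
    current = cols
    result = fit_tank_model(fcr, day, candidates[current] if current else None)
    trace = [{"step": 0, "dropped": None, "press": result.press, "kept": list(current)}]
    step = 0
    while current:
        best_drop, best_res = None, None
        for c in current:
            remaining = [x for x in current if x != c]
            cand = fit_tank_model(
                fcr, day, candidates[remaining] if remaining else None
            )
            if best_res is None or cand.press < best_res.press:
                best_drop, best_res = c, cand
        if best_res is not None and best_res.press < result.press:
            step += 1
            current = [x for x in current if x != best_drop]
            result = best_res
            trace.append(
                {"step": step, "dropped": best_drop, "press": result.press,
                 "kept": list(current)}
            )
        else:
            break
    result.elimination_trace = trace
    return result


def single_covariate_scan(
    fcr: Sequence[float], day: Sequence[float], covariates: pd.DataFrame
) -> pd.DataFrame:
    """Day + one covariate at a time: R^2, adjusted R^2, R^2hat, bias, PRESS.

    Mirrors the standard presentation of per-indicator regressions; a
    covariate that makes the design rank-deficient is reported with NaN
    statistics and flagged.
    """
    rows = []
    for c in covariates.columns:
        try:
            res = fit_tank_model(fcr, day, covariates[[c]])
            rows.append(
                {"covariate": c, "r2": res.r2, "adj_r2": res.adj_r2,
                 "r2_hat": res.r2_hat, "bias": res.bias_loo, "press": res.press,
                 "rank_deficient": False}
            )
        except ValueError:
            rows.append(
                {"covariate": c, "r2": np.nan, "adj_r2": np.nan, "r2_hat": np.nan,
                 "bias": np.nan, "press": np.nan, "rank_deficient": True}
            )
    return pd.DataFrame(rows)
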