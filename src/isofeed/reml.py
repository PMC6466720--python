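"""Restricted maximum likelihood for uni- and bivariate mixed models.

Two model families are supported, matching how feed-efficiency data are
recorded in family-tank experiments:

* tank level (model "tank"): phenotypes observed once per tank (FCR, FI,
  or tank means of individual traits), with a random additive genetic
  tank effect distributed N(0, T0 (x) G_T) and a diagonal-across-traits
  tank residual.  The ratio h_t^2 = s2_a/(s2_a + s2_e) measures the
  fraction of between-tank variance explained by genetics.
* individual level (model "individual"): per-fish phenotypes with a
  genomic additive effect N(0, G0 (x) G), a common-tank environmental
  effect N(0, T (x) I) and a full residual, giving the usual
  h^2 = s2_a/(s2_a + s2_t + s2_e) and c^2 = s2_t/(s2_a + s2_t + s2_e).

The restricted log-likelihood is evaluated densely through a Cholesky
factorization of V = sum_k C_k (x) Z_k K_k Z_k' and maximized with a
derivative-free simplex search on log-variances and atanh-correlations,
which keeps every covariance matrix positive definite during the search
and makes boundary contact (|r| -> 1, variance -> 0) explicit.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .grm import RelationshipMatrix

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "BivariateFit",
    "reml_fit",
    "reml_loglik",
    "ratio_estimates",
    "ratio_from_components",
    "correlations",
    "lr_test",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_BOUNDARY_R = 1.0 - 1e-6


@dataclasses.dataclass
class RandomTerm:
    """One random term: covariance C_k (x) Z K Z' on the stacked data."""

    name: str
    S: np.ndarray  # n x n contribution Z K Z' (identity for residual)
    diagonal: bool = False  # cross-trait covariance fixed at zero


@dataclasses.dataclass
class ModelSpec:
    """Declarative description of a (bi)variate analysis.

    ``trait2 = None`` gives a univariate fit.  ``level`` selects the model
    family; at the individual level a common-tank environmental term is
    included by default and the residual is a full 2x2 matrix, while at
    the tank level there is no separate tank term and the residual is
    diagonal across traits.  Sampling day (values 1..5) enters the fixed
    part of both traits, as a linear covariate by default or as a factor
    when ``day_as_factor`` is set.
    """

    trait1: str
    trait2: str | None = None
    level: str = "tank"  # "tank" | "individual"
    day_as_factor: bool = False
    include_genetic: bool = True
    include_tank: bool | None = None
    residual_diagonal: bool | None = None

    def __post_init__(self) -> None:
        if self.level not in ("tank", "individual"):
            raise ValueError("level must be 'tank' or 'individual'")
        if self.include_tank is None:
            self.include_tank = self.level == "individual"
        if self.residual_diagonal is None:
            self.residual_diagonal = self.level == "tank"
        if self.level == "tank" and self.include_tank:
            raise ValueError("tank-level model has no separate tank term")

    @property
    def traits(self) -> list[str]:
        return [self.trait1] if self.trait2 is None else [self.trait1, self.trait2]


@dataclasses.dataclass
class BivariateFit:
    """REML estimates for one trait or trait pair."""

    traits: list[str]
    level: str
    covariances: dict[str, np.ndarray]  # term name -> t x t covariance matrix
    loglik: float
    converged: bool
    n_obs: int
    n_fixed: int
    boundary: dict[str, bool]
    message: str = ""
    component_names: list[str] = dataclasses.field(default_factory=list)
    component_values: np.ndarray | None = None
    component_cov: np.ndarray | None = None

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def component_se(self) -> dict[str, float] | None:
        if self.component_cov is None:
            return None
        d = np.diag(self.component_cov)
        return {
            n: (float(np.sqrt(v)) if v > 0 else np.nan)
            for n, v in zip(self.component_names, d)
        }


# --- likelihood --------------------------------------------------------------

def _pack_structures(terms: Sequence[RandomTerm], n_traits: int):
    """Parameter layout: per term, log-variances then atanh(r) if full."""
    layout = []
    for term in terms:
        n_var = n_traits
        n_cor = 0 if (n_traits == 1 or term.diagonal) else 1
        layout.append((term, n_var, n_cor))
    return layout


def _covariance_from_params(theta: np.ndarray, layout, n_traits: int):
    covs = {}
    pos = 0
    for term, n_var, n_cor in layout:
        logv = np.clip(theta[pos:pos + n_var], -30.0, 30.0)
        v = np.exp(logv)
        pos += n_var
        C = np.diag(v)
        if n_cor:
            r = np.tanh(np.clip(theta[pos], -20.0, 20.0))
            pos += 1
            C[0, 1] = C[1, 0] = r * np.sqrt(v[0] * v[1])
        covs[term.name] = C
    return covs


def _build_v(covs: dict[str, np.ndarray], terms: Sequence[RandomTerm]) -> np.ndarray:
    V = None
    for term in terms:
        contrib = np.kron(covs[term.name], term.S)
        V = contrib if V is None else V + contrib
    return V


def reml_loglik(
    y: np.ndarray,
    X: np.ndarray,
    terms: Sequence[RandomTerm],
    covs: dict[str, np.ndarray],
    jitter: float = 0.0,
) -> float:
    """Restricted log-likelihood of the stacked model y ~ N(Xb, V).

    ``y`` is the trait-stacked observation vector, ``X`` the trait-block
    fixed design, and ``covs`` maps each random term to its cross-trait
    covariance matrix.
    """
    V = _build_v(covs, terms)
    n = y.size
    if jitter:
        V = V + jitter * np.eye(n)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    Vi_y = linalg.cho_solve((L, True), y)
    Vi_X = linalg.cho_solve((L, True), X)
    XtViX = X.T @ Vi_X
    try:
        Lx = linalg.cholesky(XtViX, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    Xt_Vi_y = X.T @ Vi_y
    beta = linalg.cho_solve((Lx, True), Xt_Vi_y)
    quad = float(y @ Vi_y - Xt_Vi_y @ beta)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(Lx))))
    # the log|X'X| correction makes the value invariant to full-rank
    # reparameterizations of the fixed-effects design
    logdet_xx = float(np.linalg.slogdet(X.T @ X)[1])
    p = X.shape[1]
    return -0.5 * (logdet_v + logdet_x - logdet_xx + quad + (n - p) * _LOG2PI)


def _maximize(y, X, terms, n_traits, tol_logl, tol_param, maxiter, jitter):
    layout = _pack_structures(terms, n_traits)
    n_params = sum(nv + nc for _, nv, nc in layout)

    def neg_ll(theta):
        covs = _covariance_from_params(theta, layout, n_traits)
        ll = reml_loglik(y, X, terms, covs, jitter=jitter)
        return np.inf if not np.isfinite(ll) else -ll

    # Phenotypic variance per trait, split evenly across terms for the
    # primary start and 80/20 for the robustness start.
    n = y.size // n_traits
    v_pheno = [float(np.var(y[i * n:(i + 1) * n], ddof=1)) for i in range(n_traits)]
    v_pheno = [max(v, 1e-12) for v in v_pheno]
    n_terms = len(terms)

    def start(fracs):
        theta = []
        for k, (term, n_var, n_cor) in enumerate(layout):
            theta.extend(np.log(np.maximum(fracs[k] * np.asarray(v_pheno), 1e-12)))
            theta.extend([0.0] * n_cor)
        return np.asarray(theta)

    even = [1.0 / n_terms] * n_terms
    skew = [0.8 if k == 0 else 0.2 / max(n_terms - 1, 1) for k in range(n_terms)]
    best = None
    for x0 in (start(even), start(skew)):
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": tol_param,
                "fatol": tol_logl,
                "maxiter": maxiter * n_params,
                "maxfev": maxiter * n_params,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    covs = _covariance_from_params(best.x, layout, n_traits)
    return best, covs, layout


def _component_vector(covs, terms, n_traits):
    names, values = [], []
    for term in terms:
        C = covs[term.name]
        for i, t in enumerate(range(n_traits)):
            names.append(f"{term.name}_var{t + 1}")
            values.append(C[i, i])
        if n_traits == 2 and not term.diagonal:
            names.append(f"{term.name}_cov12")
            values.append(C[0, 1])
    return names, np.asarray(values)


def _component_loglik_fn(y, X, terms, n_traits, jitter) -> Callable:
    """logL as a function of the flat component vector (for SEs)."""

    def fn(comp: np.ndarray) -> float:
        covs = {}
        pos = 0
        for term in terms:
            C = np.zeros((n_traits, n_traits))
            for t in range(n_traits):
                C[t, t] = comp[pos]
                pos += 1
            if n_traits == 2 and not term.diagonal:
                C[0, 1] = C[1, 0] = comp[pos]
                pos += 1
            covs[term.name] = C
        return reml_loglik(y, X, terms, covs, jitter=jitter)

    return fn


def _numerical_hessian(fn, x0, rel_step=1e-4):
    k = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1e-8)
    H = np.zeros((k, k))
    f0 = fn(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (fn(x0 + ei) - 2.0 * f0 + fn(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fn(x0 + ei + ej) - fn(x0 + ei - ej)
                    - fn(x0 - ei + ej) + fn(x0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def _design(spec: ModelSpec, data: pd.DataFrame):
    day = data["day"].to_numpy(float)
    if np.any((day < 1) | (day > 5)):
        raise ValueError("sampling day must lie in 1..5")
    if np.unique(day).size == 1:
        # single sampling day: the day effect is absorbed by the intercept
        X1 = np.ones((len(data), 1))
    elif spec.day_as_factor:
        levels = np.unique(day)
        cols = [np.ones(len(data))]
        cols += [(day == lev).astype(float) for lev in levels[1:]]
        X1 = np.column_stack(cols)
    else:
        X1 = np.column_stack([np.ones(len(data)), day])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("singular fixed-effects design")
    return X1


def reml_fit(
    spec: ModelSpec,
    phenotypes: pd.DataFrame,
    relationship: RelationshipMatrix | None = None,
    *,
    tol_logl: float = 1e-9,
    tol_param: float = 1e-6,
    maxiter: int = 600,
    jitter: float = 1e-8,
    compute_se: bool = False,
) -> BivariateFit:
    """Fit the model described by ``spec`` to a phenotype table.

    ``phenotypes`` needs the trait columns, ``day``, and an id column:
    ``tank`` for tank-level data (one row per tank, ids matching the
    tank relationship matrix) or ``fish_id`` + ``tank`` for individual
    data (fish ids matching the individual relationship matrix).  Rows
    with a missing value in any analysed trait are dropped.

    The ``jitter`` is a small ridge added to V before factorization to
    guard against numerically semi-definite relationship matrices; it is
    recorded in the fit message.
    """
    traits = spec.traits
    id_col = "tank" if spec.level == "tank" else "fish_id"
    needed = traits + ["day", id_col] + (["tank"] if spec.level == "individual" else [])
    data = phenotypes.dropna(subset=traits).reset_index(drop=True)
    for col in needed:
        if col not in data.columns:
            raise KeyError(f"phenotype table lacks column {col!r}")
    n = len(data)
    if n < 3:
        raise ValueError("too few records to fit")

    X1 = _design(spec, data)
    n_traits = len(traits)
    X = linalg.block_diag(*([X1] * n_traits))
    y = np.concatenate([data[t].to_numpy(float) for t in traits])

    terms: list[RandomTerm] = []
    if spec.include_genetic:
        if relationship is None:
            raise ValueError("genetic term requested but no relationship matrix given")
        order = [str(i) for i in data[id_col]]
        idx = {i: k for k, i in enumerate(relationship.ids)}
        missing = [i for i in order if i not in idx]
        if missing:
            raise ValueError(f"relationship matrix lacks entities: {missing[:5]}")
        rows = [idx[i] for i in order]
        K = relationship.values[np.ix_(rows, rows)]
        terms.append(RandomTerm("genetic", S=K, diagonal=False))
    if spec.include_tank:
        tanks = pd.get_dummies(data["tank"].astype(str)).to_numpy(float)
        if tanks.shape[1] < 2:
            raise ValueError("tank term requires at least two tanks")
        terms.append(RandomTerm("tank", S=tanks @ tanks.T, diagonal=False))
    terms.append(
        RandomTerm("residual", S=np.eye(n), diagonal=bool(spec.residual_diagonal))
    )

    res, covs, layout = _maximize(
        y, X, terms, n_traits, tol_logl, tol_param, maxiter, jitter
    )
    loglik = -float(res.fun)
    converged = bool(res.success) and np.isfinite(loglik)

    # Boundary diagnostics: near-unit correlations and near-zero variances.
    boundary: dict[str, bool] = {}
    v_scale = max(float(np.var(y, ddof=1)), 1e-12)
    for term in terms:
        C = covs[term.name]
        for t in range(n_traits):
            boundary[f"{term.name}_var{t + 1}"] = C[t, t] < 1e-8 * v_scale
        if n_traits == 2 and not term.diagonal:
            denom = np.sqrt(C[0, 0] * C[1, 1])
            r = C[0, 1] / denom if denom > 0 else 0.0
            boundary[f"{term.name}_cor"] = abs(r) > _BOUNDARY_R

    comp_names, comp_values = _component_vector(covs, terms, n_traits)
    comp_cov = None
    message = f"nelder-mead: {res.message}; jitter={jitter:g}"
    if compute_se:
        fn = _component_loglik_fn(y, X, terms, n_traits, jitter)
        H = _numerical_hessian(fn, comp_values)
        try:
            info = -H
            comp_cov = linalg.inv(info)
            if np.any(np.diag(comp_cov) <= 0):
                comp_cov = None
                message += "; information matrix indefinite, SEs omitted"
                warnings.warn("observed information indefinite; SEs omitted")
        except linalg.LinAlgError:
            comp_cov = None
            message += "; information matrix singular, SEs omitted"
            warnings.warn("observed information singular; SEs omitted")

    if not converged:
        warnings.warn(f"REML did not fully converge: {res.message}")

    return BivariateFit(
        traits=traits,
        level=spec.level,
        covariances=covs,
        loglik=loglik,
        converged=converged,
        n_obs=n,
        n_fixed=X.shape[1],
        boundary=boundary,
        message=message,
        component_names=comp_names,
        component_values=comp_values,
        component_cov=comp_cov,
    )


# --- derived quantities ------------------------------------------------------

def ratio_from_components(
    sigma_a2: float, sigma_e2: float, c2: float | None = None
) -> float:
    """Variance ratio from reported genetic and residual components.

    With ``c2 = None`` (tank level) returns ``h_t2 = s2_a / (s2_a + s2_e)``.
    With the tank fraction ``c2`` given (individual level) the total
    phenotypic variance is recovered as ``(s2_a + s2_e) / (1 - c2)`` and
    ``h2 = s2_a / total`` is returned, which is how a components table
    lacking the explicit tank variance is completed.
    """
    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    if c2 is None:
        total = sigma_a2 + sigma_e2
    else:
        if not 0.0 <= c2 < 1.0:
            raise ValueError("c2 must lie in [0, 1)")
        total = (sigma_a2 + sigma_e2) / (1.0 - c2)
    if total <= 0:
        raise ValueError("zero total variance")
    return sigma_a2 / total



def _delta_se(fit: BivariateFit, func: Callable[[np.ndarray], float]) -> float | None:
    """Delta-method SE of a scalar function of the component vector."""
    if fit.component_cov is None or fit.component_values is None:
        return None
    x0 = fit.component_values
    h = 1e-5 * np.maximum(np.abs(x0), 1e-8)
    grad = np.array([
        (func(x0 + np.eye(x0.size)[i] * h[i]) - func(x0 - np.eye(x0.size)[i] * h[i]))
        / (2 * h[i])
        for i in range(x0.size)
    ])
    var = float(grad @ fit.component_cov @ grad)
    return float(np.sqrt(var)) if var > 0 else None


def ratio_estimates(fit: BivariateFit, level: str | None = None) -> pd.DataFrame:
    """Variance ratios per trait.

    Tank level: ``h_t2 = s2_a / (s2_a + s2_e)``.  Individual level:
    ``h2 = s2_a / (s2_a + s2_t + s2_e)`` and ``c2 = s2_t / (same total)``.
    Delta-method standard errors are attached when the fit carries a
    component covariance matrix.
    """
    level = level or fit.level
    ga = fit.covariances.get("genetic")
    re = fit.covariances["residual"]
    tk = fit.covariances.get("tank")
    rows = []
    idx = {n: i for i, n in enumerate(fit.component_names)}
    for t, trait in enumerate(fit.traits):
        va = float(ga[t, t]) if ga is not None else 0.0
        ve = float(re[t, t])
        vt = float(tk[t, t]) if tk is not None else 0.0
        total = va + ve + (vt if level == "individual" else 0.0)
        if total <= 0:
            raise ValueError("zero total variance")
        row: dict[str, object] = {"trait": trait}
        if level == "tank":
            row["ht2"] = va / (va + ve)

            def _ht2(c, t=t):
                a = c[idx[f"genetic_var{t + 1}"]] if ga is not None else 0.0
                e = c[idx[f"residual_var{t + 1}"]]
                return a / (a + e)

            row["ht2_se"] = _delta_se(fit, _ht2)
        else:
            row["h2"] = va / total
            row["c2"] = vt / total

            def _h2(c, t=t):
                a = c[idx[f"genetic_var{t + 1}"]] if ga is not None else 0.0
                e = c[idx[f"residual_var{t + 1}"]]
                tt = c[idx[f"tank_var{t + 1}"]] if tk is not None else 0.0
                return a / (a + tt + e)

            def _c2(c, t=t):
                a = c[idx[f"genetic_var{t + 1}"]] if ga is not None else 0.0
                e = c[idx[f"residual_var{t + 1}"]]
                tt = c[idx[f"tank_var{t + 1}"]] if tk is not None else 0.0
                return tt / (a + tt + e)

            row["h2_se"] = _delta_se(fit, _h2)
            row["c2_se"] = _delta_se(fit, _c2)
        rows.append(row)
    return pd.DataFrame(rows)


def correlations(fit: BivariateFit) -> dict[str, object]:
    """Genetic and phenotypic correlations from a bivariate fit.

    The genetic correlation is cov_a / (s_a1 * s_a2); the phenotypic
    correlation sums the (co)variance matrices of every random term.
    Correlations estimated against the admissibility boundary are
    reported as +/-1.0 with ``boundary=True``.
    """
    if fit.n_traits != 2:
        raise ValueError("correlations require a bivariate fit")
    ga = fit.covariances.get("genetic")
    if ga is None:
        raise ValueError("fit has no genetic term")
    if ga[0, 0] <= 0 or ga[1, 1] <= 0:
        raise ValueError("zero genetic variance in one trait")
    r_g = float(ga[0, 1] / np.sqrt(ga[0, 0] * ga[1, 1]))
    at_boundary = abs(r_g) > _BOUNDARY_R
    if at_boundary:
        r_g = float(np.sign(r_g))
    P = sum(C for C in fit.covariances.values())
    r_p = float(P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))

    idx = {n: i for i, n in enumerate(fit.component_names)}

    def _rg(c):
        return c[idx["genetic_cov12"]] / np.sqrt(
            c[idx["genetic_var1"]] * c[idx["genetic_var2"]]
        )

    se = None if at_boundary else _delta_se(fit, _rg)
    return {
        "r_genetic": r_g,
        "r_phenotypic": r_p,
        "boundary": at_boundary,
        "r_genetic_se": se,
    }


def lr_test(fit_h1: BivariateFit, fit_h0: BivariateFit) -> tuple[float, float]:
    """Likelihood-ratio test for the additive genetic term.

    ``LR = 2 * (logL_H1 - logL_H0)`` compared against a chi-square with
    1 df; negative values from numerical noise are clamped to zero.  H0
    must be the same model without the genetic term on the same data.
    """
    has1 = "genetic" in fit_h1.covariances
    has0 = "genetic" in fit_h0.covariances
    if not has1 or has0:
        raise ValueError("H0 must drop the genetic term present in H1")
    if fit_h1.n_obs != fit_h0.n_obs or fit_h1.traits != fit_h0.traits:
        raise ValueError("fits are not nested on the same data")
    lr = 2.0 * (fit_h1.loglik - fit_h0.loglik)
    if lr < 0:
        if lr < -1e-4:
            warnings.warn(f"H1 log-likelihood below H0 by {-lr:.2e}; check convergence")
        lr = 0.0
    p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return float(lr), p
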