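"""REML engine correctness against independent estimators."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from isofeed.grm import RelationshipMatrix
from isofeed.reml import (
    BivariateFit,
    ModelSpec,
    RandomTerm,
    correlations,
    lr_test,
    ratio_estimates,
    ratio_from_components,
    reml_fit,
    reml_loglik,
)


def tank_frame(y, day, ids=None):
    n = len(y)
    return pd.DataFrame(
        {"tank": ids or [f"t{i}" for i in range(n)], "day": day, "y": y}
    )


def random_psd(n, rng, scale=1.0):
    A = rng.standard_normal((n, n))
    K = A @ A.T / n
    return K / np.mean(np.diag(K)) * scale


def grid_profile_ht2(y, X, K, grid):
    """Independent oracle: profiled restricted likelihood over the
    genetic-to-residual variance ratio, maximized on a dense grid."""
    n, p = X.shape
    best_ll, best_lam = -np.inf, None
    for lam in grid:
        V0 = lam * K + np.eye(n)
        L = np.linalg.cholesky(V0)
        Viy = np.linalg.solve(V0, y)
        ViX = np.linalg.solve(V0, X)
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, X.T @ Viy)
        quad = y @ Viy - (X.T @ Viy) @ beta
        s2 = quad / (n - p)
        ll = -0.5 * (
            2 * np.sum(np.log(np.diag(L)))
            + (n - p) * np.log(s2)
            + np.linalg.slogdet(XtViX)[1]
            + (n - p) * (1 + np.log(2 * np.pi))
        )
        if ll > best_ll:
            best_ll, best_lam = ll, lam
    return best_lam / (1 + best_lam)


class TestAgainstOracles:
    @pytest.mark.parametrize("seed", [5, 17, 29])
    def test_matches_dense_grid_search_on_tiny_instance(self, seed):
        rng = np.random.default_rng(seed)
        n = 24
        K = random_psd(n, rng)
        day = (np.arange(n) % 5) + 1
        Lk = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        y = (
            Lk @ rng.standard_normal(n) * np.sqrt(2.0)
            + rng.standard_normal(n)
            + 0.2 * day
        )
        rel = RelationshipMatrix(
            ids=[f"t{i}" for i in range(n)], values=K, level="tank"
        )
        fit = reml_fit(ModelSpec("y", level="tank"), tank_frame(y, day), rel)
        va = fit.covariances["genetic"][0, 0]
        ve = fit.covariances["residual"][0, 0]
        ht2 = va / (va + ve)
        X = np.column_stack([np.ones(n), day])
        ht2_grid = grid_profile_ht2(y, X, K, np.linspace(1e-4, 60, 30000))
        assert ht2 == pytest.approx(ht2_grid, abs=1e-3)

    def test_matches_anova_intraclass_on_balanced_groups(self, rng):
        g, m = 12, 5
        y = np.repeat(rng.normal(0, np.sqrt(2.0), g), m) + rng.standard_normal(g * m)
        df = pd.DataFrame(
            {
                "fish_id": [f"f{i}" for i in range(g * m)],
                "tank": np.repeat([f"t{j}" for j in range(g)], m),
                "day": np.ones(g * m),
                "y": y,
            }
        )
        fit = reml_fit(
            ModelSpec("y", level="individual", include_genetic=False), df, None
        )
        vt = fit.covariances["tank"][0, 0]
        ve = fit.covariances["residual"][0, 0]
        grp = y.reshape(g, m)
        msb = m * np.var(grp.mean(axis=1), ddof=1)
        msw = np.mean(np.var(grp, axis=1, ddof=1))
        icc = (msb - msw) / (msb + (m - 1) * msw)
        assert vt / (vt + ve) == pytest.approx(icc, abs=1e-5)

    def test_null_data_gives_zero_genetic_variance_and_lr(self):
        # under the null the ratio estimate piles up at the zero boundary
        # and the LR statistic is ~ a 50:50 mixture of 0 and chi2(1); both
        # are checked as replicate averages, not on a single draw
        ratios, lrs = [], []
        for seed in range(8):
            rng = np.random.default_rng(500 + seed)
            n = 40
            K = random_psd(n, rng)
            day = (np.arange(n) % 5) + 1
            y = rng.standard_normal(n)  # no genetic signal at all
            rel = RelationshipMatrix(
                ids=[f"t{i}" for i in range(n)], values=K, level="tank"
            )
            df = tank_frame(y, day)
            fit1 = reml_fit(ModelSpec("y", level="tank"), df, rel)
            fit0 = reml_fit(
                ModelSpec("y", level="tank", include_genetic=False), df, None
            )
            va = fit1.covariances["genetic"][0, 0]
            ve = fit1.covariances["residual"][0, 0]
            ratios.append(va / (va + ve))
            lrs.append(lr_test(fit1, fit0)[0])
        assert np.median(ratios) < 0.1
        assert np.mean(lrs) < 1.5
        assert np.median(lrs) < 0.5


class TestInvariances:
    def test_restricted_likelihood_invariant_to_reparameterization(self, rng):
        n = 20
        K = random_psd(n, rng)
        day = (np.arange(n) % 5) + 1
        X = np.column_stack([np.ones(n), day])
        y = rng.standard_normal(n) + 0.1 * day
        terms = [
            RandomTerm("genetic", S=K),
            RandomTerm("residual", S=np.eye(n)),
        ]
        covs = {"genetic": np.array([[0.7]]), "residual": np.array([[1.3]])}
        ll = reml_loglik(y, X, terms, covs)
        A = np.array([[2.0, -1.0], [0.5, 3.0]])  # full-rank transform
        ll_t = reml_loglik(y, X @ A, terms, covs)
        assert ll_t == pytest.approx(ll, abs=1e-6)

    def test_trait_order_invariance(self, rng):
        n = 30
        K = random_psd(n, rng)
        Lk = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        day = (np.arange(n) % 5) + 1
        a = Lk @ rng.standard_normal(n)
        y1 = a + 0.5 * rng.standard_normal(n)
        y2 = -0.8 * a + rng.standard_normal(n)
        df = pd.DataFrame(
            {"tank": [f"t{i}" for i in range(n)], "day": day, "u": y1, "v": y2}
        )
        rel = RelationshipMatrix(ids=[f"t{i}" for i in range(n)], values=K, level="tank")
        fit_uv = reml_fit(ModelSpec("u", "v", level="tank"), df, rel)
        fit_vu = reml_fit(ModelSpec("v", "u", level="tank"), df, rel)
        assert fit_uv.loglik == pytest.approx(fit_vu.loglik, abs=1e-4)
        r_uv = correlations(fit_uv)["r_genetic"]
        r_vu = correlations(fit_vu)["r_genetic"]
        assert r_uv == pytest.approx(r_vu, abs=2e-3)

    def test_day_values_outside_range_rejected(self):
        df = tank_frame([1.0, 2.0, 3.0, 4.0], [1, 2, 3, 7])
        with pytest.raises(ValueError):
            reml_fit(ModelSpec("y", level="tank", include_genetic=False), df, None)


class TestRatioArithmetic:
    @pytest.mark.parametrize(
        "sigma_a2, sigma_e2, c2, expected",
        [
            # tank-level components of feed intake
            (50.99, 4.68, None, 0.92),
            # individual traits: total variance recovered via (a+e)/(1-c2)
            (5.82, 6.44, 0.06, 0.45),
            (14.42, 36.35, 0.03, 0.28),
            (39.23, 97.32, 0.02, 0.28),
            (1.90, 9.14, 0.13, 0.15),
            (45.75, 364.42, 0.05, 0.11),
            (86.92, 1270.90, 0.04, 0.06),
        ],
    )
    def test_reported_component_ratios(self, sigma_a2, sigma_e2, c2, expected):
        assert ratio_from_components(sigma_a2, sigma_e2, c2) == pytest.approx(
            expected, abs=5e-3
        )

    def test_zero_genetic_variance(self):
        assert ratio_from_components(0.0, 3.0, 0.05) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ratio_from_components(0.0, 0.0)


def make_fit(ga=None, tank=None, resid=None, traits=("a", "b"), level="tank",
             loglik=-10.0, has_genetic=True):
    covs = {}
    if has_genetic and ga is not None:
        covs["genetic"] = np.asarray(ga, float)
    if tank is not None:
        covs["tank"] = np.asarray(tank, float)
    covs["residual"] = np.asarray(resid, float)
    t = len(traits)
    names = []
    vals = []
    for name, C in covs.items():
        for i in range(t):
            names.append(f"{name}_var{i+1}")
            vals.append(C[i, i])
        if t == 2 and name != "residual":
            names.append(f"{name}_cov12")
            vals.append(C[0, 1])
    return BivariateFit(
        traits=list(traits), level=level, covariances=covs, loglik=loglik,
        converged=True, n_obs=46, n_fixed=4, boundary={},
        component_names=names, component_values=np.asarray(vals),
    )


class TestDerivedQuantities:
    def test_boundary_correlation_reported_as_unit(self):
        ga = np.array([[2.0, 2.0 * (1 - 1e-9)], [2.0 * (1 - 1e-9), 2.0]])
        fit = make_fit(ga=ga, resid=np.diag([1.0, 1.0]))
        out = correlations(fit)
        assert out["r_genetic"] == 1.0
        assert out["boundary"] is True

    def test_phenotypic_correlation_sums_terms(self):
        ga = np.array([[1.0, -0.5], [-0.5, 1.0]])
        re = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = make_fit(ga=ga, resid=re, level="individual")
        out = correlations(fit)
        assert out["r_genetic"] == pytest.approx(-0.5)
        assert out["r_phenotypic"] == pytest.approx(0.0)

    def test_near_duplicate_trait_has_unit_genetic_correlation(self, rng):
        n = 30
        K = random_psd(n, rng)
        Lk = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        a = Lk @ rng.standard_normal(n) * 2.0
        day = (np.arange(n) % 5) + 1
        y1 = a + 0.3 * rng.standard_normal(n)
        df = pd.DataFrame(
            {"tank": [f"t{i}" for i in range(n)], "day": day,
             "u": y1, "v": y1 + 0.3 * rng.standard_normal(n)}
        )
        rel = RelationshipMatrix(ids=[f"t{i}" for i in range(n)], values=K, level="tank")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(ModelSpec("u", "v", level="tank"), df, rel)
        assert correlations(fit)["r_genetic"] > 0.98

    def test_zero_genetic_variance_ratio(self):
        fit = make_fit(
            ga=np.zeros((2, 2)), tank=np.diag([0.2, 0.2]),
            resid=np.diag([1.0, 1.0]), level="individual",
        )
        out = ratio_estimates(fit)
        assert (out["h2"] == 0).all()


class TestLrTest:
    def test_arithmetic_example(self):
        f1 = make_fit(ga=np.eye(2), resid=np.eye(2), loglik=-10.0)
        f0 = make_fit(resid=np.eye(2), loglik=-12.0, has_genetic=False)
        lr, p = lr_test(f1, f0)
        assert lr == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-10)
        assert p == pytest.approx(0.0455, abs=1e-3)

    def test_identical_fits(self):
        f1 = make_fit(ga=np.eye(2), resid=np.eye(2), loglik=-10.0)
        f0 = make_fit(resid=np.eye(2), loglik=-10.0, has_genetic=False)
        assert lr_test(f1, f0) == (0.0, 1.0)

    def test_numerical_noise_clamped_to_zero(self):
        f1 = make_fit(ga=np.eye(2), resid=np.eye(2), loglik=-10.0 - 1e-9)
        f0 = make_fit(resid=np.eye(2), loglik=-10.0, has_genetic=False)
        lr, p = lr_test(f1, f0)
        assert lr == 0.0 and p == 1.0

    def test_non_nested_rejected(self):
        f1 = make_fit(ga=np.eye(2), resid=np.eye(2))
        with pytest.raises(ValueError):
            lr_test(f1, f1)
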