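"""Penalised-regression engine checked against independent oracles.

The reference solutions come from a generic bound-constrained optimiser
(L-BFGS-B on the positive/negative split of the coefficients), from
closed forms where they exist, and from an independently developed
coordinate-descent implementation (scikit-survival's coxnet) for the Cox
family.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from cpop import cross_validate_lambda, fit_penalised, fit_ridge, kkt_residual


def elastic_net_oracle(X, y, lam, alpha, family, pf=None, tol=1e-12):
    """Minimise the penalised objective with a generic convex optimiser.

    Uses the beta = beta_plus - beta_minus split so the l1 term becomes
    smooth under non-negativity bounds.  Centred (unscaled) features, the
    same parametrisation the solver uses with ``standardize=False``.
    """
    n, q = X.shape
    pf = np.ones(q) if pf is None else pf
    Xc = X - X.mean(axis=0)
    has_intercept = family != "cox"

    def unpack(z):
        off = 1 if has_intercept else 0
        return (z[0] if has_intercept else 0.0), z[off:off + q], z[off + q:]

    def objective(z):
        b0, bp, bn = unpack(z)
        beta = bp - bn
        eta = b0 + Xc @ beta
        if family == "gaussian":
            loss = 0.5 * np.mean((y - eta) ** 2)
        elif family == "binomial":
            loss = np.mean(np.logaddexp(0.0, eta) - y * eta)
        else:
            raise ValueError(family)
        pen = lam * np.sum(pf * (alpha * (bp + bn)
                                 + 0.5 * (1 - alpha) * beta**2))
        return loss + pen

    def grad(z):
        b0, bp, bn = unpack(z)
        beta = bp - bn
        eta = b0 + Xc @ beta
        if family == "gaussian":
            r = -(y - eta) / n
        else:
            r = (1.0 / (1.0 + np.exp(-eta)) - y) / n
        gbeta = Xc.T @ r
        gpen_l2 = lam * (1 - alpha) * pf * beta
        gp = gbeta + gpen_l2 + lam * alpha * pf
        gn = -gbeta - gpen_l2 + lam * alpha * pf
        if has_intercept:
            return np.concatenate([[r.sum()], gp, gn])
        return np.concatenate([gp, gn])

    off = 1 if has_intercept else 0
    z0 = np.zeros(off + 2 * q)
    bounds = ([(None, None)] * off) + [(0, None)] * (2 * q)
    res = minimize(objective, z0, jac=grad, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 50000, "ftol": 1e-15, "gtol": 1e-11,
                            "maxcor": 30})
    # status 2 = line search exhausted at machine precision: the point is
    # still the optimum to the accuracy the comparisons use
    res.usable = bool(res.success or res.status == 2)
    b0, bp, bn = unpack(res.x)
    return b0, bp - bn, res


def _toy_problem(rng, n=20, q=5, family="gaussian"):
    X = rng.normal(size=(n, q))
    beta = np.zeros(q)
    beta[: q // 2 + 1] = rng.normal(scale=1.0, size=q // 2 + 1)
    eta = X @ beta
    if family == "gaussian":
        y = eta + rng.normal(scale=0.5, size=n)
    else:
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestOracleEquivalence:
    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_matches_generic_convex_optimiser(self, family):
        """Ten random tiny instances per family agree with L-BFGS-B on the
        identical objective to 1e-4."""
        rng = np.random.default_rng(42)
        for rep in range(10):
            X, y = _toy_problem(rng, family=family)
            lam, alpha = 0.05 * (1 + rep % 3), 0.9
            fit = fit_penalised(X, y, alpha=alpha, lam=lam, family=family,
                                standardize=False)
            _, beta_ref, res = elastic_net_oracle(X, y, lam, alpha, family)
            assert res.usable
            np.testing.assert_allclose(fit.coefficients, beta_ref, atol=1e-4)

    def test_weighted_penalties_match_oracle(self):
        rng = np.random.default_rng(7)
        X, y = _toy_problem(rng)
        pf = np.array([0.5, 2.0, 1.0, 0.25, 1.25])  # mean 1 already
        fit = fit_penalised(X, y, penalty_factors=pf, alpha=0.8, lam=0.1,
                            family="gaussian", standardize=False)
        _, beta_ref, _ = elastic_net_oracle(X, y, 0.1, 0.8, "gaussian", pf=pf)
        np.testing.assert_allclose(fit.coefficients, beta_ref, atol=1e-4)

    def test_near_zero_lambda_recovers_ols(self):
        rng = np.random.default_rng(3)
        X, y = _toy_problem(rng, n=40, q=5)
        fit = fit_penalised(X, y, alpha=0.9, lam=1e-8, family="gaussian",
                            standardize=False)
        ols = np.linalg.lstsq(np.column_stack([np.ones(40), X]), y,
                              rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, ols[1:], atol=1e-3)
        assert fit.intercept == pytest.approx(ols[0], abs=1e-3)


class TestRidge:
    def test_single_feature_closed_form(self):
        """Centred one-feature ridge equals sum(xy) / (sum(x^2) + n*lam)."""
        rng = np.random.default_rng(11)
        n = 30
        x = rng.normal(size=n)
        y = 1.7 * x + rng.normal(scale=0.3, size=n)
        lam = 0.37
        fit = fit_penalised(x[:, None], y, alpha=0.0, lam=lam,
                            family="gaussian", standardize=False)
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / (np.sum(xc**2) + n * lam)
        assert fit.coefficients[0] == pytest.approx(expected, abs=1e-8)

    def test_duplicate_columns_share_coefficient(self):
        rng = np.random.default_rng(12)
        n = 40
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.2, size=n)
        X = np.column_stack([x, x])
        fit = fit_penalised(X, y, alpha=0.0, lam=0.2, family="gaussian",
                            standardize=False)
        assert fit.coefficients[0] == pytest.approx(fit.coefficients[1],
                                                    abs=1e-6)

    def test_separable_binomial_stays_finite(self):
        x = np.concatenate([-np.arange(1, 11.0), np.arange(1, 11.0)])
        y = (x > 0).astype(float)
        fit = fit_ridge(x[:, None], y, family="binomial", lam=0.1)
        assert np.all(np.isfinite(fit.coefficients))
        assert abs(fit.coefficients[0]) < 50


class TestPenaltyFactors:
    def test_huge_factor_pins_coefficient_to_zero(self):
        rng = np.random.default_rng(5)
        X, y = _toy_problem(rng)
        pf = np.ones(5)
        pf[2] = 1e8
        for lam in (0.001, 0.1, 1.0):
            fit = fit_penalised(X, y, penalty_factors=pf, alpha=0.9, lam=lam,
                                family="gaussian")
            assert fit.coefficients[2] == 0.0

    def test_common_rescaling_leaves_fit_unchanged(self):
        rng = np.random.default_rng(6)
        X, y = _toy_problem(rng)
        pf = np.array([0.5, 1.5, 1.0, 2.0, 0.1])
        a = fit_penalised(X, y, penalty_factors=pf, alpha=0.9, lam=0.05,
                          family="gaussian")
        b = fit_penalised(X, y, penalty_factors=pf * 137.0, alpha=0.9,
                          lam=0.05, family="gaussian")
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        X, y = _toy_problem(rng)
        X[:, 3] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_penalised(X, y, alpha=0.9, lam=0.05, family="gaussian")
        assert fit.coefficients[3] == 0.0


class TestCox:
    def _cox_problem(self, rng, n=40, q=4):
        X = rng.normal(size=(n, q))
        eta = X @ np.array([1.0, -0.5] + [0.0] * (q - 2))
        time = rng.exponential(np.exp(-eta))
        event = (rng.random(n) < 0.8).astype(float)
        event[np.argmax(time)] = 1.0  # ensure a terminal event
        return X, time, event

    def test_kkt_residual_below_tolerance(self):
        rng = np.random.default_rng(21)
        X, time, event = self._cox_problem(rng)
        fit = fit_penalised(X, (time, event), alpha=0.9, lam=0.05,
                            family="cox")
        assert kkt_residual(fit, X, (time, event)) < 1e-6

    def test_matches_independent_coxnet(self):
        """Same penalised partial-likelihood objective as scikit-survival's
        coxnet implementation."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        rng = np.random.default_rng(22)
        X, time, event = self._cox_problem(rng, n=60, q=5)
        lam, alpha = 0.08, 0.9
        fit = fit_penalised(X, (time, event), alpha=alpha, lam=lam,
                            family="cox", standardize=False, tol=1e-9)
        ref = CoxnetSurvivalAnalysis(alphas=[lam], l1_ratio=alpha,
                                     normalize=False, tol=1e-9)
        ref.fit(X, Surv.from_arrays(event.astype(bool), time))
        np.testing.assert_allclose(fit.coefficients, ref.coef_[:, 0],
                                   atol=2e-3)

    def test_univariate_ridge_matches_newton_solve(self):
        """One covariate, no ties: penalised Newton iteration on the exact
        partial likelihood gives the same estimate."""
        from cpop.wen import cox_log_partial_likelihood

        rng = np.random.default_rng(23)
        x = rng.normal(size=30)
        time = rng.exponential(np.exp(-0.8 * x))
        assert len(np.unique(time)) == 30
        event = np.ones(30)
        lam = 0.2
        fit = fit_penalised(x[:, None], (time, event), alpha=0.0, lam=lam,
                            family="cox", standardize=False, tol=1e-10)

        def negobj(b):
            return (-cox_log_partial_likelihood(x * b, time, event) / 30
                    + 0.5 * lam * b**2)

        from scipy.optimize import minimize_scalar
        ref = minimize_scalar(negobj, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-12})
        assert fit.coefficients[0] == pytest.approx(ref.x, abs=1e-6)


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(31)
        X, y = _toy_problem(rng, n=40, q=8)
        a = cross_validate_lambda(X, y, family="gaussian", seed=9)
        b = cross_validate_lambda(X, y, family="gaussian", seed=9)
        assert a.lambda_min == b.lambda_min
        np.testing.assert_array_equal(a.mean_deviance, b.mean_deviance)
        c = cross_validate_lambda(X, y, family="gaussian", seed=10)
        assert np.any(a.mean_deviance != c.mean_deviance)

    def test_full_penalty_limit_equals_null_model_deviance(self):
        """At the top of the path every fold fits the intercept-only model,
        so the CV deviance equals the cross-validated null deviance."""
        rng = np.random.default_rng(32)
        X, y = _toy_problem(rng, n=50, q=6)
        cv = cross_validate_lambda(X, y, family="gaussian", seed=4, n_folds=5)
        from cpop.wen import make_folds
        folds = make_folds(50, 5, 4, None)
        null_dev = np.mean([
            np.mean((y[folds == k] - y[folds != k].mean()) ** 2)
            for k in range(5)])
        assert cv.mean_deviance[0] == pytest.approx(null_dev, abs=1e-6)

    def test_sparsity_under_pure_noise(self):
        """Permuted responses: repeated cross-validation keeps the selected
        model essentially empty (the all-zero solution is modal)."""
        rng = np.random.default_rng(33)
        counts = []
        for _ in range(15):
            X = rng.normal(size=(100, 300))
            y = rng.permutation(np.r_[np.zeros(50), np.ones(50)])
            fit = fit_penalised(X, y, alpha=0.9, lam="cv", family="gaussian",
                                seed=int(rng.integers(2**31)), n_repeats=3)
            counts.append(len(fit.nonzero))
        counts = np.array(counts)
        assert np.median(counts) <= 2
        assert np.mean(counts == 0) >= 0.5

    def test_lambda_band_ordering(self):
        rng = np.random.default_rng(34)
        X, y = _toy_problem(rng, n=40, q=8)
        cv = cross_validate_lambda(X, y, family="gaussian", seed=2)
        assert cv.lambda_1se >= cv.lambda_min >= cv.lambda_deep


class TestSolverInternals:
    def test_objective_monotone_descent(self):
        rng = np.random.default_rng(41)
        X, y = _toy_problem(rng, n=30, q=10)
        fit = fit_penalised(X, y, alpha=0.9, lam=0.02, family="gaussian",
                            record_objective=True)
        hist = fit.objective_history
        assert hist is not None and len(hist) >= 1
        assert np.all(np.diff(hist) <= 1e-12)

    def test_path_support_grows_as_lambda_shrinks(self):
        rng = np.random.default_rng(42)
        X, y = _toy_problem(rng, n=60, q=10)
        fit = fit_penalised(X, y, alpha=0.9, lam=float(1e-4),
                            family="gaussian", keep_path=True)
        counts = fit.path_nonzero_counts()
        assert counts[0] == 0
        assert np.all(np.diff(counts) >= 0)

    def test_kkt_satisfied_along_path(self):
        rng = np.random.default_rng(43)
        X, y = _toy_problem(rng, n=30, q=8)
        for lam in (0.2, 0.05, 0.01):
            fit = fit_penalised(X, y, alpha=0.9, lam=lam, family="gaussian")
            assert kkt_residual(fit, X, y) < 1e-5
            assert fit.converged
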