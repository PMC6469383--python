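import numpy as np
import pytest

from sgllmm.io import GroupStructure
from sgllmm.sgl import (
    SGLProblem,
    fit_path,
    fit_sgl,
    kkt_residual,
    lambda_max,
    objective,
)

from .conftest import random_problem
from .oracles import ista_sgl, sgl_objective_reference


def two_groups(p=6):
    return GroupStructure(["a", "b"], np.repeat([0, 1], p // 2))


class TestObjective:
    def test_zero_beta_is_scaled_rss(self, rng):
        pr = random_problem(rng)
        assert objective(pr, np.zeros(pr.p), 0.3) == pytest.approx(
            np.sum(pr.y**2) / (2 * pr.n)
        )

    def test_alpha_one_reduces_to_lasso_penalty(self, rng):
        pr = random_problem(rng, alpha=1.0)
        beta = rng.standard_normal(pr.p)
        lam = 0.7
        expect = np.sum((pr.y - pr.X @ beta) ** 2) / (2 * pr.n) + lam * np.sum(np.abs(beta))
        assert objective(pr, beta, lam) == pytest.approx(expect)

    def test_matches_term_by_term_recomputation(self, rng):
        pr = random_problem(rng, alpha=0.6)
        beta = rng.standard_normal(pr.p)
        expect = sgl_objective_reference(
            pr.X, pr.y, pr.groups.members, pr.group_weights, pr.alpha, 0.4, beta
        )
        assert objective(pr, beta, 0.4) == pytest.approx(expect, rel=1e-12)


class TestLambdaMax:
    def test_lasso_closed_form(self, rng):
        pr = random_problem(rng, alpha=1.0)
        expect = np.max(np.abs(pr.X.T @ pr.y)) / pr.n
        assert lambda_max(pr) == pytest.approx(expect, rel=1e-12)

    def test_zero_response(self, rng):
        X = rng.standard_normal((10, 4))
        pr = SGLProblem(X=X, y=np.zeros(10), groups=two_groups(4), alpha=0.9)
        assert lambda_max(pr) == 0.0

    def test_brackets_the_support_boundary(self, rng):
        X = rng.standard_normal((25, 4))
        y = X[:, 0] + 0.1 * rng.standard_normal(25)
        pr = SGLProblem(X=X, y=y, groups=two_groups(4), alpha=0.95)
        lmax = lambda_max(pr)
        assert fit_sgl(pr, 1.001 * lmax).n_nonzero == 0
        assert fit_sgl(pr, 0.95 * lmax).n_nonzero > 0

    def test_group_lasso_closed_form(self, rng):
        pr = random_problem(rng, alpha=0.0)
        expect = max(
            np.linalg.norm(pr.X[:, idx].T @ pr.y / pr.n) / w
            for w, idx in zip(pr.group_weights, pr.groups.members)
        )
        assert lambda_max(pr) == pytest.approx(expect, rel=1e-12)


class TestFitSGL:
    def test_at_lambda_max_beta_zero_one_pass(self, rng):
        pr = random_problem(rng)
        fit = fit_sgl(pr, lambda_max(pr))
        assert fit.n_nonzero == 0
        assert fit.n_iter == 1

    def test_orthonormal_lasso_closed_form(self, rng):
        # X^T X = n I: the lasso solution is coordinatewise soft-thresholding
        n, p = 32, 4
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = np.sqrt(n) * Q
        y = rng.standard_normal(n)
        pr = SGLProblem(X=X, y=y, groups=two_groups(p), alpha=1.0)
        lam = 0.4 * lambda_max(pr)
        fit = fit_sgl(pr, lam, tol=1e-10, kkt_tol=1e-10)
        z = X.T @ y / n
        expect = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
        np.testing.assert_allclose(fit.beta, expect, atol=1e-9)
        assert kkt_residual(pr, expect, lam) <= 1e-10

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.95, 1.0])
    def test_matches_independent_ista_oracle(self, alpha):
        rng = np.random.default_rng(100 + int(alpha * 100))
        pr = random_problem(rng, n=30, n_groups=2, group_size=3, alpha=alpha)
        lam = 0.1 * lambda_max(pr)
        fit = fit_sgl(pr, lam, tol=1e-9, kkt_tol=1e-8)
        beta_oracle = ista_sgl(
            pr.X, pr.y, pr.groups.members, pr.group_weights, alpha, lam
        )
        obj_oracle = sgl_objective_reference(
            pr.X, pr.y, pr.groups.members, pr.group_weights, alpha, lam, beta_oracle
        )
        assert fit.objective == pytest.approx(obj_oracle, rel=1e-5)
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-5)

    def test_alpha_one_matches_sklearn_lasso(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        pr = random_problem(rng, n=40, n_groups=3, group_size=3, alpha=1.0)
        lam = 0.2 * lambda_max(pr)
        fit = fit_sgl(pr, lam, tol=1e-12, kkt_tol=1e-10)
        las = sklearn.Lasso(alpha=lam, fit_intercept=False, tol=1e-14, max_iter=100_000)
        las.fit(pr.X, pr.y)
        np.testing.assert_allclose(fit.beta, las.coef_, atol=1e-6)

    def test_nonconvergence_is_flagged(self, rng):
        pr = random_problem(rng, n=20, n_groups=2, group_size=4)
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_sgl(pr, 0.01 * lambda_max(pr), max_iter=1, max_inner=1)
        assert not fit.converged


class TestKKTResidual:
    def test_perturbation_detected(self, rng):
        pr = random_problem(rng)
        lam = 0.3 * lambda_max(pr)
        fit = fit_sgl(pr, lam)
        assert fit.kkt_residual <= 1e-4
        beta = fit.beta.copy()
        j = fit.beta.nonzero()[0][0]
        beta[j] += 0.1
        assert kkt_residual(pr, beta, lam) > 1e-3

    def test_converged_fits_sweep(self):
        # solver self-consistency over many random instances
        for trial in range(50):
            rng = np.random.default_rng(trial)
            alpha = rng.choice([0.0, 0.5, 0.95, 1.0])
            pr = random_problem(rng, n=25, n_groups=3, group_size=2, alpha=float(alpha))
            lam = float(rng.uniform(0.05, 0.8)) * lambda_max(pr)
            fit = fit_sgl(pr, lam)
            assert fit.converged
            assert fit.kkt_residual <= 1e-4


class TestFitPath:
    def test_first_fit_zero_and_boundary_counts(self, rng):
        pr = random_problem(rng)
        path = fit_path(pr, nlam=20)
        assert path.fits[0].n_nonzero == 0
        assert path.fits[-1].n_nonzero >= path.fits[0].n_nonzero
        assert np.all(np.diff(path.lambdas) < 0)

    def test_warm_equals_cold_start(self, rng):
        pr = random_problem(rng, n=40)
        path = fit_path(pr, nlam=12, tol=1e-8, kkt_tol=1e-6)
        for lam, warm_fit in zip(path.lambdas, path.fits):
            cold = fit_sgl(pr, lam, tol=1e-8, kkt_tol=1e-6)
            assert cold.objective == pytest.approx(warm_fit.objective, rel=1e-5)

    def test_nested_lambda_objective_monotonicity(self, rng):
        pr = random_problem(rng)
        path = fit_path(pr, nlam=10)
        for i in range(len(path.lambdas) - 1):
            lam2 = path.lambdas[i + 1]
            obj_b2 = objective(pr, path.fits[i + 1].beta, lam2)
            obj_b1 = objective(pr, path.fits[i].beta, lam2)
            assert obj_b2 <= obj_b1 + 1e-10


class TestInvariances:
    def test_group_order_and_within_group_permutation(self, rng):
        pr = random_problem(rng, n=40, n_groups=3, group_size=3, alpha=0.8)
        lam = 0.2 * lambda_max(pr)
        fit = fit_sgl(pr, lam, tol=1e-10, kkt_tol=1e-8)
        perm = rng.permutation(pr.p)
        assignments = pr.groups.assignments[perm]
        # relabel groups in order of first appearance to shuffle group order too
        groups_p = GroupStructure(pr.groups.group_ids, assignments)
        pr_p = SGLProblem(X=pr.X[:, perm], y=pr.y, groups=groups_p, alpha=0.8)
        fit_p = fit_sgl(pr_p, lam, tol=1e-10, kkt_tol=1e-8)
        np.testing.assert_allclose(fit_p.beta, fit.beta[perm], atol=1e-7)

    def test_unscaled_loss_mode(self, rng):
        # scale_loss=False runs the textbook objective; solutions coincide
        # with the scaled problem at lambda' = 2 n lambda
        pr = random_problem(rng, n=30, alpha=0.9)
        pr_raw = SGLProblem(X=pr.X, y=pr.y, groups=pr.groups, alpha=0.9, scale_loss=False)
        lam = 0.3 * lambda_max(pr)
        f_scaled = fit_sgl(pr, lam, tol=1e-10, kkt_tol=1e-8)
        f_raw = fit_sgl(pr_raw, 2 * pr.n * lam, tol=1e-10, kkt_tol=1e-6)
        np.testing.assert_allclose(f_raw.beta, f_scaled.beta, atol=1e-6)
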