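import numpy as np
import pytest
from scipy import stats

from sgllmm.kinship import KinshipEigen, compute_rrm, eigendecompose, standardize_genotypes
from sgllmm.lmm import (
    estimate_delta,
    estimate_sigma_g2,
    profile_negloglik,
    rotate_data,
)


def random_kinship(rng, m, p):
    Z, _ = standardize_genotypes(rng.choice([0.0, 1.0, 2.0], size=(m, p)))
    return eigendecompose(compute_rrm(Z))


class TestProfileNegloglik:
    def test_constant_in_delta_when_K_is_identity(self, rng):
        # with K = I the scale absorbs (1 + delta): profile is flat
        y = rng.standard_normal(12)
        S = np.ones(12)
        v1 = profile_negloglik(0.5, S, y)
        v2 = profile_negloglik(2.0, S, y)
        # values differ by sum(log(S+d)) - m*log(...) cancellation
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_matches_dense_mvn_density_oracle(self, rng):
        ke = random_kinship(rng, 6, 10)
        y = rng.standard_normal(6)
        Uty = ke.U.T @ y
        m = 6
        for delta in (0.3, 1.0, 4.0):
            f = profile_negloglik(delta, ke.S, Uty)
            sg2 = estimate_sigma_g2(delta, ke.S, Uty)
            cov = sg2 * (ke.K + delta * np.eye(m))
            logpdf = stats.multivariate_normal(mean=np.zeros(m), cov=cov).logpdf(y)
            # f = -2*logpdf - m*log(2*pi) - m  (constant C dropped)
            assert f == pytest.approx(-2 * logpdf - m * np.log(2 * np.pi) - m, rel=1e-9)

    def test_large_delta_asymptotics(self, rng):
        ke = random_kinship(rng, 8, 12)
        y = rng.standard_normal(8)
        Uty = ke.U.T @ y
        delta = 1e8
        f = profile_negloglik(delta, ke.S, Uty)
        m = 8
        approx = m * np.log(y @ y / m) + np.sum(np.log(ke.S + delta)) - m * np.log(delta)
        assert f == pytest.approx(approx, abs=1e-5)

    def test_zero_response_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            profile_negloglik(1.0, np.ones(4), np.zeros(4))

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            profile_negloglik(0.0, np.ones(3), np.ones(3))


class TestEstimateSigmaG2:
    def test_iid_limit(self, rng):
        y = rng.standard_normal(20)
        val = estimate_sigma_g2(1e-10, np.ones(20), y)
        assert val == pytest.approx(y @ y / 20, rel=1e-8)

    def test_quadratic_scaling(self, rng):
        S = np.abs(rng.standard_normal(9))
        Uty = rng.standard_normal(9)
        assert estimate_sigma_g2(0.7, S, 2 * Uty) == pytest.approx(
            4 * estimate_sigma_g2(0.7, S, Uty)
        )

    def test_matches_direct_solve_oracle(self, rng):
        ke = random_kinship(rng, 5, 8)
        y = rng.standard_normal(5)
        delta = 0.9
        direct = y @ np.linalg.solve(ke.K + delta * np.eye(5), y) / 5
        assert estimate_sigma_g2(delta, ke.S, ke.U.T @ y) == pytest.approx(direct, rel=1e-10)


class TestEstimateDelta:
    def test_monte_carlo_recovery_of_unit_delta(self):
        # y ~ N(0, sigma_g2 (K + I)): median |ln delta_hat| < 0.35 over 20 reps
        rng = np.random.default_rng(7)
        ke = random_kinship(rng, 500, 600)
        errs = []
        for _ in range(20):
            z = rng.standard_normal(500)
            y = ke.U @ (np.sqrt(ke.S + 1.0) * z)  # delta = 1, sigma_g2 = 1
            nm = estimate_delta(ke, y)
            errs.append(abs(np.log(nm.delta)))
        assert np.median(errs) < 0.35

    def test_flat_profile_at_identity_kinship(self, rng):
        ke = KinshipEigen(K=np.eye(30), U=np.eye(30), S=np.ones(30))
        nm = estimate_delta(ke, rng.standard_normal(30))
        assert nm.flat_likelihood
        assert nm.delta == 1.0

    def test_refinement_beats_grid_and_matches_fine_grid(self, rng):
        ke = random_kinship(rng, 60, 80)
        y = ke.U @ (np.sqrt(ke.S + 0.5) * rng.standard_normal(60))
        Uty = ke.U.T @ y
        nm = estimate_delta(ke, y)
        grid = np.linspace(-10, 10, 100)
        grid_best = min(profile_negloglik(np.exp(g), ke.S, Uty) for g in grid)
        assert profile_negloglik(nm.delta, ke.S, Uty) <= grid_best + 1e-12
        # agreement with a 10x finer grid within one fine-grid step
        fine = np.linspace(-10, 10, 1000)
        fine_vals = [profile_negloglik(np.exp(g), ke.S, Uty) for g in fine]
        fine_argmin = fine[int(np.argmin(fine_vals))]
        step = fine[1] - fine[0]
        assert abs(np.log(nm.delta) - fine_argmin) <= step

    def test_small_sample_warns(self, rng):
        ke = random_kinship(rng, 6, 10)
        with pytest.warns(UserWarning, match="fewer than 10"):
            estimate_delta(ke, rng.standard_normal(6))


class TestRotateData:
    def test_identity_kinship_is_isometry(self, rng):
        ke = KinshipEigen(K=np.eye(10), U=np.eye(10), S=np.ones(10))
        nm = estimate_delta(ke, rng.standard_normal(10))
        y = rng.standard_normal(10)
        X = rng.standard_normal((10, 3))
        rot = rotate_data(ke, nm, y, X)
        # S_i + delta = 2 for all i: pure scaling of an orthogonal rotation
        assert np.linalg.norm(rot.y_tilde) == pytest.approx(np.linalg.norm(y) / np.sqrt(2))

    def test_whitening_identity_over_random_betas(self, rng):
        ke = random_kinship(rng, 15, 25)
        y = rng.standard_normal(15)
        X = rng.standard_normal((15, 4))
        nm = estimate_delta(ke, y)
        rot = rotate_data(ke, nm, y, X)
        Vinv = np.linalg.inv(ke.K + nm.delta * np.eye(15))
        for _ in range(5):
            beta = rng.standard_normal(4)
            lhs = np.sum((rot.y_tilde - rot.X_tilde @ beta) ** 2)
            resid = y - X @ beta
            rhs = resid @ Vinv @ resid
            assert lhs == pytest.approx(rhs, rel=1e-8)
        # beta = 0 special case
        assert np.sum(rot.y_tilde**2) == pytest.approx(y @ Vinv @ y, rel=1e-8)

    def test_gls_consistency(self, rng):
        # unpenalized least squares on rotated data equals textbook GLS
        ke = random_kinship(rng, 40, 60)
        y = rng.standard_normal(40)
        X = rng.standard_normal((40, 5))
        nm = estimate_delta(ke, y)
        rot = rotate_data(ke, nm, y, X)
        beta_ols = np.linalg.lstsq(rot.X_tilde, rot.y_tilde, rcond=None)[0]
        V = ke.K + nm.delta * np.eye(40)
        Vinv_X = np.linalg.solve(V, X)
        beta_gls = np.linalg.solve(X.T @ Vinv_X, Vinv_X.T @ y)
        np.testing.assert_allclose(beta_ols, beta_gls, rtol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        ke = random_kinship(rng, 8, 10)
        nm = estimate_delta(ke, rng.standard_normal(8))
        with pytest.raises(ValueError, match="rows"):
            rotate_data(ke, nm, rng.standard_normal(8), rng.standard_normal((7, 2)))


def test_null_model_save_load_roundtrip(tmp_path, rng):
    ke = random_kinship(rng, 30, 40)
    nm = estimate_delta(ke, rng.standard_normal(30))
    nm.save(tmp_path / "null.tsv")
    from sgllmm.lmm import NullModel

    back = NullModel.load(tmp_path / "null.tsv")
    assert back.delta == nm.delta
    assert back.sigma_g2 == nm.sigma_g2
    assert back.flat_likelihood == nm.flat_likelihood
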