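"""MIMIC ML fitter: implied moments, discrepancy, gradient, recovery, SEs."""

import numpy as np
import pytest

from mimicsim import (
    Dataset,
    ItemBank,
    MimicSpec,
    Scenario,
    fit_indices,
    fit_mimic,
    fml_discrepancy,
    generate_dataset,
    implied_moments,
    wald_dif_test,
)
from mimicsim.mimic_sem import _fml_and_grad, model_df, n_free_params

from conftest import simulate_structural


def _random_params(spec, rng):
    k = spec.n_items
    nb = len(spec.direct_items)
    return np.concatenate(
        [
            rng.uniform(0.5, 1.5, k - 1),
            rng.normal(0, 1, k),
            rng.uniform(0.2, 1.0, k),
            rng.normal(0, 0.5, 1 + nb),
            rng.uniform(0.5, 1.5, 1),
        ]
    )


class TestImpliedMoments:
    def test_no_latent_signal_is_diagonal(self):
        spec = MimicSpec(n_items=4, studied_item=0)
        k = 4
        params = np.zeros(n_free_params(k))
        psi = np.array([0.5, 0.6, 0.7, 0.8])
        params[2 * k - 1 : 3 * k - 1] = psi
        params[-1] = 1.0  # zeta variance (no loadings pick it up except fixed)
        params[: k - 1] = 0.0  # free loadings zero; fixed loading stays 1
        mu, sig = implied_moments(params, spec, 0.25, 0.5)
        # only the fixed-loading item carries latent variance
        fixed = spec.fixed_loading_item
        expect = np.diag(psi)
        expect[fixed, fixed] += 1.0
        assert np.allclose(sig[:k, :k], expect)
        assert np.allclose(sig[:k, k], 0.0)

    def test_path_tracing_for_item_covariate_covariances(self, rng):
        # cov(item_i, x) = (lambda_i * gamma + beta * 1[i=s]) * var(x)
        spec = MimicSpec(n_items=5, studied_item=2)
        params = _random_params(spec, rng)
        vx, mx = 0.25, 0.4
        mu, sig = implied_moments(params, spec, vx, mx)
        k = 5
        lam = np.ones(k)
        lam[spec.free_loading_items] = params[: k - 1]
        gamma, beta = params[3 * k - 1], params[3 * k]
        expect = lam * gamma * vx
        expect[2] += beta * vx
        assert np.allclose(sig[:k, k], expect)

    def test_agrees_with_structural_simulation(self, rng):
        # oracle equivalence: empirical moments of the simulated structural
        # equations converge to the implied moments
        spec = MimicSpec(n_items=4, studied_item=1)
        k = 4
        lam_free = np.array([0.8, 1.2, 0.9])
        tau = np.array([0.2, -0.1, 0.4, 0.0])
        psi = np.array([0.5, 0.4, 0.6, 0.3])
        gamma, beta, psi_z = -0.4, -0.3, 0.9
        params = np.concatenate([lam_free, tau, psi, [gamma, beta, psi_z]])
        n = 1_000_000
        x = (rng.random(n) < 0.4).astype(float)
        lam = np.ones(k)
        lam[spec.free_loading_items] = lam_free
        theta = gamma * x + rng.normal(0, np.sqrt(psi_z), n)
        y = tau + np.outer(theta, lam)
        y[:, 1] += beta * x
        y += rng.normal(0, np.sqrt(psi), (n, k))
        z = np.column_stack([y, x])
        emp_mu, emp_cov = z.mean(0), np.cov(z, rowvar=False)
        mu, sig = implied_moments(params, spec, x.var(ddof=1), x.mean())
        assert np.allclose(mu, emp_mu, atol=0.01)
        assert np.allclose(sig, emp_cov, atol=0.01)

    def test_wrong_length_raises(self):
        spec = MimicSpec(n_items=5, studied_item=0)
        with pytest.raises(ValueError):
            implied_moments(np.zeros(3), spec, 0.25, 0.5)


class TestFmlDiscrepancy:
    def test_zero_when_moments_match(self, rng):
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 4 * np.eye(4)
        m = rng.normal(size=4)
        assert fml_discrepancy(m, S, m, S) == pytest.approx(0.0, abs=1e-10)

    def test_scalar_hand_example(self):
        # log 2 + 1/2 - log 1 - 1 = 0.193147...
        val = fml_discrepancy([0.0], [[1.0]], [0.0], [[2.0]])
        assert val == pytest.approx(np.log(2) - 0.5, abs=1e-12)

    def test_nonnegative_on_random_instances(self, rng):
        # Kullback-Leibler nonnegativity
        for _ in range(50):
            p = rng.integers(2, 6)
            A = rng.normal(size=(p, p))
            B = rng.normal(size=(p, p))
            S = A @ A.T + p * np.eye(p)
            sig = B @ B.T + p * np.eye(p)
            v = fml_discrepancy(rng.normal(size=p), S, rng.normal(size=p), sig)
            assert v >= -1e-12


class TestGradient:
    @pytest.mark.parametrize("k, studied, extras", [(5, 0, ()), (5, 2, (0,)), (8, 3, ())])
    def test_analytic_matches_finite_difference(self, rng, k, studied, extras):
        spec = MimicSpec(n_items=k, studied_item=studied, extra_direct_items=extras)
        data = generate_dataset(Scenario(200, 100, 0.5, k, 3, 13, seed=4))
        z = np.column_stack([data.responses.astype(float), data.group.astype(float)])
        mbar, S = z.mean(0), np.cov(z, rowvar=False, ddof=1)
        vx, mx = S[k, k], mbar[k]
        params = _random_params(spec, rng)
        _, grad = _fml_and_grad(params, spec, mbar, S, vx, mx)
        fd = np.zeros_like(grad)
        h = 1e-6
        for i in range(len(params)):
            e = np.zeros_like(params)
            e[i] = h
            fp, _ = _fml_and_grad(params + e, spec, mbar, S, vx, mx)
            fm, _ = _fml_and_grad(params - e, spec, mbar, S, vx, mx)
            fd[i] = (fp - fm) / (2 * h)
        assert np.all(np.abs(grad - fd) <= 1e-5 * (np.abs(fd) + 1e-3))


class TestFitMimic:
    def test_parameter_recovery_large_n(self, rng):
        k = 5
        lam = np.array([1.0, 1.0, 0.8, 1.2, 0.9])
        tau = np.array([0.5, -0.2, 0.1, 0.0, 0.3])
        psi = np.array([0.5, 0.4, 0.6, 0.3, 0.5])
        gamma, beta, psi_z = -0.4, -0.3, 1.0
        data = simulate_structural(50_000, lam, tau, psi, gamma, beta, psi_z, 0, rng)
        fit = fit_mimic(data, MimicSpec(n_items=k, studied_item=0))
        assert fit.converged and not fit.heywood
        assert np.all(np.abs(fit.loadings - lam) < 0.02)
        assert abs(fit.gamma - gamma) < 0.02
        assert abs(fit.beta - beta) < 0.02
        # all estimates within 3 reported SEs of truth
        assert abs(fit.beta - beta) < 3 * fit.se_beta
        assert abs(fit.gamma - gamma) < 3 * fit.se_gamma
        # near-perfect fit at the truth
        assert fit.fml < 5e-4
        assert fit.fit_indices["cfi"] > 0.999

    def test_refit_is_bit_identical(self):
        data = generate_dataset(Scenario(150, 100, 0.5, 5, 3, 13, seed=21))
        spec = MimicSpec(n_items=5, studied_item=0)
        f1, f2 = fit_mimic(data, spec), fit_mimic(data, spec)
        assert f1.beta == f2.beta and f1.se_beta == f2.se_beta
        assert np.array_equal(f1.loadings, f2.loadings)
        assert f1.chi_square == f2.chi_square

    def test_se_calibration_under_correct_specification(self, rng):
        # empirical sd of beta-hat vs mean reported SE, within 10%
        k = 5
        lam = np.array([1.0, 1.0, 0.8, 1.2, 0.9])
        tau = np.zeros(k)
        psi = np.array([0.5, 0.4, 0.6, 0.3, 0.5])
        spec = MimicSpec(n_items=k, studied_item=0)
        betas, ses = [], []
        for _ in range(500):
            data = simulate_structural(600, lam, tau, psi, -0.4, 0.0, 1.0, 0, rng)
            fit = fit_mimic(data, spec)
            betas.append(fit.beta)
            ses.append(fit.se_beta)
        ratio = np.std(betas) / np.mean(ses)
        assert 0.9 < ratio < 1.1

    def test_null_beta_within_three_se(self, rng):
        # asymptotic normality: |beta-hat| < 3 se in >= 99% of null replications
        k = 5
        lam = np.ones(k)
        psi = np.full(k, 0.5)
        spec = MimicSpec(n_items=k, studied_item=0)
        inside = 0
        n_reps = 200
        for _ in range(n_reps):
            data = simulate_structural(2_000, lam, np.zeros(k), psi, -0.4, 0.0, 1.0, 0, rng)
            fit = fit_mimic(data, spec)
            inside += abs(fit.beta) < 3 * fit.se_beta
        assert inside / n_reps >= 0.99

    def test_degrees_of_freedom_count(self):
        assert model_df(5) == 8
        assert model_df(10) == 43
        assert MimicSpec(n_items=5, studied_item=0, extra_direct_items=(2,)).df == 7

    def test_mismatched_spec_raises(self):
        data = generate_dataset(Scenario(100, 100, 0.0, 5, 3, 13, seed=1))
        with pytest.raises(ValueError):
            fit_mimic(data, MimicSpec(n_items=6, studied_item=0))


class TestWaldTest:
    def test_null_point(self):
        z, p = wald_dif_test(0.0, 1.0)
        assert z == 0.0 and p == 1.0

    def test_frozen_tail_value(self):
        z, p = wald_dif_test(0.5, 0.25)
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.0455, abs=5e-5)

    def test_two_sided_symmetry(self):
        assert wald_dif_test(-0.5, 0.25)[1] == wald_dif_test(0.5, 0.25)[1]

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            wald_dif_test(0.5, 0.0)


class TestFitIndices:
    def test_rmsea_hand_example(self):
        idx = fit_indices(50.0, 25, 500.0, 40, 101, np.eye(3), np.eye(3))
        assert idx["rmsea"] == pytest.approx(0.1)

    def test_perfect_fit_limits(self):
        idx = fit_indices(25.0, 25, 500.0, 40, 101, np.eye(3), np.eye(3))
        assert idx["rmsea"] == 0.0
        assert idx["cfi"] == 1.0
        assert idx["rmr"] == 0.0
        assert idx["gfi"] == 1.0

    def test_saturated_model_rmsea_zero(self):
        idx = fit_indices(0.0, 0, 500.0, 40, 101, np.eye(3), np.eye(3))
        assert idx["rmsea"] == 0.0
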