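"""Fisher deconvolution, the Beta-type density q_rho, and the matrix density q_R."""

import numpy as np
import pytest
from scipy import integrate, stats

from fdmoments.corr_density import (
    CorrelationSample,
    alpha_from_variance,
    denoise_tau_variance,
    exponent_from_alpha,
    fisher,
    fisher_inv,
    pairwise_correlations,
    q_R_logpdf,
    q_rho_pdf,
    q_rho_quadrature,
    q_rho_variance,
    rho_scale_variance,
    sample_qR,
    sampling_variance,
)
from fdmoments.panels import ResidualPanel


class TestFisher:
    def test_values_and_roundtrip(self):
        assert fisher(0.0) == 0.0
        assert fisher(0.9) == pytest.approx(1.47221949, abs=1e-7)
        grid = np.linspace(-0.99, 0.99, 41)
        np.testing.assert_allclose(fisher_inv(fisher(grid)), grid, atol=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher(1.0)


class TestPairwiseCorrelations:
    def test_degenerate_pairs_excluded(self):
        X = np.array(
            [[1.0, -1, 1, -1, 1, -1],
             [-1, 1, -1, 1, -1, 1],
             [0.5, 0.1, -0.3, 0.2, -0.4, -0.1],
             [1.0, -1, 1, -1, 1, -1]]
        )
        res = ResidualPanel(X, np.array([1, 1, 1, 2, 2, 2]), effective_df=6)
        with pytest.warns(UserWarning, match="degenerate"):
            s = pairwise_correlations(res)
        assert np.all(np.abs(s.rho_bar) < 1)
        np.testing.assert_allclose(s.tau_bar, np.arctanh(s.rho_bar))

    def test_null_variance_oracle(self, residual_rows):
        """Independent residual rows: rho_bar is centered with spread set by
        the effective dimension (var ~ 1/m_eff for spherical m_eff-vectors)."""
        res = residual_rows(50, 20, seed=1)
        s = pairwise_correlations(res)
        assert s.m_eff == 18
        assert abs(s.rho_bar.mean()) < 3 / np.sqrt(s.n_pairs * s.m_eff)
        assert s.rho_bar.var() == pytest.approx(1 / 18, rel=0.15)

    def test_subsampling_budget(self, residual_rows):
        res = residual_rows(80, 10, seed=2)
        s = pairwise_correlations(res, max_pairs=500, seed=0)
        assert s.n_pairs == 500
        assert s.n_pairs_total == 80 * 79 // 2


class TestDenoise:
    def test_generative_recovery(self, rng):
        """tau_bar = tau + eps recovers Var(tau) after noise subtraction."""
        n = 100_000
        tau = rng.normal(0, np.sqrt(0.05), n)
        noise_var = sampling_variance(12)  # = 1/10
        eps = rng.normal(0, np.sqrt(noise_var), n)
        s = CorrelationSample(
            rho_bar=np.tanh(tau + eps), tau_bar=tau + eps, m_eff=12,
            n_pairs_total=n,
        )
        _, s2 = denoise_tau_variance(s)
        assert s2 == pytest.approx(0.05, rel=0.10)

    def test_noise_level_invariance(self, rng):
        """Doubling the noise while correcting with the matching constant
        leaves the denoised variance unchanged in expectation."""
        n = 200_000
        tau = rng.normal(0, np.sqrt(0.05), n)
        outs = []
        for noise_var in (0.05, 0.10):
            tb = tau + rng.normal(0, np.sqrt(noise_var), n)
            s = CorrelationSample(np.tanh(tb), tb, m_eff=10, n_pairs_total=n)
            _, s2 = denoise_tau_variance(s, fisher_var=noise_var)
            outs.append(s2)
        assert outs[0] == pytest.approx(outs[1], rel=0.10)

    def test_zero_signal_is_error(self):
        tb = np.array([0.1, -0.1, 0.05, -0.05] * 100)
        s = CorrelationSample(np.tanh(tb), tb, m_eff=102, n_pairs_total=400)
        # sampling variance 1/100 = 0.01 > Var(tau_bar) ~ 0.00625
        with pytest.raises(ValueError, match="nonpositive"):
            denoise_tau_variance(s)

    def test_rule_constants(self):
        assert sampling_variance(14) == pytest.approx(1 / 12)
        assert sampling_variance(14, rule="mk1") == pytest.approx(1 / 13)
        assert sampling_variance(14, rule="m3") == pytest.approx(1 / 13)
        assert sampling_variance(14, G=100, rule="g3") == pytest.approx(1 / 97)
        assert sampling_variance(14, rule=0.2) == 0.2


class TestRhoScaleVariance:
    def test_small_variance_limit(self):
        for s2 in (1e-6, 1e-8):
            assert rho_scale_variance(s2) / s2 == pytest.approx(1.0, rel=1e-4)

    def test_against_monte_carlo(self, rng):
        s2 = 0.25
        draws = rng.normal(0, np.sqrt(s2), 1_000_000)
        mc = np.mean(np.tanh(draws) ** 2)
        assert rho_scale_variance(s2) == pytest.approx(mc, rel=1e-3)

    def test_strict_contraction(self):
        for s2 in (0.01, 0.1, 0.5, 2.0):
            assert rho_scale_variance(s2) < s2


class TestAlphaMap:
    @pytest.mark.parametrize(
        "s2, alpha",
        [(1 / 3, 1.0), (1.0, 0.0), (1 / (2 * 17.77 + 1), 17.77)],
    )
    def test_variance_to_alpha(self, s2, alpha):
        assert alpha_from_variance(s2) == pytest.approx(alpha, abs=1e-9)

    def test_domain(self):
        with pytest.raises(ValueError):
            alpha_from_variance(1.5)

    def test_conventions(self):
        assert exponent_from_alpha(3.51, "eq22") == 3.51
        assert exponent_from_alpha(3.51, "eq24") == pytest.approx(2.51)
        with pytest.raises(ValueError):
            exponent_from_alpha(0.5, "eq24")


class TestQRho:
    def test_uniform_at_zero_shape(self):
        xs = np.linspace(-1, 1, 11)
        np.testing.assert_allclose(q_rho_pdf(xs, 0.0), 0.5)

    @pytest.mark.parametrize("a", [0.5, 3.51, 17.77])
    def test_normalization_and_variance(self, a):
        val, _ = integrate.quad(lambda x: q_rho_pdf(x, a), -1, 1)
        assert val == pytest.approx(1.0, abs=1e-10)
        m2, _ = integrate.quad(lambda x: x * x * q_rho_pdf(x, a), -1, 1)
        assert m2 == pytest.approx(q_rho_variance(a), abs=1e-10)

    def test_concentration_at_large_shape(self):
        a = 1e4
        m2, _ = integrate.quad(lambda x: x * x * q_rho_pdf(x, a), -0.1, 0.1)
        assert m2 < 1e-4

    def test_quadrature_is_exact_for_moments(self):
        x, w = q_rho_quadrature(3.51)
        assert w.sum() == pytest.approx(1.0)
        assert np.sum(w * x**2) == pytest.approx(q_rho_variance(3.51), abs=1e-12)
        assert abs(np.sum(w * x)) < 1e-14


class TestQR:
    def test_mode_and_support(self):
        assert q_R_logpdf(0.0, 0.0, 0.0, 3.0) == pytest.approx(0.0)
        # (0.9, 0.9, -0.9) is not positive definite
        assert q_R_logpdf(0.9, 0.9, -0.9, 3.0) == -np.inf

    def test_sign_flip_symmetry(self, rng):
        """Simultaneous sign flips (xi12, xi13) -> (-xi12, -xi13) correspond
        to negating variable 1 and leave the density invariant."""
        for _ in range(20):
            x = rng.uniform(-0.5, 0.5, 3)
            a = rng.uniform(0, 10)
            assert q_R_logpdf(*x, a) == pytest.approx(
                q_R_logpdf(-x[0], -x[1], x[2], a), rel=1e-12
            )

    def test_sampler_shape_properties(self):
        R = sample_qR(3.51, 500, seed=0)
        np.testing.assert_allclose(R, np.transpose(R, (0, 2, 1)), atol=1e-12)
        np.testing.assert_allclose(np.einsum("nii->ni", R), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(R).min() > -1e-12

    @pytest.mark.parametrize("a", [2.51, 17.77])
    def test_offdiagonal_marginal_variance(self, a):
        R = sample_qR(a, 100_000, seed=1)
        offs = R[:, 0, 1]
        assert offs.var() == pytest.approx(q_rho_variance(a), rel=0.02)
        assert abs(offs.mean()) < 0.01

    def test_marginal_matches_q_rho_ks(self):
        """The off-diagonal marginal of the matrix sampler reproduces the
        scalar density (the submatrix-marginalization construction)."""
        a = 3.51
        R = sample_qR(a, 10_000, seed=2, method="mc")
        xs = np.linspace(-1, 1, 4001)
        cdf_grid = np.cumsum(q_rho_pdf(xs, a))
        cdf_grid /= cdf_grid[-1]
        stat = stats.kstest(R[:, 0, 2], lambda v: np.interp(v, xs, cdf_grid))
        assert stat.pvalue > 1e-3

    def test_independence_limit(self):
        R = sample_qR(1e4, 1000, seed=3)
        assert np.abs(R[:, 0, 1]).max() < 0.05
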