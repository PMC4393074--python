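"""Histogram-count moments: lemma formulas, mixtures, and aggregation."""

import itertools

import numpy as np
import pytest
from scipy.special import ndtr

from fdmoments.moments import (
    IndependentEnsemble,
    ParametricEnsemble,
    Q_R,
    Q_rho,
    aggregate,
    aggregate_bins,
    bin_covariance,
    bin_covariance_matrix,
    bin_mean,
    bin_third_moment,
)
from fdmoments.scores import HistogramSpec

SPEC = HistogramSpec()
PHI0 = 1.0 / np.sqrt(2 * np.pi)


def _phi(x):
    return np.exp(-0.5 * x**2) * PHI0


class TestBinMean:
    def test_zero_genes(self):
        assert bin_mean(0, SPEC, 10) == 0.0

    def test_near_origin_value(self):
        b = int(np.argmin(np.abs(SPEC.centers - 0.05)))
        assert bin_mean(3226, SPEC, b) == pytest.approx(
            3226 * 0.1 * _phi(0.05), rel=1e-12
        )

    def test_total_mass(self):
        total = sum(bin_mean(1000, SPEC, b) for b in range(SPEC.n_bins))
        # midpoint-rule sum over [-6, 6] of the unit normal
        assert total == pytest.approx(1000 * (ndtr(6) - ndtr(-6)), rel=1e-3)


class TestQrho:
    def test_independence_limit(self):
        assert Q_rho(0.0, 0.0, 1e7) == pytest.approx(1 / (2 * np.pi), rel=1e-4)

    def test_symmetries(self, rng):
        ens = ParametricEnsemble.from_alpha(3.51, "eq22")
        for _ in range(15):
            z1, z2 = rng.uniform(-3, 3, 2)
            q = ens.Q_rho(z1, z2)
            assert ens.Q_rho(z2, z1) == pytest.approx(q, rel=1e-12)
            assert ens.Q_rho(-z1, -z2) == pytest.approx(q, rel=1e-12)

    def test_against_xi_monte_carlo(self, rng):
        """Quadrature mixture vs brute-force sampling of xi ~ q_rho."""
        from fdmoments.corr_density import q_rho_pdf

        a = 3.51
        xs = np.linspace(-0.99999, 0.99999, 20001)
        cdf = np.cumsum(q_rho_pdf(xs, a))
        cdf /= cdf[-1]
        xi = np.interp(rng.random(1_000_000), cdf, xs)
        mc = np.mean(
            np.exp(-(0.0) / (2 * (1 - xi**2))) / (2 * np.pi * np.sqrt(1 - xi**2))
        )
        assert Q_rho(0.0, 0.0, a) == pytest.approx(mc, rel=1e-3)


class TestQR:
    def test_independence_limit(self):
        assert Q_R(0, 0, 0, 1e6, n_mc=4096, seed=0) == pytest.approx(
            PHI0**3, rel=1e-3
        )

    def test_permutation_invariance_symmetrized(self):
        ens = ParametricEnsemble.from_alpha(3.51, "eq22", n_mc=4096, seed=1)
        sym = ens.symmetrized()
        z = (-2.55, 0.5, 1.1)
        vals = [sym.Q_R(*perm) for perm in itertools.permutations(z)]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-10)

    def test_seed_self_consistency(self):
        v1 = Q_R(0, 0, 0, 3.51, n_mc=100_000, seed=1)
        v2 = Q_R(0, 0, 0, 3.51, n_mc=100_000, seed=2)
        assert v1 == pytest.approx(v2, rel=5e-3)


class TestBinCovariance:
    def test_multinomial_limits(self):
        """Independence reduces the lemma covariance to multinomial moments
        exactly -- in particular variances are nonnegative (the sign of the
        Kronecker term)."""
        ind = IndependentEnsemble()
        G = 500
        b1 = 10
        b2 = 40
        p1 = 0.1 * _phi(SPEC.centers[b1])
        p2 = 0.1 * _phi(SPEC.centers[b2])
        assert bin_covariance(G, SPEC, ind, b1, b2) == pytest.approx(
            -G * p1 * p2, rel=1e-12
        )
        assert bin_covariance(G, SPEC, ind, b1, b1) == pytest.approx(
            G * p1 * (1 - p1), rel=1e-12
        )

    def test_full_matrix_psd_brca_configuration(self):
        ens = ParametricEnsemble.from_alpha(17.77, "eq22")
        bins = np.concatenate([SPEC.tail_bins(), SPEC.center_bins()])
        cov = bin_covariance_matrix(3226, SPEC, ens, bins)
        np.testing.assert_allclose(cov, cov.T, atol=1e-8)
        assert np.linalg.eigvalsh(cov).min() >= -1e-8 * np.trace(cov)


def _multinomial_third_oracle(G, probs, idx):
    """Exhaustive enumeration of E[(Y_a - mu_a)(Y_b - mu_b)(Y_c - mu_c)] for
    G iid categorical draws (categories = bins + 'other')."""
    p_other = 1.0 - sum(probs)
    cats = list(range(len(probs))) + ["other"]
    pvec = list(probs) + [p_other]
    mu = [G * p for p in probs]
    total = 0.0
    for assign in itertools.product(range(len(cats)), repeat=G):
        prob = 1.0
        counts = [0] * len(probs)
        for a in assign:
            prob *= pvec[a]
            if cats[a] != "other":
                counts[a] += 1
        total += prob * np.prod([counts[i] - mu[i] for i in idx])
    return total


class TestBinThirdMoment:
    def test_diagonal_matches_closed_form(self):
        ind = IndependentEnsemble()
        G, b = 200, 12
        p = 0.1 * _phi(SPEC.centers[b])
        assert bin_third_moment(G, SPEC, ind, b, b, b) == pytest.approx(
            G * p * (1 - p) * (1 - 2 * p), rel=1e-10
        )

    @pytest.mark.parametrize("idx", [(0, 0, 0), (0, 0, 1), (0, 1, 2), (0, 1, 1)])
    def test_exhaustive_enumeration_oracle(self, idx):
        """Independence limit vs exhaustive multinomial enumeration at G = 5:
        validates the Kronecker pairing of the triple-product expansion."""
        ind = IndependentEnsemble()
        G = 5
        bins = [20, 60, 90]  # three distinct bins of the default spec
        probs = [0.1 * _phi(SPEC.centers[b]) for b in bins]
        oracle = _multinomial_third_oracle(G, probs, idx)
        ours = bin_third_moment(G, SPEC, ind, bins[idx[0]], bins[idx[1]], bins[idx[2]])
        assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_permutation_symmetry(self, rng):
        ens = ParametricEnsemble.from_alpha(5.0, "eq22", n_mc=2048, seed=0).symmetrized()
        bins = rng.choice(SPEC.n_bins, size=3, replace=False)
        vals = [
            bin_third_moment(100, SPEC, ens, *perm)
            for perm in itertools.permutations(bins)
        ]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-8)


class TestAggregate:
    def test_mean_path_naive_estimates(self):
        ind = IndependentEnsemble()
        ms = aggregate(3226, SPEC, ind, order=2)
        assert round(ms.mu_F) == 20
        spec2 = HistogramSpec(delta_tail=-2.0)
        assert round(aggregate(3226, spec2, ind, order=2).mu_F) == 73

    def test_independence_is_multinomial(self):
        ind = IndependentEnsemble()
        G = 1000
        ms = aggregate(G, SPEC, ind, order=3)
        pF = ndtr(-2.5)
        pC = ndtr(1.0) - ndtr(-1.0)
        assert ms.var_F == pytest.approx(G * pF * (1 - pF), rel=1e-9)
        assert ms.cov_FC == pytest.approx(-G * pF * pC, rel=1e-9)
        assert ms.gamma_FFF == pytest.approx(
            G * pF * (1 - pF) * (1 - 2 * pF), rel=1e-9
        )

    def test_bin_sum_agrees_with_region_path(self):
        ens = ParametricEnsemble.from_alpha(17.77, "eq22", n_mc=4096, seed=3)
        reg = aggregate(3226, SPEC, ens, order=2)
        bins = aggregate_bins(3226, SPEC, ens, order=2)
        for name in ("mu_F", "mu_C", "var_F", "var_C", "cov_FC"):
            assert getattr(bins, name) == pytest.approx(
                getattr(reg, name), rel=0.01
            )

    def test_var_F_monotone_in_correlation_spread(self):
        """Heavier intergene correlation (smaller alpha) inflates Var(F)."""
        G = 3226
        prev = aggregate(G, SPEC, IndependentEnsemble(), order=2).var_F
        for alpha in (40.0, 17.77, 8.0, 4.0):
            cur = aggregate(
                G, SPEC, ParametricEnsemble.from_alpha(alpha, "eq22"), order=2
            ).var_F
            assert cur > prev
            prev = cur

    def test_provenance_and_validation(self):
        ms = aggregate(100, SPEC, IndependentEnsemble(), order=2)
        assert ms.provenance["G"] == 100
        assert abs(ms.correlation) < 1
        ms.validate()
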