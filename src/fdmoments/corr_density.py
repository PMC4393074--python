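"""Empirical correlation densities and the omnibus shape parameter alpha.

The whole dependence structure of the z scores is summarized by a single
parameter.  Pairwise sample correlations of the standardized residual rows
are Fisher-transformed, their variance is corrected for sampling noise
(deconvolution of the known Fisher sampling distribution), mapped back to
the correlation scale, and matched to the one-parameter Beta-type family

    q_rho(xi) proportional to (1 - xi^2)^a  on [-1, 1].

A consistent density over 3x3 correlation matrices, q_R, is induced by
embedding q_rho as the pairwise marginal of a rescaled inverse-Wishart
draw: if Sigma ~ W^{-1}(I, nu) then every correlation submatrix of the
corresponding correlation matrix has the same Beta-type marginals, with
nu tied to the exponent by nu_3 = 2a + 4 for the 3x3 case.

Two parameter conventions are supported (the source formulas are off by one
in the Beta shape):

* ``"eq22"`` (default, literal): exponent a = alpha, with alpha estimated
  from the variance as alpha = (1 - sigma^2) / (2 sigma^2).
* ``"eq24"`` (variance-consistent): exponent a = alpha - 1, so that the
  fitted density's variance 1/(2a+3) equals the estimated sigma^2 = 1/(2 alpha + 1)
  exactly.

The discrepancy is O(1/alpha); the literal convention reproduces the
reference downstream moment values and is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from scipy.stats import qmc

from .panels import ResidualPanel

__all__ = [
    "CorrelationSample",
    "CorrelationDensityModel",
    "fisher",
    "fisher_inv",
    "pairwise_correlations",
    "sampling_variance",
    "denoise_tau_variance",
    "rho_scale_variance",
    "alpha_from_variance",
    "exponent_from_alpha",
    "q_rho_pdf",
    "q_rho_variance",
    "q_rho_quadrature",
    "q_R_logpdf",
    "normalize_qR",
    "sample_qR",
    "estimate_alpha",
]

CONVENTIONS = ("eq22", "eq24")


# ---------------------------------------------------------------------------
# Fisher transform and the correlation sample


def fisher(rho):
    """Fisher transform tau = atanh(rho) = 0.5 log((1+rho)/(1-rho))."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("|rho| must be < 1 for the Fisher transform")
    out = np.arctanh(rho)
    return out if out.ndim else float(out)


def fisher_inv(tau):
    """Inverse Fisher transform rho = tanh(tau)."""
    out = np.tanh(np.asarray(tau, dtype=float))
    return out if out.ndim else float(out)


@dataclass
class CorrelationSample:
    """Pairwise sample correlations of residual rows and their Fisher values."""

    rho_bar: np.ndarray
    tau_bar: np.ndarray
    m_eff: int
    n_pairs_total: int
    n_excluded: int = 0

    @property
    def n_pairs(self) -> int:
        return self.rho_bar.size


def pairwise_correlations(
    res: ResidualPanel,
    max_pairs: int = 500_000,
    seed: int | None = None,
) -> CorrelationSample:
    """Sample correlations for all gene pairs, or a uniform random subsample.

    The effective per-correlation sample size is m_eff = M - K (K = 2 group
    means removed per row).  Pairs with degenerate correlation (|rho| >= 1,
    arising from duplicated or proportional rows) and zero-variance rows are
    excluded with a warning.
    """
    if res.effective_df < 5:
        raise ValueError("need effective df >= 5 for a usable correlation sample")
    X = res.values - res.values.mean(axis=1, keepdims=True)
    norms = np.sqrt((X * X).sum(axis=1))
    ok_rows = norms > 0
    n_bad_rows = int((~ok_rows).sum())
    if n_bad_rows:
        warnings.warn(f"excluding {n_bad_rows} zero-variance residual row(s)")
    X = X[ok_rows] / norms[ok_rows, None]
    G = X.shape[0]
    total = G * (G - 1) // 2
    if total <= max_pairs:
        iu, ju = np.triu_indices(G, k=1)
    else:
        rng = np.random.default_rng(seed)
        # uniform pair sampling without replacement (oversample + dedupe)
        want = max_pairs
        pairs = set()
        while len(pairs) < want:
            a = rng.integers(0, G, size=2 * (want - len(pairs)))
            b = rng.integers(0, G, size=a.size)
            for i, j in zip(a, b):
                if i != j:
                    pairs.add((min(i, j), max(i, j)))
                    if len(pairs) >= want:
                        break
        idx = np.array(sorted(pairs))
        iu, ju = idx[:, 0], idx[:, 1]
    rho = np.einsum("ij,ij->i", X[iu], X[ju])
    keep = np.abs(rho) < 1 - 1e-12
    n_excl = int((~keep).sum())
    if n_excl:
        warnings.warn(
            f"excluding {n_excl} degenerate pair correlation(s) with |rho| >= 1"
        )
    rho = rho[keep]
    m_eff = res.effective_df  # M - K
    return CorrelationSample(
        rho_bar=rho,
        tau_bar=np.arctanh(rho),
        m_eff=m_eff,
        n_pairs_total=total,
        n_excluded=n_excl + n_bad_rows,
    )


def sampling_variance(m_eff: int, G: int | None = None, rule="auto") -> float:
    """Fisher-scale sampling variance of a null residual-pair correlation.

    Residual rows with m_eff = M - K degrees of freedom behave like
    uncentered spherical m_eff-vectors, for which var(atanh rho_bar) is
    1/(m_eff - 2) under the null ("auto", the calibrated default).  The
    classical textbook constants are available by name, and any float is
    accepted for explicit control.
    """
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        return float(rule)
    if rule == "auto":
        d = m_eff - 2
    elif rule == "mk1":
        d = m_eff - 1
    elif rule == "m3":
        d = m_eff + 2 - 3  # 1/(M-3) with M = m_eff + K, K = 2
    elif rule == "g3":
        if G is None:
            raise ValueError("rule 'g3' needs the gene count G")
        d = G - 3
    else:
        raise ValueError(f"unknown fisher-variance rule {rule!r}")
    if d <= 0:
        raise ValueError(f"sampling-variance denominator {d} <= 0 (m_eff={m_eff})")
    return 1.0 / d


def denoise_tau_variance(
    sample: CorrelationSample,
    fisher_var="auto",
    G: int | None = None,
) -> tuple[float, float]:
    """Deconvolve the sampling noise from the Fisher-scale variance.

    Returns ``(sigma2_raw, sigma2_denoised)``.  The zero-mean normal fit is
    by method of moments (second moment about zero); the tau mean is a
    diagnostic, not subtracted, because column standardization already
    forces the correlation sum toward zero.
    """
    sigma2_raw = float(np.mean(sample.tau_bar**2))
    noise = sampling_variance(sample.m_eff, G=G, rule=fisher_var)
    sigma2 = sigma2_raw - noise
    if sigma2 <= 0:
        raise ValueError(
            "denoised Fisher variance is nonpositive "
            f"({sigma2_raw:.4g} - {noise:.4g}); no detectable correlation signal. "
            "Use more pairs, or fall back to independence (alpha -> infinity)."
        )
    return sigma2_raw, sigma2


_HERMITE_NODES, _HERMITE_W = special.roots_hermitenorm(96)
_HERMITE_W = _HERMITE_W / np.sqrt(2 * np.pi)


def rho_scale_variance(sigma2_tau: float) -> float:
    """Map a Fisher-scale variance back to the correlation scale.

    sigma2_rho = E[tanh(xi)^2] for xi ~ N(0, sigma2_tau), by Gauss-Hermite
    quadrature (the mean is zero by symmetry).  Always strictly below
    sigma2_tau since |tanh xi| < |xi|.
    """
    if sigma2_tau <= 0:
        raise ValueError("sigma2_tau must be positive")
    s = np.sqrt(sigma2_tau)
    return float(np.sum(_HERMITE_W * np.tanh(s * _HERMITE_NODES) ** 2))


def alpha_from_variance(sigma2_rho: float, convention: str = "eq22") -> float:
    """Omnibus parameter from the correlation-scale variance.

    alpha = (1 - sigma^2) / (2 sigma^2), equivalently sigma^2 = 1/(2 alpha + 1).
    """
    if not 0 < sigma2_rho <= 1:
        raise ValueError("sigma2_rho must be in (0, 1]")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    return (1.0 - sigma2_rho) / (2.0 * sigma2_rho)


def exponent_from_alpha(alpha: float, convention: str = "eq22") -> float:
    """Shape exponent a of (1 - xi^2)^a for a given alpha and convention."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if convention == "eq22":
        return float(alpha)
    if convention == "eq24":
        a = alpha - 1.0
        if a < 0:
            raise ValueError("eq24 convention needs alpha >= 1")
        return a
    raise ValueError(f"convention must be one of {CONVENTIONS}")


# ---------------------------------------------------------------------------
# The scalar density q_rho


def q_rho_pdf(xi, shape: float):
    """Normalized density proportional to (1 - xi^2)^shape on [-1, 1].

    ``shape`` is the exponent a (see the module docstring for its relation
    to alpha under the two conventions).  shape = 0 gives the uniform 1/2.
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(np.abs(xi) > 1):
        raise ValueError("|xi| must be <= 1")
    if shape < 0:
        raise ValueError("shape exponent must be nonnegative")
    log_norm = special.betaln(shape + 1, shape + 1) + (2 * shape + 1) * np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        core = shape * np.log1p(-(xi**2))
    core = np.where(np.abs(xi) == 1.0, 0.0 if shape == 0 else -np.inf, core)
    out = np.exp(core - log_norm)
    return out if out.ndim else float(out)


def q_rho_variance(shape: float) -> float:
    """Variance of q_rho: 1 / (2 shape + 3)."""
    return 1.0 / (2.0 * shape + 3.0)


def q_rho_quadrature(shape: float, n: int = 96) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Jacobi nodes and normalized weights for E_q[f(xi)].

    Exact for polynomial f up to degree 2n-1; the weight function is the
    density itself, so sum(w) = 1.  For extreme shapes (where the Jacobi
    recurrence loses accuracy) the density is within O(1/shape) of a normal
    with variance 1/(2 shape + 3), and Gauss-Hermite nodes are used instead.
    """
    if shape > 200:
        h, w = special.roots_hermitenorm(n)
        x = np.clip(h * np.sqrt(q_rho_variance(shape)), -1 + 1e-12, 1 - 1e-12)
        return x, w / w.sum()
    x, w = special.roots_jacobi(n, shape, shape)
    return x, w / w.sum()


# ---------------------------------------------------------------------------
# The 3x3 correlation-matrix density q_R


def _qR_log_unnorm(x12, x13, x23, shape: float):
    det = 1.0 - x12**2 - x13**2 - x23**2 + 2.0 * x12 * x13 * x23
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            det > 0,
            (2 * shape + 2) * np.log(np.maximum(det, 1e-300))
            - (shape + 2)
            * (np.log1p(-x12**2) + np.log1p(-x13**2) + np.log1p(-x23**2)),
            -np.inf,
        )
    return out


_QR_NORM_CACHE: dict[float, float] = {}


def normalize_qR(shape: float, n_points: int = 2**18) -> float:
    """Normalization constant of q_R over the PSD subset of [-1,1]^3.

    Quasi-Monte-Carlo (Sobol) integration, cached per shape.  Only needed
    for density evaluation; the sampler is normalization-free.
    """
    key = round(float(shape), 10)
    if key in _QR_NORM_CACHE:
        return _QR_NORM_CACHE[key]
    sob = qmc.Sobol(d=3, scramble=False)
    u = sob.random(n_points)
    x = 2.0 * u - 1.0
    vals = np.exp(_qR_log_unnorm(x[:, 0], x[:, 1], x[:, 2], shape))
    const = 8.0 * float(np.mean(vals))  # cube volume times mean integrand
    _QR_NORM_CACHE[key] = const
    return const


def q_R_logpdf(xi12, xi13, xi23, shape: float, normalized: bool = False):
    """Log density of a 3x3 correlation matrix with off-diagonals (xi12, xi13, xi23).

    Outside the positive-definite region the log density is -inf.  With
    ``normalized=True`` the cached quasi-MC constant is subtracted.
    """
    if shape < 0:
        raise ValueError("shape exponent must be nonnegative")
    xi12 = np.asarray(xi12, dtype=float)
    xi13 = np.asarray(xi13, dtype=float)
    xi23 = np.asarray(xi23, dtype=float)
    out = _qR_log_unnorm(xi12, xi13, xi23, shape)
    if normalized:
        out = out - np.log(normalize_qR(shape))
    return out if out.ndim else float(out)


def sample_qR(shape: float, n: int, seed=None, method: str = "qmc") -> np.ndarray:
    """Draw n 3x3 correlation matrices from q_R.

    Draws Sigma ~ inverse-Wishart(I, nu_3) with nu_3 = 2*shape + 4 and
    rescales each draw to a correlation matrix (separation into variances
    and normalized covariances).  Output shape (n, 3, 3), symmetric with
    unit diagonal.

    The default driver is a scrambled-Sobol quasi-Monte-Carlo stream pushed
    through the Bartlett decomposition (three chi-square diagonals, three
    normal subdiagonals).  Each point is still exactly q_R-distributed, but
    mixture integrals over the sample converge far faster than at the
    1/sqrt(n) Monte-Carlo rate -- essential because third central moments
    of the counts are near-cancelling differences of large terms.  Set
    ``method="mc"`` for plain pseudo-random draws.
    """
    if shape < 0:
        raise ValueError("shape exponent must be nonnegative")
    nu3 = 2.0 * shape + 4.0
    if method == "qmc":
        eng = qmc.Sobol(d=6, scramble=True, seed=seed)
        m = 1 << max(0, int(np.ceil(np.log2(max(n, 1)))))  # power of 2 keeps balance
        u = np.clip(eng.random(m)[:n], 1e-15, 1.0 - 1e-15)
        z = special.ndtri(u[:, :3])
        chi = np.column_stack(
            [stats.chi2.ppf(u[:, 3 + i], df=nu3 - i) for i in range(3)]
        )
    elif method == "mc":
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, 3))
        chi = np.column_stack(
            [rng.chisquare(nu3 - i, size=n) for i in range(3)]
        )
    else:
        raise ValueError("method must be 'qmc' or 'mc'")
    # Bartlett: W = A A^T ~ Wishart(nu_3, I); Sigma = W^{-1} ~ invW(I, nu_3)
    A = np.zeros((n, 3, 3))
    A[:, 0, 0] = np.sqrt(chi[:, 0])
    A[:, 1, 1] = np.sqrt(chi[:, 1])
    A[:, 2, 2] = np.sqrt(chi[:, 2])
    A[:, 1, 0] = z[:, 0]
    A[:, 2, 0] = z[:, 1]
    A[:, 2, 1] = z[:, 2]
    W = A @ np.transpose(A, (0, 2, 1))
    sig = np.linalg.inv(W)
    d = np.sqrt(np.einsum("nii->ni", sig))
    R = sig / (d[:, :, None] * d[:, None, :])
    # enforce exact symmetry/unit diagonal against float round-off
    R = 0.5 * (R + np.transpose(R, (0, 2, 1)))
    idx = np.arange(3)
    R[:, idx, idx] = 1.0
    return R


# ---------------------------------------------------------------------------
# Model object


@dataclass
class CorrelationDensityModel:
    """Fitted one-parameter correlation density.

    Carries the estimated (or imposed) alpha, the convention that maps it to
    the density exponent, and the intermediate variances of the estimation
    path (Fisher-scale raw and denoised, correlation-scale).
    """

    alpha: float
    convention: str = "eq22"
    sigma2_tau_raw: float | None = None
    sigma2_tau_denoised: float | None = None
    sigma2_rho: float | None = None
    m_eff: int | None = None
    n_pairs: int | None = None
    tau_mean: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"convention must be one of {CONVENTIONS}")

    @property
    def exponent(self) -> float:
        return exponent_from_alpha(self.alpha, self.convention)

    def pdf(self, xi):
        return q_rho_pdf(xi, self.exponent)

    def quadrature(self, n: int = 96):
        return q_rho_quadrature(self.exponent, n)

    def sample_matrices(self, n: int, seed=None) -> np.ndarray:
        return sample_qR(self.exponent, n, seed=seed)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "convention": self.convention,
            "exponent": self.exponent,
            "sigma2_tau_raw": self.sigma2_tau_raw,
            "sigma2_tau_denoised": self.sigma2_tau_denoised,
            "sigma2_rho": self.sigma2_rho,
            "m_eff": self.m_eff,
            "n_pairs": self.n_pairs,
            "tau_mean": self.tau_mean,
        }


def estimate_alpha(
    res: ResidualPanel,
    max_pairs: int = 500_000,
    seed: int | None = None,
    fisher_var="auto",
    convention: str = "eq22",
) -> CorrelationDensityModel:
    """Full estimation path: correlations -> Fisher -> deconvolve -> alpha."""
    sample = pairwise_correlations(res, max_pairs=max_pairs, seed=seed)
    s2_raw, s2_den = denoise_tau_variance(
        sample, fisher_var=fisher_var, G=res.n_genes
    )
    s2_rho = rho_scale_variance(s2_den)
    alpha = alpha_from_variance(s2_rho, convention)
    return CorrelationDensityModel(
        alpha=alpha,
        convention=convention,
        sigma2_tau_raw=s2_raw,
        sigma2_tau_denoised=s2_den,
        sigma2_rho=s2_rho,
        m_eff=sample.m_eff,
        n_pairs=sample.n_pairs,
        tau_mean=float(sample.tau_bar.mean()),
    )
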