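"""Moments of the z-histogram counts and of the pair (F, C).

Under joint (to third order) normality of the z scores, the mean, covariance
and third central moments of histogram bin counts are mixtures of bivariate
and trivariate normal probabilities over the empirical correlation densities:

    mu(Y_b)        ~= G Delta phi(z_b)
    phi(Y_b,Y_b')  ~= G(G-1) Delta^2 Q_rho(z_b, z_b') + delta_bb' mu_b - mu_b mu_b'
    gamma(...)     ~= third-order analogue built from Q_R and Q_rho

where Q_rho mixes the bivariate normal density over the scalar correlation
density q_rho, and Q_R mixes the trivariate density over the 3x3 matrix
density q_R.  Region-level moments of the tail count F and center count C
are obtained either by summing bin moments (the literal, testing path) or,
preferably, by replacing bin products with exact normal box probabilities
over the tail and center intervals (no truncation, no midpoint error).

Note the Kronecker-delta term in the covariance enters with a PLUS sign:
the same-gene term of the exact expansion adds delta_bb' mu_b, which is the
only sign consistent with nonnegative variances in the independence limit
(where the formulas reduce exactly to multinomial moments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .corr_density import (
    CorrelationDensityModel,
    exponent_from_alpha,
    q_rho_quadrature,
    sample_qR,
)
from .scores import HistogramSpec

__all__ = [
    "CountMomentSet",
    "CorrelationEnsemble",
    "ParametricEnsemble",
    "IndependentEnsemble",
    "PluginEnsemble",
    "bin_mean",
    "Q_rho",
    "Q_R",
    "bin_covariance",
    "bin_covariance_matrix",
    "bin_third_moment",
    "aggregate",
    "aggregate_bins",
    "bvn_box",
    "tvn_box",
]

_CLIP = 8.5  # |z| beyond which unit-normal mass (~1e-17) is ignored in quadrature
_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(x):
    return np.exp(-0.5 * np.asarray(x) ** 2) / _SQRT2PI


def _gl_nodes(lo: float, hi: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    lo = max(lo, -_CLIP)
    hi = min(hi, _CLIP)
    x, w = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (hi - lo)
    return half * x + 0.5 * (hi + lo), half * w


def _interval_prob(iv: tuple[float, float]) -> float:
    lo, hi = iv
    return float(ndtr(hi) - (0.0 if np.isinf(lo) else ndtr(lo)))


# ---------------------------------------------------------------------------
# Normal box probabilities, vectorized over the correlation parameter(s)


def bvn_box(A, B, rho, n_nodes: int = 48) -> np.ndarray:
    """P(z1 in A, z2 in B | corr rho) for standard bivariate normal (z1, z2).

    ``rho`` may be an array; intervals may be semi-infinite.  Computed by
    Gauss-Legendre quadrature over A of phi(t) times the conditional normal
    probability of B.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    t, wt = _gl_nodes(A[0], A[1], n_nodes)
    s = np.sqrt(np.maximum(1.0 - rho**2, 1e-14))[:, None]
    r = rho[:, None]
    blo, bhi = B
    hi_term = ndtr((min(bhi, _CLIP) - r * t) / s) if not np.isinf(bhi) else 1.0
    lo_term = ndtr((max(blo, -_CLIP) - r * t) / s) if not np.isinf(blo) else 0.0
    inner = hi_term - lo_term
    return (inner * (_phi(t) * wt)).sum(axis=1)


def tvn_box(A, B, D, R, n_nodes: int = 32, chunk: int = 4096) -> np.ndarray:
    """P(z1 in A, z2 in B, z3 in D | corr matrix R) for each R in a stack.

    ``R`` has shape (n, 3, 3).  Double Gauss-Legendre quadrature over A and B
    with the conditional normal CDF over D; vectorized over the matrix stack
    in chunks to bound memory.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim == 2:
        R = R[None]
    t, wt = _gl_nodes(A[0], A[1], n_nodes)
    u, wu = _gl_nodes(B[0], B[1], n_nodes)
    dlo, dhi = D
    out = np.empty(R.shape[0])
    wt_phi = wt * _phi(t)
    for start in range(0, R.shape[0], chunk):
        r = R[start : start + chunk]
        r12, r13, r23 = r[:, 0, 1], r[:, 0, 2], r[:, 1, 2]
        den = np.maximum(1.0 - r12**2, 1e-14)
        s2 = np.sqrt(den)
        b1 = (r13 - r12 * r23) / den
        b2 = (r23 - r12 * r13) / den
        v3 = 1.0 - (r13**2 + r23**2 - 2.0 * r12 * r13 * r23) / den
        s3 = np.sqrt(np.maximum(v3, 1e-14))
        # (nc, nt, nu) arrays
        tt = t[None, :, None]
        uu = u[None, None, :]
        cond2 = _phi((uu - r12[:, None, None] * tt) / s2[:, None, None]) / s2[:, None, None]
        m3 = b1[:, None, None] * tt + b2[:, None, None] * uu
        s3n = s3[:, None, None]
        inner = (ndtr((dhi - m3) / s3n) if not np.isinf(dhi) else 1.0) - (
            ndtr((dlo - m3) / s3n) if not np.isinf(dlo) else 0.0
        )
        out[start : start + chunk] = np.einsum(
            "t,u,ctu->c", wt_phi, wu, cond2 * inner
        )
    return out


def _n2_pdf(z1, z2, rho):
    s2 = np.maximum(1.0 - rho**2, 1e-14)
    q = (z1**2 - 2.0 * rho * z1 * z2 + z2**2) / s2
    return np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(s2))


def _n3_pdf(z, R):
    """Trivariate normal pdf at z (len 3) for each correlation matrix in R."""
    z1, z2, z3 = z
    r12, r13, r23 = R[:, 0, 1], R[:, 0, 2], R[:, 1, 2]
    det = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    det = np.maximum(det, 1e-14)
    q = (
        z1 * z1 * (1.0 - r23**2)
        + z2 * z2 * (1.0 - r13**2)
        + z3 * z3 * (1.0 - r12**2)
        + 2.0 * z1 * z2 * (r13 * r23 - r12)
        + 2.0 * z1 * z3 * (r12 * r23 - r13)
        + 2.0 * z2 * z3 * (r12 * r13 - r23)
    ) / det
    return np.exp(-0.5 * q) / ((2.0 * np.pi) ** 1.5 * np.sqrt(det))


# ---------------------------------------------------------------------------
# Correlation ensembles: how pair/triplet expectations are evaluated


class CorrelationEnsemble:
    """Interface for expectations over the correlation densities.

    Subclasses provide E_xi[.] over the scalar density (pairs) and E_Xi[.]
    over the 3x3 matrix density (triplets).
    """

    def pair_box(self, A, B) -> float:
        raise NotImplementedError

    def triplet_box(self, A, B, D) -> float:
        raise NotImplementedError

    def Q_rho(self, z1, z2):
        raise NotImplementedError

    def Q_R(self, z1, z2, z3) -> float:
        raise NotImplementedError


class ParametricEnsemble(CorrelationEnsemble):
    """One-parameter ensemble: Gauss-Jacobi over q_rho, shared seeded q_R sample.

    The q_R Monte-Carlo sample is drawn once at construction and reused for
    every triplet evaluation in a run (variance reduction across regions and
    reproducibility).
    """

    def __init__(self, model, n_mc: int = 50_000, seed=None, n_quad: int = 96):
        if isinstance(model, CorrelationDensityModel):
            self.shape = model.exponent
        else:
            self.shape = float(model)  # a bare exponent
        if self.shape < 0:
            raise ValueError("shape exponent must be nonnegative")
        self.n_mc = int(n_mc)
        self.seed = seed
        self._xi, self._w = q_rho_quadrature(self.shape, n_quad)
        self._R: np.ndarray | None = None

    @classmethod
    def from_alpha(cls, alpha: float, convention: str = "eq22", **kw):
        return cls(exponent_from_alpha(alpha, convention), **kw)

    @property
    def matrices(self) -> np.ndarray:
        if self._R is None:
            self._R = sample_qR(self.shape, self.n_mc, seed=self.seed)
        return self._R

    def symmetrized(self) -> "ParametricEnsemble":
        """Expand the shared sample by all index permutations (exact
        exchangeability of triplet evaluations)."""
        out = ParametricEnsemble(self.shape, self.n_mc, self.seed)
        R = self.matrices
        perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
        out._R = np.concatenate([R[:, p, :][:, :, p] for p in perms])
        return out

    def pair_box(self, A, B) -> float:
        return float(np.sum(self._w * bvn_box(A, B, self._xi)))

    def triplet_box(self, A, B, D) -> float:
        return float(np.mean(tvn_box(A, B, D, self.matrices)))

    def Q_rho(self, z1, z2):
        z1 = np.asarray(z1, dtype=float)[..., None]
        z2 = np.asarray(z2, dtype=float)[..., None]
        out = np.sum(self._w * _n2_pdf(z1, z2, self._xi), axis=-1)
        return out if out.ndim else float(out)

    def Q_R(self, z1, z2, z3) -> float:
        return float(np.mean(_n3_pdf((z1, z2, z3), self.matrices)))


class IndependentEnsemble(CorrelationEnsemble):
    """alpha -> infinity limit: all correlations are zero (analytic)."""

    shape = np.inf

    def pair_box(self, A, B) -> float:
        return _interval_prob(A) * _interval_prob(B)

    def triplet_box(self, A, B, D) -> float:
        return _interval_prob(A) * _interval_prob(B) * _interval_prob(D)

    def Q_rho(self, z1, z2):
        out = _phi(np.asarray(z1, dtype=float)) * _phi(z2)
        return out if np.ndim(out) else float(out)

    def Q_R(self, z1, z2, z3) -> float:
        return float(_phi(z1) * _phi(z2) * _phi(z3))


class PluginEnsemble(CorrelationEnsemble):
    """Exact empirical ensemble: explicit pairwise correlations and triplet
    correlation matrices (e.g. read off a known G x G correlation matrix).

    With ``symmetrize=True`` each matrix is expanded by all 6 simultaneous
    row/column permutations, which makes triplet expectations invariant to
    the slot assignment of genes to the three region arguments.
    """

    def __init__(self, rhos, matrices, symmetrize: bool = True):
        self.rhos = np.asarray(rhos, dtype=float)
        R = np.asarray(matrices, dtype=float)
        if symmetrize:
            perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
            R = np.concatenate([R[:, p, :][:, :, p] for p in perms])
        self.matrices = R

    @classmethod
    def from_correlation_matrix(cls, Sigma) -> "PluginEnsemble":
        Sigma = np.asarray(Sigma, dtype=float)
        G = Sigma.shape[0]
        iu, ju = np.triu_indices(G, k=1)
        rhos = Sigma[iu, ju]
        trips = []
        for i in range(G - 2):
            for j in range(i + 1, G - 1):
                for k in range(j + 1, G):
                    idx = np.array([i, j, k])
                    trips.append(Sigma[np.ix_(idx, idx)])
        return cls(rhos, np.array(trips), symmetrize=True)

    def pair_box(self, A, B) -> float:
        return float(np.mean(bvn_box(A, B, self.rhos)))

    def triplet_box(self, A, B, D) -> float:
        return float(np.mean(tvn_box(A, B, D, self.matrices)))

    def Q_rho(self, z1, z2):
        z1 = np.asarray(z1, dtype=float)[..., None]
        z2 = np.asarray(z2, dtype=float)[..., None]
        out = np.mean(_n2_pdf(z1, z2, self.rhos), axis=-1)
        return out if out.ndim else float(out)

    def Q_R(self, z1, z2, z3) -> float:
        return float(np.mean(_n3_pdf((z1, z2, z3), self.matrices)))


# ---------------------------------------------------------------------------
# Lemma-literal bin-level moments (spec ops; used for testing and diagnostics)


def bin_mean(G: int, spec: HistogramSpec, b: int) -> float:
    """Expected count of bin b under the unit-normal null: G Delta phi(z_b)."""
    return float(G * spec.delta_bin * _phi(spec.centers[b]))


def Q_rho(z1, z2, alpha: float, convention: str = "eq22", n_quad: int = 96):
    """Mixture value integral q_rho(xi) N2(z1, z2; xi) dxi (Gauss-Jacobi)."""
    ens = ParametricEnsemble.from_alpha(alpha, convention, n_quad=n_quad)
    return ens.Q_rho(z1, z2)


def Q_R(z1, z2, z3, alpha: float, n_mc: int = 50_000, seed=None,
        convention: str = "eq22") -> float:
    """Monte-Carlo mixture integral q_R(Xi) N3(z; 0, Xi) dXi."""
    ens = ParametricEnsemble.from_alpha(alpha, convention, n_mc=n_mc, seed=seed)
    return ens.Q_R(z1, z2, z3)


def bin_covariance(
    G: int, spec: HistogramSpec, ensemble: CorrelationEnsemble, b: int, bp: int
) -> float:
    """Covariance of a histogram count pair (Y_b, Y_b')."""
    zb, zbp = spec.centers[b], spec.centers[bp]
    D = spec.delta_bin
    mu_b, mu_bp = bin_mean(G, spec, b), bin_mean(G, spec, bp)
    same = 1.0 if b == bp else 0.0
    return float(
        G * (G - 1) * D * D * ensemble.Q_rho(zb, zbp) + same * mu_b - mu_b * mu_bp
    )


def bin_covariance_matrix(
    G: int, spec: HistogramSpec, ensemble: CorrelationEnsemble, bins
) -> np.ndarray:
    """Full covariance matrix of the counts of the given bins (vectorized)."""
    bins = np.asarray(bins)
    z = spec.centers[bins]
    D = spec.delta_bin
    mu = G * D * _phi(z)
    Q = ensemble.Q_rho(z[:, None], z[None, :])
    return G * (G - 1) * D * D * Q + np.diag(mu) - np.outer(mu, mu)


def bin_third_moment(
    G: int,
    spec: HistogramSpec,
    ensemble: CorrelationEnsemble,
    b: int,
    bp: int,
    bpp: int,
) -> float:
    """Third central moment of the histogram count triplet (Y_b, Y_b', Y_b'').

    Expansion of the raw triple product into the all-distinct (Q_R), the
    three pair-coincidence (Q_rho, with Kronecker deltas pairing the two
    remaining distinct bins) and the triple-coincidence terms, followed by
    central-moment conversion.
    """
    z = spec.centers
    D = spec.delta_bin
    zb, zbp, zbpp = z[b], z[bp], z[bpp]
    G2 = G * (G - 1)
    G3 = G2 * (G - 2)
    mu_b, mu_bp, mu_bpp = (bin_mean(G, spec, i) for i in (b, bp, bpp))
    raw = G3 * D**3 * ensemble.Q_R(zb, zbp, zbpp)
    # pair coincidences: the two equal bins collapse; the surviving pair of
    # distinct gene indices carries the corresponding bivariate mixture
    if b == bp:
        raw += G2 * D * D * ensemble.Q_rho(zb, zbpp)
    if b == bpp:
        raw += G2 * D * D * ensemble.Q_rho(zb, zbp)
    if bp == bpp:
        raw += G2 * D * D * ensemble.Q_rho(zb, zbp)
    if b == bp == bpp:
        raw += mu_b
    cov = lambda i, j: bin_covariance(G, spec, ensemble, i, j)
    return float(
        raw
        - mu_b * mu_bp * mu_bpp
        - (mu_b * cov(bp, bpp) + mu_bp * cov(b, bpp) + mu_bpp * cov(b, bp))
    )


# ---------------------------------------------------------------------------
# Aggregation to the moments of (F, C)


@dataclass
class CountMomentSet:
    """First three central moments of the pair (F, C) with provenance."""

    mu_F: float
    mu_C: float
    var_F: float
    var_C: float
    cov_FC: float
    gamma_FFF: float | None = None
    gamma_FFC: float | None = None
    gamma_FCC: float | None = None
    gamma_CCC: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def order(self) -> int:
        return 2 if self.gamma_FFF is None else 3

    @property
    def correlation(self) -> float:
        return self.cov_FC / np.sqrt(self.var_F * self.var_C)

    def second_moment_matrix(self) -> np.ndarray:
        return np.array([[self.var_F, self.cov_FC], [self.cov_FC, self.var_C]])

    def validate(self) -> None:
        if self.var_F < 0 or self.var_C < 0:
            raise ValueError(
                f"negative variance in moment set (var_F={self.var_F:.4g}, "
                f"var_C={self.var_C:.4g}); try increasing n_mc"
            )
        if abs(self.cov_FC) > np.sqrt(self.var_F * self.var_C) * (1 + 1e-9):
            raise ValueError(
                "second-moment matrix is not PSD "
                f"(corr={self.correlation:.4f}); try increasing n_mc"
            )

    def to_dict(self) -> dict:
        d = {
            "mu_F": self.mu_F,
            "mu_C": self.mu_C,
            "var_F": self.var_F,
            "var_C": self.var_C,
            "cov_FC": self.cov_FC,
            "corr_FC": self.correlation,
        }
        if self.order == 3:
            d.update(
                gamma_FFF=self.gamma_FFF,
                gamma_FFC=self.gamma_FFC,
                gamma_FCC=self.gamma_FCC,
                gamma_CCC=self.gamma_CCC,
            )
        d["provenance"] = dict(self.provenance)
        return d


def _region_third(G, PA, E2, E3, regions):
    """Third central moment of (N_A, N_B, N_D) for equal-or-disjoint regions.

    PA maps region -> interval probability; E2/E3 map region tuples to the
    mixture box probabilities; ``regions`` is the (A, B, D) label triple.
    """
    A, B, D = regions
    G2 = G * (G - 1)
    G3 = G2 * (G - 2)
    mu = {r: G * PA[r] for r in PA}
    raw = G3 * E3[tuple(sorted((A, B, D)))]
    if A == B:
        raw += G2 * E2[tuple(sorted((A, D)))]
    if A == D:
        raw += G2 * E2[tuple(sorted((A, B)))]
    if B == D:
        raw += G2 * E2[tuple(sorted((A, B)))]
    if A == B == D:
        raw += G * PA[A]
    cov = {
        key: G2 * E2[key] + (G * PA[key[0]] if key[0] == key[1] else 0.0)
        - G * PA[key[0]] * G * PA[key[1]]
        for key in E2
    }
    c = lambda r, s: cov[tuple(sorted((r, s)))]
    return (
        raw
        - mu[A] * mu[B] * mu[D]
        - (mu[A] * c(B, D) + mu[B] * c(A, D) + mu[D] * c(A, B))
    )


def aggregate(
    G: int,
    spec: HistogramSpec,
    ensemble: CorrelationEnsemble,
    order: int = 3,
) -> CountMomentSet:
    """Region-level moments of (F, C) via exact normal box probabilities.

    The tail region is the untruncated semi-infinite interval, so no
    analytic remainder is needed (truncation only concerns the bin-sum
    testing path).  Raises if the resulting second-moment matrix is not PSD.
    """
    F = spec.tail_interval()
    C = spec.center_interval()
    iv = {"F": F, "C": C}
    PA = {r: _interval_prob(iv[r]) for r in iv}
    E2 = {
        ("F", "F"): ensemble.pair_box(F, F),
        ("C", "C"): ensemble.pair_box(C, C),
        ("C", "F"): ensemble.pair_box(F, C),
    }
    G2 = G * (G - 1)
    mu_F, mu_C = G * PA["F"], G * PA["C"]
    var_F = G2 * E2[("F", "F")] + mu_F - mu_F**2
    var_C = G2 * E2[("C", "C")] + mu_C - mu_C**2
    cov_FC = G2 * E2[("C", "F")] - mu_F * mu_C
    gammas = {}
    if order >= 3:
        E3 = {
            ("F", "F", "F"): ensemble.triplet_box(F, F, F),
            ("C", "F", "F"): ensemble.triplet_box(F, F, C),
            ("C", "C", "F"): ensemble.triplet_box(F, C, C),
            ("C", "C", "C"): ensemble.triplet_box(C, C, C),
        }
        gammas = {
            "gamma_FFF": _region_third(G, PA, E2, E3, ("F", "F", "F")),
            "gamma_FFC": _region_third(G, PA, E2, E3, ("F", "F", "C")),
            "gamma_FCC": _region_third(G, PA, E2, E3, ("F", "C", "C")),
            "gamma_CCC": _region_third(G, PA, E2, E3, ("C", "C", "C")),
        }
    ms = CountMomentSet(
        mu_F=float(mu_F),
        mu_C=float(mu_C),
        var_F=float(var_F),
        var_C=float(var_C),
        cov_FC=float(cov_FC),
        **{k: float(v) for k, v in gammas.items()},
        provenance={
            "G": G,
            "order": order,
            "path": "region",
            "shape": getattr(ensemble, "shape", None),
            "n_mc": getattr(ensemble, "n_mc", None),
            "seed": getattr(ensemble, "seed", None),
            "spec": {
                "delta_bin": spec.delta_bin,
                "c": spec.c,
                "delta_tail": spec.delta_tail,
                "tail_side": spec.tail_side,
            },
        },
    )
    ms.validate()
    return ms


def aggregate_bins(
    G: int,
    spec: HistogramSpec,
    ensemble: CorrelationEnsemble,
    order: int = 2,
) -> CountMomentSet:
    """Bin-sum aggregation path (lemma-literal; testing/diagnostics).

    Means get the analytic sub-z_min remainder G Phi(z_min); second and
    third moments are truncated at the binned range, and bin probabilities
    use the midpoint approximation Delta phi(z_b), so this path agrees with
    :func:`aggregate` only up to O(Delta^2) and the truncated tail mass.
    """
    tb = spec.tail_bins()
    cb = spec.center_bins()
    remainder = G * float(ndtr(spec.z_min)) if spec.tail_side == "left" else 0.0
    mu_F = sum(bin_mean(G, spec, b) for b in tb) + remainder
    mu_C = sum(bin_mean(G, spec, b) for b in cb)
    cov_tt = bin_covariance_matrix(G, spec, ensemble, tb)
    cov_cc = bin_covariance_matrix(G, spec, ensemble, cb)
    z = spec.centers
    D = spec.delta_bin
    mu_t = G * D * _phi(z[tb])
    mu_c = G * D * _phi(z[cb])
    Q_tc = ensemble.Q_rho(z[tb][:, None], z[cb][None, :])
    cov_tc = G * (G - 1) * D * D * Q_tc - np.outer(mu_t, mu_c)
    gammas = {}
    if order >= 3:
        g = {"FFF": 0.0, "FFC": 0.0, "FCC": 0.0, "CCC": 0.0}
        for key, (s1, s2, s3) in {
            "FFF": (tb, tb, tb),
            "FFC": (tb, tb, cb),
            "FCC": (tb, cb, cb),
            "CCC": (cb, cb, cb),
        }.items():
            tot = 0.0
            for b in s1:
                for bp in s2:
                    for bpp in s3:
                        tot += bin_third_moment(G, spec, ensemble, b, bp, bpp)
            g[key] = tot
        gammas = {f"gamma_{k}": v for k, v in g.items()}
    ms = CountMomentSet(
        mu_F=float(mu_F),
        mu_C=float(mu_C),
        var_F=float(cov_tt.sum()),
        var_C=float(cov_cc.sum()),
        cov_FC=float(cov_tc.sum()),
        **{k: float(v) for k, v in gammas.items()},
        provenance={"G": G, "order": order, "path": "bins"},
    )
    ms.validate()
    return ms
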