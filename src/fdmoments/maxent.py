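"""Maximum-entropy joint distribution of (F, C) and conditional inference.

Given the first two or three central moments of the tail count F and the
center count C, the least-informative joint distribution consistent with
them is the exponential-family density

    p(f, c) proportional to exp( sum_k lambda_k T_k(f~, c~) )

on a discrete mesh over the feasible domain {f >= 0, c >= 0, f + c <= G},
where the sufficient statistics T_k are the monomials of total degree <= 2
(5 constraints) or <= 3 (9 constraints) in mean/sd-normalized coordinates
(f~, c~).  The multipliers are found by minimizing the convex dual
(log-partition minus the target moments), whose gradient is exactly the
moment mismatch; a damped Newton iteration with the exact Hessian (the
covariance of the statistics) converges in a few tens of iterations.

The observable C then conditions the inference: p(F | C = C_obs) is a
renormalized mesh row, from which point estimates (posterior mean), central
quantile intervals, and exceedance probabilities P(F >= x | C) follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .moments import CountMomentSet, CorrelationEnsemble, aggregate
from .scores import HistogramSpec, ZScorePanel, observed_counts

__all__ = [
    "SupportMesh",
    "JointCountDistribution",
    "ConditionalF",
    "build_mesh",
    "fit_maxent",
    "conditional",
    "control_discoveries",
]


@dataclass(frozen=True)
class SupportMesh:
    """Equispaced (F, C) grids with the feasibility mask f + c <= G.

    Axis ranges cover mean +- k sd, clipped to [0, G]; each axis is affinely
    normalized ((x - mu) / sd) to keep the cubic statistics well conditioned.
    """

    f_grid: np.ndarray
    c_grid: np.ndarray
    G: int
    f_norm: tuple[float, float]  # (mu, sd) of the normalization map
    c_norm: tuple[float, float]

    @property
    def mask(self) -> np.ndarray:
        """Boolean (n_F, n_C) feasibility mask."""
        return (self.f_grid[:, None] + self.c_grid[None, :]) <= self.G

    @property
    def shape(self) -> tuple[int, int]:
        return self.f_grid.size, self.c_grid.size

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        mf, sf = self.f_norm
        mc, sc = self.c_norm
        return (self.f_grid - mf) / sf, (self.c_grid - mc) / sc


def build_mesh(
    moments: CountMomentSet,
    G: int,
    n_F: int = 100,
    n_C: int = 500,
    k: float = 6.0,
) -> SupportMesh:
    """Mesh covering mean +- k sd per axis, clipped to the domain.

    The default 100 x 500 resolution suffices at moderate correlation
    levels; heavy covariance may require refining (e.g. 400 x 2000).
    """
    sd_F = np.sqrt(moments.var_F)
    sd_C = np.sqrt(moments.var_C)
    if sd_F <= 0 or sd_C <= 0:
        raise ValueError("degenerate (zero-sd) axis; cannot build a mesh")
    f_lo = max(0.0, moments.mu_F - k * sd_F)
    f_hi = min(float(G), moments.mu_F + k * sd_F)
    c_lo = max(0.0, moments.mu_C - k * sd_C)
    c_hi = min(float(G), moments.mu_C + k * sd_C)
    mesh = SupportMesh(
        f_grid=np.linspace(f_lo, f_hi, n_F),
        c_grid=np.linspace(c_lo, c_hi, n_C),
        G=G,
        f_norm=(moments.mu_F, sd_F),
        c_norm=(moments.mu_C, sd_C),
    )
    if not mesh.mask.any():
        raise ValueError("empty feasibility mask; inconsistent moments or G")
    return mesh


def _statistics(mesh: SupportMesh, order: int) -> np.ndarray:
    """Monomial sufficient statistics on feasible cells, shape (n_cells, K)."""
    fn, cn = mesh.normalized()
    F = np.broadcast_to(fn[:, None], mesh.mask.shape)[mesh.mask]
    C = np.broadcast_to(cn[None, :], mesh.mask.shape)[mesh.mask]
    cols = [F, C, F * F, F * C, C * C]
    if order >= 3:
        cols += [F**3, F * F * C, F * C * C, C**3]
    return np.column_stack(cols)


def _targets(moments: CountMomentSet, order: int) -> np.ndarray:
    """Raw moments of the normalized coordinates implied by the moment set."""
    sF = np.sqrt(moments.var_F)
    sC = np.sqrt(moments.var_C)
    rho = moments.cov_FC / (sF * sC)
    t = [0.0, 0.0, 1.0, rho, 1.0]
    if order >= 3:
        if moments.order < 3:
            raise ValueError("order-3 fit requires the four third central moments")
        t += [
            moments.gamma_FFF / sF**3,
            moments.gamma_FFC / (sF * sF * sC),
            moments.gamma_FCC / (sF * sC * sC),
            moments.gamma_CCC / sC**3,
        ]
    return np.array(t)


@dataclass
class JointCountDistribution:
    """Mesh-discretized maxent fit of p(F, C)."""

    mesh: SupportMesh
    probabilities: np.ndarray  # (n_F, n_C), zero on infeasible cells
    lagrange: np.ndarray
    order: int
    target_moments: np.ndarray
    achieved_moments: np.ndarray
    n_iterations: int
    grad_norm: float

    def __post_init__(self) -> None:
        tot = self.probabilities.sum()
        if not np.isclose(tot, 1.0, atol=1e-10):
            raise ValueError(f"probabilities sum to {tot}, not 1")

    @property
    def entropy(self) -> float:
        p = self.probabilities[self.probabilities > 0]
        return float(-(p * np.log(p)).sum())

    def marginal_F(self) -> np.ndarray:
        return self.probabilities.sum(axis=1)

    def marginal_C(self) -> np.ndarray:
        return self.probabilities.sum(axis=0)


def fit_maxent(
    moments: CountMomentSet,
    mesh: SupportMesh | None = None,
    order: int = 3,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> JointCountDistribution:
    """Fit the maxent distribution matching the moment set on the mesh.

    Solves the convex dual psi(lambda) = log Z(lambda) - lambda . m by damped
    Newton with the exact Hessian.  Initialized from the analytic Gaussian
    solution of the order-2 problem (cubic multipliers start at zero).
    """
    moments.validate()
    if mesh is None:
        mesh = build_mesh(moments, int(moments.provenance.get("G", 10**9)))
    T = _statistics(mesh, order)
    m = _targets(moments, order)
    K = T.shape[1]

    # Gaussian initialization in normalized coordinates
    rho = float(np.clip(m[3], -0.999, 0.999))
    Lam = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))
    lam = np.zeros(K)
    lam[2] = -0.5 * Lam[0, 0]
    lam[3] = -Lam[0, 1]
    lam[4] = -0.5 * Lam[1, 1]

    def dual_parts(lam):
        eta = T @ lam
        logZ = logsumexp(eta)
        p = np.exp(eta - logZ)
        return logZ - lam @ m, p

    psi, p = dual_parts(lam)
    grad = T.T @ p - m
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            break
        H = (T * p[:, None]).T @ T - np.outer(T.T @ p, T.T @ p)
        step = np.linalg.solve(H + 1e-12 * np.eye(K), -grad)
        # backtracking line search on the convex dual
        t_ls = 1.0
        for _ in range(60):
            cand = lam + t_ls * step
            psi_new, p_new = dual_parts(cand)
            if psi_new <= psi + 1e-4 * t_ls * (grad @ step):
                break
            t_ls *= 0.5
        else:
            raise RuntimeError(
                "maxent line search failed; the target moments may be "
                f"infeasible on this support (iteration {it}, psi={psi:.6g})"
            )
        lam, psi, p = cand, psi_new, p_new
        grad = T.T @ p - m
    else:
        raise RuntimeError(
            f"maxent did not converge in {max_iter} iterations "
            f"(|grad|_inf = {np.max(np.abs(grad)):.3g}); the moments may be "
            "infeasible (e.g. skewness unreachable on bounded support)"
        )
    probs = np.zeros(mesh.mask.shape)
    probs[mesh.mask] = p
    return JointCountDistribution(
        mesh=mesh,
        probabilities=probs,
        lagrange=lam,
        order=order,
        target_moments=m,
        achieved_moments=T.T @ p,
        n_iterations=it,
        grad_norm=float(np.max(np.abs(grad))),
    )


@dataclass
class ConditionalF:
    """p(F | C = C_obs): a renormalized slice of the joint mesh."""

    f_grid: np.ndarray
    pmf: np.ndarray
    C_obs: float
    C_used: float  # the mesh row actually sliced

    @property
    def mean(self) -> float:
        return float(self.f_grid @ self.pmf)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.pmf @ (self.f_grid - self.mean) ** 2))

    def cdf(self, x: float) -> float:
        return float(self.pmf[self.f_grid <= x].sum())

    def quantile(self, q: float) -> float:
        cum = np.cumsum(self.pmf)
        return float(self.f_grid[np.searchsorted(cum, q, side="left")])

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    def interval(self, level: float = 0.5) -> tuple[float, float]:
        """Central credible interval (default 50%; 75% is the other
        conventional reporting level)."""
        a = (1.0 - level) / 2.0
        return self.quantile(a), self.quantile(1.0 - a)

    def exceedance(self, x: float) -> float:
        """P(F >= x | C)."""
        return float(self.pmf[self.f_grid >= x].sum())

    def to_dict(self) -> dict:
        lo50, hi50 = self.interval(0.50)
        lo75, hi75 = self.interval(0.75)
        return {
            "C_obs": self.C_obs,
            "C_used": self.C_used,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "interval_50": [lo50, hi50],
            "interval_75": [lo75, hi75],
        }


def conditional(
    joint: JointCountDistribution, C_obs: float, interpolate: bool = False
) -> ConditionalF:
    """Slice the joint at the mesh row nearest C_obs (tie -> lower row).

    With ``interpolate=True`` the two bracketing rows are blended linearly
    before renormalization.
    """
    c = joint.mesh.c_grid
    if not (c[0] - 0.5 * (c[1] - c[0]) <= C_obs <= c[-1] + 0.5 * (c[1] - c[0])):
        raise ValueError(
            f"C_obs={C_obs} outside the mesh C-range [{c[0]:.1f}, {c[-1]:.1f}]; "
            "rebuild the mesh with a larger k or check the moment inputs"
        )
    if interpolate and c[0] < C_obs < c[-1]:
        j = int(np.searchsorted(c, C_obs)) - 1
        w = (C_obs - c[j]) / (c[j + 1] - c[j])
        col = (1 - w) * joint.probabilities[:, j] + w * joint.probabilities[:, j + 1]
        c_used = C_obs
    else:
        d = np.abs(c - C_obs)
        j = int(np.flatnonzero(d == d.min())[0])  # tie -> lower index
        col = joint.probabilities[:, j]
        c_used = float(c[j])
    tot = col.sum()
    if tot <= 0:
        raise ValueError(f"zero-mass conditional slice at C={c_used}")
    return ConditionalF(
        f_grid=joint.mesh.f_grid, pmf=col / tot, C_obs=float(C_obs), C_used=c_used
    )


def control_discoveries(
    zpanel: ZScorePanel,
    ensemble: CorrelationEnsemble,
    gamma: float,
    lam: float,
    deltas,
    spec: HistogramSpec | None = None,
    order: int = 3,
    n_F: int = 100,
    n_C: int = 500,
) -> dict:
    """Exceedance-bound selection of the tail threshold.

    Scans candidate thresholds delta from most to least extreme; for each,
    recomputes the moments, the maxent joint and p(F | C_obs), and checks
    the false-discovery-proportion bound P(F / G* >= gamma | C) <= lambda,
    where G* is the number of scores at or beyond delta.  Returns the least
    extreme threshold satisfying the bound, together with the full scan
    table (one row per candidate).
    """
    if not (0 < gamma <= 1) or not (0 < lam < 1 + 1e-12):
        raise ValueError("need gamma in (0, 1] and lambda in (0, 1)")
    base = spec or HistogramSpec()
    G = zpanel.n_genes
    table = []
    selected = None
    for d in sorted(deltas):  # most extreme (most negative) first
        s = HistogramSpec(
            delta_bin=base.delta_bin,
            z_min=base.z_min,
            z_max=base.z_max,
            c=base.c,
            delta_tail=float(d),
            tail_side=base.tail_side,
        )
        g_star, c_obs = observed_counts(zpanel, s)
        row = {"delta": float(d), "G_star": g_star, "C_obs": c_obs,
               "exceedance": None, "accepted": False}
        if g_star > 0:
            moments = aggregate(G, s, ensemble, order=order)
            mesh = build_mesh(moments, G, n_F=n_F, n_C=n_C)
            joint = fit_maxent(moments, mesh, order=order)
            cond = conditional(joint, c_obs)
            exc = cond.exceedance(gamma * g_star)
            row["exceedance"] = exc
            row["F_mean"] = cond.mean
            if exc <= lam:
                row["accepted"] = True
                selected = row  # later (less extreme) rows overwrite
        table.append(row)
    return {
        "gamma": gamma,
        "lambda": lam,
        "selected": selected,
        "table": table,
    }
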