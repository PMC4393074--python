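"""Model/Results interface to the false-discovery moment estimator.

`FalseDiscoveryModel` wraps an expression panel plus the analysis settings;
`fit()` runs the full pipeline -- residualization, alpha estimation,
moment aggregation, maxent joint fit, conditioning on the observed center
count -- and returns a `FalseDiscoveryResults` carrying every intermediate
estimate, the conditional distribution of the number of false discoveries,
and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import maxent as _maxent
from .corr_density import CorrelationDensityModel, estimate_alpha
from .maxent import ConditionalF, JointCountDistribution, build_mesh, fit_maxent
from .moments import CountMomentSet, ParametricEnsemble, aggregate
from .panels import ExpressionPanel, load_expression, residualize, standardize_columns
from .scores import HistogramSpec, ZScorePanel, observed_counts, z_scores

__all__ = ["FalseDiscoveryModel", "FalseDiscoveryResults"]


class FalseDiscoveryModel:
    """Moment-based estimator of the number of false discoveries.

    Parameters
    ----------
    panel : ExpressionPanel
        Gene-by-array expression matrix with a two-group design.
    spec : HistogramSpec, optional
        z-axis geometry (bin width, center half-width c, tail threshold
        delta).  Defaults: Delta = 0.1, c = 1, delta = -2.5, left tail.
    convention : {"eq22", "eq24"}
        Beta-family parameter convention (see `fdmoments.corr_density`).
    fisher_var : str or float
        Fisher sampling-variance rule for the deconvolution step.
    max_pairs : int
        Budget for the pairwise-correlation subsample.
    n_mc : int
        Size of the shared 3x3 correlation-matrix sample for third moments.

    Examples
    --------
    >>> from fdmoments import FalseDiscoveryModel, simulate
    >>> cfg = simulate.GammaGammaConfig(G=500, M=8, seed=1)
    >>> panel = simulate.simulate_null_matrix(cfg)
    >>> res = FalseDiscoveryModel(panel, seed=1).fit(order=3)
    >>> print(res.summary())                     # doctest: +SKIP
    """

    def __init__(
        self,
        panel: ExpressionPanel,
        spec: HistogramSpec | None = None,
        convention: str = "eq22",
        fisher_var="auto",
        max_pairs: int = 500_000,
        n_mc: int = 50_000,
        seed: int | None = None,
    ):
        self.panel = panel
        self.spec = spec or HistogramSpec()
        self.convention = convention
        self.fisher_var = fisher_var
        self.max_pairs = max_pairs
        self.n_mc = n_mc
        self.seed = seed

    @classmethod
    def from_files(
        cls, matrix_path, design, log_transform: bool = False, **kwargs
    ) -> "FalseDiscoveryModel":
        """Build from a delimited expression table and a design mapping."""
        return cls(load_expression(matrix_path, design, log_transform), **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, groups, log_transform: bool = False, **kwargs
    ) -> "FalseDiscoveryModel":
        """Build from a genes-by-arrays DataFrame (index = gene ids)."""
        values = df.to_numpy(dtype=float)
        if log_transform:
            if np.any(values <= 0):
                raise ValueError("nonpositive under log")
            values = np.log(values)
        panel = ExpressionPanel(
            values=values,
            gene_ids=np.asarray(df.index.astype(str)),
            groups=np.asarray(groups, dtype=int),
            log_transformed=log_transform,
            array_ids=np.asarray(df.columns.astype(str)),
        )
        return cls(panel, **kwargs)

    def fit(
        self,
        order: int = 3,
        n_F: int = 100,
        n_C: int = 500,
        alpha: float | None = None,
    ) -> "FalseDiscoveryResults":
        """Run the pipeline and return the fitted results.

        ``alpha`` overrides the estimated omnibus parameter (e.g. to impose
        a judgment-based dependence level); otherwise it is estimated from
        the residual correlations.
        """
        res = standardize_columns(residualize(self.panel))
        if alpha is None:
            density = estimate_alpha(
                res,
                max_pairs=self.max_pairs,
                seed=self.seed,
                fisher_var=self.fisher_var,
                convention=self.convention,
            )
        else:
            density = CorrelationDensityModel(alpha=alpha, convention=self.convention)
        zpanel = z_scores(self.panel)
        tail_count, center_count = observed_counts(zpanel, self.spec)
        ensemble = ParametricEnsemble(
            density.exponent, n_mc=self.n_mc, seed=self.seed
        )
        moments = aggregate(self.panel.n_genes, self.spec, ensemble, order=order)
        mesh = build_mesh(moments, self.panel.n_genes, n_F=n_F, n_C=n_C)
        joint = fit_maxent(moments, mesh, order=order)
        cond = _maxent.conditional(joint, center_count)
        return FalseDiscoveryResults(
            model=self,
            density=density,
            zpanel=zpanel,
            tail_count=tail_count,
            center_count=center_count,
            moments=moments,
            joint=joint,
            conditional_F=cond,
            order=order,
        )


@dataclass
class FalseDiscoveryResults:
    """Fitted pipeline state: estimates, uncertainties and diagnostics."""

    model: FalseDiscoveryModel
    density: CorrelationDensityModel
    zpanel: ZScorePanel
    tail_count: int
    center_count: int
    moments: CountMomentSet
    joint: JointCountDistribution
    conditional_F: ConditionalF
    order: int

    @property
    def alpha(self) -> float:
        return self.density.alpha

    @property
    def estimate(self) -> float:
        """Posterior-mean number of false discoveries E[F | C]."""
        return self.conditional_F.mean

    @property
    def naive_estimate(self) -> float:
        """The usual mean estimator G * Phi(delta) (ignores dependence)."""
        from scipy.special import ndtr

        return self.model.panel.n_genes * float(ndtr(self.model.spec.delta_tail))

    def conditional(self, C_obs: float | None = None) -> ConditionalF:
        if C_obs is None:
            return self.conditional_F
        return _maxent.conditional(self.joint, C_obs)

    def control(self, gamma: float, lam: float, deltas) -> dict:
        """Exceedance-bound threshold selection on the fitted z scores."""
        ensemble = ParametricEnsemble(
            self.density.exponent, n_mc=self.model.n_mc, seed=self.model.seed
        )
        return _maxent.control_discoveries(
            self.zpanel, ensemble, gamma, lam, deltas,
            spec=self.model.spec, order=self.order,
        )

    def plot_joint(self, ax=None):
        """Contour plot of the fitted p(F, C) (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.joint.mesh
        ax.contour(m.c_grid, m.f_grid, self.joint.probabilities, levels=10)
        ax.set_xlabel("center count C")
        ax.set_ylabel("tail count F")
        return ax

    def to_dict(self) -> dict:
        spec = self.model.spec
        return {
            "G": self.model.panel.n_genes,
            "M": self.model.panel.n_arrays,
            "spec": {
                "delta_bin": spec.delta_bin,
                "c": spec.c,
                "delta_tail": spec.delta_tail,
                "tail_side": spec.tail_side,
            },
            "order": self.order,
            "density": self.density.to_dict(),
            "tail_count": self.tail_count,
            "center_count": self.center_count,
            "moments": self.moments.to_dict(),
            "conditional": self.conditional_F.to_dict(),
            "naive_estimate": self.naive_estimate,
            "maxent": {
                "iterations": self.joint.n_iterations,
                "grad_norm": self.joint.grad_norm,
                "entropy": self.joint.entropy,
            },
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        d = self.to_dict()
        lines = [
            "False-discovery moment model",
            "=" * 60,
            f"genes G = {d['G']}, arrays M = {d['M']}, order = {self.order}",
            f"tail delta = {d['spec']['delta_tail']}, center c = {d['spec']['c']}, "
            f"Delta = {d['spec']['delta_bin']}",
            "-" * 60,
            f"omnibus alpha          {self.alpha:12.4f}  ({self.density.convention})",
            f"observed tail count    {self.tail_count:12d}",
            f"observed center count  {self.center_count:12d}",
            f"mu_F / mu_C            {self.moments.mu_F:12.2f} / {self.moments.mu_C:.2f}",
            f"sd_F / sd_C            {np.sqrt(self.moments.var_F):12.2f} / "
            f"{np.sqrt(self.moments.var_C):.2f}",
            f"corr(F, C)             {self.moments.correlation:12.4f}",
            "-" * 60,
            f"E[F | C] (posterior)   {self.estimate:12.2f}",
            f"median[F | C]          {self.conditional_F.median:12.2f}",
            "50% interval           [{:.1f}, {:.1f}]".format(
                *self.conditional_F.interval(0.5)
            ),
            "75% interval           [{:.1f}, {:.1f}]".format(
                *self.conditional_F.interval(0.75)
            ),
            f"naive G*Phi(delta)     {self.naive_estimate:12.2f}",
            "=" * 60,
        ]
        return "\n".join(lines)
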