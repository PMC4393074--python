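"""Two-sample t statistics, the probit z transform, and histogram counting.

Each gene's pooled-variance two-sample t statistic is mapped to a z value
through z = Phi^{-1}(T_df(t)), so that under the null every z is a unit
normal variate while the joint dependence of the t statistics is carried
over.  The z axis is partitioned into width-Delta bins; two special regions
drive the inference:

* the *center area* [-c, c], whose null count C is treated as observable
  (essentially no non-null score lands there), and
* the left *tail area* (-inf, delta], whose null count F is the number of
  false discoveries to be estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panels import ExpressionPanel

__all__ = [
    "ZScorePanel",
    "HistogramSpec",
    "BinCounts",
    "two_sample_t",
    "t_to_z",
    "z_scores",
    "bin_scores",
    "observed_counts",
]


@dataclass
class ZScorePanel:
    """Per-gene z values plus the degrees of freedom used in the t->z map."""

    z: np.ndarray
    df: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z scores must be finite")

    @property
    def n_genes(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class HistogramSpec:
    """Binning of the z axis and the tail/center region geometry.

    Bin edges are anchored at zero, so with the default Delta = 0.1 the
    region boundaries +-c = +-1 and delta = -2.5 fall exactly on edges.
    Scores are assigned to half-open bins [lo, hi); a score exactly at -c
    therefore belongs to the center-side bin.
    """

    delta_bin: float = 0.1
    z_min: float = -6.0
    z_max: float = 6.0
    c: float = 1.0
    delta_tail: float = -2.5
    tail_side: str = "left"

    def __post_init__(self) -> None:
        if self.delta_bin <= 0:
            raise ValueError("bin width must be positive")
        if not (self.z_min < self.delta_tail < -self.c < 0 < self.c < self.z_max):
            raise ValueError(
                "require z_min < delta < -c < 0 < c < z_max, got "
                f"z_min={self.z_min}, delta={self.delta_tail}, c={self.c}, z_max={self.z_max}"
            )
        if self.tail_side not in ("left", "right", "double"):
            raise ValueError("tail_side must be 'left', 'right' or 'double'")
        for name, v in (("c", self.c), ("delta_tail", self.delta_tail),
                        ("z_min", self.z_min), ("z_max", self.z_max)):
            r = v / self.delta_bin
            if abs(r - round(r)) > 1e-9:
                raise ValueError(f"{name}={v} must fall on a bin edge (multiple of Delta)")

    @property
    def edges(self) -> np.ndarray:
        n_lo = int(round(-self.z_min / self.delta_bin))
        n_hi = int(round(self.z_max / self.delta_bin))
        return np.arange(-n_lo, n_hi + 1) * self.delta_bin

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def region_of_bins(self) -> np.ndarray:
        """Label every bin 'tail', 'center' or 'other' (bins subset of region)."""
        centers = self.centers
        lab = np.full(self.n_bins, "other", dtype=object)
        lab[np.abs(centers) < self.c] = "center"
        if self.tail_side in ("left", "double"):
            lab[centers < self.delta_tail] = "tail"
        if self.tail_side in ("right", "double"):
            lab[centers > -self.delta_tail] = "tail"
        return lab

    def tail_bins(self) -> np.ndarray:
        return np.flatnonzero(self.region_of_bins() == "tail")

    def center_bins(self) -> np.ndarray:
        return np.flatnonzero(self.region_of_bins() == "center")

    def tail_interval(self) -> tuple[float, float]:
        """The semi-infinite tail region as an interval (left-sided default)."""
        if self.tail_side == "left":
            return (-np.inf, self.delta_tail)
        if self.tail_side == "right":
            return (-self.delta_tail, np.inf)
        raise ValueError("double-sided tail is not a single interval")

    def center_interval(self) -> tuple[float, float]:
        return (-self.c, self.c)


@dataclass
class BinCounts:
    """Observed z-histogram bin counts with region labels."""

    counts: np.ndarray
    spec: HistogramSpec
    n_out_of_range: int = 0

    @property
    def regions(self) -> np.ndarray:
        return self.spec.region_of_bins()


def two_sample_t(panel: ExpressionPanel) -> tuple[np.ndarray, int]:
    """Pooled-variance two-sample t statistic per gene; df = M - 2."""
    i1 = panel.group_columns(1)
    i2 = panel.group_columns(2)
    if i1.size < 2 or i2.size < 2:
        raise ValueError("both groups need at least 2 arrays for a t statistic")
    x1 = panel.values[:, i1]
    x2 = panel.values[:, i2]
    n1, n2 = i1.size, i2.size
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    zero = np.flatnonzero(sp2 == 0)
    if zero.size:
        ids = panel.gene_ids[zero][:20]
        raise ValueError(
            f"zero pooled variance; t undefined for gene(s): {ids.tolist()}"
        )
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, df


def t_to_z(t, df: int):
    """Map t statistics to z values: z = Phi^{-1}(T_df(t)).

    Monotone in t and antisymmetric (z(-t) = -z(t)).  Evaluated through the
    survival function on the positive half-line for numerical symmetry.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite t statistic")
    # exploit antisymmetry: evaluate on |t| via the survival function, which
    # keeps tail probabilities accurate, then restore the sign
    z = stats.norm.isf(stats.t.sf(np.abs(t), df))
    return np.copysign(z, t) if t.ndim else float(np.copysign(z, t))


def z_scores(panel: ExpressionPanel) -> ZScorePanel:
    """Full t -> z pipeline for a panel."""
    t, df = two_sample_t(panel)
    return ZScorePanel(z=t_to_z(t, df), df=df)


def bin_scores(zpanel: ZScorePanel, spec: HistogramSpec) -> BinCounts:
    """Assign each score to a half-open bin [lo, hi); out-of-range counted apart."""
    z = zpanel.z
    edges = spec.edges
    idx = np.floor((z - edges[0]) / spec.delta_bin).astype(int)
    in_range = (idx >= 0) & (idx < spec.n_bins)
    counts = np.bincount(idx[in_range], minlength=spec.n_bins)
    return BinCounts(counts=counts, spec=spec,
                     n_out_of_range=int((~in_range).sum()))


def observed_counts(zpanel: ZScorePanel, spec: HistogramSpec) -> tuple[int, int]:
    """(tail_count, center_count) computed from the raw z values.

    The tail count uses the untruncated semi-infinite region z <= delta
    (or its right/double-sided analogue); the center count is #{|z| <= c}.
    """
    z = zpanel.z
    if spec.tail_side == "left":
        tail = int(np.sum(z <= spec.delta_tail))
    elif spec.tail_side == "right":
        tail = int(np.sum(z >= -spec.delta_tail))
    else:
        tail = int(np.sum(np.abs(z) >= -spec.delta_tail))
    center = int(np.sum(np.abs(z) <= spec.c))
    return tail, center
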