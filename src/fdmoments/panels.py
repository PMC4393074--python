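"""Expression matrices, group designs, and residualization.

The pipeline consumes a gene-by-array expression matrix together with a
two-group design (e.g. control vs. treatment).  Under the all-null analysis
convention every gene is treated as non-differentially expressed, and the
object of interest is the *residual* matrix obtained by removing each gene's
within-group means; after per-array (column) standardization this residual
matrix is the sole source of the intergene correlation information used
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionPanel",
    "ResidualPanel",
    "load_expression",
    "write_expression",
    "residualize",
    "standardize_columns",
]


@dataclass
class ExpressionPanel:
    """Gene-by-array expression matrix with a two-group design.

    Parameters
    ----------
    values : ndarray, shape (G, M)
        Expression levels; genes in rows, arrays in columns.  Nonnegative raw
        scale or real-valued log scale.
    gene_ids : sequence of str
        Unique identifier per gene (row).
    groups : ndarray of int, shape (M,)
        Group label 1 or 2 per array (column).
    log_transformed : bool
        Whether ``values`` are natural logs of the raw levels.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    groups: np.ndarray
    log_transformed: bool = False
    array_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x arrays)")
        G, M = self.values.shape
        if G < 4 or M < 4:
            raise ValueError(f"need at least 4 genes and 4 arrays, got G={G}, M={M}")
        if self.gene_ids.shape != (G,):
            raise ValueError("gene_ids length must match the number of rows")
        if len(np.unique(self.gene_ids)) != G:
            raise ValueError("gene_ids must be unique")
        if self.groups.shape != (M,):
            raise ValueError("groups length must match the number of columns")
        bad = set(np.unique(self.groups)) - {1, 2}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")
        if self.n_per_group(1) == 0 or self.n_per_group(2) == 0:
            raise ValueError("both treatment groups must be non-empty")
        if self.array_ids is None:
            self.array_ids = np.array([f"a{m + 1}" for m in range(M)])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def n_per_group(self, k: int) -> int:
        return int(np.sum(self.groups == k))

    def group_columns(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.groups == k)


@dataclass
class ResidualPanel:
    """Residual expression matrix X° with within-group gene means removed.

    ``effective_df`` counts the independent observations per row that remain
    after removing the two group means (M - 2).
    """

    values: np.ndarray
    groups: np.ndarray
    effective_df: int
    column_standardized: bool = False
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]


def load_expression(path, design, log_transform: bool = False) -> ExpressionPanel:
    """Read a delimited expression table and attach a two-group design.

    The file must be a rectangular numeric table with a header row of array
    names and the gene identifier in the first column.  ``design`` maps array
    ids to group labels ("1"/"2" or 1/2); it may be a dict, a sequence aligned
    with the columns, or the path of a two-column delimited file.
    """
    sep = _sniff_sep(path)
    # C engine + round_trip parsing keeps written floats bit-identical
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"no data rows found in {path!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression table {path!r}: {exc}") from None
    if not np.all(np.isfinite(values)):
        raise ValueError("expression table contains missing/non-finite entries")
    array_ids = np.asarray(df.columns.astype(str))
    groups = _resolve_design(design, array_ids)
    if log_transform:
        if np.any(values <= 0):
            raise ValueError("nonpositive under log: cannot log-transform entries <= 0")
        values = np.log(values)
    return ExpressionPanel(
        values=values,
        gene_ids=np.asarray(df.index.astype(str)),
        groups=groups,
        log_transformed=log_transform,
        array_ids=array_ids,
    )


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    for cand in ("\t", ",", ";"):
        if cand in header:
            return cand
    return r"\s+"


def _resolve_design(design, array_ids: np.ndarray) -> np.ndarray:
    if isinstance(design, (str,)):
        tab = pd.read_csv(design, sep=_sniff_sep(design), header=None)
        design = dict(zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1]))
    if isinstance(design, dict):
        missing = [a for a in array_ids if a not in design]
        if missing:
            raise ValueError(f"design is missing arrays: {missing}")
        labels = [design[a] for a in array_ids]
    else:
        labels = list(design)
        if len(labels) != len(array_ids):
            raise ValueError("design length does not match the number of arrays")
    try:
        groups = np.array([int(v) for v in labels])
    except (TypeError, ValueError):
        raise ValueError(f"unknown group label in design: {labels!r}") from None
    return groups


def write_expression(panel: ExpressionPanel, path, sep: str = "\t") -> None:
    """Write a panel back to a delimited table (same dialect as the loader)."""
    df = pd.DataFrame(panel.values, index=panel.gene_ids, columns=panel.array_ids)
    df.index.name = "gene"
    # 17 significant digits guarantee bit-exact float round-trips
    df.to_csv(path, sep=sep, float_format="%.17g")


def residualize(panel: ExpressionPanel) -> ResidualPanel:
    """Subtract each gene's average response within each treatment group.

    Every row of the result sums to zero within each group; the per-row
    effective degrees of freedom are M - 2.
    """
    for k in (1, 2):
        if panel.n_per_group(k) < 2:
            raise ValueError(
                f"group {k} has a single array; residuals would be degenerate"
            )
    resid = panel.values.copy()
    for k in (1, 2):
        cols = panel.group_columns(k)
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)
    return ResidualPanel(
        values=resid,
        groups=panel.groups.copy(),
        effective_df=panel.n_arrays - 2,
        gene_ids=panel.gene_ids,
    )


def standardize_columns(panel: ResidualPanel, ddof: int = 1) -> ResidualPanel:
    """Standardize each column (array) to mean zero and unit sample variance.

    Column standardization normalizes per-array brightness and forces the sum
    of all pairwise row covariances toward zero, which justifies fitting a
    zero-symmetric density to the observed correlations.  The unit-variance
    convention is the sample variance (denominator G-1); the choice only
    rescales columns and leaves all downstream correlations unchanged.
    """
    X = panel.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    # a column is constant when its spread is at round-off level
    bad = np.flatnonzero(sd <= 1e-13 * np.maximum(np.abs(X).max(axis=0), 1.0))
    if bad.size:
        raise ValueError(f"constant column(s) cannot be standardized: arrays {bad.tolist()}")
    return ResidualPanel(
        values=(X - mean) / sd,
        groups=panel.groups.copy(),
        effective_df=panel.effective_df,
        column_standardized=True,
        gene_ids=panel.gene_ids,
    )
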