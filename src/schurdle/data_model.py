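"""Expression-assay container, detection thresholding, CDR, and design matrices.

Expression values are assumed to be on the log2(TPM + 1) scale, stored as a
dense cells x genes matrix (cells are observations/rows).  A detection
indicator matrix ``Z = [z_ig]`` marks entries above a background threshold,
and the cellular detection rate (CDR) of cell *i* is the fraction of genes
detected in that cell,

    CDR_i = (1/N) * sum_g z_ig .

The CDR acts as a proxy for global technical and biological factors (cell
volume, capture efficiency) and is typically entered as a covariate in both
components of the hurdle model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionAssay",
    "DesignSpec",
    "apply_threshold",
    "compute_cdr",
    "build_design",
    "estimate_threshold",
]


@dataclass
class ExpressionAssay:
    """Cells x genes expression matrix with detection calls and per-cell CDR.

    Parameters
    ----------
    values
        Non-negative expression matrix, cells in rows, genes in columns,
        log2(TPM + 1) units.
    cell_ids, gene_ids
        Unique ordered identifiers matching the matrix dimensions.
    threshold
        Detection background level; entries strictly greater than it are
        called detected.  The values themselves are never modified.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    threshold: float = 0.0
    detection: np.ndarray = field(init=False)
    cdr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_cells, n_genes = self.values.shape
        if n_genes == 0:
            raise ValueError("assay must contain at least one gene")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, g = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite expression value at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[g]!r}"
            )
        neg = self.values < 0
        if neg.any():
            i, g = np.argwhere(neg)[0]
            raise ValueError(
                f"negative expression value at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[g]!r}"
            )
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError("id lengths do not match matrix dimensions")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if not np.isfinite(self.threshold) or self.threshold < 0:
            raise ValueError("threshold must be a finite non-negative real")
        self.detection = (self.values > self.threshold).astype(np.int8)
        self.cdr = self.detection.mean(axis=1)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignSpec:
    """Declarative description of a model design.

    ``formula_terms`` is an ordered list of covariate names to include; the
    reserved name ``"cdr"`` pulls the cellular detection rate from the assay.
    Categorical covariates are dummy-coded against ``reference_levels`` (first
    level in sorted order when unspecified).
    """

    covariates: pd.DataFrame
    formula_terms: list[str]
    include_cdr: bool = False
    reference_levels: dict[str, str] = field(default_factory=dict)
    # name of a categorical covariate within whose levels the CDR is centered
    # ("precision variable" use: makes the CDR orthogonal to that factor so
    # treatment coefficients keep their marginal interpretation)
    center_cdr_by: str | None = None

    def all_terms(self) -> list[str]:
        terms = list(self.formula_terms)
        if self.include_cdr and "cdr" not in terms:
            terms.append("cdr")
        return terms

    def drop_term(self, term: str) -> "DesignSpec":
        """Return a copy of the spec with one term removed (for nested fits)."""
        terms = [t for t in self.formula_terms if t != term]
        include_cdr = self.include_cdr and term != "cdr"
        if terms == self.formula_terms and include_cdr == self.include_cdr:
            raise ValueError(f"term {term!r} not present in the design")
        return DesignSpec(
            self.covariates, terms, include_cdr, dict(self.reference_levels),
            self.center_cdr_by,
        )


def apply_threshold(
    raw: np.ndarray,
    threshold: float = 0.0,
    cell_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> ExpressionAssay:
    """Build an :class:`ExpressionAssay` from a raw matrix and a background level.

    Entries at or below ``threshold`` are treated as unexpressed for the
    discrete component; the continuous component later conditions on
    detection.  Values are passed through unchanged — thresholding changes
    detection status only.
    """
    raw = np.asarray(raw, dtype=float)
    n_cells, n_genes = raw.shape
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n_cells)]
    if gene_ids is None:
        gene_ids = [f"gene{g}" for g in range(n_genes)]
    return ExpressionAssay(raw, list(cell_ids), list(gene_ids), float(threshold))


def compute_cdr(assay: ExpressionAssay) -> np.ndarray:
    """Cellular detection rate per cell: row mean of the detection matrix."""
    if assay.n_genes == 0:
        raise ValueError("cannot compute CDR with zero genes")
    return assay.detection.mean(axis=1)


def estimate_threshold(raw: np.ndarray, bandwidth: float = 0.5) -> float:
    """Data-driven background threshold (approximate).

    Places the threshold at the deepest trough of a fixed-bandwidth Gaussian
    kernel density estimate of the pooled nonzero expression values, searching
    below the main (upper) mode.  This is a simple stand-in for adaptive
    background estimation; detection calls are typically insensitive to the
    exact background level, and ``threshold=0`` remains the default.
    """
    pos = np.asarray(raw, dtype=float)
    pos = pos[pos > 0]
    if pos.size < 10:
        return 0.0
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(pos, bw_method=bandwidth / max(pos.std(), 1e-8))
    grid = np.linspace(0, np.quantile(pos, 0.95), 256)
    dens = kde(grid)
    main_mode = int(np.argmax(dens))
    if main_mode < 2:
        return 0.0
    trough = int(np.argmin(dens[:main_mode]))
    # no interior trough -> unimodal below the mode, keep zero background
    if trough == 0:
        return 0.0
    return float(grid[trough])


def build_design(spec: DesignSpec, assay: ExpressionAssay) -> pd.DataFrame:
    """Expand a :class:`DesignSpec` into a cells x p design matrix.

    The first column is the intercept; categorical covariates are
    treatment-contrast coded against the reference level; the reserved term
    ``"cdr"`` is filled from ``assay.cdr``.  Column names are retained for
    coefficient labeling and term-wise tests.

    Raises on unknown terms and on rank deficiency (naming the collinear
    columns).
    """
    cov = spec.covariates
    if len(cov) != assay.n_cells:
        raise ValueError(
            f"covariate table has {len(cov)} rows but assay has {assay.n_cells} cells"
        )
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(assay.n_cells)}
    term_map: dict[str, list[str]] = {}
    for term in spec.all_terms():
        if term == "cdr":
            cdr = np.asarray(assay.cdr, dtype=float)
            if spec.center_cdr_by is not None:
                if spec.center_cdr_by not in cov.columns:
                    raise ValueError(
                        f"center_cdr_by names unknown covariate {spec.center_cdr_by!r}"
                    )
                groups = cov[spec.center_cdr_by].astype(str).to_numpy()
                cdr = cdr.copy()
                for lev in np.unique(groups):
                    sel = groups == lev
                    cdr[sel] -= cdr[sel].mean()
            cols["cdr"] = cdr
            term_map["cdr"] = ["cdr"]
            continue
        if term not in cov.columns:
            raise ValueError(f"unknown design term {term!r}")
        col = cov[term]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            cols[term] = col.to_numpy(dtype=float)
            term_map[term] = [term]
        else:
            levels = sorted(col.astype(str).unique())
            ref = spec.reference_levels.get(term, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found for term {term!r}")
            names = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{term}[{lev}]"
                cols[name] = (col.astype(str) == lev).to_numpy(dtype=float)
                names.append(name)
            term_map[term] = names
    X = pd.DataFrame(cols, index=cov.index if len(cov.index) == assay.n_cells else None)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        culprits = _collinear_columns(X.to_numpy())
        names = [X.columns[j] for j in culprits]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {names}")
    X.attrs["term_map"] = term_map
    return X


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        sub = X[:, kept + [j]]
        if np.linalg.matrix_rank(sub) < len(kept) + 1:
            bad.append(j)
        else:
            kept.append(j)
    return bad


def term_columns(X: pd.DataFrame, term: str) -> list[int]:
    """Column indices of ``X`` belonging to a named design term."""
    term_map = X.attrs.get("term_map", {})
    if term in term_map:
        names = term_map[term]
    elif term in X.columns:
        names = [term]
    else:
        raise ValueError(f"term {term!r} not found in the design")
    return [X.columns.get_loc(n) for n in names]
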