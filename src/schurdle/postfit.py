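"""Residual and score machinery for fitted hurdle models.

Standardized deviance residuals are computed separately for the detection
(binomial) and level (Gaussian) components and combined by averaging the
available components per cell: when a cell does not express the gene, its
continuous residual is missing and the combined residual is the discrete
residual alone.  CDR-corrected single-cell scores subtract the model's
nuisance-only prediction from the observed expression,

    s_ij = y_ij - z_hat_ij * y_hat_ij ,

where z_hat and y_hat are the component predictions restricted to the
nuisance terms (intercept included); module scores average s_ij over the
genes of a module.  Residual correlation and PCA expose co-expression
structure remaining after the modeled effects are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionAssay, term_columns
from .hurdle import HurdleFit

__all__ = [
    "ResidualMatrix",
    "deviance_residuals",
    "cell_scores",
    "module_scores",
    "residual_correlation",
    "residual_pca",
]

# cap on a single observation's deviance contribution when the fitted
# probability is numerically 0 or 1 but the observation disagrees
_DEVIANCE_CAP = 75.0


@dataclass
class ResidualMatrix:
    """Cells x genes residuals per component plus their combination."""

    discrete: np.ndarray
    continuous: np.ndarray  # NaN where detection = 0
    combined: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    n_clamped: int = 0


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -36, 36)))


def deviance_residuals(
    fit: HurdleFit, assay: ExpressionAssay, standardize: bool = True
) -> ResidualMatrix:
    """Standardized deviance residuals of both components.

    Discrete: signed sqrt of the Bernoulli deviance of z against the fitted
    probability, divided by sqrt(1 - leverage) of the logistic fit when
    ``standardize``.  Continuous (expressed cells only): raw residual scaled
    by the shrunken residual sd and sqrt(1 - leverage) of the expressed-
    subset least-squares fit.  Deviance contributions are clamped at a cap
    when a fitted probability is numerically degenerate but discordant.
    """
    X = fit.design.to_numpy(dtype=float)
    Z = assay.detection.astype(float)
    Y = assay.values
    eta = X @ fit.beta_d.T  # (n, G)
    p_hat = _expit(eta)

    with np.errstate(divide="ignore", invalid="ignore"):
        unit_dev = -2.0 * np.where(Z == 1.0, np.log(p_hat), np.log1p(-p_hat))
    n_clamped = int((unit_dev > _DEVIANCE_CAP).sum())
    unit_dev = np.minimum(unit_dev, _DEVIANCE_CAP)
    disc = np.sign(Z - p_hat) * np.sqrt(np.maximum(unit_dev, 0.0))

    # continuous residuals on expressed cells, scaled by the shrunken sd
    mu_c = X @ np.where(np.isfinite(fit.beta_c), fit.beta_c, 0.0).T
    raw = Y - mu_c
    s2 = fit.sigma2_effective()
    s2 = np.where(np.isfinite(s2) & (s2 > 0), s2, np.nan)
    with np.errstate(invalid="ignore"):
        cont = raw / np.sqrt(s2)[None, :]
    # an exact fit with zero residual variance still has residual 0
    cont = np.where(np.abs(raw) < 1e-12, 0.0, cont)
    cont = np.where(Z == 1.0, cont, np.nan)

    if standardize:
        # discrete leverage: h = w_i * x_i' H^{-1} x_i with H the penalized
        # Hessian (cov_d is its inverse, in the original parameterization)
        w = p_hat * (1.0 - p_hat)
        quad_d = np.einsum("np,gpq,nq->ng", X, fit.cov_d, X)
        h_d = np.clip(w * quad_d, 0.0, 0.999)
        disc = disc / np.sqrt(1.0 - h_d)
        # continuous leverage from the expressed-subset normal equations
        h_c = _continuous_leverage(X, Z)
        with np.errstate(invalid="ignore"):
            cont = cont / np.sqrt(1.0 - np.clip(h_c, 0.0, 0.999))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        combined = np.nanmean(np.stack([disc, cont]), axis=0)
    return ResidualMatrix(
        discrete=disc,
        continuous=cont,
        combined=combined,
        gene_ids=list(assay.gene_ids),
        cell_ids=list(assay.cell_ids),
        n_clamped=n_clamped,
    )


def _continuous_leverage(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Hat-matrix diagonals of the per-gene 0/1-weighted least squares fits."""
    XtWX = np.einsum("ng,np,nq->gpq", Z, X, X)
    G = Z.shape[1]
    p = X.shape[1]
    inv = np.full((G, p, p), np.nan)
    eigs = np.linalg.eigvalsh(XtWX)
    ok = eigs[:, 0] > 1e-9 * np.maximum(eigs[:, -1], 1.0)
    if ok.any():
        inv[ok] = np.linalg.inv(XtWX[ok])
    for g in np.flatnonzero(~ok):
        inv[g] = np.linalg.pinv(XtWX[g], rcond=1e-9)
    h = np.einsum("np,gpq,nq->ng", X, inv, X) * Z
    return h


def cell_scores(
    fit: HurdleFit, assay: ExpressionAssay, nuisance_terms: list[str]
) -> pd.DataFrame:
    """Nuisance-corrected expression scores s_ij = y_ij - z_hat_ij * y_hat_ij.

    The predictions use only the intercept plus the listed nuisance terms
    (e.g. ``["cdr"]`` removes the CDR effect while retaining treatment
    signal in the scores).  Passing every design term yields full-model
    unconditional-mean residuals; an empty list leaves an intercept-only
    correction.
    """
    cols = [0]  # intercept
    for t in nuisance_terms:
        cols.extend(term_columns(fit.design, t))
    cols = sorted(set(cols))
    X = fit.design.to_numpy(dtype=float)[:, cols]
    bd = fit.beta_d[:, cols]
    bc = np.where(np.isfinite(fit.beta_c), fit.beta_c, 0.0)[:, cols]
    z_hat = _expit(X @ bd.T)
    y_hat = X @ bc.T
    scores = assay.values - z_hat * y_hat
    return pd.DataFrame(scores, index=assay.cell_ids, columns=assay.gene_ids)


def module_scores(gene_scores: pd.DataFrame, collection) -> pd.DataFrame:
    """Per-cell module scores: plain mean of member-gene scores.

    Modules are intersected with the scored gene universe; duplicate
    listings are collapsed and empty modules dropped with a warning.
    """
    universe = set(gene_scores.columns)
    out = {}
    for name, members in collection.sets.items():
        genes = [g for g in dict.fromkeys(members) if g in universe]
        if not genes:
            warnings.warn(f"module {name!r} has no genes in the fitted universe; dropped")
            continue
        out[name] = gene_scores[genes].mean(axis=1)
    return pd.DataFrame(out, index=gene_scores.index)


def residual_correlation(
    residuals: ResidualMatrix,
    genes: list[str] | None = None,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson correlation of combined residuals between gene pairs.

    Computed per cell group (one group when ``groups`` is None); returns a
    long table (gene1, gene2, group, rho, p, p_adj) with two-sided
    t-approximation p-values, BH-adjusted across all pairs in the output.
    Zero-variance genes within a group yield missing correlations.
    """
    from .testing import bh_adjust

    if genes is None:
        genes = residuals.gene_ids
    gidx = [residuals.gene_ids.index(g) for g in genes]
    R = residuals.combined[:, gidx]
    if groups is None:
        groups = np.zeros(R.shape[0], dtype=int)
    groups = np.asarray(groups)
    rows = []
    for lev in pd.unique(groups):
        sub = R[groups == lev]
        n = sub.shape[0]
        if n < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 cells")
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(sub, rowvar=False)
        C[np.ix_(sd == 0, range(len(genes)))] = np.nan
        C[np.ix_(range(len(genes)), np.flatnonzero(sd == 0))] = np.nan
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                rho = C[a, b]
                if np.isfinite(rho):
                    r = min(abs(rho), 1 - 1e-12)
                    t = r * np.sqrt((n - 2) / (1 - r * r))
                    pv = 2.0 * stats.t.sf(t, n - 2)
                else:
                    pv = np.nan
                rows.append((genes[a], genes[b], lev, rho, pv))
    out = pd.DataFrame(rows, columns=["gene1", "gene2", "group", "rho", "p"])
    padj = np.full(len(out), np.nan)
    finite = out["p"].notna().to_numpy()
    if finite.any():
        padj[finite] = bh_adjust(out.loc[finite, "p"].to_numpy())
    out["p_adj"] = padj
    return out


def residual_pca(
    residuals: ResidualMatrix, genes: list[str] | None = None, k: int = 2
):
    """Centered PCA of combined residuals over a gene subset.

    Returns ``(coordinates, loadings, explained_variance_ratio)`` with a
    deterministic sign convention: each loading vector's largest-magnitude
    entry is positive.  ``k`` beyond the matrix rank is truncated with a
    warning.
    """
    from sklearn.decomposition import PCA

    if genes is None:
        genes = residuals.gene_ids
    gidx = [residuals.gene_ids.index(g) for g in genes]
    M = residuals.combined[:, gidx]
    max_k = min(M.shape)
    if k > max_k:
        warnings.warn(f"k={k} exceeds max rank {max_k}; truncated")
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(M)
    loadings = pca.components_.T  # genes x k
    for j in range(k):
        top = np.argmax(np.abs(loadings[:, j]))
        if loadings[top, j] < 0:
            loadings[:, j] *= -1.0
            coords[:, j] *= -1.0
    coords_df = pd.DataFrame(
        coords, index=residuals.cell_ids, columns=[f"PC{j+1}" for j in range(k)]
    )
    load_df = pd.DataFrame(loadings, index=genes, columns=coords_df.columns)
    return coords_df, load_df, pca.explained_variance_ratio_
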