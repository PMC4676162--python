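"""Per-gene two-part (hurdle) model fitting.

Each gene g is modeled with two conditionally independent regressions on a
shared design matrix X:

    logit Pr(Z_ig = 1)        = X_i beta_g^D      (detection, logistic)
    Y_ig | Z_ig = 1  ~  Normal(X_i beta_g^C, sigma_g^2)   (level, Gaussian)

The discrete component is regularized with independent Student-t priors on
the coefficients (Cauchy by default) so that estimates stay finite under
complete or quasi-complete separation; predictors are internally centered
and scaled to sd 0.5 before the prior is applied, and estimates are mapped
back to the original scale.  The continuous component is ordinary least
squares on the expressed cells only, with an unbiased residual-variance
denominator (n_expressed - p) so that downstream empirical-Bayes shrinkage
can reason in residual degrees of freedom.

All genes are fitted simultaneously with batched Newton/least-squares
linear algebra; the public single-gene functions are thin wrappers over the
same engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionAssay

__all__ = [
    "FitSettings",
    "GeneFit",
    "HurdleFit",
    "fit_discrete",
    "fit_continuous",
    "fit_all",
]

_ETA_CAP = 30.0  # linear-predictor clamp; keeps exp() finite under separation


@dataclass(frozen=True)
class FitSettings:
    """Regularization and numeric tolerances for hurdle fitting.

    ``prior_scale``/``prior_df`` parameterize the Student-t prior on
    non-intercept discrete coefficients after standardizing predictors to
    sd 0.5 (df 1 makes it Cauchy); the intercept gets a wider scale.
    ``use_prior=False`` gives the unpenalized logistic MLE.
    """

    use_prior: bool = True
    prior_scale: float = 2.5
    prior_df: float = 1.0
    intercept_scale: float = 10.0
    intercept_df: float = 1.0
    tol: float = 1e-8
    max_iter: int = 100


@dataclass
class GeneFit:
    """Single-gene paired regression results (views into a :class:`HurdleFit`)."""

    gene_id: str
    beta_d: np.ndarray
    beta_c: np.ndarray
    sigma2: float
    df_resid_c: int
    n_expressed: int
    cov_d: np.ndarray
    cov_c: np.ndarray
    converged_d: bool
    converged_c: bool
    degenerate_d: bool
    loglik_d: float
    loglik_c: float


class HurdleFit:
    """Collection of per-gene hurdle fits sharing one design matrix.

    Stores results as dense arrays (genes x terms) for speed; use
    :meth:`gene_fit` for a per-gene view.  ``sigma2`` uses the unbiased
    denominator; ``sigma2_shrunk`` is populated by the shrinkage step and
    falls back to the raw estimate until then.
    """

    def __init__(
        self,
        gene_ids: list[str],
        design: pd.DataFrame,
        settings: FitSettings,
        beta_d: np.ndarray,
        cov_d: np.ndarray,
        loglik_d: np.ndarray,
        converged_d: np.ndarray,
        degenerate_d: np.ndarray,
        beta_c: np.ndarray,
        cov_c: np.ndarray,
        sigma2: np.ndarray,
        ssr: np.ndarray,
        df_resid_c: np.ndarray,
        n_expressed: np.ndarray,
        loglik_c: np.ndarray,
        rank_c: np.ndarray,
    ) -> None:
        self.gene_ids = list(gene_ids)
        self.design = design
        self.settings = settings
        self.beta_d = beta_d
        self.cov_d = cov_d
        self.loglik_d = loglik_d
        self.converged_d = converged_d
        self.degenerate_d = degenerate_d
        self.beta_c = beta_c
        self.cov_c = cov_c
        self.sigma2 = sigma2
        self.ssr = ssr
        self.df_resid_c = df_resid_c
        self.n_expressed = n_expressed
        self.loglik_c = loglik_c
        self.rank_c = rank_c
        self.sigma2_shrunk: np.ndarray | None = None
        self.shrinkage_prior = None  # set by shrinkage.shrink_fit

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def p(self) -> int:
        return self.design.shape[1]

    def sigma2_effective(self) -> np.ndarray:
        """Shrunken residual variance when available, raw otherwise."""
        if self.sigma2_shrunk is not None:
            return self.sigma2_shrunk
        return self.sigma2

    def cov_c_effective(self) -> np.ndarray:
        """Continuous coefficient covariance rescaled by the shrunken variance."""
        if self.sigma2_shrunk is None:
            return self.cov_c
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = self.sigma2_shrunk / self.sigma2
        scale = np.where(np.isfinite(scale), scale, 1.0)
        return self.cov_c * scale[:, None, None]

    def gene_fit(self, gene: str) -> GeneFit:
        g = self.gene_ids.index(gene)
        return GeneFit(
            gene_id=gene,
            beta_d=self.beta_d[g],
            beta_c=self.beta_c[g],
            sigma2=float(self.sigma2[g]),
            df_resid_c=int(self.df_resid_c[g]),
            n_expressed=int(self.n_expressed[g]),
            cov_d=self.cov_d[g],
            cov_c=self.cov_c[g],
            converged_d=bool(self.converged_d[g]),
            converged_c=True,
            degenerate_d=bool(self.degenerate_d[g]),
            loglik_d=float(self.loglik_d[g]),
            loglik_c=float(self.loglik_c[g]),
        )

    def coefficient_table(self) -> pd.DataFrame:
        """Long-format coefficient table (gene, component, term, estimate, se)."""
        terms = list(self.design.columns)
        rows = []
        for g, gene in enumerate(self.gene_ids):
            for j, t in enumerate(terms):
                rows.append((gene, "D", t, self.beta_d[g, j], np.sqrt(self.cov_d[g, j, j])))
                se_c = np.sqrt(self.cov_c[g, j, j]) if np.isfinite(self.cov_c[g, j, j]) else np.nan
                rows.append((gene, "C", t, self.beta_c[g, j], se_c))
        return pd.DataFrame(rows, columns=["gene", "component", "term", "estimate", "se"])


# ---------------------------------------------------------------------------
# discrete component: batched penalized logistic regression
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray):
    """Center non-intercept columns and scale them to sd 0.5.

    Returns the standardized matrix and the linear map T with
    beta_original = T @ beta_standardized.
    """
    n, p = X.shape
    is_intercept = np.array([np.allclose(X[:, j], X[0, j]) for j in range(p)])
    means = np.where(is_intercept, 0.0, X.mean(axis=0))
    sds = X.std(axis=0)
    scales = np.where(is_intercept | (sds < 1e-12), 1.0, 2.0 * sds)
    Xs = (X - means) / scales
    T = np.diag(1.0 / scales)
    if is_intercept.any():
        i0 = int(np.argmax(is_intercept))
        Xs[:, i0] = X[:, i0]
        T[i0, i0] = 1.0
        for j in range(p):
            if j != i0:
                T[i0, j] = -means[j] / scales[j]
    return Xs, T, is_intercept


def _binom_loglik(eta: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Column-wise Bernoulli log-likelihood for linear predictors eta (n x G)."""
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    return (Z * eta - np.log1p(np.exp(eta))).sum(axis=0)


def _logistic_batch(X: np.ndarray, Z: np.ndarray, settings: FitSettings):
    """Fit penalized logistic regressions for all genes at once.

    Parameters
    ----------
    X : (n, p) design matrix.
    Z : (n, G) binary detection matrix (one column per gene).

    Returns (beta, cov, loglik, converged, degenerate) in original scale.
    The optimizer maximizes the Bernoulli log-likelihood plus independent
    Student-t log-prior terms via an MM scheme: at each iterate the t prior
    is replaced by its normal (ridge) surrogate with precision
    (nu+1)/(nu*s^2 + beta^2), giving damped Newton steps whose fixed point
    is a stationary point of the exact penalized objective.
    """
    n, p = X.shape
    G = Z.shape[1]
    Z = np.asarray(Z, dtype=float)
    Xs, T, is_intercept = _standardize(X)

    if settings.use_prior:
        s = np.full(p, settings.prior_scale)
        nu = np.full(p, settings.prior_df)
        s[is_intercept] = settings.intercept_scale
        nu[is_intercept] = settings.intercept_df
    else:
        s = nu = None

    zbar = Z.mean(axis=0)
    degenerate = (zbar == 0.0) | (zbar == 1.0)
    B = np.zeros((G, p))
    if is_intercept.any():
        i0 = int(np.argmax(is_intercept))
        B[:, i0] = np.log(np.clip(zbar, 1e-3, 1 - 1e-3) / np.clip(1 - zbar, 1e-3, 1 - 1e-3))

    def log_prior(Bm: np.ndarray) -> np.ndarray:
        if s is None:
            return np.zeros(Bm.shape[0])
        return (-(nu + 1) / 2.0 * np.log1p(Bm**2 / (nu * s**2))).sum(axis=1)

    def objective(Bm: np.ndarray, cols: np.ndarray | slice = slice(None)) -> np.ndarray:
        return _binom_loglik(Xs @ Bm.T, Z[:, cols]) + log_prior(Bm)

    obj = objective(B)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)
    for _ in range(settings.max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Ba = B[idx]
        eta = np.clip(Xs @ Ba.T, -_ETA_CAP, _ETA_CAP)  # (n, m)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = (Xs.T @ (Z[:, idx] - mu)).T  # (m, p)
        H = np.einsum("nm,np,nq->mpq", W, Xs, Xs)
        if s is not None:
            lam = (nu + 1) / (nu * s**2 + Ba**2)  # (m, p)
            grad -= lam * Ba
            H = H + lam[:, :, None] * np.eye(p)[None, :, :]
        else:
            H = H + 1e-10 * np.eye(p)[None, :, :]
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        # backtracking line search, vectorized over genes
        t_step = np.ones(len(idx))
        new_obj = np.full(len(idx), -np.inf)
        pending = np.ones(len(idx), dtype=bool)
        Bnew = Ba.copy()
        for _half in range(25):
            trial = Ba[pending] + t_step[pending, None] * step[pending]
            otrial = objective(trial, idx[pending])
            ok = otrial >= obj[idx][pending] - 1e-12
            sel = np.flatnonzero(pending)
            Bnew[sel[ok]] = trial[ok]
            new_obj[sel[ok]] = otrial[ok]
            pending[sel[ok]] = False
            t_step[pending] *= 0.5
            if not pending.any():
                break
        # genes still pending made no progress; freeze them
        new_obj[pending] = obj[idx][pending]
        rel = np.abs(new_obj - obj[idx]) / (np.abs(obj[idx]) + 1e-12)
        B[idx] = Bnew
        obj[idx] = new_obj
        # require both a flat objective and a vanishing penalized gradient,
        # so slow MM tails near the optimum do not stop early
        eta2 = np.clip(Xs @ Bnew.T, -_ETA_CAP, _ETA_CAP)
        mu2 = 1.0 / (1.0 + np.exp(-eta2))
        g2 = (Xs.T @ (Z[:, idx] - mu2)).T
        if s is not None:
            g2 -= (nu + 1) * Bnew / (nu * s**2 + Bnew**2)
        done = (rel < settings.tol) & (np.abs(g2).max(axis=1) < 1e-8)
        converged[idx[done]] = True
        active[idx[done]] = False

    # covariance: negative inverse Hessian of the penalized objective at the
    # optimum; if the exact t-prior curvature is not positive definite for a
    # gene, fall back to the PSD ridge surrogate.
    eta = np.clip(Xs @ B.T, -_ETA_CAP, _ETA_CAP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    H0 = np.einsum("ng,np,nq->gpq", W, Xs, Xs)
    if s is not None:
        curv = (nu + 1) * (nu * s**2 - B**2) / (nu * s**2 + B**2) ** 2
        H = H0 + curv[:, :, None] * np.eye(p)[None, :, :]
        bad = np.linalg.eigvalsh(H)[:, 0] <= 1e-10
        if bad.any():
            lam = (nu + 1) / (nu * s**2 + B**2)
            H[bad] = H0[bad] + lam[bad][:, :, None] * np.eye(p)[None, :, :]
    else:
        H = H0 + 1e-10 * np.eye(p)[None, :, :]
    cov_s = np.linalg.inv(H)
    beta = B @ T.T
    cov = np.einsum("ij,gjk,lk->gil", T, cov_s, T)
    loglik = _binom_loglik(np.clip(X @ beta.T, -_ETA_CAP, _ETA_CAP), Z)
    return beta, cov, loglik, converged, degenerate


def fit_discrete(
    z: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    prior_scale: float | None = 2.5,
    settings: FitSettings | None = None,
):
    """Fit the detection (logistic) component for one gene.

    ``prior_scale=None`` (or 0) disables the prior and returns the
    unpenalized MLE.  Returns ``(beta_d, cov_d, loglik_d, converged_d)``;
    degenerate detection patterns (all 0 or all 1) still yield finite
    coefficients, with the degenerate flag exposed through :func:`fit_all`.
    """
    Xm = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=float).reshape(-1, 1)
    if settings is None:
        if prior_scale is None or prior_scale == 0:
            settings = FitSettings(use_prior=False)
        else:
            settings = FitSettings(prior_scale=float(prior_scale))
    beta, cov, loglik, conv, _deg = _logistic_batch(Xm, z, settings)
    return beta[0], cov[0], float(loglik[0]), bool(conv[0])


# ---------------------------------------------------------------------------
# continuous component: batched conditional least squares
# ---------------------------------------------------------------------------


def _ols_batch(X: np.ndarray, Y: np.ndarray, Z: np.ndarray):
    """Least squares of Y on X restricted to rows with Z = 1, per gene.

    Implemented as weighted least squares with 0/1 weights so every gene is
    solved in one batched operation.  Genes whose expressed-subset design is
    singular (too few expressed cells, or collinearity within the subset)
    are re-solved with a pseudo-inverse and their rank recorded.
    """
    n, p = X.shape
    G = Y.shape[1]
    Zf = np.asarray(Z, dtype=float)
    Yw = Y * Zf
    XtWX = np.einsum("ng,np,nq->gpq", Zf, X, X)
    XtWy = np.einsum("ng,np->gp", Yw, X)
    n_expr = Zf.sum(axis=0).astype(int)

    beta = np.zeros((G, p))
    xtx_inv = np.full((G, p, p), np.nan)
    rank = np.zeros(G, dtype=int)
    eigs = np.linalg.eigvalsh(XtWX)
    ok = (eigs[:, 0] > 1e-9 * np.maximum(eigs[:, -1], 1.0)) & (n_expr >= p)
    if ok.any():
        beta[ok] = np.linalg.solve(XtWX[ok], XtWy[ok][:, :, None])[:, :, 0]
        xtx_inv[ok] = np.linalg.inv(XtWX[ok])
        rank[ok] = p
    for g in np.flatnonzero(~ok & (n_expr > 0)):
        beta[g] = np.linalg.pinv(XtWX[g], rcond=1e-9) @ XtWy[g]
        rank[g] = np.linalg.matrix_rank(XtWX[g], tol=1e-9)

    resid = (Y - X @ beta.T) * Zf
    ssr = np.einsum("ng,ng->g", resid, resid)
    df = np.maximum(n_expr - rank, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = np.where(df >= 1, ssr / np.maximum(df, 1), np.nan)
        # profile Gaussian log-likelihood at the variance MLE ssr/n
        s2_mle = np.where(n_expr > 0, ssr / np.maximum(n_expr, 1), np.nan)
        loglik = np.where(
            n_expr > 0,
            -0.5 * n_expr * (np.log(2 * np.pi * np.maximum(s2_mle, 1e-300)) + 1.0),
            0.0,
        )
    cov = xtx_inv * np.where(np.isfinite(sigma2), sigma2, np.nan)[:, None, None]
    return beta, cov, sigma2, ssr, df, n_expr, loglik, rank


def fit_continuous(y: np.ndarray, z: np.ndarray, X: np.ndarray | pd.DataFrame):
    """Fit the level (Gaussian) component for one gene on its expressed cells.

    Returns ``(beta_c, cov_c, sigma2, df_resid_c, loglik_c)``.  The residual
    variance uses the unbiased denominator ``n_expressed - rank``; with no
    expressed cells the continuous part is absent (all-NaN coefficients); with
    ``n_expressed <= p`` the variance is undefined (NaN) and downstream code
    relies entirely on shrinkage.
    """
    Xm = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    z = np.asarray(z).reshape(-1, 1)
    beta, cov, sigma2, ssr, df, n_expr, loglik, rank = _ols_batch(Xm, y, z)
    if n_expr[0] == 0:
        beta = np.full_like(beta, np.nan)
    return beta[0], cov[0], float(sigma2[0]), int(df[0]), float(loglik[0])


# ---------------------------------------------------------------------------
# whole-assay driver
# ---------------------------------------------------------------------------


def fit_all(
    assay: ExpressionAssay,
    design: pd.DataFrame,
    settings: FitSettings | None = None,
) -> HurdleFit:
    """Fit the hurdle model independently for every gene in the assay.

    Genes with zero expressed cells are retained (continuous part absent,
    flagged) so downstream indexing never silently drops genes.
    """
    settings = settings or FitSettings()
    X = design.to_numpy(dtype=float)
    if X.shape[0] != assay.n_cells:
        raise ValueError(
            f"design has {X.shape[0]} rows but assay has {assay.n_cells} cells"
        )
    Z = assay.detection
    Y = assay.values
    beta_d, cov_d, ll_d, conv_d, degen = _logistic_batch(X, Z, settings)
    beta_c, cov_c, sigma2, ssr, df, n_expr, ll_c, rank = _ols_batch(X, Y, Z)
    beta_c[n_expr == 0] = np.nan
    return HurdleFit(
        gene_ids=assay.gene_ids,
        design=design,
        settings=settings,
        beta_d=beta_d,
        cov_d=cov_d,
        loglik_d=ll_d,
        converged_d=conv_d,
        degenerate_d=degen,
        beta_c=beta_c,
        cov_c=cov_c,
        sigma2=sigma2,
        ssr=ssr,
        df_resid_c=df,
        n_expressed=n_expr,
        loglik_c=ll_c,
        rank_c=rank,
    )
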