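"""Differential-expression inference for the hurdle model.

Because the detection and level components are conditionally independent,
their test statistics (likelihood-ratio or Wald, each asymptotically
chi-square) can be summed and remain asymptotically chi-square with the
component degrees of freedom added.  The continuous-component tests use the
empirical-Bayes shrunken variance.  Gene-level p-values are adjusted with
the Benjamini-Hochberg FDR procedure, and a gene is called differentially
expressed when the adjusted p-value falls below ``fdr_cut`` (default 0.01)
and the absolute log2 fold-change exceeds ``logfc_cut`` (default log2 1.5).

The fold-change is defined on the unconditional mean scale,
E[Y] = Pr(Z=1) * E[Y | Z=1], evaluated at the two contrast levels with every
other covariate (including the CDR) held at its observed mean; this makes
the discrete and continuous effects commensurable on the log2 expression
scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import DesignSpec, ExpressionAssay, build_design, term_columns
from .hurdle import FitSettings, HurdleFit, fit_all
from .shrinkage import shrink_fit

__all__ = [
    "component_tests",
    "combine_tests",
    "bh_adjust",
    "call_de",
    "estimate_logfc",
    "de_test",
    "deviance_decomposition",
]

DEFAULT_FDR_CUT = 0.01
DEFAULT_LOGFC_CUT = float(np.log2(1.5))


def _check_nested(full: HurdleFit, reduced: HurdleFit) -> None:
    full_cols = set(full.design.columns)
    red_cols = set(reduced.design.columns)
    if not red_cols < full_cols:
        raise ValueError(
            "designs are not nested: reduced must be the full design minus the "
            "tested term's columns"
        )


def component_tests(
    fit_full: HurdleFit,
    fit_reduced: HurdleFit,
    method: str = "lrt",
    term: str | None = None,
) -> pd.DataFrame:
    """Per-gene discrete and continuous test statistics for a dropped term.

    LRT: twice the component log-likelihood difference, floored at 0.  The
    continuous likelihood is evaluated with the full model's shrunken
    variance as a fixed plug-in for both fits, so the statistic reduces to
    (SSR_reduced - SSR_full) / sigma2_shrunk.  Wald: quadratic form of the
    term's coefficients against their covariance (shrunken for the
    continuous part).  Degenerate discrete fits (all-0/all-1 detection) and
    absent continuous fits contribute statistic 0 while their df still
    counts — a conservative convention.
    """
    _check_nested(fit_full, fit_reduced)
    G = fit_full.n_genes
    df_term = fit_full.p - fit_reduced.p
    if df_term <= 0:
        raise ValueError("full design has no columns beyond the reduced design")

    if method == "lrt":
        chisq_d = np.maximum(2.0 * (fit_full.loglik_d - fit_reduced.loglik_d), 0.0)
        s2 = fit_full.sigma2_effective()
        s2 = np.where(np.isfinite(s2) & (s2 > 0), s2, np.nan)
        with np.errstate(invalid="ignore"):
            chisq_c = np.maximum((fit_reduced.ssr - fit_full.ssr) / s2, 0.0)
        chisq_c = np.where(np.isfinite(chisq_c), chisq_c, 0.0)
    elif method == "wald":
        if term is None:
            raise ValueError("Wald tests require the tested term's name")
        cols = term_columns(fit_full.design, term)
        if len(cols) != df_term:
            raise ValueError(
                f"term {term!r} spans {len(cols)} columns but designs differ by {df_term}"
            )
        chisq_d = _wald_quadform(fit_full.beta_d, fit_full.cov_d, cols)
        chisq_c = _wald_quadform(fit_full.beta_c, fit_full.cov_c_effective(), cols)
    else:
        raise ValueError(f"unknown test method {method!r}")

    chisq_d = np.where(fit_full.degenerate_d, 0.0, chisq_d)
    chisq_c = np.where(fit_full.n_expressed == 0, 0.0, chisq_c)
    return pd.DataFrame(
        {
            "gene": fit_full.gene_ids,
            "chisq_d": chisq_d,
            "df_d": np.full(G, df_term),
            "chisq_c": chisq_c,
            "df_c": np.full(G, df_term),
        }
    )


def _wald_quadform(beta: np.ndarray, cov: np.ndarray, cols: list[int]) -> np.ndarray:
    b = beta[:, cols]
    V = cov[np.ix_(range(beta.shape[0]), cols, cols)]
    out = np.zeros(beta.shape[0])
    for g in range(beta.shape[0]):
        bg, Vg = b[g], V[g]
        if not (np.isfinite(bg).all() and np.isfinite(Vg).all()):
            continue
        if np.allclose(bg, 0.0):
            continue
        try:
            out[g] = float(bg @ np.linalg.solve(Vg, bg))
        except np.linalg.LinAlgError:
            out[g] = 0.0
    return np.maximum(out, 0.0)


def combine_tests(
    chisq_d: np.ndarray, df_d: np.ndarray, chisq_c: np.ndarray, df_c: np.ndarray
):
    """Sum component chi-square statistics and their degrees of freedom.

    Returns ``(chisq_comb, df_comb, p_comb)``; a combined df of 0 yields
    p = 1 (nothing was testable for that gene).
    """
    chisq_d = np.asarray(chisq_d, dtype=float)
    chisq_c = np.asarray(chisq_c, dtype=float)
    if (chisq_d < 0).any() or (chisq_c < 0).any():
        raise ValueError("chi-square statistics must be non-negative")
    df_d = np.asarray(df_d)
    df_c = np.asarray(df_c)
    chisq = chisq_d + chisq_c
    df = df_d + df_c
    p = np.ones_like(chisq, dtype=float)
    pos = df > 0
    p[pos] = stats.chi2.sf(chisq[pos], df[pos])
    return chisq, df, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def estimate_logfc(
    fit: HurdleFit,
    term: str,
    contrast: tuple[float, float] = (1.0, 0.0),
) -> pd.DataFrame:
    """Model-based log2 fold-change between two levels of a design term.

    The term must resolve to a single design column (for a dummy-coded
    factor, pass the specific column, e.g. ``"treatment[stim]"``).
    ``contrast = (high, low)`` gives the column values to compare (the dummy
    default 1 vs 0 compares the coded level to the reference).  All other
    columns sit at their observed means.  Components decompose the total
    as a discrete part (change in detection probability at the average
    level) plus a continuous part (change in level at the average detection
    probability), which sum exactly to the total.
    """
    cols = term_columns(fit.design, term)
    if len(cols) != 1:
        raise ValueError(
            f"fold-change needs a single-column term; {term!r} spans {len(cols)} "
            "columns — pass one dummy column explicitly"
        )
    j = cols[0]
    xbar = fit.design.to_numpy(dtype=float).mean(axis=0)
    x_hi, x_lo = xbar.copy(), xbar.copy()
    x_hi[j], x_lo[j] = contrast
    beta_c = np.where(np.isfinite(fit.beta_c), fit.beta_c, 0.0)
    p_hi = _expit(fit.beta_d @ x_hi)
    p_lo = _expit(fit.beta_d @ x_lo)
    m_hi = beta_c @ x_hi
    m_lo = beta_c @ x_lo
    logfc = p_hi * m_hi - p_lo * m_lo
    disc = (p_hi - p_lo) * (m_hi + m_lo) / 2.0
    cont = (p_hi + p_lo) / 2.0 * (m_hi - m_lo)
    return pd.DataFrame(
        {"gene": fit.gene_ids, "logfc": logfc, "logfc_disc": disc, "logfc_cont": cont}
    )


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def call_de(
    result: pd.DataFrame,
    fdr_cut: float = DEFAULT_FDR_CUT,
    logfc_cut: float = DEFAULT_LOGFC_CUT,
) -> pd.DataFrame:
    """Flag differentially expressed genes: p_adj < fdr_cut and |logfc| > logfc_cut."""
    out = result.copy()
    out["is_de"] = (out["p_adj"] < fdr_cut) & (out["logfc"].abs() > logfc_cut)
    return out


def de_test(
    assay: ExpressionAssay,
    spec: DesignSpec,
    term: str,
    method: str = "lrt",
    settings: FitSettings | None = None,
    fdr_cut: float = DEFAULT_FDR_CUT,
    logfc_cut: float = DEFAULT_LOGFC_CUT,
    contrast: tuple[float, float] = (1.0, 0.0),
    shrink: bool = True,
):
    """End-to-end differential-expression test for one design term.

    Fits the full and term-dropped hurdle models, applies variance
    shrinkage, combines the component chi-square tests, BH-adjusts across
    genes, estimates fold-changes, and applies the DE call.  Returns
    ``(results_table, fit_full)``.
    """
    design_full = build_design(spec, assay)
    design_red = build_design(spec.drop_term(term), assay)
    fit_full = fit_all(assay, design_full, settings)
    fit_red = fit_all(assay, design_red, settings)
    if shrink:
        shrink_fit(fit_full)
    # resolve a multi-column term to its single dummy column when unambiguous
    cols = term_columns(design_full, term)
    fc_term = term if len(cols) == 1 else design_full.columns[cols[0]]
    comp = component_tests(fit_full, fit_red, method=method, term=fc_term)
    chisq, df, p = combine_tests(
        comp["chisq_d"], comp["df_d"], comp["chisq_c"], comp["df_c"]
    )
    fc = estimate_logfc(fit_full, fc_term, contrast)
    res = comp.assign(
        chisq=chisq,
        df=df,
        p=p,
        p_adj=bh_adjust(p),
        logfc=fc["logfc"].to_numpy(),
        logfc_disc=fc["logfc_disc"].to_numpy(),
        logfc_cont=fc["logfc_cont"].to_numpy(),
    )
    return call_de(res, fdr_cut, logfc_cut), fit_full


def deviance_decomposition(
    assay: ExpressionAssay,
    spec: DesignSpec,
    term: str,
    settings: FitSettings | None = None,
) -> pd.DataFrame:
    """Fraction of model deviance attributable to one design term, per gene.

    Fits the full, term-dropped, and intercept-only models and reports

        fraction = (deviance(dropped) - deviance(full)) / deviance(null)

    per component and combined.  Discrete deviance is the binomial deviance
    (saturated Bernoulli log-likelihood is 0); continuous deviance is
    SSR / sigma2_shrunk with the full model's shrunken variance as the common
    scale.  Genes with zero null deviance get fraction 0 and a flag.
    """
    design_full = build_design(spec, assay)
    fit_full = fit_all(assay, design_full, settings)
    shrink_fit(fit_full)
    dropped_spec = spec.drop_term(term)
    fit_drop = fit_all(assay, build_design(dropped_spec, assay), settings)
    null_spec = DesignSpec(spec.covariates, [], include_cdr=False)
    fit_null = fit_all(assay, build_design(null_spec, assay), settings)

    s2 = fit_full.sigma2_effective()
    s2 = np.where(np.isfinite(s2) & (s2 > 0), s2, np.nan)

    def dev_d(f: HurdleFit) -> np.ndarray:
        return -2.0 * f.loglik_d

    def dev_c(f: HurdleFit) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            d = f.ssr / s2
        return np.where(np.isfinite(d), d, 0.0)

    rows = {}
    for label, dev in (("d", dev_d), ("c", dev_c)):
        d_full, d_drop, d_null = dev(fit_full), dev(fit_drop), dev(fit_null)
        num = np.maximum(d_drop - d_full, 0.0)
        rows[f"num_{label}"] = num
        rows[f"null_{label}"] = d_null
    num_comb = rows["num_d"] + rows["num_c"]
    null_comb = rows["null_d"] + rows["null_c"]

    def frac(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            f = num / den
        return np.where(den > 0, f, 0.0)

    return pd.DataFrame(
        {
            "gene": fit_full.gene_ids,
            "frac_d": frac(rows["num_d"], rows["null_d"]),
            "frac_c": frac(rows["num_c"], rows["null_c"]),
            "frac_comb": frac(num_comb, null_comb),
            "null_deviance_zero": null_comb <= 0,
        }
    )
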