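# schurdle

Hurdle-model analysis of single-cell RNA-seq expression: differential
expression with cellular-detection-rate (CDR) adjustment, empirical-Bayes
variance shrinkage, bootstrap competitive gene-set enrichment, and
residual-based co-expression analysis — plus a generative simulator with the
same statistical structure.

## The problem and the model

Single-cell expression measured on the log₂(TPM + 1) scale is strongly
bimodal: a gene is either undetected in a cell (exact zero) or detected at a
roughly Gaussian positive level.  Treating such data with a single
continuous model conflates two distinct signals — *whether* a gene turns on
and *how much* it is expressed when on.  schurdle fits, independently per
gene *g*, a two-part generalized linear model on a shared design matrix
**X**:

    logit Pr(Z_ig = 1)          = X_i β_g^D            (detection, logistic)
    Y_ig | Z_ig = 1  ~  N(X_i β_g^C, σ_g²)             (level, Gaussian)

where `z_ig = 1[y_ig > threshold]`.  Cells differ globally in the fraction
of genes they express — the **cellular detection rate**,
`CDR_i = (1/N) Σ_g z_ig` — a proxy for cell volume and technical efficiency.
The CDR enters both components as a covariate, so global nuisance variation
is estimated jointly with the treatment effects instead of contaminating
them.

On top of the per-gene fits the package provides:

- **Regularized logistic estimation** (Student-t/Cauchy coefficient priors
  on standardized predictors) so estimates stay finite under complete
  separation — routine in sparse single-cell data.
- **Empirical-Bayes variance shrinkage**: gene precisions `τ_g² = 1/σ_g²`
  get a Gamma(α, β) prior fitted by marginal maximum likelihood across
  genes; the shrunken precision `(α + df_g/2)/(β + ssr_g/2)` is a convex
  combination of the per-gene MLE and the common precision, equivalent to
  2α pseudo-observations with precision β/α.
- **Combined tests**: the discrete and continuous components are
  conditionally independent, so their χ² statistics (LRT or Wald) sum, with
  degrees of freedom added.  Genes are called differentially expressed at
  BH-FDR < 0.01 with model-based |log₂ fold-change| > log₂ 1.5.
- **Competitive GSEA** on model coefficients: a Z test of the set-average
  coefficient against the complement, with the sampling variance of each
  average including inter-gene covariances estimated by bootstrapping cells
  — the covariance terms are what keeps correlated gene modules from
  inflating significance.  Component Z scores combine by Stouffer's method.
- **Residuals and module scores**: standardized deviance residuals per
  component (averaged where both exist) for co-expression and PCA, and
  nuisance-corrected cell scores `s_ij = y_ij − ẑ_ij·ŷ_ij` averaged over
  gene modules.

## Worked example

```python
from schurdle import DesignSpec, SimScenario, de_test, simulate

scenario = SimScenario(
    n_cells=200, n_genes=300,
    disc_effect=0.8, cont_effect=0.8, frac_affected=0.25,
    seed=7,
)
assay, covariates, truth = simulate(scenario)
spec = DesignSpec(covariates, ["treatment"], include_cdr=True)
results, fit = de_test(assay, spec, "treatment")

print(f"DE genes at FDR<0.01 and |log2 FC|>log2(1.5): {results.is_de.sum()} / {len(results)}")
print(f"true effect genes recovered: {results.is_de[truth['affected']].sum()} / {truth['affected'].sum()}")
print(f"shrinkage prior: alpha={fit.shrinkage_prior.alpha:.2f}, beta={fit.shrinkage_prior.beta:.2f}")
print(results.sort_values("p_adj").head(5)[["gene", "chisq", "df", "p_adj", "logfc"]].to_string(index=False))
```

prints

```
DE genes at FDR<0.01 and |log2 FC|>log2(1.5): 42 / 300
true effect genes recovered: 41 / 75
shrinkage prior: alpha=4.05, beta=2.00
   gene     chisq  df        p_adj    logfc
gene222 55.663544   2 2.454349e-10 0.868160
gene164 50.167891   2 1.915456e-09 1.177451
 gene25 47.804873   2 4.162015e-09 0.875057
 gene73 43.701921   2 1.618894e-08 0.455449
gene183 43.973913   2 1.618894e-08 1.530902
```

Each gene's `chisq` is the sum of its detection and level χ² statistics
(2 df total here: one treatment coefficient per component); `logfc` is the
model-based difference in unconditional mean expression
`E[Y] = Pr(Z=1)·E[Y|Z=1]` between arms with other covariates at their means.
At this sample size the 41 of 42 calls that are true effect genes reflect
the FDR target; the fitted prior closely recovers the simulation's
Gamma(4, 2) precision distribution.

The same workflow is available from the shell:

```bash
schurdle simulate --n-cells 200 --n-genes 300 --cont-effect 0.8 \
    --frac-affected 0.25 --seed 7 --out sim/
schurdle de --matrix sim/matrix.csv --covariates sim/covariates.csv \
    --formula "treatment + cdr" --out de.csv
schurdle gsea --matrix sim/matrix.csv --covariates sim/covariates.csv \
    --gmt modules.gmt --term treatment --nboot 50 --seed 7 --out gsea.csv
```

(plus `fit`, `residuals`, `scores`, and a YAML-configured `run`).

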