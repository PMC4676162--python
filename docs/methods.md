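# Methods

## Model

Expression is a cells × genes matrix on the log₂(TPM + 1) scale.  A
detection indicator `z_ig = 1[y_ig > t]` is derived from a background
threshold `t` (default 0; thresholding never alters the stored values, only
detection status).  Per gene, two conditionally independent regressions
share one design matrix:

- **Detection** (discrete): `logit Pr(z_ig = 1) = X_i β_g^D`, Bernoulli
  logistic regression over all cells.
- **Level** (continuous): `y_ig | z_ig = 1 ~ N(X_i β_g^C, σ_g²)`, ordinary
  least squares over the expressed cells only.

Conditional independence means the two fits never exchange information;
values at unexpressed cells never enter the continuous fit.

The cellular detection rate `CDR_i = mean_g z_ig` summarizes global
per-cell detection; it proxies cell volume and capture efficiency and is
normally included as a covariate in both components (`include_cdr=True`).
Interpretation caveat: when a treatment genuinely shifts global detection,
the CDR is partly treatment-caused and CDR-adjusted treatment coefficients
answer "what would change if the CDR were held constant."  For unbiased
marginal treatment estimation the CDR can instead be used as a *precision
variable* — centered within the levels of a grouping factor
(`DesignSpec(center_cdr_by="treatment")`), which makes it orthogonal to the
treatment while still absorbing within-group size variation.  The recovery
experiment in the acceptance script uses this mode for exactly that reason.

## Estimation

**Discrete component.**  The Bernoulli log-likelihood is penalized with
independent Student-t log-priors on the coefficients: predictors are
internally centered and scaled to sd 0.5, then the prior has df 1 (Cauchy)
and scale 2.5 on non-intercept coefficients and df 1, scale 10 on the
intercept.  This keeps estimates finite under complete or quasi-complete
separation while being effectively flat where the data are informative.
Optimization is a damped Newton/MM scheme: at each iterate the t prior is
replaced by its normal surrogate with precision `(ν+1)/(νs² + β²)`, giving
PSD Hessians; a vectorized backtracking line search guarantees monotone
ascent, and convergence requires both a relative objective change below
1e-8 and a penalized-gradient sup-norm below 1e-8 (the MM tail is linear,
so the objective criterion alone can stop early), within 100 iterations.
All genes are fitted simultaneously with batched linear algebra.
Coefficient covariances come from the inverse penalized Hessian at the
optimum (exact t-prior curvature when positive definite, the MM surrogate
otherwise).  `use_prior=False` gives the unpenalized MLE.  Genes detected
in all or no cells are fitted (the prior keeps them finite) and flagged
degenerate.

**Continuous component.**  OLS on the expressed subset, implemented as 0/1
weighted least squares so all genes solve in one batched operation.
Residual variance uses the unbiased denominator `df_g = n_expressed − rank`
so that shrinkage can reason in residual degrees of freedom; singular
expressed-subset designs fall back to a pseudo-inverse with the rank
recorded.  No regularization of continuous coefficients.

**Variance shrinkage.**  With `ssr_g · τ_g ~ χ²_{df_g}` and
`τ_g ~ Gamma(α, β)`, the gene precision integrates out in closed form; the
summed marginal log-likelihood is maximized over `(log α, log β)` by
L-BFGS-B from a moment-matched start plus two perturbed restarts, bounded
to `[1e-6, 1e6]` on both parameters (outside that range the log-gamma
terms cancel catastrophically and the surface is numerically flat).  The
shrunken precision is the posterior mean `(α + df_g/2)/(β + ssr_g/2)`; genes
with `df = 0` receive exactly the prior mean `α/β`, so sparsely expressed
genes remain testable.  The continuous coefficient covariance used
downstream is rescaled by (shrunken variance / raw variance).

## Testing

Per tested term, the full and term-dropped models are fitted.  The
likelihood-ratio statistics are, per component: discrete, twice the
unpenalized log-likelihood difference at the fitted coefficients;
continuous, `(SSR_reduced − SSR_full)/σ²_shrunk` with the full model's
shrunken variance as a fixed plug-in (equivalently twice the Gaussian
log-likelihood difference at that common variance).  Both are floored at 0.
Wald tests (quadratic form of the term's coefficients against their
covariance, shrunken for the continuous part) are available for speed.
Degenerate discrete fits and absent continuous fits contribute statistic 0
while their df still counts — a conservative choice.  Component statistics
and df add; the combined p-value is the χ² upper tail.  BH adjustment is
applied across genes; the DE call requires `p_adj < 0.01` and model-based
`|log₂ FC| > log₂ 1.5` (both configurable).

**Fold-change** is defined on the unconditional mean
`E[Y] = Pr(Z=1)·E[Y|Z=1]`, evaluated at the two contrast levels with every
other covariate at its observed mean.  The reported components — discrete
`(p₁−p₀)(m₁+m₀)/2` and continuous `(p₁+p₀)(m₁−m₀)/2` — sum exactly to the
total.  This definition is a package decision (conditional-positive means
are the obvious alternative); it is used consistently by the DE gate.

**Deviance attribution.**  For a term of interest, the fraction
`(deviance(dropped) − deviance(full)) / deviance(null)` is reported per
gene and component, with binomial deviance for the discrete part and
`SSR/σ²_shrunk` for the continuous part on the full model's variance scale.

## Gene-set enrichment

For one tested coefficient, the set average θ̂ is compared with the
complement average θ̂₀ by `Z = (θ̂ − θ̂₀)/√(Var θ̂ + Var θ̂₀)`, where each
variance is `(1/m²)[Σ Var(β̂_g) + 2 Σ_{g<h} Cov(β̂_g, β̂_h)]` with variances
and covariances estimated from bootstrap replicates of the whole fit.
Bootstrap resampling draws cells with replacement, stratified within the
primary factor's levels so group sizes are preserved (default 50
replicates; a few dozen suffice for stable variances).  Covariances are
pairwise-complete over non-degenerate replicates with pair-specific means;
pairs sharing fewer than 3 replicates contribute 0.  Component Z scores
combine as `(z_D + z_C)/√2` (Stouffer, equal weights, no centering of
coefficients before averaging), rewarding consensus between detection and
level effects; p-values are two-sided normal with BH across sets.  An
asymptotic mode (model-based variances, zero covariances) is available for
exploration.

The tested universe excludes genes detected in fewer than 10% of cells
(default, configurable): for nearly undetected genes the bootstrap
coefficient variance is badly behaved (resampled refits rest on a handful
of cells) and inflates the dispersion of null Z scores.

## Residuals and scores

Deviance residuals are computed per component: discrete,
`sign(z − p̂)·√(unit binomial deviance)`, with the unit deviance capped at
75 when a numerically degenerate fitted probability disagrees with the
observation; continuous (expressed cells only), the raw residual over the
shrunken sd.  Standardization divides by `√(1 − leverage)` with each
component's own hat diagonals (the penalized Hessian for the logistic
part); an unstandardized mode is available.  The combined residual is the
unweighted mean of the available components — the discrete residual alone
when the cell does not express the gene.  Note Bernoulli deviance residuals
have nonzero expectation at skewed detection probabilities; only the
continuous residuals are mean-zero by construction.

Cell scores subtract the nuisance-only prediction:
`s_ij = y_ij − ẑ_ij·ŷ_ij` with both linear predictors restricted to the
intercept plus the declared nuisance terms (e.g. the CDR).  Module scores
are plain means of member-gene scores per cell.  Residual correlation is
Pearson over cells (per cell group), with t-approximation p-values and BH
across pairs; residual PCA is centered, with signs fixed so each loading
vector's largest-magnitude entry is positive.

## Simulator

The generator draws, per scenario: gene baselines `a_g ~ N(0, 1.5)` (logit)
and `m_g ~ N(6, 2)` (log₂ units) — chosen to produce realistic bimodality
and a wide spread of detection rates; precisions `τ_g ~ Gamma(4, 2)`
(residual sd ≈ 0.7 on the log₂ scale); a per-cell size factor with sd 0.5
entering both components with loading 1 (one global factor moving detection
and level together, the simplest mechanism consistent with the
cell-volume story); optional treatment–size correlation (`confound_rho`);
and an optional shared factor on the positive means of a gene subset
(`latent_corr_sd`, `latent_corr_frac`) to induce gene–gene correlation
unexplained by the design.  Detection and level are then drawn from the
model equations; positive draws are floored at 1e-6 so expressed values
clear the zero background (negative Gaussian draws are rare at these
baselines).  Everything is a pure function of the scenario including its
seed, and the truth record retains all latent quantities for recovery
tests.

What the simulator does *not* emulate: count-level noise (UMI/read
sampling), library-size normalization artifacts, batch structure, gene
length effects, or the zero-inflation patterns of droplet protocols.
Passing calibration and recovery tests therefore demonstrates correctness
of the estimation machinery under the model's own assumptions, not
robustness to real-data violations of them.

## Experiment sizes and design choices in the validation suite

- Null calibration: 300 genes × 200 cells, 100 random balanced
  relabelings; combined p-values pooled across splits for the uniformity
  check.
- Recovery/power: 200 genes × 500 cells, effects 0.8 (logit) and 0.8
  (log₂) on 25% of genes, CDR as a within-group-centered precision
  variable (see above).
- Combined-test null: 10⁴ independent null genes at 200 cells (one batched
  fit), compared with χ²₂.  The per-component χ²₁ check uses 500 cells and
  moderate detection rates because the binomial LRT's discreteness
  dominates the KS distance at smaller n regardless of implementation.
- GSEA: 300 genes × 200 cells, 30 bootstrap replicates, sets of 20.
  Calibration pools 1000 random sets across 5 independent datasets;
  the correlation-control comparison pools 30 independent datasets × 33
  sets, because the realized latent-factor draw of a single dataset
  dominates both quantities.  The factor loading 0.82 makes the pairwise
  residual correlation among module genes ≈ 0.5 — a strongly co-regulated
  module, the regime the covariance correction exists for.
- Confounding: 2000 genes × 200 cells, treatment–size correlation 0.5.
  The gene count matters: the CDR is a noisy size estimate when averaged
  over few genes, and the resulting attenuation leaves residual
  confounding; thousands of genes is the realistic operating condition.
- Residual co-expression: 40 genes × 200 cells with and without the global
  size factor.

## Known limitations

- The adaptive background-threshold rule (`estimate_threshold`, KDE trough
  below the main mode) is a labeled approximation; the default remains 0
  and detection calls are typically insensitive to the choice.
- Discrete-part LRTs use unpenalized log-likelihoods at the regularized
  estimates; under heavy prior influence (tiny n) they are conservative.
- The GSEA Z denominator omits the covariance between θ̂ and θ̂₀; when both
  sets load on a common factor the test is conservative rather than
  anti-conservative.
- No random-effects terms; one observation level (cells) only.
- Fold-changes require a single-column (binary or dummy) contrast; multi-df
  terms are tested but not summarized as one fold-change.
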