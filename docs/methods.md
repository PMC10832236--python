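# Methods

## Pipeline model

The package integrates K independent miRNA expression studies, each a
features × samples matrix with sample sex (female/male) and condition
(control/AD). The analysis is stratified throughout: effects are estimated
separately within each sex, and studies are integrated separately per
tissue (blood, brain), giving four meta-analyses.

### Preprocessing

Samples with conditions other than control/AD (e.g. MCI arms) are dropped,
as are samples with unknown sex — sex is the stratifying variable and
cannot be imputed. Feature ids are harmonized to mature miRBase-style ids
through a user-supplied two-column map; features without a mature mapping
(precursor-only probes) are removed. Duplicate feature ids are collapsed by
keeping the row with the highest mean expression across samples — row-level
retention preserves within-row covariance, whereas a per-cell max would
fabricate chimeric profiles; ties keep the first row in input order and are
logged. If a matrix minimum is negative the whole matrix is shifted up by
|min| so the minimum becomes exactly zero ("add the minimum" is read as the
shift that makes the non-negativity goal true); non-negative matrices are
not shifted, so logFCs are never distorted needlessly. Array matrices not
yet on the log scale get log2(x + 1); the +1 pseudocount keeps zero at zero
and the transform defined at 0. Counts are never log-transformed here.

### Per-study differential expression

One linear model per study, parameterized by the four group means
(control-F, AD-F, control-M, AD-M), with contrasts AD.F − Control.F and
AD.M − Control.M. A single model (rather than two per-sex fits) pools one
residual-variance estimate per study across all four groups; the contrast
estimates are identical either way. Groups with zero samples drop out of
the design and contrasts touching them are disabled for that study.

RNA-seq counts are transformed to log2-CPM with a 0.5 count offset and a
libsize + 1 denominator, and receive per-observation precision weights: the
residual √sd from an unweighted fit is smoothed against average log2-count
by lowess (span 0.5; a flat trend is used below 50 miRNAs, where the lowess
fit is unstable), the trend is evaluated at each observation's fitted
log-count, and the weight is that prediction to the power −4 (an inverse
predicted variance).

Residual variances are shrunk by empirical Bayes: s²_g ~ s₀²·F(d_g, d₀) is
assumed, and (d₀, s₀²) are estimated by matching the mean and variance of
log s²_g via digamma/trigamma identities, with the trigamma inverted by
Newton iteration. When the spread of log-variances does not exceed its
sampling spread the prior degrees of freedom are infinite (complete
shrinkage); if the inversion misbehaves on degenerate inputs the fallback
is a median-based prior (d₀ = 10, s₀² = median s²). Zero-variance miRNAs
are excluded from prior estimation and flagged in the output. Moderated
t-statistics use d₀ + d_g degrees of freedom, two-sided p-values, and
Benjamini–Hochberg adjustment within each study × contrast (so per-study
significant counts are meaningful on their own).

### Random-effects integration

Per tissue × sex, miRNAs observed in at least two studies are combined with
the DerSimonian–Laird moment estimator (formulas in the README). Inference
on the combined effect uses the normal approximation (z) with a 95% CI —
the standard form of the DL methodology; Knapp–Hartung adjustment is out of
scope, as are alternative τ² estimators (REML, Paule–Mandel). Strata with
exactly two contributing studies are allowed; their τ² estimates are noisy,
which is logged rather than suppressed. Matching across studies is by exact
mature-id string; -5p and -3p arms are distinct features. BH adjustment is
applied within each of the four meta-analyses separately, since each is
reported separately.

### Functional enrichment

Every analyzed miRNA — not only significant ones — contributes a signed
index, by default sign(μ̂)·(−log₁₀ p) (a signed-z alternative is available;
the transform is configurable because the ranking literature admits both).
Zero p-values are clamped to the smallest positive float with a warning.
The index transfers to genes as the mean over targeting miRNAs — mean
rather than sum, so hub genes targeted by many weak miRNAs are not inflated
by degree — and gene scores are rank-transformed to standard-normal
quantiles. Gene-set testing is a univariate logistic regression of term
membership on the normalized score over the universe of genes reachable
from the target map (mirroring the transfer construction); the slope is the
log odds ratio and its Wald test the p-value, BH-adjusted across terms.
Term size bounds default to [10, 500] annotated genes — conventional
gene-set bounds; the annotation is consumed pre-propagated (ancestors
already expanded) as a flat TSV. On complete separation or an unstable fit
the Rao score test replaces the Wald test and the term is flagged.

## Synthetic data generator

The generator emulates the integration setting the pipeline targets:
multiple studies per tissue with a mix of platforms (default six studies —
four brain, two blood; arrays as Gaussian log2-scale matrices with baseline
Normal(8, 2), RNA-seq as negative-binomial counts with log-normal mean
abundances, dispersion 0.1 and library-size factors within 2× of each
other), sex-imbalanced groups (default 12/12/8/8 control-F/AD-F/control-M/
AD-M, reflecting the female skew of AD cohorts), and planted effects:
fractions of miRNAs are assigned shared, female-only or male-only classes
(defaults 10%/5%/5%), and each non-null miRNA's realized per-study effect
is drawn once per study from Normal(μ_class, τ²) (defaults μ = 1.0 log2
units, τ² = 0.05, within-study σ² = 0.25) and added to the AD samples of
the sexes its class touches. Null miRNAs have effect exactly zero
everywhere. The global seed expands into per-study substreams, so appending
a study never changes earlier studies' data.

Target and GO structure: non-null miRNAs draw their targets from a
concentrated gene pool (n_genes/8), and a subset of GO terms (default 5 of
50) draws its member genes from the same pool, making those terms genuinely
enriched among genes regulated by perturbed miRNAs; background terms draw
uniformly. The pool size was chosen so the planted preferential targeting
is strong enough to be recoverable — with a much larger pool the planted
structure dilutes below detectability and ceases to be what it claims.

What the generator does not emulate: probe-level microarray artifacts,
batch effects, cell-type composition, covariates such as age or APOE, and
correlated miRNA co-expression. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to those real-data complications.

## Numerical choices

- BH adjustment delegates to the standard step-up implementation; moderated
  p-values are clamped to [tiny, 1].
- Trigamma inversion: Newton iteration with the standard starting point
  0.5 + 1/y, 50-iteration cap, relative tolerance 1e-10.
- Lowess trend predictions are floored at 1e-4 before the −4 power so
  weights stay finite; a constant average-log-count axis falls back to the
  flat trend.
- Correlation distances for sample clustering replace undefined values
  (constant samples) by 1 and are clipped at 0 before average linkage.
- DL τ² truncates at zero; I² is defined as 0 when Q = 0. The 95% CI uses
  the exact normal quantile (1.95996…).
- Simulation sizes in the validation suite — e.g. 500 replicates of the
  6-study/200-miRNA recovery design, 100 replicates of the specificity
  design, 1000-term null calibrations — were chosen so Monte-Carlo error is
  small relative to the tolerances being checked while the whole suite runs
  in about a minute; rate assertions carry explicit ~2σ Monte-Carlo
  allowances.

## Known limitations

- Covariate adjustment (age, APOE, post-mortem interval) is not supported;
  the four-group design is the full model.
- Inference ignores the uncertainty of the estimated precision weights and
  of τ² (standard for voom-style and DL pipelines, but approximate at small
  k; τ² at k = 2 is especially noisy and flagged).
- The enrichment model treats genes as independent observations; correlated
  annotation (nested GO terms) is handled only through BH across terms.
- Live retrieval of expression data, target tables or ontologies is out of
  scope; all inputs are flat files.
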