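# mirmeta

Sex-stratified miRNA differential-expression meta-analysis.

Alzheimer's disease differs between women and men in prevalence and
progression, and individual transcriptomic studies are usually too small —
and too sex-imbalanced — to resolve sex-specific miRNA dysregulation on
their own. `mirmeta` implements the full analysis chain for integrating
several independent miRNA expression studies (microarray and RNA-seq, blood
and brain) into sex-stratified consensus profiles, together with a synthetic
multi-study generator with known ground truth so that every stage can be
validated by parameter recovery without downloading any data.

## Method

For each study, a group-means linear model is fitted over the four
sex × condition groups and two contrasts are estimated: AD female − control
female, and AD male − control male. RNA-seq counts are first converted to
log2 counts-per-million, `log2((c + 0.5)/(L + 1) · 10⁶)`, with
per-observation precision weights from a lowess fit of residual √sd against
average log-count (weight = predicted value⁻⁴). Per-miRNA residual
variances s²_g on d_g degrees of freedom are shrunk toward a prior (d₀, s₀²)
estimated across miRNAs by moment matching of log s²_g:

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),   t_g = β̂_g / (s̃_g √v_g)

on d₀ + d_g degrees of freedom, with Benjamini–Hochberg adjustment within
each study × contrast.

Per tissue (blood, brain) and sex, each miRNA observed in ≥ 2 studies is
combined by a DerSimonian–Laird random-effects model. With y_i the study
logFCs and v_i their squared standard errors, w_i = 1/v_i:

    Q  = Σ w_i (y_i − ŷ_FE)²
    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))
    μ̂  = Σ y_i/(v_i+τ²) / Σ 1/(v_i+τ²),   I² = max(0, (Q−(k−1))/Q)·100

with normal-theory z inference, 95% CI, and BH adjustment within each of the
four meta-analyses (blood-F, blood-M, brain-F, brain-M).

For functional profiling, every analyzed miRNA gets a signed index
sign(μ̂)·(−log₁₀ p), transferred to target genes through a miRNA→gene map
(gene score = mean index over targeting miRNAs, then rank-transformed to
standard-normal quantiles). Each GO Biological Process term of 10–500
annotated genes is tested with a logistic model of term membership on the
gene index; the slope is the log odds ratio (lor), with BH adjustment across
terms. A companion report ranks genes by how many significant miRNAs target
them, and the reporting module provides per-study QC (PCA, clustering),
direction-aware signature intersections between the sexes, cross-sex
discordance tables and volcano exports.

## Worked example

```python
import mirmeta as M

cfg = M.SimulationConfig(n_mirnas=300, seed=1)   # 6 studies: 4 brain, 2 blood
bundles, truth = M.simulate_multistudy(cfg)
de = [r for b in bundles for r in M.run_de(b)]
meta = M.run_meta(de)
for (tissue, sex), mr in sorted(meta.items()):
    sig = mr.table[mr.table["adj_p"] < 0.05]
    print(f"{tissue}-{sex}: {len(mr.table)} miRNAs, "
          f"{(sig['direction'] == 'up').sum()} up / "
          f"{(sig['direction'] == 'down').sum()} down, "
          f"median tau2 = {mr.table['tau2'].median():.3f}")

enr = M.run_enrichment(meta, truth.target_map, truth.annotation)
print(enr[("blood", "female")].gsa.head(3)[["go_name", "n_genes", "lor", "adj_p"]])
```

prints

```
blood-female: 300 miRNAs, 37 up / 3 down, median tau2 = 0.000
blood-male: 300 miRNAs, 30 up / 2 down, median tau2 = 0.000
brain-female: 300 miRNAs, 45 up / 3 down, median tau2 = 0.005
brain-male: 300 miRNAs, 43 up / 4 down, median tau2 = 0.008
                      go_name  n_genes     lor  adj_p
go_id
GO:0000004  planted process 4       40  1.9449    0.0
GO:0000003  planted process 3       40  1.9052    0.0
GO:0000005  planted process 5       40  1.7852    0.0
```

The generator planted 10% shared, 5% female-only and 5% male-only
overexpression (log2 effect 1.0, between-study variance τ² = 0.05): most
planted miRNAs reach significance in the matching strata, the five planted
GO terms top the enrichment, and null miRNAs stay at the nominal error rate.

The same pipeline runs from the shell:

```
mirmeta simulate --out data --seed 1
mirmeta preprocess --manifest data/manifest.yaml --out prep
mirmeta de --in prep --out de
mirmeta meta --de de --out meta
mirmeta enrich --meta meta --targets data/targets.tsv --go data/go_annotation.tsv --out enrich
mirmeta report --meta meta --out report
```

Real studies enter the same way: per-study expression TSVs, sample-metadata
TSVs (sample_id, sex, condition), a YAML manifest (platform, logged flag,
tissue), an optional source→mature miRNA id map, and miRNA→gene /
gene→GO-BP tables as flat TSVs.

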