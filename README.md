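# medeg

Integrative analysis of genome-wide DNA methylation and mRNA expression
in a two-group (case vs control) cohort, as used to find
**methylation-regulated differentially expressed genes (MeDEGs)** in
peripheral-blood studies of autoimmune disease: genes whose expression
change between groups is accompanied by an inverse (or, less commonly,
concordant) change in promoter or gene-body methylation, and which can
then serve as candidate diagnostic markers.

The package is aimed at epigenomics/regulatory-genomics analysts who
have probe-level matrices in hand (log2 expression intensities and
methylation β-values with detection p-values) and want a tested,
reproducible implementation of the full integration chain:

1. **Differential expression** — per-probe OLS of
   `log2 y ~ group + age + sex + pc1 + pc2` (the PCs absorb
   population-stratification-like structure), Benjamini–Hochberg FDR,
   gene collapse by max |fold change|, DEG call at
   `p_adj < 0.05` and `|FC| > 1.5`.
2. **Differential methylation** — detection-p and sex-chromosome
   filtering, locus-by-locus Wilcoxon rank-sum test, effect size
   `Δβ = median β(case) − median β(control)`, DMP call at
   `p_adj < 0.05` and `|Δβ| > 0.12`, gene collapse by max |Δβ|.
3. **Genomic annotation** — nearest-TSS gene mapping (< 10 kb),
   strand-aware region categories (TSS200 / TSS1500 / 5'UTR / 1st exon /
   body / 3'UTR / IGR) and CpG context (island / shore / shelf / open
   sea).
4. **Integration** — per gene, Pearson correlation over all
   (expression probe × methylation probe) pairs on the pooled samples,
   keep the max-|r| pair; genes significant on both layers are
   classified by the signs of their changes (inverse-up-hypo,
   inverse-down-hyper, positive-…).
5. **Diagnostic panel search** — radial-kernel SVM tuned over a
   cost × γ grid with leave-one-out cross-validation (per-fold
   standardization, no leakage) and greedy/exhaustive forward selection
   of a minimal gene panel; plus 2-D hierarchical clustering with
   misclassification counts.
6. **Downstream** — hypergeometric gene-set enrichment (GMT input, BH
   across sets), case-subgroup contrasts (e.g. interstitial lung
   disease), and qPCR relative quantities (2^−ΔΔCt).

A **synthetic cohort generator** (`medeg.simulate`) plants all of this
structure — differential signal on both layers, latent
methylation–expression coupling, covariates, detection failures,
annotation geometry — so the entire pipeline runs and is tested without
any external data.

## Worked example

```python
from medeg import SimConfig, generate_cohort, run_pipeline

cohort = generate_cohort(SimConfig(seed=1))   # 18 cases vs 19 controls
res = run_pipeline(cohort)
print(res.summary())
```

prints

```
Differential expression (OLS group test)
  probes tested : 4000
  covariates    : age, sex, pc1, pc2
  thresholds    : p_adj < 0.05, |FC| > 1.5
  genes         : 2000
  DEGs          : 100 (61 up, 39 down)

Differential methylation (ranksum test)
  probes removed: {'sex_chromosome': 100, 'detection': 50}
  probes tested : 4850
  thresholds    : p_adj < 0.05, |delta beta| > 0.12
  DMPs          : 150 (77 hypo, 73 hyper)
  DMGs          : 144

Methylation-expression integration
  common gene universe : 1787
  DEG/DMG overlap      : 25
  inverse MeDEGs       : 20 (12 up-hypo, 8 down-hyper)
  positive class       : 5
  promoter DMP genes   : 15
```

This cohort has 100 planted DEGs, 150 planted DMPs and 25
methylation-coupled genes (20 inverse, 5 positive); the pipeline
recovers all of them here — the calling thresholds sit below the planted
effect sizes, and the false-discovery control keeps spurious calls out.
The per-gene MeDEG table carries the evidence:

```python
print(res.integration.records.head(3).round(3))
```

```
            fc  log2_fc  delta_beta      r meth_probe_id               class  promoter_dmp
gene_id
G00109  -1.681   -0.749       0.216 -0.507      cg000019  inverse-down-hyper         False
G00283   1.631    0.705      -0.190 -0.501      cg000009     inverse-up-hypo          True
G00308  -2.190   -1.131       0.228 -0.593      cg000017  inverse-down-hyper         False
```

e.g. `G00308` is 2.2-fold down-regulated in cases while its paired CpG
probe gains 0.23 in median β, with supporting pooled correlation
r = −0.59 — the canonical signature of a methylation-silenced gene.

A diagnostic panel on a strongly separable feature set:

```python
from medeg.simulate import simulate_feature_matrix
from medeg import search_feature_panel

features, labels = simulate_feature_matrix(seed=1)   # 6 informative of 20
result = search_feature_panel(features, labels, max_size=6)
print(result.summary())
```

```
SVM panel: g05
  LOOCV accuracy : 1.000
  cost / gamma   : 2 / 0.5
```

Every sample is predicted correctly when held out once — with a
3-pooled-SD class separation a single informative gene already suffices.

A thin CLI mirrors the library (`medeg simulate-cohort`, `medeg deg`,
`medeg dmp`, `medeg integrate`, `medeg panel`, `medeg cluster`,
`medeg enrich`, `medeg subgroup`, `medeg qpcr`); run `medeg --help`.

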