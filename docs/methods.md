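# Methods

`medeg` re-implements, as a tested and reusable pipeline, an integrative
analysis of genome-wide DNA methylation and mRNA expression in a
two-group case/control cohort profiled on expression and 450K-style
methylation microarrays.  The pipeline starts from numeric matrices
(log2 expression intensities; methylation beta-values with companion
detection p-values) — low-level array processing (background correction,
normalization, probe re-annotation) is assumed done upstream and is out
of scope.

## Differential expression

For each expression probe the model is an ordinary least-squares fit

    log2(y) ~ group + age + sex + pc1 + pc2

where `group` codes case = 1 / control = 0, so the group coefficient is
the covariate-adjusted log2 fold change (case minus control).  `pc1` and
`pc2` are the sample scores on the first two principal axes of the
probe-centered expression matrix, computed on all probes before any
filtering; their role is to absorb group-independent global structure
(population stratification, residual batch effects).  The t statistic
and two-sided p-value of the group coefficient are reported per probe
and Benjamini-Hochberg adjusted across all tested probes.

Two deliberate design choices:

* **Unmoderated OLS instead of an empirical-Bayes moderated t.**  At
  n = 37 samples the per-probe residual degrees of freedom (31 with the
  full covariate set) make variance moderation a second-order
  refinement; a plain linear model keeps the fold change and the p-value
  consistent within a single fit and removes a heavyweight dependency.
* **Fold change = back-transformed group coefficient**
  (`fc = sign(coef) * 2^|coef|`), not a raw group-mean ratio, so the
  effect estimate and its test come from the same adjusted model.

Probes with zero variance get log2FC 0 and p = 1 rather than an error,
so pipelines never abort on constant rows.  A genuinely singular design
(e.g. sex completely confounded with group) raises an estimation error
naming the collinear column.

Transcript-to-gene collapse keeps, per gene, the probe with the largest
|FC| (ties: smaller adjusted p, then lexicographic probe ID).  A gene is
called differentially expressed (DEG) iff `p_adj < 0.05` and
`|FC| > 1.5`, both strict.

## Differential methylation

Probes are first filtered: any probe whose detection p-value exceeds
0.01 in at least one sample is removed (the strictest common reading of
detection filtering; per-sample masking was rejected to keep matrices
complete), as are probes annotated to chrX/chrY (both sexes are present
in the cohort).  Locus-by-locus testing then uses the two-sided Wilcoxon
rank-sum test on beta-values, with the effect size

    delta_beta = median beta(case) - median beta(control)

(medians, not means).  A position is a DMP iff `p_adj < 0.05` and
`|delta_beta| > 0.12`, both strict.  Rank-sum p-values are exact when
the pooled sample size is at most 12 and the data contain no ties,
otherwise the normal approximation with tie and continuity correction is
used.

A rank test cannot absorb covariates; since the study design also calls
for covariate adjustment, an optional `mode="ols"` applies the same
linear model as the expression layer to logit-transformed beta-values
(PCs, when supplied, are computed on the logit scale).  The default
remains the unadjusted rank-sum — the explicitly specified method — and
both modes share the delta-beta filter.

Gene-level collapse (DMG table) keeps the max-|delta-beta| DMP per gene;
genes with significant positions in both directions keep the
max-|delta-beta| label and are flagged `both_directions`.

## Genomic annotation

Coordinates are 0-based, intervals half-open (BED convention)
throughout.  Each methylation probe maps to the gene with the nearest
TSS when that distance is strictly below 10 kb (ties: lexicographically
smallest gene ID).  Gene-region classification is strand-aware with the
450K annotation precedence TSS200 > TSS1500 > 5'UTR > 1stExon > 3'UTR >
Body: TSS200 is within 200 bp upstream of the TSS, TSS1500 the
201-1500 bp band, 5'UTR the transcript span before the CDS, the first
exon runs from the TSS to its recorded boundary, 3'UTR the span after
the CDS.  Positions outside every defined feature are intergenic (IGR)
even when a nearest gene exists.  The promoter set is {TSS1500, TSS200,
5'UTR, 1stExon}.  CpG context uses the platform's standard distance
bands: island (inside an island interval), shore (within 2 kb of an
island boundary), shelf (within 4 kb), open sea (farther).  "Distance to
TSS" is reported unsigned; the upstream/downstream distinction only
matters inside region classification.

The same nearest-TSS mapping is used both for the DMG collapse and for
the integration step (a platform annotation could differ; one consistent
rule keeps the two layers comparable).

## Integration and MeDEG classification

The common gene universe contains genes with at least one expression
probe and at least one methylation probe mapped within 10 kb of the TSS.
For every such gene the Pearson correlation r is computed over all
samples — cases and controls pooled, which is the only reading that
yields one r per probe pair and maximizes power for coupling shared by
the whole cohort — for every expression-probe x methylation-probe pair,
and the pair with maximal |r| is kept (ties: more negative r, then
lexicographic probe IDs).  Pairs with undefined correlation (zero
variance) are skipped; genes with no defined pair are excluded and
logged.

Genes significant on both layers (DEG and DMG) are classified purely by
the signs of their changes: `inverse-up-hypo` (expression up,
methylation down), `inverse-down-hyper`, `positive-up-hyper`,
`positive-down-hypo`.  The correlation r is reported as supporting
evidence but does not define the class — the class describes the
direction structure of the two effects, which is how such gene lists are
conventionally tabulated.  `promoter_dmp` flags genes whose
representative DMP lies in the promoter set.  A strict pairing
requirement (the max-|r| methylation probe must itself be the gene's
DMP) was considered and not made the default: the evidence for
methylation regulation is the joint significance plus direction, and
binding the two probe choices together discards genes where array
redundancy puts the best-correlated probe next to the most significant
one.

## SVM panel search

A radial-kernel SVM is tuned over the grid cost = 2^-5 … 2^15 and
gamma = 2^-15 … 2^3 (multiplicative steps of 4).  For each grid point
the full leave-one-out cross-validation (LOOCV) is run: every sample is
predicted once by a model trained on the other n-1 samples.  Features
are standardized inside each training fold only; this prevents
information leaking from the held-out sample and is standard practice
for radial kernels.  The reported grid point is the
one with maximal LOOCV accuracy, ties resolved toward the smallest cost,
then the smallest gamma (prefer smoother models).

Two shortcuts provably never change the result: the grid is scanned in
ascending (cost, gamma) order and stops at the first point with
accuracy 1.0 (identical to the tie rule), and a grid point's fold loop
aborts once its error count makes beating the incumbent impossible.

Panel search over candidate genes is greedy forward selection by
default: each step adds the feature (lexicographic order on ties) that
maximizes the LOOCV accuracy of the extended panel, stopping at
accuracy 1.0, at the size cap (default 6), or when no addition improves
accuracy — the last rule keeps the accuracy path monotonically
non-decreasing and the panel minimal.  An exhaustive mode evaluates
every subset per size (candidate count capped at 30).  Hyperparameters
are tuned on the same LOOCV that is reported, matching the emulated
procedure; this is optimistic as a generalization estimate (no nested
CV), a known caveat of perfect-separation claims at n = 37.

Two-dimensional hierarchical clustering of samples uses one-minus-
Pearson distance and average linkage by default (common for microarray
heatmaps); the 2-cluster cut is compared against the true groups under
the better of the two cluster-to-group mappings to count misclassified
samples.

## Downstream analyses

Gene-set enrichment is a generic one-sided hypergeometric
over-representation test against a user-supplied background, BH-adjusted
across sets.  It stands in for external annotation services; its
p-values will not numerically match any proprietary pathway database.
The case-subgroup contrast (e.g. interstitial lung disease vs not)
uses the two-sided rank-sum test per gene at raw p < 0.05 — deliberately
uncorrected, matching how such small confirmatory contrasts are
conventionally reported; this is a liberal choice and is flagged as
such.  qPCR relative quantities follow the 2^-ddCt convention against a
housekeeping reference and a calibrator sample.

## Synthetic cohort generator

The generator emulates the study design end-to-end: 18 cases vs 19
controls; 2000 genes with 2 expression probes each (one designated probe
carries the full planted signal, the other an attenuated 0.5x copy, to
exercise the max-|FC| collapse); 5000 methylation probes; 100 planted
DEGs (log2FC +/-1.0) and 150 planted DMPs (delta-beta +/-0.20), of which
20 inverse-coupled and 5 positive-coupled genes (12 up-hypo + 8
down-hyper; 1 up-hyper + 4 down-hypo, mirroring the direction mix of the
emulated study's gene table); age ~ Normal(43, 10), sex ~ Bernoulli(0.5),
an ILD flag on 10 of the cases; 1% detection failures and 2%
chrX/Y probes to exercise the filters.  Effect sizes sit deliberately
above the calling thresholds — the emulated study does not report its
real effect-size distribution, so the defaults describe a
comfortably-detectable regime and everything is configurable.

Key mechanisms:

* **Beta-values through a logit-normal latent.**  Group shifts and
  coupling compose additively on the logit scale, and because the noise
  is symmetric the population median beta-difference equals the
  configured effect exactly: the latent shift is calibrated per probe as
  `logit(beta0 + delta) - logit(beta0)` from its baseline `beta0`
  (baselines of planted probes are drawn so the shifted value stays
  inside (0.05, 0.95)).  Non-planted baselines are drawn from a bimodal
  mixture, as on real methylation arrays.
* **Coupling.**  Each MeDEG gene owns a per-sample latent factor
  f ~ Normal(0, 0.3^2) entering its designated expression probe with
  coefficient +0.8 and its methylation probe's latent with -0.8
  (inverse classes) or +0.8 (positive classes).  The factor's scale is
  the generator's choice: the pooled correlation of an inverse pair is
  already dominated by the opposing group shifts (expected pooled
  r ~ -0.6 to -0.75), so the factor only needs to add within-group
  coupling (latent within-group r ~ -0.4) without drowning the planted
  effects — at sd 0.3 it adds 0.24 to both layers' latent noise,
  leaving the planted shifts at roughly two noise SDs.
* **Nuisance structure.**  Two global group-independent factors (probe
  loadings ~ Normal(0, 0.4^2)) enter every expression probe.  They are
  the population-stratification/batch analogue that the PC covariates
  exist to remove: without them the planted effects dominate total
  variance and PC1 would coincide with the case/control axis, making PC
  adjustment self-defeating.  Methylation is left free of this
  structure because its default test is unadjusted.
* **Geometry.**  Genes occupy 20 kb slots on one synthetic chromosome
  (transcript 10 kb, CDS inset 400 bp, first exon 600 bp, random
  strand); ~30% of genes get a CpG island across the TSS and three
  islands sit in a gene-free desert region, so probes realize every
  region category and every CpG context.  Planted MeDEG probes are
  placed ~60% in promoter categories and the rest in gene bodies;
  one non-coupled gene carries two DMPs of opposite sign to exercise
  the dual-direction flag; a few planted DMPs are intergenic
  (unmapped), so DMP and DMG counts differ as in real data.

What the generator does **not** emulate: raw array intensities, dye
bias, batch structure beyond the global factors, beta-value
heteroscedasticity near the boundaries, spatial correlation of
neighboring CpGs, cell-type composition effects, and realistic
effect-size spectra.  Passing recovery tests therefore demonstrates that
the pipeline's logic is correct and well-calibrated under its own
modeling assumptions, not that real-data preprocessing choices
(normalization, cell-type correction) are unnecessary.

## Numerical and procedural choices

* Strict inequalities at every calling threshold (a gene at exactly
  |FC| = 1.5 or p_adj = 0.05 is not called).
* BH adjustment via the standard step-up procedure with monotonicity
  enforcement; validated against a brute-force oracle in the tests.
* Rank-sum: exact null only for pooled n <= 12 without ties; the
  continuity-corrected normal approximation makes the test slightly
  conservative at cohort sizes (empirical null rate ~4.7% at nominal
  5%, inside the +/-1% calibration band).
* Deterministic tie-breaks everywhere (documented per operation), so
  identical inputs give identical outputs across runs and platforms.
* PCs use an SVD with the sign convention that each component's
  largest-magnitude probe loading is positive.
* Degenerate inputs (constant probes, empty DMP sets, empty cohorts)
  produce defined, documented results instead of errors wherever the
  downstream interpretation is unambiguous.

## Problem sizes used in the checks

The recovery checks run the full pipeline on 20 generator seeds at the
default configuration (2000 genes / 5000 probes / 37 samples); null
calibration aggregates 100 seeds of effect-free cohorts at 150 genes /
300 probes, which gives ~30k null tests per layer and a Monte-Carlo
standard error well below the +/-1% band.  The SVM benchmark uses the
37-sample, 20-candidate design with six 3-pooled-SD features.  These
sizes are the package's own reproducibility choices: large enough that
the binomial noise of every rate sits far inside its acceptance band,
small enough to re-run routinely.

## Known limitations

* The OLS t-test assumes roughly Gaussian residuals on the log2 scale;
  heavy-tailed probes would benefit from the moderation it omits.
* Tuning hyperparameters on the reported LOOCV overstates
  generalization accuracy; a nested evaluation would be needed for an
  unbiased estimate.
* The hypergeometric enrichment ignores gene-set overlap structure and
  GO hierarchy.
* The integration treats one probe pair per gene; genes with several
  independently regulated CpGs are summarized by their strongest signal
  only.
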