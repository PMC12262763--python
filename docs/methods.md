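# Methods

`sceqtlkit` implements a multi-resolution single-cell cis-eQTL mapping and
GWAS colocalisation pipeline, together with a synthetic-data generator that
plants resolution-specific regulatory effects so every stage can be validated
against known truth.  This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic
validation demonstrates.

## The statistical pipeline

### Cell quality control

Cells are filtered in two layers.  The absolute layer keeps a cell iff it has
at least 250 genes expressed, at least 500 total counts, and a mitochondrial
read percentage of at most 20% (blood-derived cells) or 50% (gut-derived
cells).  The relative layer then works within each cell lineage: for each of
the three metrics, cells outside `median ± n·MAD` are removed, with n = 2.5
by default and n = 2 for the epithelial lineage, whose dispersion is much
larger.  The MAD is unscaled (no 1.4826 normal-consistency factor) and the
window bounds are inclusive, so a degenerate MAD of 0 keeps exactly the cells
at the median.  The three metric windows are combined by conjunction; whether
they should instead be applied sequentially is underdetermined, and
conjunction is order-free.  Note the relative filter is *not* idempotent in
general — removing cells shifts the median and MAD — although it is stable
on the typical "compact bulk plus outliers" configuration.

An optional per-sample epithelial depth exclusion (median genes per cell
< 2000) exists as a flag and is off in synthetic runs, where depth is
homogeneous by construction.

### Pseudobulk aggregation

Counts are normalised per cell to a library size of 10,000 and
log-transformed (`ln[cp10k+1]`), then averaged across each donor's cells in
an *annotation context*: a (resolution, annotation, site-mode) triple, where
resolution ∈ {all cells, major population, cell type} and site-mode is one of
the anatomical sites or "cross-site" (pooling all sites).  A donor
contributes only with ≥ 5 cells in the context; a context is retained only
with ≥ 30 donors; and a gene is kept only if non-zero in ≥ 20% of the
context's donor rows (computed on the pre-filter donor set — the alternative
ordering is unstated upstream and this choice is isolated in one function).
Each retained gene is inverse normal transformed (INT) across donors:
`x_i -> Φ⁻¹((r_i − 0.5)/n)` with average ranks for ties.  The rank offset is
a convention; it is isolated behind `inverse_normal_transform`.

### cis-eQTL mapping

For gene G in context C the model is ordinary least squares:

    Ex_{G,C} ~ GT + PC_GT + PC_Ex

with GT the alternative-allele dosage, five genotype principal components
(population structure) computed once from the full dosage matrix, and K
expression PCs computed per context from the INT matrix.  Candidate variants
lie within 1 Mb of the TSS (both bounds inclusive) with in-sample MAF
strictly above 0.05.  The scan residualises expression and dosages against
the covariates and uses the correlation shortcut, t = r·sqrt(dof/(1−r²)),
dof = n − n_cov − 2; this is algebraically identical to the full OLS fit and
is verified against statsmodels in the tests.

Gene-level significance comes from permuting the (residualised) expression
vector across donors and recording the minimum nominal p over candidates;
the empirical p-value is (1 + #{perm ≤ obs})/(1 + B).  Optionally a
Beta(a, b) distribution is fitted to the permutation minima by maximum
likelihood and its CDF at the observed minimum reported instead; this gives
continuous gene-level p-values whose BH q-values are not quantised at the
1/(B+1) floor, and is the pipeline default.  eGenes are called by
Benjamini–Hochberg within context at FDR 0.05.

The number of expression PCs can be selected by re-running the scan over a
grid (2 to 100 in steps of 2, truncated so K < n_donors − n_genotype_PCs − 2)
and keeping the K with the most eGenes, ties to the smallest K.  Grid
selection is expensive and off by default in the bundled synthetic runs,
which use K = 2.

One caveat recorded here because it bit during development: expression PCs
are estimated from the same matrix that contains the gene under test.  With
thousands of genes the self-contamination is negligible, but with very small
gene panels (≲ 20 genes and K ≥ 2) the focal gene leaks into the PCs and the
permutation p-values become anti-conservative.  Synthetic panels are sized
accordingly (hundreds of genes, or no expression PCs in single-gene
constructions).

Conditionally independent signals come from forward regression: the lead's
dosage joins the covariates, the permutation scan re-runs, and a new signal
is appended while its permutation p stays below the stopping threshold
(default: the context's BH threshold).  A candidate perfectly collinear with
a prior lead stops the recursion with a warning.

### Interaction eQTLs

The interaction model adds the interaction variable and its product with
dosage:

    Ex_{G,C} ~ GT + I + GT:I + PC_GT + PC_Ex

I is one of sex, age (5-year bins), disease status, smoking, or an
inflammation score; continuous scores are standardized before entering the
model.  Two departures from the base scan: a stricter MAF filter of 0.1
applied within *every level* of I (continuous I is binned at the median for
the filter only), and removal of any expression PC with |Pearson r| > 0.25
against I.  Significance of the product term is a two-sided t-test;
gene-level ieGene calling permutes the I assignments across donors (keeping
genotype main effects intact) and applies BH at 0.05.  The multiplicity
procedure is our design choice — a global permutation of I rather than a
within-genotype-stratum permutation, since strata are variant-specific while
the gene-level statistic spans variants; the global permutation is exact for
the joint null of the I and GT:I terms, which is the relevant null for
calling an interaction.

### Signal grouping and attribution

Lead variants for the same gene across contexts are grouped by greedy
plink-style LD clumping: sort leads by p ascending (ties broken
lexicographically on variant id), seed a clump at the best unassigned lead,
absorb all unassigned leads with r² > 0.5 within 1 Mb, repeat.  LD is
in-sample Pearson r² between dosage vectors; no external panel.  Each signal
(or eGene) is attributed to the *minimum resolution* at which it was
detected — the coarsest, under the ordering all cells < major population <
cell type — and to a site-sharing class, with `cross_site_only` marking
detections present only when sites are pooled.

### Colocalisation

For each eGene with q ≤ 0.05, a 2 Mb window is centred on its lead variant;
if the window's minimum GWAS p is below the suggestive threshold 5×10⁻⁵, the
shared (allele-harmonised, sign-flipped where ref/alt are swapped) variant
set feeds the five-hypothesis approximate-Bayes-factor framework.  Wakefield
log-ABFs are computed from beta/se with prior effect SD 0.15 for
quantitative traits and 0.2 (log-odds) for case-control; priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵.  The H3 weight's bracketed difference
ΣBF1·ΣBF2 − ΣBF1BF2 is evaluated in log space with `log1p(−exp(·))` and
clamped at zero if floating error drives it negative.  A pair colocalises at
PP4 > 0.75.  Results whose lead GWAS variant falls inside the HLA region
(chr6:28,510,120–33,480,577, GRCh38) are masked as likely false positives;
surviving calls are assigned to the closest known disease locus anchor
within 500 kb, ties to the smaller locus id.  Windows with fewer than 25
shared variants are skipped.  Only primary-signal windows are colocalised;
conditioning GWAS summary statistics for secondary signals is out of scope.

### Effector nomination and resolution odds ratios

Because detection power varies enormously across annotations, the effector
annotation for a colocalised gene is nominated power-agnostically: among
annotations with a nominal eQTL p < 0.05 at the lead variant and median raw
pseudobulk expression > 0, compute the fraction of variance in INT
expression explained by the lead dosage (simple OLS r², equal to squared
Pearson correlation) and take the argmax; ties are all reported in
deterministic order rather than broken silently.

Per-resolution enrichment of colocalisation is summarised by an odds ratio:
OR_r = [a/(A−a)] / [b/(B−b)], with a of A effector genes and b of B eGenes
attributed (by minimum detection resolution) to class r; zero cells take a
Haldane–Anscombe +0.5 on all four cells of the affected table.  This 2×2
construction is our explicit reading of an under-specified summary statistic
and is documented in the configuration.

### Genomic-annotation enrichment

Signals are characterised by TSS distance (|index variant − TSS|),
nearest-gene fraction (is the eGene's TSS the closest TSS to the index
variant), and a promoter-normalised enhancer enrichment.  For the latter,
per resolution class: overlap fractions of the class's index variants with
enhancer and promoter tracks are each normalised by the fractions of a
random-variant baseline (MAF-matched variants drawn from all tested
variants), and the enhancer/promoter ratio is taken.  Confidence intervals
come from resampling LD *blocks* (never individual variants) containing the
class's variants, 1000 times, with the 2.5–97.5 percentile interval
reported; classes are compared by two-tailed t-tests between bootstrap
distributions.  Two numerical choices: a 0.5 pseudocount enters every
overlap count in every replicate, keeping ratios finite when a replicate's
promoter overlap is empty at small scale; and each class's bootstrap
generator is seeded identically, so identical variant sets yield
bit-identical replicate streams and a between-class t-test p of exactly 1 —
the natural reading of the symmetry requirement.  BED semantics throughout:
0-based half-open intervals, so a 1-based position p is inside [s, e) iff
s < p ≤ e.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
nothing more.

* **Genotypes** are hard-call dosages from thresholded latent Gaussians:
  haplotypes share a per-block factor (latent correlation 0.9), giving
  Hardy–Weinberg genotypes with elevated within-block r² (≈ 0.4–0.6 after
  attenuation by thresholding) and near-zero across-block r².  Variants sit
  on one chromosome at fixed spacing.
* **Cells**: every (donor, cell type) pair receives a fixed number of cells,
  assigned round-robin to sites.  Counts are Poisson around
  `exp(ln base_mean + β·dosage·[cell type ∈ active set] + β_I·dosage·I +
  donor noise)`, with donor noise N(0, 0.3 by default) shared across the
  donor's cells — the simplest model preserving the mean structure the
  pseudobulk pipeline estimates.  Planted effects activate in all cell
  types (ubiquitous), one major population's types, or a single cell type.
  The default gene panel is 300 genes with per-cell base means of 1–5
  counts, sized so cells clear the absolute QC thresholds.
* **GWAS**: an independent cohort (default n = 2000) is redrawn with the
  same MAF/block design (two-sample colocalisation), a quantitative
  phenotype is built from the causal map plus unit Gaussian noise, and
  marginal per-variant beta/se/p are reported, so LD partners of causal
  variants carry attenuated signal.
* **Tracks**: promoters tile around TSSs, enhancers are placed over variants
  the truth ledger flags, LD blocks tile the chromosome gaplessly.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, dispersion beyond Poisson, trans effects, multi-chromosome
genomes, imputed fractional dosages, or realistic LD decay within blocks.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated model, not robustness to real-data
artefacts.

## Validation problem sizes

The bundled validation runs are sized for a single CPU: cohorts of 120–200
donors, 60–240 variants in blocks of 6–8, gene panels of 6–300, 6–18 cells
per donor per type, 200–500 permutations, 1000 bootstrap replicates, and
20–50 replicates per recovery experiment.  Two regimes are worth noting as
deliberate design choices.  For colocalisation discrimination and
conditional-signal recovery, planted effects flow through the full cell
pipeline (β = 0.5 on the ln scale with the generator's default noise), which
yields the strong, well-identified eQTLs the discrimination claims are
about.  For resolution attribution, the hierarchy has 8 cell types in 2
populations and β = 0.5, chosen from a power analysis so that a cell-type
effect's 4-fold dilution at the population level sits below the detection
threshold while the undiluted effect sits far above it; attribution rates at
this operating point are near but above the 80% level, and dip toward it for
unlucky seeds — the attribution statistic is intrinsically a power statement.

## Known limitations

* The Beta-approximated permutation p assumes the fitted Beta describes the
  min-p null tail; with very few permutations (< 100) it is unreliable and a
  warning fires.
* `select_expression_pcs` re-permutes per grid value and is quadratic in
  practice; it is intended for real-scale runs, not the bundled synthetic
  defaults.
* The CLI stage subcommands re-derive upstream stages deterministically from
  the config seed rather than parsing partial run directories; at desk scale
  this is cheap and keeps stage dependencies explicit.
* Interaction mapping runs in the all-cells cross-site context in the
  bundled pipeline; per-context ieQTL grids are available through the
  library API.
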