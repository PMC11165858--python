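# Methods

This note documents the statistical procedures, the synthetic-data
generator, and the numerical and design choices behind `ernaqtl`.

## Coordinate conventions

All intervals are 0-based, half-open (BED convention); GTF input is shifted
on read. Abutting intervals merge (`[0,5) ∪ [5,10) = [0,10)`) because every
downstream rule is about base coverage, not interval identity. Chromosome
names are never normalized — a `chr1`/`1` mismatch between two inputs raises
an error listing the offending names rather than guessing.

## Enhancer annotation

Replicate peak sets are reduced per assay to the sub-regions of the peak
union supported by at least `min_support = 2` distinct samples. Support is
resolved **per base** on the merged union rather than by whole-peak
reciprocal overlap: per-base support is invariant to sample order and robust
to boundary jitter, at the cost of occasionally trimming a peak to its
reproducible core. Open-chromatin (ATAC) peaks with ≥ 1 bp of H3K27ac
overlap become candidate enhancers; the **ATAC interval** is reported
(accessibility defines the element, acetylation confirms activity), with the
overlap segment available as an option. Candidates overlapping
`[tss − 2500, tss + 2501)` of any gene are removed whole — the exclusion is
of peaks, not of partial peaks. Tumor and normal tissue groups are processed
independently.

## eRNA quantification

Each enhancer contributes one eRNA region: the ± 3 kb window around
`floor((start + end)/2)`, clipped (and flagged) at chromosome boundaries.
Overlapping regions are kept — one region per enhancer — and exact
duplicates deduplicated. Regions with ≥ 1 bp overlap with a protein-coding
gene extended 1 kb past both termini are excluded.

A read counts toward a region on ≥ 1 bp overlap; a read overlapping k
regions counts fully in each (default) or 1/k in each (`fractional`).
RPKM = count / (region length in kb × library size in millions), where
library size is the **total** reads in the sample's input, not
reads-in-regions. Detectable eRNAs have mean RPKM ≥ 0.5 and are nonzero in
strictly more than 50 % of samples (mean RPM ≥ 1 under the `rpm_tcga` mode).
Boundary semantics are strict where the defining phrasing is strict: a
feature expressed in exactly half the samples is removed.

For QTL mapping, each feature is transformed to normal scores
`Φ⁻¹((rank − 3/8)/(n + 1/4))` with average ranks on ties (Blom offset), the
standard outlier guard in molecular-QTL practice; cross-sample quantile
normalization to a common distribution is not what regression on a single
feature needs, so the rank-based transform is the default. Constant features
map to zero scores with a warning.

## Genotype QC

Variants are removed when INFO < 0.4, MAF < 5 %, missing rate ≥ 5 %, or the
Hardy–Weinberg exact-test *p* < 10⁻⁶; ties at the thresholds follow the
removal phrasing (MAF = 0.05 and INFO = 0.4 are kept, missingness = 0.05 is
removed). The HWE test conditions on observed allele counts and sums the
probabilities of all heterozygote counts no more probable than the observed
one, computed in log space with a normalizing pass so counts in the tens of
thousands are stable. Dosages are hard calls; fractional input is rounded
with a warning. In a case-control cohort the HWE test can be restricted to
controls (`hwe_samples`), the standard practice; the expression cohort uses
all samples.

## cis-QTL mapping

For every (variant, eRNA) pair with variant-to-region distance ≤ 1 Mb
(distance 0 inside the region; a variant at exactly 1 Mb is tested), the
normalized expression is regressed by OLS on [1, dosage, covariates], with
pairwise deletion of missing dosages and a two-sided *p* from the t
distribution with n − k − 2 degrees of freedom. Covariates (population
structure components, batch, age, sex, ordered tumor stage, purity) are
consumed as supplied numeric columns and never computed internally. Pairs
monomorphic after deletion are skipped with a recorded reason.

FDR control is Storey's q-value over **all tested pairs in the dataset**
(per cancer type / per tissue state): π₀(λ) = #{p > λ}/(m(1 − λ)) on the
grid λ = 0.05…0.95, smoothed by a cubic polynomial fit and evaluated at the
largest λ, clipped to (0, 1]; q-values are the monotone step-up transform
capped at 1. Below 100 p-values the smoother is unstable and a fixed
λ = 0.5 estimate is used with a warning. Only this single nominal pass is
performed — no permutation-based top-variant pass — because Storey FDR is
applied directly to the nominal p-values.

The fit is exercised against three independent routes in the test suite:
statsmodels OLS, the Frisch–Waugh residual regression, and an explicitly
solved normal-equations system.

## Enrichment

Control variants are drawn 1:1 (configurable) from the tested pool, matched
within strata of MAF (0.05-wide bins over [0.05, 0.5]), LD-proxy count at
r² > 0.2 (bins 0 / 1–5 / 6–20 / 21–50 / > 50) and variant type, without
replacement, deterministically under a seed. The matching r² threshold
reuses the GWAS block threshold since no separate value is canonical; bin
widths are coarse enough to fill strata at the package's simulation scale.
An exhausted stratum falls back to the nearest MAF bin with a warning.

Per-feature enrichment is a two-sided Fisher exact test on the
(in/out) × (signal/control) table; the odds ratio uses a Haldane–Anscombe
+0.5 correction when any cell is zero, the 95 % CI comes from the log-OR
normal approximation, and Bonferroni correction multiplies by the declared
family size (e.g. all TFs tested). GWAS LD-block membership is tag SNPs plus
variants with r² > 0.2 to a tag. π₁ enrichment applies the same Storey
machinery to a category's GWAS p-values and reports 1 − π₀.

## Specificity and target genes

Sharing is decided at the (variant, eRNA)-pair level: significant in both
states → shared, otherwise state-specific; percentages are reported against
each state's own total (one decimal). Effect concordance over shared pairs
is the fraction with matching β signs (zero flagged, counted concordant)
plus the Pearson correlation of βs. Expression-pattern classes partition
eRNAs detected in ≥ 1 cancer type by detection breadth: 1 type (specific),
2–9 (intermediate), ≥ 10 (ubiquitous).

Candidate target genes lie within 1 Mb of the region edge (TSS anchor).
Each candidate gets a partial correlation: both vectors are residualized on
[1, covariates] and the residuals correlated, p from the t distribution with
n − k − 2 df; this equals the precision-matrix closed form to 10⁻¹⁰ on
random instances. Links require |pcor| ≥ 0.3 and Benjamini–Hochberg q < 0.05
over all candidates — BH rather than Storey here, since only the QTL stage
names Storey's method and a small candidate table estimates π₀ poorly. The
adjustment set is the **full covariate table** (tumor purity plus
age/sex/batch): purity is the dominant biological confounder of bulk
co-expression, but technical covariates shared between an eRNA and a gene
driven by a different eRNA otherwise leak correlation of the same order as
the |pcor| threshold. Purity adjustment can be disabled by passing a reduced
covariate frame.

## Case-control association

Genetic codings: additive (0/1/2), recessive (dosage 2 vs rest), allelic
(each subject expanded to two allele observations with covariates
duplicated — a convention that treats alleles as independent, standard in
this literature), and genotype contrast (homozygote vs homozygote, dropping
heterozygotes, which reproduces the common CC-vs-TT table presentation).
The fit is unconditional ML logistic regression of phenotype on [1, coded
genotype, gender, age (continuous), smoking, drinking (binary)]; OR =
exp(β) with Wald 95 % CI. Separation raises an error recommending an exact
or penalized alternative instead of silently penalizing. The effect-allele
orientation is fixed by the caller and never auto-flipped to the minor
allele. Stages combine either by a pooled re-fit with stage indicator
covariates or by fixed-effect inverse-variance meta-analysis of log-ORs;
both are reported because neither is canonically "the" combined analysis.

## Synthetic-data generator

The generator emulates, at desk scale, the statistical structure each stage
assumes. Defaults (all overridable in `SimulationConfig`):

| Parameter | Default | Meaning |
|---|---|---|
| `chrom_length` | 2 Mb | one synthetic chromosome |
| `n_genes` / `n_enhancers` | 30 / 40 | placed with ≥ 6.5 kb gaps |
| `collision_fraction` | 0.1 | enhancers planted inside exclusion zones |
| `n_peak_samples` | 4 per assay | replicate peak sets |
| `peak_fnr` / `peak_fpr` / `peak_jitter_sd` | 0.05 / 0.05 / 25 bp | peak noise |
| `n_variants` / `ld_block_size` / `ld_rho` | 600 / 20 / 0.6 | LD structure |
| `maf_range` | [0.05, 0.5] | per-variant MAF, uniform |
| `n_samples` | 154 | expression cohort (paired-tissue scale) |
| `qtl_beta` | 1.5 | planted allelic effect on log abundance |
| planted QTLs | 2 shared + 1 tumor- + 1 normal-specific | |
| `noise_sd` | 1.0 | residual log-abundance SD |
| `library_size_mean` | 20,000 | reads per sample (scaled down) |
| `n_target_links` / `target_gamma` | 3 / 0.01 | gene links per RPKM unit |
| `purity_effect` | 1.0 | purity confounding of gene expression |
| `n_cases` / `n_controls` / `planted_or` | 1,000 / 1,000 / 0.91 | per stage |

Entity placement keeps clean enhancers ≥ 6.5 kb from genes and from each
other, so ± 3 kb eRNA regions of distinct enhancers never overlap each other
or a 1 kb-extended gene; the `collision_fraction` deliberately violates this
(alternating TSS-flank hits, removed at annotation, and near-gene placements
whose region — not the enhancer — collides, removed at the coding filter).
Truth regions are numbered exactly as the analysis pipeline numbers its
candidate set, so noise-free runs are id-for-id comparable.

Genotypes: within blocks of `ld_block_size` variants, haplotype alleles copy
their left neighbour with probability `ld_rho` or redraw at their own MAF —
a first-order chain that gives tunable block r² without coalescent
machinery, sufficient to exercise proxy counting and r² > 0.2 block logic.
Diploid dosage is the sum of two independent haplotypes, which guarantees
HWE by construction. INFO scores are Beta(5, 1) (≈ 1 % below the 0.4
threshold, so the filter fires occasionally), missingness 1 % at random,
90 % SNVs.

Expression: latent log abundance a = μ_e + β·g + covariate terms +
N(0, noise_sd); counts are Poisson with rate ∝ depth × region kb × exp(a).
Poisson rather than negative-binomial is the default because the analysis
consumes RPKM, not count dispersion (an overdispersed path can be emulated
by raising `noise_sd`). When reads are materialized, each counted read is
placed uniformly inside its region and background reads uniformly in the
complement, so the counting path reproduces the count matrix exactly and
library size equals the read-file length. Planted effects are placed only on
variants that pass the QC thresholds (an effect on a variant QC would delete
is untestable by construction). Target genes follow g = ν + γ·RPKM +
purity_effect·(purity − 0.6) + N(0, 1) with purity ~ U(0.3, 0.9).

Case-control subjects are drawn in batches from
P(case) = logistic(−1 + log(OR)·dosage + 0.2·gender + 0.02·(age − 60) +
0.4·smoking + 0.3·drinking) until the case and control quotas fill; the
intercept puts prevalence near 0.27 so sampling is efficient, and a
numerically degenerate prevalence raises.

Everything is reproducible byte-for-byte under a fixed seed: each stage
draws from a PCG64 stream spawned from (seed, crc32(stage name)), so stages
are independent and stable across platforms and processes.

### What the generator does *not* emulate

No sequence content, mappability structure, strand, splicing, or somatic
mutation; no population stratification (covariates are supplied, not
derived from genotypes); library sizes are ~250× smaller than real RNA-seq,
with baseline abundance raised so per-region counts stay informative —
absolute RPKM values are therefore larger than in real tissue although all
normalization identities hold. Passing tests demonstrate the statistical
machinery is correct under the stated model, not that real-data artifacts
(batch-confounded genotypes, overdispersion, mapping bias) are handled.

## Numerical choices and problem sizes

- Per-pair OLS solves the normal equations directly (k ≤ ~10 covariates);
  an exactly collinear design raises rather than silently pseudo-inverting.
  An exact fit (zero residual) reports p = 0 with infinite t.
- p-values are floored at the smallest positive double so Storey's
  machinery never sees literal zeros.
- π₀ smoothing is a degree-3 polynomial in λ — deterministic and stable on
  a 19-point grid; estimates are clipped to [1/m, 1].
- The HWE test compares probabilities with a 1 + 10⁻¹² relative slack when
  summing the "as or less probable" outcomes, the usual guard against
  floating-point ties.
- Calibration suites run at deliberately modest sizes chosen to make their
  Monte-Carlo error small relative to the asserted bands: 50 × 2,000 null
  tests at n = 200 for type-I error (99 % binomial CI half-width ≈ 0.002),
  2,000 fits for CI coverage, 100 replicates at n = 50,000 for odds-ratio
  recovery.

## Known limitations

- The q-value implementation offers only the smoother π₀ estimate (plus the
  small-m fixed-λ fallback), not Storey's bootstrap alternative.
- `fractional` read counting loops in Python; it is an alternative policy,
  not the default path, and is sized for the package's simulation scale.
- The pooled stage combination assumes a shared covariate coding across
  stages; stage-by-covariate interactions are not modelled.
- Trans-QTLs, conditional secondary signals, interaction QTLs and
  survival models are out of scope.
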