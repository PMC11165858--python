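# ernaqtl

Enhancer RNAs (eRNAs) are non-coding transcripts produced from active
enhancers; genetic variants that shift their expression in *cis* — eRNA
quantitative trait loci (eRNAQTLs) — are a mechanistic bridge between
non-coding risk variants and gene regulation in cancer. `ernaqtl` implements
the full analysis chain as a tested, reusable Python package, for
statistical geneticists and regulatory-genomics analysts who want each stage
as a library function rather than a collection of one-off scripts:

1. **Enhancer annotation** from replicate ATAC-seq and H3K27ac ChIP-seq peak
   sets: per-base reproducibility across ≥ 2 samples, assay intersection,
   exclusion of peaks within ± 2.5 kb of any TSS.
2. **eRNA quantification**: ± 3 kb regions around enhancer midpoints,
   exclusion of regions overlapping protein-coding genes (± 1 kb), read
   counting, RPKM/RPM normalization, detectability filtering (mean RPKM
   ≥ 0.5 in > 50 % of samples), rank-based inverse-normal transform.
3. **Genotype QC**: INFO < 0.4, MAF < 5 %, missingness ≥ 5 %, and
   Hardy–Weinberg exact-test *p* < 10⁻⁶ removals.
4. **cis-QTL mapping** (`CisQTLModel`): for every variant–eRNA pair within
   1 Mb, OLS of normalized expression on allele dosage plus covariates
   (*y* = α + β·g + Cγ + ε), with genome-wide FDR by Storey's q-value
   (π₀ estimated from the *p*-value distribution); significant at q < 0.05.
5. **Enrichment**: control variants matched on MAF, LD-proxy count
   (r² > 0.2) and variant type; two-sided Fisher exact tests with Bonferroni
   correction; GWAS LD-block overlap and π₁ = 1 − π₀ enrichment.
6. **Specificity and targets**: tumor/normal sharing at the
   (variant, eRNA)-pair level, effect-size concordance, expression-pattern
   classes (1 / 2–9 / ≥ 10 cancer types), and target-gene linking by
   distance (≤ 1 Mb) plus purity-adjusted partial correlation
   (|pcor| ≥ 0.3, BH-FDR < 0.05).
7. **Case-control association** (`CaseControlModel`): unconditional
   logistic regression under additive / recessive / allelic /
   genotype-contrast codings, per stage and combined (pooled re-fit or
   fixed-effect inverse-variance meta-analysis).

A first-class synthetic-data generator (`ernaqtl.simulate`) produces every
input — jittered replicate peaks, LD-structured genotypes under HWE, Poisson
read counts with planted additive cis effects, purity-confounded target
genes, case-control cohorts with a planted per-allele odds ratio — together
with a truth table, so the whole pipeline is testable end to end without any
external download.

## Worked example

```python
from ernaqtl import (SimulationConfig, simulate_dataset, CisQTLModel,
                     CaseControlModel, qc_filter, rpkm,
                     detectability_filter, inverse_normal_transform)
from ernaqtl.quantify import ERNARegion
from ernaqtl.intervals import GenomicInterval

cfg = SimulationConfig(seed=1)                      # 154-sample cohort
ds = simulate_dataset(cfg, states=("tumor",), stages=("stage1",))
regions = [ERNARegion(r["erna_id"],
                      GenomicInterval(r["chrom"], r["start"], r["end"]),
                      (r["start"] + r["end"]) // 2) for r in ds.truth.regions]
expr = inverse_normal_transform(
    detectability_filter(rpkm(ds.expression["tumor"]["counts"])))
geno, tally = qc_filter(ds.genotypes)
res = CisQTLModel(expr, geno, ds.expression["tumor"]["covariates"],
                  regions, state="tumor").fit()
print(res.summary())
print(CaseControlModel(ds.cohorts["stage1"], model="additive",
                       stage="stage1").fit().summary())
```

prints

```
cis-eRNAQTL mapping results [tumor]
==============================================
samples:            154
cis window:         1,000,000 bp
tested pairs:       16,385
skipped (monomorphic): 0
estimated pi0:      0.992
significant (q < 0.05): 8
top pair:           var00458 x eRNA_00035 (beta=1.098, p=2.98e-34, q=4.84e-30)

case-control association [additive] stage=stage1
==============================================
n cases / controls: 1,000 / 1,000
method:             logistic
OR (95% CI):        0.978 (0.852-1.123)
log-OR (SE):        -0.0220 (0.0705)
P:                  0.755
```

Reading the output: 16,385 variant–eRNA pairs fell within the 1 Mb cis
window; the estimated proportion of true nulls π₀ ≈ 0.99 matches a dataset
where only a few effects are planted, and the 8 significant pairs are the
planted eRNAQTLs together with their LD proxies (adjacent-variant
correlation is 0.6 by default, so tagging variants are genuinely
associated).  The association stage is a 2,000-subject cohort with a planted
per-allele OR of 0.91 — far below the power needed at that size, hence the
wide CI spanning 1; the combined multi-stage analysis at n = 50,000
(see `scripts/acceptance.py`) recovers it.

The same chain is available from the shell:

```sh
ernaqtl demo --seed 1 --out demo_out        # full pipeline + JSON report
ernaqtl simulate --seed 1 --out data/
ernaqtl enhancers --atac-bed 'data/peaks_ATAC_s*.bed' \
    --h3k27ac-bed 'data/peaks_H3K27ac_s*.bed' --genes data/genes.gtf \
    --out enhancers.bed
```

## Documentation

`docs/methods.md` describes the statistical model of every stage, the
synthetic-data generator's assumptions, the numerical choices, and known
limitations.
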