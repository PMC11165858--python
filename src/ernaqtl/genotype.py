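"""Genotype container, VCF I/O, and variant-level quality control.

QC mirrors the standard post-imputation filters: variants are removed when
the imputation confidence (INFO) score is < 0.4, minor allele frequency is
< 5%, missing rate is >= 5%, or the Hardy-Weinberg exact-test p-value is
< 1e-6.  Boundary semantics follow the removal phrasing: a variant at MAF
exactly 0.05 is retained, one at missing rate exactly 0.05 is removed.

Dosages are hard calls in {0, 1, 2} (NaN for missing); fractional expected
dosages are rounded on input with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "compute_maf",
    "hwe_exact_test",
    "qc_filter",
    "read_vcf",
    "write_vcf",
]


@dataclass
class GenotypeMatrix:
    """Variants x samples hard-call dosages with per-variant metadata.

    ``variants`` has index = variant id and columns chrom, pos, ref, alt,
    variant_type ('SNV'/'indel'), info; :meth:`compute_metadata` adds maf,
    missing_rate, hwe_p.
    """

    dosages: pd.DataFrame  # variants x samples, float with NaN = missing
    variants: pd.DataFrame

    def __post_init__(self):
        if not self.dosages.index.equals(self.variants.index):
            raise ValueError("dosages and variants must share the variant index")
        vals = self.dosages.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size and not np.allclose(obs, np.round(obs)):
            warnings.warn("fractional dosages rounded to hard calls")
            self.dosages = self.dosages.round()
        if obs.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in {0, 1, 2} or be missing")

    @property
    def variant_ids(self):
        return self.dosages.index

    @property
    def samples(self):
        return self.dosages.columns

    def compute_metadata(self, hwe_samples=None) -> "GenotypeMatrix":
        """Fill maf, missing_rate, hwe_p columns.

        ``hwe_samples`` restricts the HWE test to a sample subset (e.g.
        controls in a case-control cohort); MAF and missingness always use
        all samples.
        """
        d = self.dosages.to_numpy(dtype=float)
        miss = np.isnan(d)
        self.variants["missing_rate"] = miss.mean(axis=1)
        with np.errstate(invalid="ignore"):
            self.variants["maf"] = [compute_maf(row) for row in d]
        d_hwe = (
            self.dosages.loc[:, hwe_samples].to_numpy(dtype=float)
            if hwe_samples is not None
            else d
        )
        hwe = np.empty(d.shape[0])
        for i, row in enumerate(d_hwe):
            obs = row[~np.isnan(row)]
            hwe[i] = hwe_exact_test(
                int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())
            )
        self.variants["hwe_p"] = hwe
        return self

    def subset_variants(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[ids], self.variants.loc[ids].copy())


def compute_maf(dosages) -> float:
    """Minor allele frequency from hard-call dosages (folded to <= 0.5)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing; MAF undefined")
    alt = d.sum() / (2 * d.size)
    return float(min(alt, 1.0 - alt))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count (the SNP-HWE formulation).  Returns 1.0 for
    degenerate inputs (monomorphic sites).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele copies
    if n_rare == 0:
        return 1.0
    # possible heterozygote counts share the parity of n_rare
    het_obs = n_Aa
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log-probabilities: P(het) prop. to
    #   2^het * n! / (hom_r! het! hom_c!) with hom_r = (n_rare - het)/2
    log_probs = np.empty(hets.size)
    for k, het in enumerate(hets):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        log_probs[k] = (
            het * math.log(2)
            - math.lgamma(hom_r + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_c + 1)
        )
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, het_obs)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_min: float = 1e-6,
    info_min: float = 0.4,
    hwe_samples=None,
) -> tuple[GenotypeMatrix, dict]:
    """Apply the four variant-level QC filters; returns (filtered, tally).

    Retains variants with MAF >= maf_min, missing rate < miss_max,
    HWE p >= hwe_min, and INFO >= info_min.  The tally counts removals per
    criterion (a variant can be counted under several).  Idempotent.
    """
    if not {"maf", "missing_rate", "hwe_p"} <= set(g.variants.columns):
        g = g.compute_metadata(hwe_samples=hwe_samples)
    v = g.variants
    info = v["info"] if "info" in v.columns else pd.Series(1.0, index=v.index)
    fail_maf = v["maf"] < maf_min
    fail_miss = v["missing_rate"] >= miss_max
    fail_hwe = v["hwe_p"] < hwe_min
    fail_info = info < info_min
    keep = ~(fail_maf | fail_miss | fail_hwe | fail_info)
    tally = {
        "input": len(v),
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_miss.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "removed_info": int(fail_info.sum()),
        "retained": int(keep.sum()),
    }
    return g.subset_variants(v.index[keep]), tally


def read_vcf(path, info_key: str = "INFO_SCORE") -> GenotypeMatrix:
    """Read GT dosages and an imputation-score INFO key from a VCF 4.x file."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, meta = [], [], []
    for i, var in enumerate(vcf):
        vid = var.ID or f"{var.CHROM}_{var.POS}"
        alt = var.ALT[0] if var.ALT else "."
        gt = np.asarray(var.gt_types, dtype=float)  # 0 HOM_REF,1 HET,2 UNKNOWN,3 HOM_ALT
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        ids.append(vid)
        rows.append(dos)
        meta.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS - 1,  # 0-based internally
                "ref": var.REF,
                "alt": alt,
                "variant_type": "SNV" if len(var.REF) == 1 and len(alt) == 1 else "indel",
                "info": float(var.INFO.get(info_key, 1.0)),
            }
        )
    dosages = pd.DataFrame(np.asarray(rows), index=ids, columns=samples)
    return GenotypeMatrix(dosages, pd.DataFrame(meta, index=ids))


def write_vcf(g: GenotypeMatrix, path, info_key: str = "INFO_SCORE") -> None:
    """Write hard-call genotypes as a minimal VCF 4.2 (GT plus one INFO key)."""
    v = g.variants
    order = v.sort_values(["chrom", "pos"]).index
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={info_key},Number=1,Type=Float,Description="Imputation confidence score">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(v["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for vid in order:
            row = v.loc[vid]
            dstr = "\t".join(
                gt_map.get(d, "./.") if not (isinstance(d, float) and np.isnan(d)) else "./."
                for d in g.dosages.loc[vid]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t{info_key}={row['info']:.4f}\tGT\t{dstr}\n"
            )
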