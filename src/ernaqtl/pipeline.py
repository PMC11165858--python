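"""End-to-end demo pipeline and its configuration.

``run_pipeline`` generates a synthetic dataset, writes every input in its
standard on-disk format, reads the files back through the package's own
parsers, and runs annotation -> quantification -> genotype QC -> cis-QTL
mapping (tumor and normal) -> sharing/concordance -> matched-control
enrichment -> target linking -> case-control association, collecting stage
counts into a machine-readable JSON report.  Two runs with the same
configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from .association import CaseControlModel, combine_stages
from .enhancers import annotate_enhancers
from .genotype import qc_filter, read_vcf
from .intervals import read_bed, read_gene_annotation
from .qtl import CisQTLModel
from .quantify import (
    ExpressionMatrix,
    build_erna_regions,
    count_reads,
    detectability_filter,
    filter_coding_overlap,
    inverse_normal_transform,
    rpkm,
)
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .specificity import classify_qtl_sharing, effect_concordance, link_targets

__all__ = ["PipelineConfig", "run_pipeline", "dosage_ld_table"]


@dataclass
class PipelineConfig:
    """Analysis parameters plus the embedded simulation configuration.

    Unknown keys in a config file are rejected rather than ignored.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_support: int = 2
    tss_flank: int = 2_500
    half_width: int = 3_000
    gene_extension: int = 1_000
    detect_mode: str = "rpkm_cohort"
    multi_count: str = "all"
    window: int = 1_000_000
    fdr: float = 0.05
    pcor_min: float = 0.3
    link_fdr: float = 0.05
    control_ratio: int = 1
    gwas_r2_min: float = 0.2
    assoc_models: tuple = ("additive", "recessive", "allelic", "genotype_contrast")
    combine_methods: tuple = ("pooled", "ivw_meta")
    threads: int = 1  # accepted for interface symmetry; execution is deterministic

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = d.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim_d) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        for key in ("maf_range", "info_beta", "gene_length_range", "enhancer_width_range"):
            if key in sim_d:
                sim_d[key] = tuple(sim_d[key])
        for key in ("assoc_models", "combine_methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(sim=SimulationConfig(**sim_d), **d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def dosage_ld_table(genotypes, within_block: bool = True) -> pd.DataFrame:
    """Pairwise dosage r^2 within LD blocks (columns id_a, id_b, r2)."""
    v = genotypes.variants
    d = genotypes.dosages
    rows = []
    blocks = v.groupby("block").groups if "block" in v.columns else {0: v.index}
    for _, ids in blocks.items():
        ids = list(ids)
        arr = d.loc[ids].to_numpy(dtype=float)
        # impute column means for missing entries before correlating
        col_mean = np.nanmean(arr, axis=1, keepdims=True)
        arr = np.where(np.isnan(arr), col_mean, arr)
        sd = arr.std(axis=1)
        ok = sd > 0
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(arr)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r2 = corr[i, j] ** 2 if ok[i] and ok[j] else 0.0
                rows.append((ids[i], ids[j], float(r2)))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "r2"])


def _read_expression(paths: dict, state: str) -> tuple[ExpressionMatrix, pd.DataFrame]:
    d = paths["expression"][state]
    counts = pd.read_csv(d["counts"], sep="\t", index_col=0)
    lib = pd.read_csv(d["library_sizes"], sep="\t", index_col=0)["library_size"]
    covars = pd.read_csv(d["covariates"], sep="\t", index_col=0)
    em = ExpressionMatrix(counts, units="counts", library_sizes=lib.astype(float))
    return em, covars


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic-data pipeline; returns the JSON-able report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    ds = simulate_dataset(cfg, make_reads=True)
    paths = write_dataset(ds, out / "inputs")
    report: dict = {"seed": cfg.seed, "config": config.to_dict()}

    # --- enhancer annotation (round-trips peaks and genes through disk)
    atac = [read_bed(p) for p in paths["peaks"]["ATAC"]]
    k27 = [read_bed(p) for p in paths["peaks"]["H3K27ac"]]
    genes = read_gene_annotation(paths["genes"], dialect="gtf")
    enh = annotate_enhancers(
        atac, k27, genes, min_support=config.min_support, tss_flank=config.tss_flank
    )
    report["peaks_in"] = {a: sum(len(s) for s in sets) for a, sets in ds.peaks.items()}
    report["enhancers"] = len(enh)

    # --- eRNA regions and per-state quantification
    regions = filter_coding_overlap(
        build_erna_regions(
            enh, half_width=config.half_width,
            chrom_lengths={cfg.chrom: cfg.chrom_length},
        ),
        genes,
        extension=config.gene_extension,
    )
    report["erna_regions"] = len(regions)

    # --- genotype QC (VCF round-trip)
    geno = read_vcf(paths["genotypes"]).compute_metadata()
    geno_qc, tally = qc_filter(geno)
    report["genotype_qc"] = tally

    state_results = {}
    detectable_counts = {}
    expr_norm_by_state = {}
    covars_by_state = {}
    for state in ds.expression:
        reads = {
            s: pd.read_csv(p, sep="\t", header=None, names=["chrom", "start", "end"])
            for s, p in paths["expression"][state]["reads"].items()
        }
        counts = count_reads(regions, reads, multi_count=config.multi_count)
        expr = detectability_filter(rpkm(counts), mode=config.detect_mode)
        detectable_counts[state] = len(expr.features)
        norm = inverse_normal_transform(expr)
        _, covars = _read_expression(paths, state)
        expr_norm_by_state[state] = norm
        covars_by_state[state] = covars
        res = CisQTLModel(
            norm, geno_qc, covars, regions, window=config.window, state=state
        ).fit(fdr=config.fdr)
        res.to_tsv(out / f"qtl_{state}.tsv")
        state_results[state] = res
    report["detectable_ernas"] = detectable_counts
    report["tested_pairs"] = {s: len(r.table) for s, r in state_results.items()}
    report["significant_qtls"] = {
        s: int(r.table["significant"].sum()) for s, r in state_results.items()
    }
    report["pi0"] = {s: round(r.pi0, 4) for s, r in state_results.items()}

    # --- tumor/normal sharing and effect concordance
    calls, sharing = classify_qtl_sharing(
        state_results.get("tumor", set()), state_results.get("normal", set())
    )
    calls.to_csv(out / "sharing_calls.tsv", sep="\t", index=False)
    report["sharing"] = sharing
    shared = calls[calls["class"] == "shared"]
    if len(shared) >= 2:
        bt = state_results["tumor"].table.set_index(["variant_id", "erna_id"])["beta"]
        bn = state_results["normal"].table.set_index(["variant_id", "erna_id"])["beta"]
        idx = pd.MultiIndex.from_frame(shared[["variant_id", "erna_id"]])
        conc, r = effect_concordance(
            pd.DataFrame({"beta_tumor": bt.loc[idx].to_numpy(),
                          "beta_normal": bn.loc[idx].to_numpy()})
        )
        report["shared_effect_concordance"] = round(conc, 4)
        report["shared_effect_correlation"] = round(r, 4)

    # --- matched-control enrichment on the tumor signal
    tumor_res = state_results.get("tumor")
    if tumor_res is not None and tumor_res.table["significant"].any():
        ld = dosage_ld_table(geno_qc)
        tested = sorted(set(tumor_res.table["variant_id"]))
        annot = geno_qc.variants.loc[tested, ["maf", "variant_type"]].copy()
        annot["ld_proxy_count"] = enr.ld_proxy_counts(tested, ld, r2_min=config.gwas_r2_min)
        signal = sorted(set(tumor_res.significant["variant_id"]))
        rng = cfg.rng("enrichment")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            controls = enr.match_controls(
                signal, annot, ratio=config.control_ratio, seed=rng
            )
        pos = geno_qc.variants["pos"]
        in_region = {
            vid
            for vid in tested
            if any(
                r.interval.start <= pos[vid] < r.interval.end for r in regions
            )
        }
        random_feat = set(
            pd.Index(tested)[rng.random(len(tested)) < 0.2]
        )
        enrich = enr.fisher_enrichment(
            signal, controls,
            {"erna_region": in_region, "random_feature": random_feat},
        )
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["enrichment"] = {
            row["feature"]: {"or": round(row["or_"], 3), "p_adj": float(row["p_adj"])}
            for _, row in enrich.iterrows()
        }
        # synthetic GWAS: small p at planted loci and their proxies
        planted = {q["variant_id"] for q in ds.truth.qtl_effects}
        proxies = set(planted)
        strong = ld[ld["r2"] > config.gwas_r2_min]
        proxies |= set(strong.loc[strong["id_a"].isin(planted), "id_b"])
        proxies |= set(strong.loc[strong["id_b"].isin(planted), "id_a"])
        gwas_p = pd.Series(rng.uniform(0, 1, len(tested)), index=tested)
        hit = gwas_p.index.isin(proxies)
        gwas_p[hit] = rng.beta(0.2, 1.0, int(hit.sum()))
        block = enr.gwas_ld_block_enrichment(
            signal, sorted(planted), ld, controls, r2_min=config.gwas_r2_min
        )
        report["gwas_block_or"] = round(float(block["or_"].iloc[0]), 3)
        cats = {
            c: set(calls.loc[calls["class"] == c, "variant_id"])
            for c in ("tumor_specific", "normal_specific", "shared")
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi1 = enr.pi1_gwas_enrichment(cats, gwas_p)
        report["gwas_pi1"] = {k: (None if pd.isna(v) else round(v, 4)) for k, v in pi1.items()}

    # --- target-gene linking on the tumor state
    if "tumor" in ds.expression:
        gene_expr = ds.expression["tumor"]["gene_expr"]
        tumor_norm = expr_norm_by_state["tumor"]
        counts_t = ds.expression["tumor"]["counts"]
        erna_rpkm = rpkm(counts_t).subset(
            [f for f in tumor_norm.features if f in counts_t.values.index]
        )
        links = link_targets(
            erna_rpkm, gene_expr, regions, genes,
            covars=covars_by_state["tumor"],
            window=config.window, pcor_min=config.pcor_min, fdr=config.link_fdr,
        )
        links.to_csv(out / "target_links.tsv", sep="\t", index=False)
        report["target_links"] = int(links["linked"].sum())

    # --- case-control association per stage and combined
    assoc_rows = []
    for stage, cohort in ds.cohorts.items():
        for model in config.assoc_models:
            res = CaseControlModel(cohort, model=model, stage=stage).fit()
            assoc_rows.append(res)
    for method in config.combine_methods:
        for model in config.assoc_models:
            per_stage = [r for r in assoc_rows if r.model == model and r.stage != "combined"]
            if method == "ivw_meta":
                assoc_rows.append(combine_stages(results=per_stage, method="ivw_meta"))
            else:
                assoc_rows.append(
                    combine_stages(cohorts=ds.cohorts, model=model, method="pooled")
                )
    assoc_table = pd.DataFrame(
        [
            {
                "stage": r.stage, "model": r.model, "method": r.method,
                "or": r.or_, "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                "n_cases": r.n_cases, "n_controls": r.n_controls,
            }
            for r in assoc_rows
        ]
    )
    assoc_table.to_csv(out / "association.tsv", sep="\t", index=False, float_format="%.6g")
    add = assoc_table[
        (assoc_table["model"] == "additive") & (assoc_table["method"] == "ivw_meta")
    ]
    if len(add):
        report["combined_additive_or"] = round(float(add["or"].iloc[0]), 4)
    report["planted_or"] = cfg.planted_or

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
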