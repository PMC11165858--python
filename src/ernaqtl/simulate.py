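"""Synthetic data generator with planted effects for every pipeline stage.

Generates, on a single synthetic chromosome: gene models and true enhancer
intervals (with a configurable fraction of enhancers deliberately placed in
TSS flanks or next to gene bodies to exercise the exclusion filters);
replicate ATAC / H3K27ac peak sets with jittered boundaries, dropout and
spurious peaks; LD-structured diploid genotypes under Hardy-Weinberg
equilibrium (haplotype-copying chain within blocks); eRNA read counts with
planted additive cis effects plus covariate and batch structure; target-gene
expression driven by eRNA abundance with tumor-purity confounding; and
case-control cohorts with a planted per-allele odds ratio.

Every planted quantity is recorded in a :class:`TruthTable` emitted
alongside the data; recovery tests read truth only from there.  All outputs
are byte-identical under a fixed seed (numpy PCG64 streams spawned per
stage).

Entity layout keeps neighbouring features analytically separable: genes and
clean enhancers are placed with at least ``entity_gap`` bp between them so
that +/- 3 kb eRNA regions of distinct enhancers never overlap each other or
a 1 kb-extended gene.  Collision enhancers intentionally violate this.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .intervals import GeneModel, GenomicInterval, IntervalSet
from .quantify import ERNARegion, ExpressionMatrix, build_erna_regions, filter_coding_overlap

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_peaks",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_case_control",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the package's study conditions.

    Geometry is desk-scale (one 2 Mb chromosome) while cohort sizes mirror a
    paired tumor/normal eQTL cohort (154 expression samples).  Library sizes
    are scaled down so that read files stay small; eRNA baseline abundance
    is raised correspondingly so that counts per region stay informative.
    """

    seed: int = 1
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    # genome layout
    n_genes: int = 30
    n_enhancers: int = 40
    gene_length_range: tuple = (2_000, 8_000)
    enhancer_width_range: tuple = (400, 1_200)
    collision_fraction: float = 0.1
    noncoding_gene_fraction: float = 0.1
    entity_gap: int = 6_500  # keeps +/-3 kb regions of neighbours disjoint
    # peaks
    n_peak_samples: int = 4
    peak_jitter_sd: float = 25.0
    peak_fnr: float = 0.05
    peak_fpr: float = 0.05
    # genotypes
    n_variants: int = 600
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.6
    snv_fraction: float = 0.9
    info_beta: tuple = (5.0, 1.0)
    geno_missing_rate: float = 0.01
    # expression cohort
    n_samples: int = 154
    erna_log_mean: float = 6.0
    erna_log_sd: float = 0.5
    noise_sd: float = 1.0
    batch_effect: float = 0.5
    age_effect: float = 0.1
    sex_effect: float = 0.1
    erna_purity_effect: float = 0.5
    library_size_mean: float = 20_000.0
    depth_log_sd: float = 0.2
    background_reads: float = 15_000.0
    read_length: int = 100
    # planted cis effects
    n_shared_qtl: int = 2
    n_tumor_specific_qtl: int = 1
    n_normal_specific_qtl: int = 1
    qtl_beta: float = 1.5
    planted_min_maf: float = 0.1
    planted_qtl_table: list | None = None  # explicit (variant, erna, beta, state) rows
    # target genes
    n_target_links: int = 3
    target_gamma: float = 0.01
    planted_target_table: list | None = None
    purity_effect: float = 1.0
    gene_base_mean: float = 5.0
    gene_noise_sd: float = 1.0
    # case-control cohort
    n_cases: int = 1_000
    n_controls: int = 1_000
    planted_or: float = 0.91
    assoc_maf: float = 0.3
    assoc_intercept: float = -1.0

    def __post_init__(self):
        for name in ("peak_fnr", "peak_fpr", "collision_fraction", "ld_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """A deterministic per-stage RNG stream derived from the seed."""
        tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF  # stable across processes
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


@dataclass
class TruthTable:
    """Ground truth of every planted quantity; recovery tests read only this."""

    enhancers: list = field(default_factory=list)  # dicts: chrom/start/end/kind
    regions: list = field(default_factory=list)  # expected surviving eRNA regions
    qtl_effects: list = field(default_factory=list)  # variant_id/erna_id/beta/state
    target_links: list = field(default_factory=list)  # erna_id/gene_id/gamma
    planted_or: float = 1.0

    def clear_enhancer_set(self) -> IntervalSet:
        return IntervalSet(
            GenomicInterval(e["chrom"], e["start"], e["end"])
            for e in self.enhancers
            if e["kind"] == "clear"
        )

    def all_enhancer_set(self) -> IntervalSet:
        return IntervalSet(
            GenomicInterval(e["chrom"], e["start"], e["end"]) for e in self.enhancers
        )

    def qtl_pairs(self, state: str) -> set:
        want = {"shared", f"{state}_specific"}
        return {
            (q["variant_id"], q["erna_id"]) for q in self.qtl_effects if q["state"] in want
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], IntervalSet, list[dict]]:
    """Place genes and enhancers on the chromosome.

    Clean entities are separated by >= ``entity_gap``; a
    ``collision_fraction`` of enhancers is deliberately placed inside a TSS
    flank (even picks) or just outside a gene terminus so that only the
    +/- 3 kb eRNA region collides with the 1 kb-extended gene (odd picks).
    Returns (genes, all true enhancers, per-enhancer annotation dicts).
    """
    rng = rng if rng is not None else cfg.rng("genome")
    n_coll = int(round(cfg.collision_fraction * cfg.n_enhancers))
    if n_coll > cfg.n_genes:
        raise ValueError("collision enhancers cannot outnumber genes")
    n_clear = cfg.n_enhancers - n_coll
    gene_lengths = rng.integers(*cfg.gene_length_range, size=cfg.n_genes, endpoint=True)
    enh_widths = rng.integers(*cfg.enhancer_width_range, size=n_clear, endpoint=True)
    kinds = ["gene"] * cfg.n_genes + ["enh"] * n_clear
    lengths = np.concatenate([gene_lengths, enh_widths])
    order = rng.permutation(len(kinds))
    required = int(lengths.sum() + (len(kinds) + 1) * cfg.entity_gap)
    if required > cfg.chrom_length:
        raise ValueError(
            f"infeasible packing: need {required} bp, chromosome is {cfg.chrom_length} bp"
        )
    slack = cfg.chrom_length - required
    extra = rng.multinomial(slack, np.full(len(kinds) + 1, 1.0 / (len(kinds) + 1)))
    genes: list[GeneModel] = []
    enh_rows: list[dict] = []
    pos = 0
    for slot, idx in enumerate(order):
        pos += cfg.entity_gap + int(extra[slot])
        start, end = pos, pos + int(lengths[idx])
        if kinds[idx] == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = (
                "lincRNA" if rng.random() < cfg.noncoding_gene_fraction else "protein_coding"
            )
            genes.append(
                GeneModel(
                    f"gene_{len(genes) + 1:04d}",
                    GenomicInterval(cfg.chrom, start, end, strand=strand),
                    biotype=biotype,
                )
            )
        else:
            enh_rows.append(
                {"chrom": cfg.chrom, "start": start, "end": end, "kind": "clear"}
            )
        pos = end
    # collision enhancers, one per distinct protein-coding gene (the
    # exclusion filters they exercise only apply to coding genes)
    coding_idx = [i for i, g in enumerate(genes) if g.biotype == "protein_coding"]
    if n_coll > len(coding_idx):
        raise ValueError("collision enhancers cannot outnumber protein-coding genes")
    coll_genes = rng.choice(coding_idx, size=n_coll, replace=False) if n_coll else []
    for i, gi in enumerate(coll_genes):
        g = genes[gi]
        w = int(rng.integers(*cfg.enhancer_width_range, endpoint=True))
        if i % 2 == 0:  # inside the TSS flank -> removed at the enhancer stage
            center = g.tss + int(rng.integers(-1000, 1001))
            kind = "tss_collision"
        else:  # enhancer clean, but its +/-3 kb region hits the extended gene
            center = g.interval.start - 3500
            kind = "region_collision"
        start = max(0, center - w // 2)
        enh_rows.append({"chrom": cfg.chrom, "start": start, "end": start + w, "kind": kind})
    enh_rows.sort(key=lambda r: (r["chrom"], r["start"], r["end"]))
    enhancers = IntervalSet(
        GenomicInterval(r["chrom"], r["start"], r["end"]) for r in enh_rows
    )
    return genes, enhancers, enh_rows


def simulate_peaks(
    true_enhancers: IntervalSet,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
    assay: str = "peaks",
) -> list[IntervalSet]:
    """Replicate peak sets around the true enhancers for one assay.

    Each enhancer appears in each sample with probability 1 - ``peak_fnr``;
    boundaries are jittered by round(Normal(0, peak_jitter_sd)); spurious
    peaks are added at rate ``peak_fpr`` per true peak, placed uniformly.
    """
    rng = rng if rng is not None else cfg.rng(f"peaks:{assay}")
    n_samples = n_samples if n_samples is not None else cfg.n_peak_samples
    out = []
    truth = [(iv.chrom, iv.start, iv.end) for iv in true_enhancers]
    for s in range(n_samples):
        ivs = []
        for chrom, start, end in truth:
            if rng.random() < cfg.peak_fnr:
                continue
            js = start + int(np.rint(rng.normal(0, cfg.peak_jitter_sd)))
            je = end + int(np.rint(rng.normal(0, cfg.peak_jitter_sd)))
            js = max(0, js)
            if je <= js:
                je = js + 50  # jitter collapsed the peak; keep a minimal stub
            ivs.append(GenomicInterval(chrom, js, je))
        n_spur = rng.poisson(cfg.peak_fpr * len(truth))
        for _ in range(n_spur):
            w = int(rng.integers(*cfg.enhancer_width_range, endpoint=True))
            s0 = int(rng.integers(0, max(1, cfg.chrom_length - w)))
            ivs.append(GenomicInterval(cfg.chrom, s0, s0 + w))
        out.append(IntervalSet(ivs, label=f"{assay}_s{s + 1}"))
    return out


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """LD-structured diploid genotypes under HWE.

    Haplotypes are generated per block of ``ld_block_size`` variants by a
    first-order copying chain: the first allele is Bernoulli(MAF); each
    subsequent allele copies the previous haplotype allele with probability
    ``ld_rho``, else is redrawn at its own MAF.  Dosage is the sum of two
    independent haplotypes, which guarantees HWE at every variant.
    """
    rng = rng if rng is not None else cfg.rng("genotypes")
    m, n = cfg.n_variants, cfg.n_samples
    pos = np.sort(rng.choice(cfg.chrom_length, size=m, replace=False))
    mafs = rng.uniform(*cfg.maf_range, size=m)
    H = np.empty((2 * n, m), dtype=np.int8)
    for b0 in range(0, m, cfg.ld_block_size):
        b1 = min(b0 + cfg.ld_block_size, m)
        H[:, b0] = rng.random(2 * n) < mafs[b0]
        for j in range(b0 + 1, b1):
            copy = rng.random(2 * n) < cfg.ld_rho
            fresh = rng.random(2 * n) < mafs[j]
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
    dos = (H[0::2] + H[1::2]).T.astype(float)  # variants x samples
    if cfg.geno_missing_rate > 0:
        dos[rng.random(dos.shape) < cfg.geno_missing_rate] = np.nan
    ids = [f"var{i + 1:05d}" for i in range(m)]
    samples = [f"S{i + 1:03d}" for i in range(n)]
    is_snv = rng.random(m) < cfg.snv_fraction
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "ref": np.where(is_snv, bases[ref_idx], bases[ref_idx] + "A"),
            "alt": np.where(is_snv, bases[alt_idx], bases[ref_idx]),
            "variant_type": np.where(is_snv, "SNV", "indel"),
            "info": rng.beta(*cfg.info_beta, size=m),
            "block": np.arange(m) // cfg.ld_block_size,
        },
        index=ids,
    )
    return GenotypeMatrix(pd.DataFrame(dos, index=ids, columns=samples), variants)


def _plant_qtl_effects(
    genotypes: GenotypeMatrix, regions: list[ERNARegion], cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Choose (variant, eRNA, beta, state) rows among analyzable variants.

    Planted variants must pass the QC thresholds (so they survive to
    mapping) and carry realized MAF >= ``planted_min_maf``; one effect per
    eRNA and per LD block, variant within the cis window of its region.
    """
    if cfg.planted_qtl_table is not None:
        return [dict(row) for row in cfg.planted_qtl_table]
    states = (
        ["shared"] * cfg.n_shared_qtl
        + ["tumor_specific"] * cfg.n_tumor_specific_qtl
        + ["normal_specific"] * cfg.n_normal_specific_qtl
    )
    if not states:
        return []
    if not regions:
        warnings.warn("no surviving eRNA regions; nothing to plant QTL effects on")
        return []
    v = genotypes.variants
    if "maf" not in v.columns:
        genotypes.compute_metadata()
        v = genotypes.variants
    eligible = v[
        (v["maf"] >= max(cfg.planted_min_maf, 0.05))
        & (v["missing_rate"] < 0.05)
        & (v["hwe_p"] >= 1e-6)
        & (v["info"] >= 0.4)
    ]
    region_order = list(rng.permutation(len(regions)))
    used_blocks: set = set()
    effects = []
    for state in states:
        placed = False
        while region_order and not placed:
            r = regions[region_order.pop()]
            near = eligible[
                (eligible["chrom"] == r.interval.chrom)
                & (eligible["pos"] >= r.interval.start - 1_000_000)
                & (eligible["pos"] <= r.interval.end - 1 + 1_000_000)
                & (~eligible["block"].isin(used_blocks))
            ]
            if near.empty:
                continue
            vid = near.index[rng.integers(0, len(near))]
            used_blocks.add(int(near.at[vid, "block"]))
            effects.append(
                {
                    "variant_id": vid,
                    "erna_id": r.erna_id,
                    "beta": float(cfg.qtl_beta),
                    "state": state,
                }
            )
            placed = True
        if not placed:
            raise ValueError("could not place all planted QTL effects; enlarge the genome")
    return effects


def _plant_target_links(
    regions: list[ERNARegion], genes: list[GeneModel], qtl_effects: list[dict],
    cfg: SimulationConfig, rng: np.random.Generator,
) -> list[dict]:
    if cfg.planted_target_table is not None:
        return [dict(row) for row in cfg.planted_target_table]
    if cfg.n_target_links == 0 or not regions:
        if not regions and cfg.n_target_links:
            warnings.warn("no surviving eRNA regions; nothing to link targets to")
        return []
    # prefer QTL-bearing eRNAs, then the remaining regions in random order
    qtl_ernas = [q["erna_id"] for q in qtl_effects]
    others = [r.erna_id for r in regions if r.erna_id not in qtl_ernas]
    rng.shuffle(others)
    candidates = list(dict.fromkeys(qtl_ernas + others))
    region_map = {r.erna_id: r for r in regions}
    used_genes: set = set()
    links = []
    for eid in candidates:
        if len(links) >= cfg.n_target_links:
            break
        r = region_map[eid]
        near = [
            g
            for g in genes
            if g.gene_id not in used_genes
            and g.interval.chrom == r.interval.chrom
            and abs(g.tss - r.source_midpoint) <= 1_000_000
        ]
        if not near:
            continue
        g = near[rng.integers(0, len(near))]
        used_genes.add(g.gene_id)
        links.append({"erna_id": eid, "gene_id": g.gene_id, "gamma": float(cfg.target_gamma)})
    if len(links) < cfg.n_target_links:
        raise ValueError("could not place all planted target links")
    return links


def simulate_expression(
    genotypes: GenotypeMatrix,
    regions: list[ERNARegion],
    genes: list[GeneModel],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    qtl_effects: list[dict] = (),
    target_links: list[dict] = (),
    state: str = "tumor",
    make_reads: bool = False,
):
    """eRNA read counts, gene expression, covariates (and optionally reads).

    Latent log-abundance per region and sample is
    ``mu_e + beta * dosage + covariate effects + Normal(0, noise_sd)``; read
    counts are Poisson with rate proportional to sample depth and region
    length in kb.  Target-gene expression is
    ``nu_g + gamma * eRNA_RPKM + purity_effect * purity + noise``.  When
    ``make_reads`` is set, each counted read is materialized uniformly
    within its region (plus uniform background reads), so the read-counting
    path reproduces the count matrix exactly.

    Returns ``(counts, gene_expr, covariates, reads)`` where ``reads`` is a
    dict sample -> DataFrame(chrom, start, end) or None.
    """
    rng = rng if rng is not None else cfg.rng(f"expression:{state}")
    n = cfg.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]
    purity = rng.uniform(0.3, 0.9, size=n)
    age = rng.normal(60, 10, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    batch = rng.integers(0, 2, size=n).astype(float)
    covariates = pd.DataFrame(
        {"purity": purity, "age": age, "sex": sex, "batch": batch}, index=samples
    )
    mu = rng.normal(cfg.erna_log_mean, cfg.erna_log_sd, size=len(regions))
    A = np.tile(mu[:, None], (1, n))
    A += cfg.batch_effect * batch + cfg.age_effect * (age - 60) / 10
    A += cfg.sex_effect * sex + cfg.erna_purity_effect * (purity - 0.6)
    region_idx = {r.erna_id: i for i, r in enumerate(regions)}
    dos = genotypes.dosages
    active = {"shared", f"{state}_specific"}
    for q in qtl_effects:
        if q["state"] not in active or q["erna_id"] not in region_idx:
            continue
        g = dos.loc[q["variant_id"], samples].to_numpy(dtype=float)
        g = np.nan_to_num(g, nan=float(np.nanmean(g)))  # latent model ignores missingness
        A[region_idx[q["erna_id"]]] += q["beta"] * g
    A += rng.normal(0, cfg.noise_sd, size=A.shape)
    depth = np.exp(rng.normal(0, cfg.depth_log_sd, size=n))
    lib_expected = cfg.library_size_mean * depth
    kb = np.array([r.length / 1000.0 for r in regions])
    rate = (lib_expected[None, :] / 1e6) * kb[:, None] * np.exp(A)
    counts = rng.poisson(rate).astype(float)
    background = rng.poisson(cfg.background_reads * depth).astype(float)
    lib_sizes = pd.Series(background + counts.sum(axis=0), index=samples)
    counts_em = ExpressionMatrix(
        pd.DataFrame(counts, index=[r.erna_id for r in regions], columns=samples),
        units="counts",
        library_sizes=lib_sizes,
        feature_lengths=pd.Series({r.erna_id: float(r.length) for r in regions}),
    )
    # gene expression with purity confounding and planted eRNA drivers
    rpkm_vals = counts / (kb[:, None] * (lib_sizes.to_numpy()[None, :] / 1e6))
    nu = rng.normal(cfg.gene_base_mean, 1.0, size=len(genes))
    G = np.tile(nu[:, None], (1, n)) + cfg.purity_effect * (purity - 0.6)
    gene_idx = {g.gene_id: i for i, g in enumerate(genes)}
    for link in target_links:
        if link["erna_id"] in region_idx and link["gene_id"] in gene_idx:
            G[gene_idx[link["gene_id"]]] += link["gamma"] * rpkm_vals[region_idx[link["erna_id"]]]
    G += rng.normal(0, cfg.gene_noise_sd, size=G.shape)
    gene_em = ExpressionMatrix(
        pd.DataFrame(G, index=[g.gene_id for g in genes], columns=samples),
        units="normal_scores",
    )
    reads = None
    if make_reads:
        reads = {}
        rl = cfg.read_length
        # background reads are placed outside the eRNA regions (they model
        # genic/other transcription), so region counts from the read files
        # reproduce the count matrix exactly
        blocked = sorted(
            (max(0, r.interval.start - rl + 1), r.interval.end) for r in regions
        )
        gaps, cursor = [], 0
        for s0, e0 in blocked:
            if s0 > cursor:
                gaps.append((cursor, s0))
            cursor = max(cursor, e0)
        if cursor < cfg.chrom_length - rl:
            gaps.append((cursor, cfg.chrom_length - rl))
        gap_lens = np.array([e - s for s, e in gaps], dtype=np.int64)
        gap_starts = np.array([s for s, _ in gaps], dtype=np.int64)
        gap_cum = np.concatenate([[0], np.cumsum(gap_lens)])
        total_free = int(gap_cum[-1])
        for si, s in enumerate(samples):
            starts_all = []
            for ri, r in enumerate(regions):
                c = int(counts[ri, si])
                if c == 0:
                    continue
                span = max(1, r.length - rl)
                starts_all.append(r.interval.start + rng.integers(0, span, size=c))
            nb = int(background[si])
            if nb and total_free > 0:
                u = rng.integers(0, total_free, size=nb)
                gi = np.searchsorted(gap_cum, u, side="right") - 1
                starts_all.append(gap_starts[gi] + (u - gap_cum[gi]))
            starts = np.concatenate(starts_all) if starts_all else np.empty(0, dtype=int)
            reads[s] = pd.DataFrame(
                {"chrom": cfg.chrom, "start": starts, "end": starts + rl}
            )
    return counts_em, gene_em, covariates, reads


def simulate_case_control(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    stage: str = "stage1",
) -> pd.DataFrame:
    """A case-control cohort with a planted per-allele odds ratio.

    Disease probability is ``logistic(intercept + log(OR) * dosage +
    covariate terms)``; subjects are drawn in batches until the case and
    control quotas are filled.  Covariates: gender ~ Bernoulli(0.5),
    age ~ Normal(60, 10), smoking / drinking ~ Bernoulli(0.3).
    """
    rng = rng if rng is not None else cfg.rng(f"case_control:{stage}")
    log_or = np.log(cfg.planted_or)
    cases, controls = [], []
    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    guard = 0
    while need_cases > 0 or need_controls > 0:
        guard += 1
        if guard > 2000:
            raise RuntimeError("case-control sampling did not converge")
        b = 4 * (cfg.n_cases + cfg.n_controls)
        gender = rng.integers(0, 2, size=b).astype(float)
        age = rng.normal(60, 10, size=b)
        smoking = (rng.random(b) < 0.3).astype(float)
        drinking = (rng.random(b) < 0.3).astype(float)
        dosage = rng.binomial(2, cfg.assoc_maf, size=b).astype(float)
        eta = (
            cfg.assoc_intercept
            + log_or * dosage
            + 0.2 * gender
            + 0.02 * (age - 60)
            + 0.4 * smoking
            + 0.3 * drinking
        )
        prob = 1.0 / (1.0 + np.exp(-eta))
        if prob.mean() < 1e-6 or prob.mean() > 1 - 1e-6:
            raise ValueError("planted disease prevalence is numerically 0 or 1")
        y = (rng.random(b) < prob).astype(int)
        df = pd.DataFrame(
            {
                "phenotype": y,
                "dosage": dosage,
                "gender": gender,
                "age": age,
                "smoking": smoking,
                "drinking": drinking,
            }
        )
        new_cases = df[df["phenotype"] == 1].iloc[:need_cases]
        new_controls = df[df["phenotype"] == 0].iloc[:need_controls]
        cases.append(new_cases)
        controls.append(new_controls)
        need_cases -= len(new_cases)
        need_controls -= len(new_controls)
    out = pd.concat(cases + controls, ignore_index=True)
    out["stage"] = stage
    return out


@dataclass
class SimulatedDataset:
    """Everything one seed generates, plus the truth table."""

    cfg: SimulationConfig
    genes: list
    enhancers: IntervalSet  # all true enhancers, collisions included
    peaks: dict  # assay -> list[IntervalSet]
    genotypes: GenotypeMatrix
    truth: TruthTable
    expression: dict  # state -> dict(counts, gene_expr, covariates, reads)
    cohorts: dict  # stage -> DataFrame


def simulate_dataset(
    cfg: SimulationConfig,
    states: tuple = ("tumor", "normal"),
    stages: tuple = ("stage1", "stage2"),
    make_reads: bool = False,
) -> SimulatedDataset:
    """Generate a full coherent dataset for every pipeline stage."""
    genes, enhancers, enh_rows = simulate_genome(cfg)
    # expected surviving eRNA regions, with ids numbered exactly as the
    # analysis pipeline numbers them: TSS-flank collisions drop out before
    # region building, region collisions only at the coding filter (after
    # ids are assigned over the candidate set)
    post_tss = IntervalSet(
        GenomicInterval(r["chrom"], r["start"], r["end"])
        for r in enh_rows
        if r["kind"] != "tss_collision"
    )
    regions = filter_coding_overlap(
        build_erna_regions(post_tss, chrom_lengths={cfg.chrom: cfg.chrom_length}), genes
    )
    genotypes = simulate_genotypes(cfg).compute_metadata()
    rng_plant = cfg.rng("plant")
    qtl_effects = _plant_qtl_effects(genotypes, regions, cfg, rng_plant)
    target_links = _plant_target_links(regions, genes, qtl_effects, cfg, rng_plant)
    truth = TruthTable(
        enhancers=enh_rows,
        regions=[
            {
                "erna_id": r.erna_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
            }
            for r in regions
        ],
        qtl_effects=qtl_effects,
        target_links=target_links,
        planted_or=cfg.planted_or,
    )
    peaks = {
        assay: simulate_peaks(enhancers, cfg, assay=assay)
        for assay in ("ATAC", "H3K27ac")
    }
    expression = {}
    for state in states:
        counts, gene_em, covars, reads = simulate_expression(
            genotypes, regions, genes, cfg,
            qtl_effects=qtl_effects, target_links=target_links,
            state=state, make_reads=make_reads,
        )
        expression[state] = {
            "counts": counts, "gene_expr": gene_em, "covariates": covars, "reads": reads,
        }
    cohorts = {stage: simulate_case_control(cfg, stage=stage) for stage in stages}
    return SimulatedDataset(cfg, genes, enhancers, peaks, genotypes, truth, expression, cohorts)


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write every component in its standard on-disk format; returns paths."""
    from pathlib import Path

    from .genotype import write_vcf
    from .intervals import write_bed, write_gtf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"peaks": {}, "expression": {}}
    for assay, sets in ds.peaks.items():
        paths["peaks"][assay] = []
        for i, ps in enumerate(sets):
            p = out / f"peaks_{assay}_s{i + 1}.bed"
            write_bed(ps, p)
            paths["peaks"][assay].append(str(p))
    write_gtf(ds.genes, out / "genes.gtf")
    paths["genes"] = str(out / "genes.gtf")
    write_vcf(ds.genotypes, out / "genotypes.vcf")
    paths["genotypes"] = str(out / "genotypes.vcf")
    for state, parts in ds.expression.items():
        d = {}
        p = out / f"erna_counts_{state}.tsv"
        parts["counts"].values.to_csv(p, sep="\t")
        d["counts"] = str(p)
        p = out / f"library_sizes_{state}.tsv"
        parts["counts"].library_sizes.rename("library_size").to_csv(p, sep="\t")
        d["library_sizes"] = str(p)
        p = out / f"gene_expr_{state}.tsv"
        parts["gene_expr"].values.to_csv(p, sep="\t")
        d["gene_expr"] = str(p)
        p = out / f"covariates_{state}.tsv"
        parts["covariates"].to_csv(p, sep="\t")
        d["covariates"] = str(p)
        if parts["reads"] is not None:
            rd = out / f"reads_{state}"
            rd.mkdir(exist_ok=True)
            d["reads"] = {}
            for s, df in parts["reads"].items():
                rp = rd / f"{s}.bed"
                df.to_csv(rp, sep="\t", header=False, index=False)
                d["reads"][s] = str(rp)
        paths["expression"][state] = d
    paths["cohorts"] = {}
    for stage, df in ds.cohorts.items():
        p = out / f"cohort_{stage}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths["cohorts"][stage] = str(p)
    ds.truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")
    return paths
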