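"""Tumor/normal QTL sharing, expression-pattern classes, and target linking.

Sharing is defined at the (variant, eRNA) pair level: a pair significant in
both states is shared, otherwise it is tumor- or normal-specific.  eRNAs are
classed by how many cancer types detect them (1 = specific, 2-9 =
intermediate, >= 10 = ubiquitous).  Target genes are linked to eRNAs by
physical distance (region edge to gene TSS <= 1 Mb) combined with
co-expression: the partial correlation of eRNA and gene expression given
covariates (tumor purity above all), thresholded at |pcor| >= 0.3 and
Benjamini-Hochberg FDR < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GeneModel
from .quantify import ERNARegion, ExpressionMatrix

__all__ = [
    "classify_qtl_sharing",
    "effect_concordance",
    "classify_expression_pattern",
    "partial_correlation",
    "link_targets",
    "correlate_with_fractions",
]


def _pair_set(qtls) -> set:
    """Accept a set of (variant_id, erna_id) tuples or a QTL results table."""
    if isinstance(qtls, pd.DataFrame):
        df = qtls
        if "significant" in df.columns:
            df = df[df["significant"]]
        return set(map(tuple, df[["variant_id", "erna_id"]].to_numpy()))
    if hasattr(qtls, "significant_pairs"):  # CisQTLResults
        return qtls.significant_pairs
    return set(map(tuple, qtls))


def classify_qtl_sharing(tumor, normal) -> tuple[pd.DataFrame, dict]:
    """Classify (variant, eRNA) pairs as tumor_specific / normal_specific / shared.

    Accepts significant-pair sets, QTL tables, or fitted QTL results for
    each state.  Returns (calls, summary); summary percentages are relative
    to each state's own total, rounded to one decimal.
    """
    t_pairs, n_pairs = _pair_set(tumor), _pair_set(normal)
    shared = t_pairs & n_pairs
    rows = (
        [(v, e, "shared") for v, e in sorted(shared)]
        + [(v, e, "tumor_specific") for v, e in sorted(t_pairs - shared)]
        + [(v, e, "normal_specific") for v, e in sorted(n_pairs - shared)]
    )
    calls = pd.DataFrame(rows, columns=["variant_id", "erna_id", "class"])
    n_t, n_n, n_s = len(t_pairs), len(n_pairs), len(shared)
    summary = {
        "n_tumor": n_t,
        "n_normal": n_n,
        "n_shared": n_s,
        "n_tumor_specific": n_t - n_s,
        "n_normal_specific": n_n - n_s,
        "tumor_specific_pct": round(100.0 * (n_t - n_s) / n_t, 1) if n_t else float("nan"),
        "normal_specific_pct": round(100.0 * (n_n - n_s) / n_n, 1) if n_n else float("nan"),
    }
    return calls, summary


def effect_concordance(shared_betas: pd.DataFrame) -> tuple[float, float]:
    """Direction concordance and Pearson correlation of shared-pair betas.

    ``shared_betas`` needs columns beta_tumor / beta_normal.  A zero beta is
    counted as concordant with either sign (flagged with a warning).
    Returns (concordant fraction, Pearson r).
    """
    bt = shared_betas["beta_tumor"].to_numpy(dtype=float)
    bn = shared_betas["beta_normal"].to_numpy(dtype=float)
    if bt.size < 2:
        raise ValueError("need at least 2 shared pairs with both betas")
    zero = (bt == 0) | (bn == 0)
    if zero.any():
        warnings.warn(f"{zero.sum()} pair(s) with a zero beta counted as concordant")
    conc = float((zero | (np.sign(bt) == np.sign(bn))).mean())
    r = float(stats.pearsonr(bt, bn)[0])
    return conc, r


def classify_expression_pattern(detectability: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Class eRNAs by the number of cancer types detecting them.

    ``detectability`` is a boolean eRNA x cancer-type matrix.  Classes:
    specific (exactly 1 type), intermediate (2-9), ubiquitous (>= 10).
    eRNAs detected nowhere are excluded from the denominator and reported
    separately.  Percentages are rounded to two decimals.
    """
    n_types = detectability.astype(bool).sum(axis=1)
    detected = n_types[n_types > 0]
    cls = pd.Series(
        np.select(
            [detected == 1, detected <= 9], ["specific", "intermediate"], "ubiquitous"
        ),
        index=detected.index,
    )
    patterns = pd.DataFrame({"n_types_detected": detected, "class": cls})
    denom = len(detected)
    counts = cls.value_counts()
    summary = {"denominator": denom, "n_undetected": int((n_types == 0).sum())}
    for name in ("specific", "intermediate", "ubiquitous"):
        c = int(counts.get(name, 0))
        summary[f"n_{name}"] = c
        summary[f"{name}_pct"] = round(100.0 * c / denom, 2) if denom else float("nan")
    return patterns, summary


def partial_correlation(x, y, covars=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both vectors are residualized on [1, covars] by OLS and the residuals
    correlated; the p-value uses the t distribution with n - k - 2 degrees
    of freedom.  With no covariates this reduces to the plain Pearson
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covars is None or (hasattr(covars, "size") and np.size(covars) == 0):
        C = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covars, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        C = np.column_stack([np.ones(n), C])
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} samples, got {n}")
    coef_x, *_ = np.linalg.lstsq(C, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(C, y, rcond=None)
    rx = x - C @ coef_x
    ry = y - C @ coef_y
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx == 0 or sy == 0:
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def _region_tss_distance(region: ERNARegion, tss: int) -> int:
    if region.interval.start <= tss < region.interval.end:
        return 0
    if tss < region.interval.start:
        return region.interval.start - tss
    return tss - (region.interval.end - 1)


def link_targets(
    erna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    regions: list[ERNARegion],
    genes: list[GeneModel],
    covars: pd.DataFrame | None = None,
    window: int = 1_000_000,
    pcor_min: float = 0.3,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Link eRNAs to candidate target genes by distance plus co-expression.

    Candidates are (eRNA, gene) pairs whose region-edge-to-TSS distance is
    <= ``window``; each candidate gets a covariate-adjusted partial
    correlation, q-values are Benjamini-Hochberg over all candidates, and a
    link is reported when |pcor| >= ``pcor_min`` and q < ``fdr``.  The full
    candidate table is returned with a boolean ``linked`` column.
    """
    samples = list(erna_expr.samples)
    if list(gene_expr.samples) != samples:
        gene_expr = ExpressionMatrix(
            gene_expr.values.loc[:, samples], gene_expr.units, gene_expr.library_sizes
        )
    C = None if covars is None else covars.loc[samples].to_numpy(dtype=float)
    gene_map = {g.gene_id: g for g in genes}
    region_map = {r.erna_id: r for r in regions}
    rows = []
    for eid in erna_expr.features:
        r = region_map.get(eid)
        if r is None:
            continue
        x = erna_expr.values.loc[eid].to_numpy(dtype=float)
        for gid in gene_expr.features:
            g = gene_map.get(gid)
            if g is None or g.interval.chrom != r.interval.chrom:
                continue
            dist = _region_tss_distance(r, g.tss)
            if dist > window:
                continue
            y = gene_expr.values.loc[gid].to_numpy(dtype=float)
            try:
                pcor, p = partial_correlation(x, y, C)
            except ValueError:
                continue
            rows.append((eid, gid, dist, pcor, p))
    table = pd.DataFrame(rows, columns=["erna_id", "gene_id", "distance", "pcor", "p"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["linked"] = (table["pcor"].abs() >= pcor_min) & (table["q"] < fdr)
    else:
        table["q"] = pd.Series(dtype=float)
        table["linked"] = pd.Series(dtype=bool)
    return table


def correlate_with_fractions(
    erna_expr: ExpressionMatrix,
    fractions: pd.DataFrame,
    purity: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Purity-adjusted partial correlation of eRNAs with cell-type fractions.

    ``fractions`` is samples x cell types (supplied externally, e.g. from
    immune deconvolution); BH-FDR is applied across the whole
    eRNA x cell-type table.
    """
    samples = list(erna_expr.samples)
    frac = fractions.loc[samples]
    pur = purity.loc[samples].to_numpy(dtype=float)
    rows = []
    for eid in erna_expr.features:
        x = erna_expr.values.loc[eid].to_numpy(dtype=float)
        for ct in frac.columns:
            pcor, p = partial_correlation(x, frac[ct].to_numpy(dtype=float), pur)
            rows.append((eid, ct, pcor, p))
    table = pd.DataFrame(rows, columns=["erna_id", "cell_type", "pcor", "p"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] < fdr
    return table
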