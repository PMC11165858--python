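"""Matched-control construction and enrichment statistics for QTL variants.

Signal variants (e.g. significant eRNAQTL variants) are compared with
control variants drawn from the tested pool, matched on minor allele
frequency (0.05-wide bins over [0.05, 0.5]), number of LD proxies at
r^2 > 0.2 (binned 0 / 1-5 / 6-20 / 21-50 / >50), and variant type.
Per-feature enrichment is a two-sided Fisher exact test on the
in/out x signal/control 2x2 table with Bonferroni correction; GWAS overlap
is additionally summarized by pi1 (= 1 - pi0) of the GWAS p-values within a
variant category.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .qtl import storey_qvalues

__all__ = [
    "ld_proxy_counts",
    "variant_strata",
    "match_controls",
    "fisher_enrichment",
    "gwas_ld_block_enrichment",
    "pi1_gwas_enrichment",
    "enrichment_ratio_vs_expression",
]

MAF_BIN_EDGES = np.arange(0.05, 0.55, 0.05)
LD_BIN_EDGES = (0, 1, 6, 21, 51)  # bins: 0, 1-5, 6-20, 21-50, >50 proxies


def ld_proxy_counts(variant_ids, ld_table: pd.DataFrame, r2_min: float = 0.2) -> pd.Series:
    """Number of distinct partners with r^2 > ``r2_min`` per variant.

    ``ld_table`` has columns id_a, id_b, r2 (unordered pairs).
    """
    strong = ld_table[ld_table["r2"] > r2_min]
    counts = pd.Series(0, index=pd.Index(variant_ids, name="variant_id"), dtype=int)
    for col in ("id_a", "id_b"):
        vc = strong[col].value_counts()
        common = counts.index.intersection(vc.index)
        counts.loc[common] += vc.loc[common].astype(int)
    return counts


def _maf_bin(maf: np.ndarray) -> np.ndarray:
    return np.clip(np.digitize(maf, MAF_BIN_EDGES, right=False), 1, len(MAF_BIN_EDGES)) - 1


def variant_strata(annotations: pd.DataFrame) -> pd.DataFrame:
    """Matching-stratum coordinates per variant.

    ``annotations`` is indexed by variant id with columns maf,
    ld_proxy_count, variant_type; returns the same index with integer
    maf_bin / ld_bin columns plus a combined string label.
    """
    mb = _maf_bin(annotations["maf"].to_numpy(dtype=float))
    lb = np.digitize(annotations["ld_proxy_count"].to_numpy(dtype=float), LD_BIN_EDGES) - 1
    out = pd.DataFrame(
        {"maf_bin": mb, "ld_bin": lb, "variant_type": annotations["variant_type"]},
        index=annotations.index,
    )
    out["stratum"] = [
        f"maf{m}|ld{l}|{t}" for m, l, t in zip(mb, lb, out["variant_type"])
    ]
    return out


def match_controls(
    signal,
    annotations: pd.DataFrame,
    ratio: int = 1,
    seed: int | np.random.Generator = 0,
    pool=None,
) -> list:
    """Draw ``ratio`` stratum-matched control variants per signal variant.

    ``annotations`` (indexed by variant id, columns maf / ld_proxy_count /
    variant_type) must cover both the signal and the pool; the pool defaults
    to every annotated variant outside the signal.  Controls are drawn
    without replacement within the signal variant's (MAF bin, LD-proxy bin,
    variant type) stratum.  An exhausted stratum falls back to the nearest
    MAF bin with the same LD bin and type (with a warning); a signal variant
    with no eligible control left contributes none (logged via warning).
    Deterministic under a fixed seed.
    """
    signal = list(signal)
    missing = set(signal) - set(annotations.index)
    if missing:
        raise ValueError(f"signal variants missing from annotations: {sorted(missing)[:5]}")
    if pool is None:
        pool = annotations.index.difference(signal)
    else:
        pool = pd.Index(pool)
        if len(pool.intersection(signal)):
            raise ValueError("control pool must be disjoint from the signal set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strata = variant_strata(annotations)
    # per-stratum shuffled queues of available pool variants
    queues: dict[tuple, list] = {}
    for key, grp in strata.loc[pool].groupby(["maf_bin", "ld_bin", "variant_type"]):
        ids = list(grp.index)
        rng.shuffle(ids)
        queues[key] = ids
    controls: list = []
    n_fallback = n_unmatched = 0
    for vid in sorted(signal):  # sorted: independent of caller's set ordering
        m, l, t = strata.loc[vid, ["maf_bin", "ld_bin", "variant_type"]]
        for _ in range(ratio):
            q = queues.get((m, l, t))
            if q:
                controls.append(q.pop())
                continue
            # nearest-MAF-bin fallback, same LD bin and variant type
            picked = None
            for delta in range(1, len(MAF_BIN_EDGES)):
                for mb in (m - delta, m + delta):
                    q = queues.get((mb, l, t))
                    if q:
                        picked = q.pop()
                        break
                if picked is not None:
                    break
            if picked is None:
                n_unmatched += 1
            else:
                n_fallback += 1
                controls.append(picked)
    if n_fallback:
        warnings.warn(f"{n_fallback} control draw(s) used a nearest-MAF-bin fallback")
    if n_unmatched:
        warnings.warn(f"{n_unmatched} signal variant draw(s) found no eligible control")
    return controls


def _fisher_row(feature, a, b, c, d, n_tests) -> dict:
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    if min(a, b, c, d) == 0:  # Haldane-Anscombe continuity correction
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    or_ = (a_ * d_) / (b_ * c_)
    se_log = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return {
        "feature": feature,
        "a": a, "b": b, "c": c, "d": d,
        "or_": or_,
        "ci_low": math.exp(math.log(or_) - 1.959964 * se_log),
        "ci_high": math.exp(math.log(or_) + 1.959964 * se_log),
        "p": p,
        "p_adj": min(1.0, p * n_tests),
        "n_tests": n_tests,
    }


def fisher_enrichment(
    signal, controls, membership: dict, n_tests: int | None = None
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of signal vs controls per feature.

    ``membership`` maps feature name -> set of member variant ids.  The 2x2
    table per feature is (signal-in, signal-out, control-in, control-out);
    the odds ratio uses a Haldane-Anscombe +0.5 correction when any cell is
    zero, with a 95% CI from the log-OR normal approximation.  ``p_adj`` is
    Bonferroni over ``n_tests`` (default: number of features supplied).
    """
    signal, controls = set(signal), set(controls)
    if signal & controls:
        raise ValueError("signal and control sets must be disjoint")
    if n_tests is None:
        n_tests = len(membership)
    rows = []
    for feature, members in membership.items():
        members = set(members)
        a = len(signal & members)
        c = len(controls & members)
        rows.append(
            _fisher_row(feature, a, len(signal) - a, c, len(controls) - c, n_tests)
        )
    return pd.DataFrame(rows)


def gwas_ld_block_enrichment(
    qtl_variants,
    gwas_tags,
    ld_table: pd.DataFrame,
    controls,
    r2_min: float = 0.2,
) -> pd.DataFrame:
    """Enrichment of QTL variants in GWAS LD blocks.

    A variant is in the GWAS block when it is a tag SNP itself or has
    r^2 > ``r2_min`` with one.  Returns a single-feature
    :func:`fisher_enrichment` table.
    """
    tags = set(gwas_tags)
    members = set(tags)
    strong = ld_table[ld_table["r2"] > r2_min]
    members |= set(strong.loc[strong["id_a"].isin(tags), "id_b"])
    members |= set(strong.loc[strong["id_b"].isin(tags), "id_a"])
    return fisher_enrichment(
        qtl_variants, controls, {"gwas_ld_block": members}, n_tests=1
    )


def pi1_gwas_enrichment(category_variants: dict, gwas_p: pd.Series) -> pd.Series:
    """pi1 = 1 - pi0 of GWAS p-values per variant category.

    ``category_variants`` maps category name -> variant ids;  ``gwas_p``
    maps variant id -> GWAS p-value.  Categories with fewer than 100
    annotated p-values trigger a warning (pi0 estimation is noisy there).
    """
    out = {}
    for cat, ids in category_variants.items():
        pvals = gwas_p.reindex(pd.Index(set(ids))).dropna().to_numpy()
        if pvals.size == 0:
            out[cat] = np.nan
            continue
        if pvals.size < 100:
            warnings.warn(f"category {cat!r}: only {pvals.size} GWAS p-values; pi1 is noisy")
        out[cat] = storey_qvalues(pvals).pi1
    return pd.Series(out, name="pi1")


def enrichment_ratio_vs_expression(
    tumor_specific_or: pd.Series, shared_or: pd.Series, feature_fc: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between the log enrichment ratio and expression FC.

    The ratio is log(tumor-specific OR / shared OR) per feature; features
    with a non-positive OR are dropped with a warning.  Returns (rho, p).
    """
    common = tumor_specific_or.index.intersection(shared_or.index).intersection(
        feature_fc.index
    )
    ts, sh = tumor_specific_or.loc[common], shared_or.loc[common]
    ok = (ts > 0) & (sh > 0)
    if (~ok).any():
        warnings.warn(f"dropped {(~ok).sum()} feature(s) with non-positive OR")
    ratio = np.log(ts[ok] / sh[ok])
    rho, p = stats.spearmanr(ratio, feature_fc.loc[ratio.index])
    return float(rho), float(p)
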