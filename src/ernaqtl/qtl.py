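"""Covariate-adjusted cis linear-model QTL mapping with Storey FDR.

For every (variant, eRNA) pair within the cis window (1 Mb by default) the
normalized expression vector is regressed on allele dosage plus covariates
by ordinary least squares; the two-sided p-value of the dosage coefficient
comes from the t distribution.  Genome-wide significance is controlled by
Storey q-values computed over all tested pairs in the dataset (one nominal
pass; no permutation pass), with pairs at q < 0.05 flagged significant.

The modelling surface follows the Model -> fit() -> Results idiom:

>>> model = CisQTLModel(expr_scores, genotypes, covariates, regions)
>>> res = model.fit(fdr=0.05)
>>> res.significant          # significant pair table
>>> print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix
from .quantify import ERNARegion, ExpressionMatrix

__all__ = [
    "cis_pairs",
    "fit_linear_qtl",
    "storey_qvalues",
    "QValueResult",
    "CisQTLModel",
    "CisQTLResults",
    "map_ernaqtls",
]


class MonomorphicError(ValueError):
    """Dosage constant in the analysis subset; the test is undefined."""


def cis_pairs(
    variants: pd.DataFrame, regions: list[ERNARegion], window: int = 1_000_000
) -> list[tuple[str, str]]:
    """All (variant_id, erna_id) pairs with variant-to-region distance <= window.

    Distance is 0 for a variant inside the region, otherwise base pairs to
    the nearest covered base of the region; a variant at exactly ``window``
    is paired.  ``variants`` needs columns chrom, pos (0-based).
    """
    pairs = []
    by_chrom = {c: g.sort_values("pos") for c, g in variants.groupby("chrom")}
    for r in regions:
        grp = by_chrom.get(r.interval.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, r.interval.start - window, side="left")
        hi = np.searchsorted(pos, (r.interval.end - 1) + window, side="right")
        for vid in grp.index[lo:hi]:
            pairs.append((vid, r.erna_id))
    return pairs


def fit_linear_qtl(
    y: np.ndarray, dosage: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """OLS of y on [1, dosage, covariates]; returns (beta, se, t, p) for dosage.

    Samples with missing dosage or expression are dropped pairwise.  The
    two-sided p-value uses the t distribution with n - k - 2 degrees of
    freedom (k = number of covariates).  Raises :class:`MonomorphicError`
    when the dosage is constant after deletion.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep &= ~np.isnan(C).any(axis=1)
        C = C[keep]
    else:
        C = None
    y, g = y[keep], g[keep]
    n = y.size
    k = 0 if C is None else C.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete samples, got {n}")
    if np.all(g == g[0]):
        raise MonomorphicError("monomorphic-in-analysis")
    X = np.empty((n, k + 2))
    X[:, 0] = 1.0
    X[:, 1] = g
    if C is not None:
        X[:, 2:] = C
    xtx = X.T @ X
    xty = X.T @ y
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular design matrix (collinear covariates?)") from exc
    coef = xtx_inv @ xty
    resid = y - X @ coef
    df = n - (k + 2)
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    if se == 0.0:
        # exact fit: report an infinite statistic, p underflows to 0
        return beta, 0.0, np.inf if beta > 0 else -np.inf, 0.0
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, se, float(t), float(max(p, np.finfo(float).tiny))


@dataclass
class QValueResult:
    """Storey q-values with the estimated proportion of true nulls.

    ``pi0`` is in (0, 1]; ``pi1 = 1 - pi0`` is used as an enrichment
    statistic for GWAS p-value overlap.  ``qvalues`` aligns with the input
    p-value order.
    """

    pi0: float
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray
    qvalues: np.ndarray

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


def storey_qvalues(p, lambda_grid=None) -> QValueResult:
    """Storey's q-value procedure.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    (0.05..0.95 by 0.05 by default) and smoothed by a cubic polynomial fit;
    the smoothed value at the largest lambda, clipped to (0, 1], estimates
    pi0.  q-values are the step-up transform q_(i) = min_{j>=i}
    pi0 * m * p_(j) / j, capped at 1.  For fewer than 100 p-values the
    smoother is unstable and a fixed lambda = 0.5 estimate is used (with a
    warning).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) & ~np.isclose(p, 0)) or np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if m < 100:
        warnings.warn("fewer than 100 p-values: using fixed lambda = 0.5 for pi0")
        pi0 = (p > 0.5).sum() / (m * 0.5)
    else:
        coefs = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coefs, lam.max()))
    pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(pi0=pi0, lambda_grid=lam, pi0_lambda=pi0_lam, qvalues=q)


class CisQTLModel:
    """cis-QTL linear model over all (variant, eRNA) pairs within a window.

    Parameters
    ----------
    expression
        :class:`ExpressionMatrix` of normalized scores (features x samples).
    genotypes
        :class:`GenotypeMatrix`; samples must cover the expression samples.
    covariates
        Optional DataFrame (samples x covariates), all numeric: population
        structure components, batch indicators, age, sex, ordered tumor
        stage.  Consumed as supplied, never computed here.
    regions
        eRNA regions giving each feature its genomic location.
    window
        cis window in bp (distance from variant to region edge).
    state
        Label carried into the result table (e.g. 'tumor' or 'normal').
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        covariates: pd.DataFrame | None,
        regions: list[ERNARegion],
        window: int = 1_000_000,
        state: str = "",
    ):
        self.expression = expression
        self.genotypes = genotypes
        self.regions = {r.erna_id: r for r in regions}
        self.window = int(window)
        self.state = state
        samples = list(expression.samples)
        missing = set(samples) - set(genotypes.samples)
        if missing:
            raise ValueError(f"samples absent from genotypes: {sorted(missing)[:5]}")
        self.samples = samples
        if covariates is not None:
            missing_c = set(samples) - set(covariates.index)
            if missing_c:
                raise ValueError(f"samples absent from covariates: {sorted(missing_c)[:5]}")
            self.covariates = covariates.loc[samples].astype(float)
        else:
            self.covariates = None

    def fit(self, fdr: float = 0.05) -> "CisQTLResults":
        """Fit every cis pair, attach Storey q-values, flag q < fdr."""
        region_list = [self.regions[f] for f in self.expression.features if f in self.regions]
        pairs = cis_pairs(self.genotypes.variants, region_list, window=self.window)
        expr = self.expression.values.loc[:, self.samples]
        dos = self.genotypes.dosages.loc[:, self.samples]
        C = None if self.covariates is None else self.covariates.to_numpy()
        vmeta = self.genotypes.variants
        rows, skipped = [], []
        for vid, eid in pairs:
            y = expr.loc[eid].to_numpy(dtype=float)
            g = dos.loc[vid].to_numpy(dtype=float)
            try:
                beta, se, t, p = fit_linear_qtl(y, g, C)
            except MonomorphicError:
                skipped.append((vid, eid, "monomorphic-in-analysis"))
                continue
            n_used = int((~(np.isnan(y) | np.isnan(g))).sum())
            rows.append(
                (
                    vid, eid, vmeta.at[vid, "chrom"], int(vmeta.at[vid, "pos"]),
                    n_used, beta, se, t, p,
                )
            )
        table = pd.DataFrame(
            rows,
            columns=["variant_id", "erna_id", "chrom", "pos", "n", "beta", "se", "t", "p"],
        )
        if len(table):
            qres = storey_qvalues(table["p"].to_numpy())
            table["q"] = qres.qvalues
            table["significant"] = table["q"] < fdr
        else:
            qres = None
            table["q"] = pd.Series(dtype=float)
            table["significant"] = pd.Series(dtype=bool)
        table["state"] = self.state
        return CisQTLResults(model=self, table=table, qvalue_result=qres, fdr=fdr,
                             skipped=skipped)


@dataclass
class CisQTLResults:
    """Fitted cis-QTL associations: full pair table plus FDR bookkeeping."""

    model: CisQTLModel
    table: pd.DataFrame
    qvalue_result: QValueResult | None
    fdr: float
    skipped: list = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def significant_pairs(self) -> set:
        return set(map(tuple, self.significant[["variant_id", "erna_id"]].to_numpy()))

    @property
    def pi0(self) -> float:
        return self.qvalue_result.pi0 if self.qvalue_result else float("nan")

    def summary(self) -> str:
        t = self.table
        lines = [
            "cis-eRNAQTL mapping results" + (f" [{self.model.state}]" if self.model.state else ""),
            "=" * 46,
            f"samples:            {len(self.model.samples)}",
            f"cis window:         {self.model.window:,} bp",
            f"tested pairs:       {len(t):,}",
            f"skipped (monomorphic): {len(self.skipped)}",
            f"estimated pi0:      {self.pi0:.3f}",
            f"significant (q < {self.fdr:g}): {int(t['significant'].sum()):,}",
        ]
        if t["significant"].any():
            top = t.loc[t["p"].idxmin()]
            lines.append(
                f"top pair:           {top['variant_id']} x {top['erna_id']} "
                f"(beta={top['beta']:.3f}, p={top['p']:.3g}, q={top['q']:.3g})"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def map_ernaqtls(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    regions: list[ERNARegion],
    window: int = 1_000_000,
    fdr: float = 0.05,
    state: str = "",
) -> CisQTLResults:
    """Convenience wrapper: build a :class:`CisQTLModel` and fit it."""
    return CisQTLModel(expression, genotypes, covariates, regions, window, state).fit(fdr=fdr)
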