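"""eRNA region construction, read counting, normalization, and filtering.

eRNA-transcribing regions are the +/- ``half_width`` (3 kb) windows around
enhancer midpoints.  Regions overlapping a protein-coding gene extended by
1 kb at both termini are excluded.  Read counts are normalized to RPKM
(reads per kilobase per million mapped reads, where "mapped reads" is the
total number of reads in the sample's input, not reads-in-regions) or RPM.
For QTL mapping, expression is rank-transformed per feature to normal scores
(Blom offset), the standard guard against outlier-driven regression scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .enhancers import EnhancerSet
from .intervals import GeneModel, GenomicInterval, IntervalSet

__all__ = [
    "ERNARegion",
    "ExpressionMatrix",
    "build_erna_regions",
    "filter_coding_overlap",
    "count_reads",
    "rpkm",
    "rpm",
    "detectability_filter",
    "inverse_normal_transform",
]


@dataclass(frozen=True)
class ERNARegion:
    """A candidate eRNA-transcribing region centered on an enhancer midpoint.

    ``clipped`` flags regions truncated at a chromosome boundary (width then
    falls short of ``2 * half_width``).
    """

    erna_id: str
    interval: GenomicInterval
    source_midpoint: int
    clipped: bool = False

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class ExpressionMatrix:
    """Features x samples abundance with library-size metadata.

    ``units`` is one of ``counts``, ``RPKM``, ``RPM``, ``normal_scores``;
    count-like units must be non-negative.  ``feature_lengths`` (bp) is
    required for RPKM.
    """

    values: pd.DataFrame  # features x samples
    units: str = "counts"
    library_sizes: pd.Series | None = None  # total mapped reads per sample
    feature_lengths: pd.Series | None = None  # bp per feature

    def __post_init__(self):
        if self.units in ("counts", "RPKM", "RPM") and (self.values.values < 0).any():
            raise ValueError(f"negative values not allowed under units={self.units}")
        if self.library_sizes is not None:
            missing = set(self.values.columns) - set(self.library_sizes.index)
            if missing:
                raise ValueError(f"library_sizes missing samples: {sorted(missing)}")

    @property
    def features(self):
        return self.values.index

    @property
    def samples(self):
        return self.values.columns

    def subset(self, features) -> "ExpressionMatrix":
        fl = self.feature_lengths.loc[features] if self.feature_lengths is not None else None
        return ExpressionMatrix(
            self.values.loc[features], self.units, self.library_sizes, fl
        )


def build_erna_regions(
    enhancers: EnhancerSet | IntervalSet,
    half_width: int = 3000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[ERNARegion]:
    """+/- ``half_width`` windows around enhancer midpoints.

    Midpoint is ``floor((start + end) / 2)``.  Regions running past position
    0 (or past a supplied chromosome length) are clipped and flagged.
    Duplicate coordinates are deduplicated; overlapping regions are kept as
    is (one region per enhancer).  Ids are assigned in coordinate order.
    """
    ivs = enhancers.intervals if isinstance(enhancers, EnhancerSet) else enhancers
    if len(ivs) == 0:
        return []
    seen = set()
    regions = []
    for iv in ivs:  # IntervalSet iterates in coordinate order
        mid = iv.midpoint
        start = mid - half_width
        end = mid + half_width
        clipped = False
        if start < 0:
            start, clipped = 0, True
        if chrom_lengths is not None and iv.chrom in chrom_lengths:
            limit = chrom_lengths[iv.chrom]
            if end > limit:
                end, clipped = limit, True
        key = (iv.chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        regions.append(
            ERNARegion(
                erna_id=f"eRNA_{len(regions) + 1:05d}",
                interval=GenomicInterval(iv.chrom, start, end),
                source_midpoint=mid,
                clipped=clipped,
            )
        )
    return regions


def filter_coding_overlap(
    regions: list[ERNARegion], genes: list[GeneModel], extension: int = 1000
) -> list[ERNARegion]:
    """Drop regions overlapping any protein-coding gene extended by
    ``extension`` bp beyond both termini (>= 1 bp overlap removes)."""
    ext: dict[str, list] = {}
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        ext.setdefault(g.interval.chrom, []).append(
            (max(0, g.interval.start - extension), g.interval.end + extension)
        )
    ext_arr = {c: np.asarray(sorted(v), dtype=np.int64) for c, v in ext.items()}
    kept = []
    for r in regions:
        arr = ext_arr.get(r.interval.chrom)
        if arr is not None:
            hit = (arr[:, 0] < r.interval.end) & (arr[:, 1] > r.interval.start)
            if hit.any():
                continue
        kept.append(r)
    return kept


def _reads_to_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    if isinstance(reads, IntervalSet):
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in reads],
                "start": [iv.start for iv in reads],
                "end": [iv.end for iv in reads],
            }
        )
    raise TypeError(f"unsupported read container {type(reads)}")


def count_reads(
    regions: list[ERNARegion],
    alignments: dict[str, "pd.DataFrame | IntervalSet"],
    multi_count: str = "all",
) -> ExpressionMatrix:
    """Count reads per region and sample.

    A read is assigned to a region when >= 1 bp overlaps.  Under the default
    ``multi_count='all'`` policy a read overlapping k regions contributes a
    full count to each (regions may legitimately overlap after the +/- 3 kb
    expansion); ``'fractional'`` contributes 1/k instead.  Library size is
    the total number of reads in the sample's input.
    """
    if multi_count not in ("all", "fractional"):
        raise ValueError(f"unknown multi_count policy {multi_count!r}")
    region_ids = [r.erna_id for r in regions]
    by_chrom: dict[str, list] = {}
    for idx, r in enumerate(regions):
        by_chrom.setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end, idx)
        )
    counts = pd.DataFrame(0.0, index=region_ids, columns=list(alignments))
    lib = {}
    for sample, reads in alignments.items():
        df = _reads_to_frame(reads)
        lib[sample] = len(df)
        col = np.zeros(len(regions))
        for chrom, grp in df.groupby("chrom", sort=False):
            regs = by_chrom.get(chrom)
            if not regs:
                continue
            rs = np.sort(grp["start"].to_numpy())
            re_ = np.sort(grp["end"].to_numpy())
            if multi_count == "all":
                # reads overlapping [s, e): start < e minus end <= s
                for s, e, idx in regs:
                    col[idx] += np.searchsorted(rs, e, side="left") - np.searchsorted(
                        re_, s, side="right"
                    )
            else:
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                regs_arr = np.asarray([(s, e) for s, e, _ in regs])
                idxs = [i for _, _, i in regs]
                for s0, e0 in zip(starts, ends):
                    hit = np.nonzero((regs_arr[:, 0] < e0) & (regs_arr[:, 1] > s0))[0]
                    if hit.size:
                        w = 1.0 / hit.size
                        for h in hit:
                            col[idxs[h]] += w
        counts[sample] = col
    lengths = pd.Series({r.erna_id: r.length for r in regions}, dtype=float)
    return ExpressionMatrix(
        counts, units="counts", library_sizes=pd.Series(lib, dtype=float),
        feature_lengths=lengths,
    )


def rpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads."""
    if counts.units != "counts":
        raise ValueError(f"expected counts, got units={counts.units}")
    if counts.library_sizes is None or counts.feature_lengths is None:
        raise ValueError("RPKM requires library_sizes and feature_lengths")
    lib = counts.library_sizes.loc[counts.samples]
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero/negative library size for samples: {bad}")
    kb = counts.feature_lengths.loc[counts.features] / 1000.0
    vals = counts.values.div(lib / 1e6, axis=1).div(kb, axis=0)
    return ExpressionMatrix(vals, "RPKM", counts.library_sizes, counts.feature_lengths)


def rpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per million mapped reads (no length normalization)."""
    if counts.units != "counts":
        raise ValueError(f"expected counts, got units={counts.units}")
    if counts.library_sizes is None:
        raise ValueError("RPM requires library_sizes")
    lib = counts.library_sizes.loc[counts.samples]
    if (lib <= 0).any():
        raise ValueError("zero/negative library size")
    return ExpressionMatrix(
        counts.values.div(lib / 1e6, axis=1), "RPM", counts.library_sizes,
        counts.feature_lengths,
    )


_MODE_DEFAULTS = {"rpkm_cohort": ("RPKM", 0.5, 0.5), "rpm_tcga": ("RPM", 1.0, 0.5)}


def detectability_filter(
    expr: ExpressionMatrix,
    min_mean: float | None = None,
    min_frac_samples: float | None = None,
    mode: str = "rpkm_cohort",
) -> ExpressionMatrix:
    """Keep features with mean >= ``min_mean`` and expressed (nonzero) in
    strictly more than ``min_frac_samples`` of samples.

    Mode defaults: ``rpkm_cohort`` keeps mean RPKM >= 0.5 in > 50% of
    samples; ``rpm_tcga`` keeps mean RPM >= 1 in > 50% of samples.
    """
    if mode not in _MODE_DEFAULTS:
        raise ValueError(f"unknown mode {mode!r}")
    units, d_mean, d_frac = _MODE_DEFAULTS[mode]
    if expr.units != units:
        raise ValueError(f"mode {mode} expects units {units}, got {expr.units}")
    min_mean = d_mean if min_mean is None else min_mean
    min_frac_samples = d_frac if min_frac_samples is None else min_frac_samples
    means = expr.values.mean(axis=1)
    frac = (expr.values > 0).mean(axis=1)
    keep = expr.features[(means >= min_mean) & (frac > min_frac_samples)]
    return expr.subset(keep)


def inverse_normal_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature rank-based inverse-normal transform.

    Values are replaced by ``Phi^-1((rank - 3/8) / (n + 1/4))`` with average
    ranks for ties (Blom scores).  Invariant to any strictly monotone
    transform of the input.  Constant features map to all zeros with a
    warning.
    """
    n = expr.values.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    out = np.empty_like(expr.values.to_numpy(dtype=float))
    constant = []
    for i, (fid, row) in enumerate(expr.values.iterrows()):
        x = row.to_numpy(dtype=float)
        if np.all(x == x[0]):
            out[i] = 0.0
            constant.append(fid)
            continue
        ranks = rankdata(x, method="average")
        out[i] = ndtri((ranks - 0.375) / (n + 0.25))
    if constant:
        warnings.warn(
            f"{len(constant)} constant feature(s) set to all-zero scores: "
            f"{constant[:5]}{'...' if len(constant) > 5 else ''}"
        )
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.features, columns=expr.samples),
        units="normal_scores",
        library_sizes=expr.library_sizes,
        feature_lengths=expr.feature_lengths,
    )
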