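"""Active-enhancer annotation from replicate chromatin peak sets.

Enhancers are called in three steps: (1) per assay, keep the sub-regions of
the peak union supported by at least ``min_support`` distinct samples
(support is resolved per base, which is robust to boundary jitter and
independent of sample order); (2) intersect open-chromatin (ATAC) peaks with
H3K27ac peaks, reporting the ATAC interval by default (accessibility defines
the element, the acetylation mark confirms activity); (3) drop any candidate
overlapping a TSS +/- flank window (2.5 kb by default) of any gene — whole
peaks are removed, never trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    _check_chrom_compat,
    intersect,
    merge,
)

__all__ = [
    "EnhancerSet",
    "reproducible_peaks",
    "candidate_enhancers",
    "exclude_tss_flanks",
    "annotate_enhancers",
]


@dataclass
class EnhancerSet:
    """The annotated enhancer intervals plus provenance counts.

    ``provenance`` records how many peak samples per assay supported the
    annotation and how many candidates the TSS filter removed.
    """

    intervals: IntervalSet
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def reproducible_peaks(peak_sets: list[IntervalSet], min_support: int = 2) -> IntervalSet:
    """Sub-regions of the peak union supported by >= ``min_support`` samples.

    Each sample's peaks are merged first, so one sample contributes at most
    one unit of support per base.  Returns the supported segments (trimmed
    to where the support criterion holds), merged across abutments.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(peak_sets) < min_support:
        raise ValueError(
            f"need at least min_support={min_support} peak sets, got {len(peak_sets)}"
        )
    # event sweep: +1 at each merged-peak start, -1 at each end, per chrom
    events: dict[str, list] = {}
    for ps in peak_sets:
        for chrom, arr in merge(ps).by_chrom().items():
            ev = events.setdefault(chrom, [])
            for s, e in arr:
                ev.append((s, 1))
                ev.append((e, -1))
    out = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        support = 0
        seg_start = None
        for pos, delta in ev:
            new_support = support + delta
            if support < min_support <= new_support:
                seg_start = pos
            elif new_support < min_support <= support:
                if pos > seg_start:
                    out.append(GenomicInterval(chrom, int(seg_start), int(pos)))
                seg_start = None
            support = new_support
    return merge(IntervalSet(out))


def candidate_enhancers(
    atac: IntervalSet, h3k27ac: IntervalSet, report: str = "a"
) -> IntervalSet:
    """ATAC intervals with >= 1 bp of H3K27ac overlap (both assays active).

    ``report='segment'`` returns the overlap segments instead of the full
    ATAC intervals.
    """
    _check_chrom_compat(atac, h3k27ac)
    return intersect(atac, h3k27ac, min_overlap=1, report=report)


def exclude_tss_flanks(
    candidates: IntervalSet, genes: list[GeneModel], flank: int = 2500
) -> EnhancerSet:
    """Remove candidates overlapping any TSS +/- ``flank`` window.

    The window is ``[tss - flank, tss + flank + 1)``: +/- flank bases around
    the TSS base itself.  Any overlap removes the whole candidate.
    """
    windows = IntervalSet(
        [
            GenomicInterval(
                g.interval.chrom, max(0, g.tss - flank), g.tss + flank + 1, id=g.gene_id
            )
            for g in genes
        ]
    )
    win_by_chrom = merge(windows).by_chrom() if len(windows) else {}
    kept = []
    for iv in candidates:
        arr = win_by_chrom.get(iv.chrom)
        if arr is not None:
            lo = np.searchsorted(arr[:, 1], iv.start, side="right")
            hi = np.searchsorted(arr[:, 0], iv.end, side="left")
            if hi > lo:
                continue
        kept.append(iv)
    return EnhancerSet(
        IntervalSet(kept, label=candidates.label),
        provenance={
            "candidates_in": len(candidates),
            "removed_tss_flank": len(candidates) - len(kept),
            "flank": flank,
        },
    )


def annotate_enhancers(
    atac_sets: list[IntervalSet],
    h3k27ac_sets: list[IntervalSet],
    genes: list[GeneModel],
    min_support: int = 2,
    tss_flank: int = 2500,
    report: str = "a",
) -> EnhancerSet:
    """Full annotation pipeline: reproducibility per assay, assay
    intersection, TSS-flank exclusion."""
    atac = reproducible_peaks(atac_sets, min_support=min_support)
    k27 = reproducible_peaks(h3k27ac_sets, min_support=min_support)
    cands = candidate_enhancers(atac, k27, report=report)
    enh = exclude_tss_flanks(cands, genes, flank=tss_flank)
    enh.provenance.update(
        {
            "atac_samples": len(atac_sets),
            "h3k27ac_samples": len(h3k27ac_sets),
            "min_support": min_support,
            "atac_reproducible": len(atac),
            "h3k27ac_reproducible": len(k27),
        }
    )
    return enh
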