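"""Genomic interval containers and arithmetic.

All coordinates are 0-based, half-open (BED convention) everywhere in the
package.  GTF input is converted on read (1-based inclusive -> 0-based
half-open).  Chromosome names are never normalized: a ``chr1`` vs ``1``
mismatch between two inputs raises :class:`ChromNameError` rather than being
silently reconciled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "BedParseError",
    "ChromNameError",
    "read_bed",
    "write_bed",
    "read_gene_annotation",
    "write_gtf",
    "merge",
    "intersect",
    "total_length",
]


class BedParseError(ValueError):
    """A malformed line in a BED/GTF file; message names the line number."""


class ChromNameError(ValueError):
    """Two inputs use incompatible chromosome naming conventions."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``'+'``, ``'-'``, ``'.'``; ``id`` is an optional
    feature name.  ``attrs`` keeps any extra BED columns verbatim.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None
    attrs: tuple = ()

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`, grouped by chromosome.

    May contain overlapping intervals unless passed through :func:`merge`.
    Iteration order is deterministic: chromosome (lexicographic), then
    (start, end).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self._ivs: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self._ivs)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._ivs)

    def __getitem__(self, i):
        return self._ivs[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(iv.chrom, iv.start, iv.end) for iv in self] == [
            (iv.chrom, iv.start, iv.end) for iv in other
        ]

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self._ivs})

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Return ``{chrom: (n, 2) int array of [start, end)}`` sorted by start."""
        out: dict[str, list] = {}
        for iv in self._ivs:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self._ivs],
                "start": [iv.start for iv in self._ivs],
                "end": [iv.end for iv in self._ivs],
                "id": [iv.id for iv in self._ivs],
                "strand": [iv.strand for iv in self._ivs],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-resolved TSS/TES.

    TSS is ``start`` on the '+' strand and ``end - 1`` on the '-' strand
    (the last covered base in half-open coordinates); TES is the opposite
    terminus.  ``biotype == 'protein_coding'`` marks the gene as eligible
    for the coding-overlap exclusion applied to eRNA regions.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand {self.interval.strand!r} leaves TSS undefined"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


def _check_chrom_compat(a: IntervalSet, b: IntervalSet) -> None:
    """Raise ChromNameError when two non-empty sets share no chromosome but a
    'chr'-prefix toggle would reconcile them."""
    ca, cb = set(a.chroms()), set(b.chroms())
    if not ca or not cb or ca & cb:
        return
    toggled = {c[3:] if c.startswith("chr") else "chr" + c for c in ca}
    if toggled & cb:
        raise ChromNameError(
            "chromosome naming mismatch between inputs: "
            f"{sorted(ca)} vs {sorted(cb)} (add/strip 'chr' upstream)"
        )


def read_bed(path, label: str = "") -> IntervalSet:
    """Read a BED3+ file (tab-separated, no header) into an :class:`IntervalSet`.

    Extra columns beyond the first six are retained in ``attrs``.  Malformed
    lines raise :class:`BedParseError` naming the offending line number.
    """
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            try:
                ivs.append(
                    GenomicInterval(
                        parts[0], start, end, strand=strand, id=name,
                        attrs=tuple(parts[6:]),
                    )
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(ivs, label=label or str(path))


def write_bed(iset: IntervalSet, path) -> None:
    """Write an IntervalSet as BED6 in deterministic order (chrom, start)."""
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n"
            )


def _parse_gtf_attrs(raw: str) -> dict:
    out = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gene_annotation(path, dialect: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF or BED12.

    GTF: ``gene`` features are used when present, otherwise gene extents are
    the union of that gene's transcripts.  1-based inclusive coordinates are
    converted to 0-based half-open.  Records without a strand raise, since
    the TSS would be undefined.

    BED12: the name column is the gene id; BED carries no biotype so genes
    default to ``protein_coding`` (the conservative choice for the coding
    exclusion filter).
    """
    if dialect == "bed12":
        genes = []
        for iv in read_bed(path):
            if iv.strand not in ("+", "-"):
                raise ValueError(f"BED12 record {iv.id or iv.start}: strand missing, TSS undefined")
            genes.append(GeneModel(iv.id or f"{iv.chrom}:{iv.start}", iv))
        return genes
    if dialect != "gtf":
        raise ValueError(f"unknown dialect {dialect!r}")

    gene_rows: dict[str, dict] = {}
    seen_gene_feature = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise BedParseError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attrs_raw = parts[:9]
            if feature not in ("gene", "transcript"):
                continue
            attrs = _parse_gtf_attrs(attrs_raw)
            gid = attrs.get("gene_id")
            if gid is None:
                raise BedParseError(f"{path}:{lineno}: missing gene_id attribute")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: gene {gid} strand {strand!r}, TSS undefined")
            start0, end0 = int(start) - 1, int(end)  # GTF is 1-based inclusive
            biotype = attrs.get("gene_type", attrs.get("gene_biotype", "protein_coding"))
            row = gene_rows.get(gid)
            if feature == "gene" or (row is None and gid not in seen_gene_feature):
                if feature == "gene":
                    seen_gene_feature.add(gid)
                    gene_rows[gid] = dict(
                        chrom=chrom, start=start0, end=end0, strand=strand, biotype=biotype
                    )
                elif row is None:
                    gene_rows[gid] = dict(
                        chrom=chrom, start=start0, end=end0, strand=strand, biotype=biotype
                    )
            elif gid not in seen_gene_feature:
                row["start"] = min(row["start"], start0)
                row["end"] = max(row["end"], end0)
    return [
        GeneModel(
            gid,
            GenomicInterval(r["chrom"], r["start"], r["end"], strand=r["strand"], id=gid),
            biotype=r["biotype"],
        )
        for gid, r in gene_rows.items()
    ]


def write_gtf(genes: Iterable[GeneModel], path, source: str = "ernaqtl") -> None:
    """Write gene models as GTF ``gene`` features (1-based inclusive)."""
    genes = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";\n'
            )


def merge(iset: IntervalSet) -> IntervalSet:
    """Maximal non-overlapping cover of an interval set.

    Abutting intervals ([0,5), [5,10)) merge: downstream region logic treats
    coverage, not interval identity.  Idempotent.
    """
    out = []
    for chrom, arr in iset.by_chrom().items():
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s <= cur_e:  # overlap or abutment under half-open coordinates
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return IntervalSet(out, label=iset.label)


def _overlap_bases(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> int:
    """Total bases of [s, e) covered by the disjoint sorted intervals (starts, ends)."""
    lo = np.searchsorted(ends, s, side="right")
    hi = np.searchsorted(starts, e, side="left")
    if hi <= lo:
        return 0
    ov = np.minimum(ends[lo:hi], e) - np.maximum(starts[lo:hi], s)
    return int(np.clip(ov, 0, None).sum())


def intersect(
    a: IntervalSet,
    b: IntervalSet,
    min_overlap: int = 1,
    report: str = "a",
) -> IntervalSet:
    """Intervals of ``a`` with at least ``min_overlap`` bases covered by ``b``.

    ``report='a'`` returns the qualifying ``a`` intervals unchanged;
    ``report='segment'`` returns the covered sub-segments instead.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if report not in ("a", "segment"):
        raise ValueError(f"unknown report mode {report!r}")
    _check_chrom_compat(a, b)
    b_merged = merge(b).by_chrom() if len(b) else {}
    out = []
    for iv in a:
        arr = b_merged.get(iv.chrom)
        if arr is None:
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        if _overlap_bases(starts, ends, iv.start, iv.end) < min_overlap:
            continue
        if report == "a":
            out.append(iv)
        else:
            lo = np.searchsorted(ends, iv.start, side="right")
            hi = np.searchsorted(starts, iv.end, side="left")
            for s, e in zip(
                np.maximum(starts[lo:hi], iv.start), np.minimum(ends[lo:hi], iv.end)
            ):
                if e > s:
                    out.append(GenomicInterval(iv.chrom, int(s), int(e), strand=iv.strand, id=iv.id))
    return IntervalSet(out, label=a.label)


def total_length(iset: IntervalSet) -> int:
    """Union length in bases (merges first, so overlaps are not double-counted)."""
    return sum(len(iv) for iv in merge(iset))
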