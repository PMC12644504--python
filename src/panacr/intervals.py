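"""Coordinate-safe genomic interval algebra and text-format readers/writers.

All coordinates are 0-based half-open (the BED convention) everywhere in the
package; GFF3, which is 1-based inclusive, is converted on read and write.
Strand is carried but ignored by all overlap computations — chromatin
accessibility is unstranded; strand only matters for TSS-relative
orientation in :mod:`panacr.annotation`.

Bookended intervals ([100,200) and [200,300)) fuse during :meth:`IntervalSet.merge`
with ``min_gap=0``: reduce-style fusing, which keeps union length stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``extras`` keeps dialect-specific columns (narrowPeak signal/p/q/summit,
    TE superfamily, ...) so files round-trip bit-exactly.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.chrom:
            raise UsageError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise UsageError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self):
        return (self.chrom, self.start, self.end)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An immutable, canonically sorted collection of :class:`GenomicInterval`.

    Sorted by (chrom, start, end). ``total_bp`` is the union length only
    after :meth:`merge`.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._intervals = sorted(intervals, key=lambda iv: iv.key)
        self._by_chrom_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @classmethod
    def from_arrays(cls, chroms, starts, ends) -> "IntervalSet":
        return cls(
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(chroms, starts, ends)
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [iv.key for iv in self] == [iv.key for iv in other]

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, bp={self.total_bp})"

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self._intervals)

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-contig (starts, ends) arrays, sorted by start."""
        if self._by_chrom_cache is None:
            out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, group in itertools.groupby(self._intervals, key=lambda iv: iv.chrom):
                ivs = list(group)
                out[chrom] = (
                    np.array([iv.start for iv in ivs], dtype=np.int64),
                    np.array([iv.end for iv in ivs], dtype=np.int64),
                )
            self._by_chrom_cache = out
        return self._by_chrom_cache

    # ------------------------------------------------------------------ algebra

    def merge(self, min_gap: int = 0) -> "IntervalSet":
        """Fuse intervals closer than or equal to ``min_gap`` (bookended fuse at 0)."""
        out = []
        for chrom, (starts, ends) in self.by_chrom().items():
            ms, me = merge_arrays(starts, ends, min_gap)
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(ms, me)
            )
        return IntervalSet(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Exact bp-intersection of the two unions."""
        a = self.merge()
        b = other.merge()
        out = []
        bmap = b.by_chrom()
        for chrom, (sa, ea) in a.by_chrom().items():
            if chrom not in bmap:
                continue
            sb, eb = bmap[chrom]
            i = j = 0
            while i < len(sa) and j < len(sb):
                lo = max(sa[i], sb[j])
                hi = min(ea[i], eb[j])
                if lo < hi:
                    out.append(GenomicInterval(chrom, int(lo), int(hi)))
                if ea[i] <= eb[j]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """bp of this union not covered by ``other`` (complement intersection)."""
        a = self.merge()
        bmap = other.merge().by_chrom()
        out = []
        for chrom, (sa, ea) in a.by_chrom().items():
            if chrom not in bmap:
                out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(sa, ea))
                continue
            sb, eb = bmap[chrom]
            for s, e in zip(sa, ea):
                cur = s
                j = int(np.searchsorted(eb, s, side="right"))
                while j < len(sb) and sb[j] < e:
                    if sb[j] > cur:
                        out.append(GenomicInterval(chrom, int(cur), int(sb[j])))
                    cur = max(cur, eb[j])
                    j += 1
                if cur < e:
                    out.append(GenomicInterval(chrom, int(cur), int(e)))
        return IntervalSet(out)

    def overlaps_any(
        self, reference: "IntervalSet", min_bp: int = 1
    ) -> tuple["IntervalSet", "IntervalSet"]:
        """Partition queries into (hit, miss) by >= min_bp shared with any single
        reference interval."""
        if min_bp < 1:
            raise UsageError(f"min_bp must be >= 1, got {min_bp}")
        mask = self.overlap_mask(reference, min_bp)
        hits = [iv for iv, m in zip(self._intervals, mask) if m]
        misses = [iv for iv, m in zip(self._intervals, mask) if not m]
        return IntervalSet(hits), IntervalSet(misses)

    def overlap_mask(self, reference: "IntervalSet", min_bp: int = 1) -> np.ndarray:
        """Boolean per query interval (in canonical order)."""
        if min_bp < 1:
            raise UsageError(f"min_bp must be >= 1, got {min_bp}")
        refmap = {}
        for chrom, (sr, er) in reference.by_chrom().items():
            refmap[chrom] = (sr, er, np.maximum.accumulate(er))
        mask = np.zeros(len(self._intervals), dtype=bool)
        for i, iv in enumerate(self._intervals):
            if iv.chrom not in refmap:
                continue
            sr, er, ecum = refmap[iv.chrom]
            hi = int(np.searchsorted(sr, iv.end - min_bp, side="right"))
            lo = int(np.searchsorted(ecum[:hi], iv.start + min_bp, side="left"))
            if lo < hi:
                ov = np.minimum(er[lo:hi], iv.end) - np.maximum(sr[lo:hi], iv.start)
                mask[i] = bool((ov >= min_bp).any())
        return mask

    def max_overlap_bp(self, reference: "IntervalSet") -> np.ndarray:
        """Total union-bp shared per query with the reference union."""
        refmap = reference.merge().by_chrom()
        out = np.zeros(len(self._intervals), dtype=np.int64)
        for i, iv in enumerate(self._intervals):
            if iv.chrom not in refmap:
                continue
            sr, er = refmap[iv.chrom]
            lo = int(np.searchsorted(er, iv.start, side="right"))
            hi = int(np.searchsorted(sr, iv.end, side="left"))
            if lo < hi:
                ov = np.minimum(er[lo:hi], iv.end) - np.maximum(sr[lo:hi], iv.start)
                out[i] = int(np.clip(ov, 0, None).sum())
        return out

    def genome_fraction(self, genome: "GenomeSpec", denominator: str = "assembly") -> float:
        """Percent of the genome covered by the union of this set."""
        if denominator == "assembly":
            denom = genome.assembly_size
        elif denominator == "effective":
            denom = genome.effective_size
        else:
            raise UsageError(f"denominator must be 'assembly' or 'effective', got {denominator!r}")
        if denom <= 0:
            raise UsageError("denominator must be positive")
        return 100.0 * self.merge().total_bp / denom


def merge_arrays(starts: np.ndarray, ends: np.ndarray, min_gap: int = 0):
    """Merge sorted-by-start (starts, ends) arrays; returns merged arrays."""
    if len(starts) == 0:
        return starts, ends
    cummax = np.maximum.accumulate(ends)
    breaks = starts[1:] > cummax[:-1] + min_gap
    idx = np.flatnonzero(np.concatenate(([True], breaks)))
    ms = starts[idx]
    me = np.maximum.reduceat(ends, idx)
    return ms, me


class GenomeSpec:
    """Contig lengths plus the effective genome size used as a denominator.

    The effective size defaults to the assembly length but may differ (e.g.
    a mappable-genome size supplied to the peak caller).
    """

    def __init__(self, contigs: Mapping[str, int], effective_size: int | None = None):
        self.contigs = dict(contigs)
        for c, l in self.contigs.items():
            if l <= 0:
                raise UsageError(f"contig {c!r} has non-positive length {l}")
        self._effective = effective_size
        if effective_size is not None and effective_size <= 0:
            raise UsageError("effective_size must be positive")

    @property
    def assembly_size(self) -> int:
        return sum(self.contigs.values())

    @property
    def effective_size(self) -> int:
        return self._effective if self._effective is not None else self.assembly_size

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs

    def validate(self, intervals: Iterable[GenomicInterval], source: str = "") -> None:
        """Exact contig-name matching; raises on unknown contigs or out-of-bounds ends."""
        for iv in intervals:
            if iv.chrom not in self.contigs:
                raise ValidationError(
                    f"{source}: contig {iv.chrom!r} absent from genome spec"
                )
            if iv.end > self.contigs[iv.chrom]:
                raise ValidationError(
                    f"{source}: interval [{iv.start},{iv.end}) exceeds contig "
                    f"{iv.chrom} length {self.contigs[iv.chrom]}"
                )


@dataclass
class GeneModel:
    """A gene with 0-based half-open body [start, end) and strand-aware TSS/TTS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise UsageError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise UsageError(f"invalid gene body [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        """bp coordinate of the transcription start (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """bp coordinate of the transcription termination (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> IntervalSet:
        """Gene-body bp not covered by exons."""
        body = IntervalSet([GenomicInterval(self.chrom, self.start, self.end)])
        if len(self.exons) == 0:
            return IntervalSet()
        return body.subtract(self.exons)


# ---------------------------------------------------------------------- readers

_DIALECT_COLS = {
    "bed3": 3,
    "bed6": 6,
    "narrowPeak": 10,
    "bedgraph": 4,
    "te_bed": 4,
    "sweep_table": 4,
    "chrom_sizes": 2,
}


def read_chrom_sizes(path, effective_size: int | None = None) -> GenomeSpec:
    df = _read_table(path, 2)
    return GenomeSpec(
        {str(c): int(l) for c, l in zip(df[0], df[1])}, effective_size=effective_size
    )


def read_intervals(path, dialect: str, genome: GenomeSpec | None = None) -> IntervalSet:
    """Read a tab-separated interval file in one of the supported dialects.

    Coordinates are taken as 0-based half-open. Raises :class:`FormatError`
    with the 1-based line number on malformed records.
    """
    if dialect not in _DIALECT_COLS:
        raise UsageError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECT_COLS)}")
    if dialect == "chrom_sizes":
        raise UsageError("use read_chrom_sizes() for the chrom_sizes dialect")
    df = _read_table(path, _DIALECT_COLS[dialect])
    bad = df.index[(df[1].astype(np.int64) >= df[2].astype(np.int64))]
    if len(bad):
        line = int(bad[0]) + 1
        raise FormatError(
            f"start >= end ({df.loc[bad[0], 1]} >= {df.loc[bad[0], 2]})",
            path=path,
            line=line,
        )
    intervals = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if dialect == "bed3":
            iv = GenomicInterval(chrom, start, end)
        elif dialect == "bed6":
            iv = GenomicInterval(
                chrom, start, end,
                strand=str(row[5]), name=str(row[3]), score=float(row[4]),
            )
        elif dialect == "narrowPeak":
            iv = GenomicInterval(
                chrom, start, end,
                strand=str(row[5]), name=str(row[3]), score=float(row[4]),
                extras={
                    "signal": float(row[6]),
                    "pvalue": float(row[7]),
                    "qvalue": float(row[8]),
                    "summit": int(row[9]),
                },
            )
        elif dialect == "bedgraph":
            iv = GenomicInterval(chrom, start, end, score=float(row[3]))
        elif dialect == "te_bed":
            iv = GenomicInterval(
                chrom, start, end, name=str(row[3]),
                extras={"superfamily": str(row[3])},
            )
        elif dialect == "sweep_table":
            iv = GenomicInterval(chrom, start, end, score=float(row[3]))
        intervals.append(iv)
    s = IntervalSet(intervals)
    if genome is not None:
        genome.validate(s, source=str(path))
    return s


def _read_table(path, ncols: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=range(ncols))
    if df.shape[1] != ncols:
        raise FormatError(
            f"expected {ncols} columns, found {df.shape[1]}", path=path
        )
    return df


def read_methylation(path) -> pd.DataFrame:
    """Per-cytosine calls: chrom, 0-based pos, strand, context, methylated, total."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "pos", "strand", "context", "methylated", "total"],
        dtype={"chrom": str, "pos": np.int64, "strand": str, "context": str,
               "methylated": np.int64, "total": np.int64},
    )
    bad = df.index[(df["methylated"] < 0) | (df["methylated"] > df["total"])]
    if len(bad):
        raise FormatError("methylated count outside [0, total]", path=path,
                          line=int(bad[0]) + 1)
    unknown = set(df["context"]) - {"CpG", "CHG", "CHH"}
    if unknown:
        raise FormatError(f"unknown methylation context(s): {sorted(unknown)}", path=path)
    return df


# ---------------------------------------------------------------------- writers

def write_intervals(s: IntervalSet, path, dialect: str) -> None:
    with open(path, "w") as fh:
        for iv in s:
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_fmt(iv.score)}\t{iv.strand}\n"
                )
            elif dialect == "narrowPeak":
                x = iv.extras
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_fmt(iv.score)}\t{iv.strand}\t{_fmt(x.get('signal', 0.0))}\t"
                    f"{_fmt(x.get('pvalue', -1.0))}\t{_fmt(x.get('qvalue', -1.0))}\t"
                    f"{int(x.get('summit', (iv.length // 2)))}\n"
                )
            elif dialect == "te_bed":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.extras.get('superfamily', iv.name or '.')}\n"
                )
            elif dialect == "sweep_table":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt(iv.score)}\n")
            else:
                raise UsageError(f"unsupported write dialect {dialect!r}")


def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.contigs.items():
            fh.write(f"{chrom}\t{length}\n")


def _fmt(x) -> str:
    if x is None:
        return "0"
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


# ------------------------------------------------------------------------- GFF3

def read_gff3(path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3, converting to
    0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                exons=IntervalSet(exons),
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tpanacr\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tpanacr\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )
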