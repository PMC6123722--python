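"""Alignment record access and tumor-side read selection.

Reads are modelled by a light :class:`AlignedRead` record so that the caller
core operates identically on records fetched from an indexed BAM/SAM via
pysam and on in-memory read lists produced by the simulator.

Tumor reads are filtered before assembly (duplicates, low mapping quality,
likely multi-mapped reads); normal-sample reads are deliberately used
unfiltered to maximize sensitivity for alleles present in the normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AlignedRead",
    "ReadIndex",
    "ReadSelectionParams",
    "ContigNotFoundError",
    "IndexRequiredError",
    "fetch_reads",
    "is_multimapped",
    "select_tumor_reads",
]

_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MD=XN")


class ContigNotFoundError(KeyError):
    """Requested contig is absent from the alignment source."""


class IndexRequiredError(ValueError):
    """Random access requested on an unindexed alignment source."""


@dataclass
class AlignedRead:
    """One aligned sequencing read (0-based coordinates, BAM convention)."""

    qname: str
    chrom: str
    start: int
    mapq: int
    seq: str
    quals: np.ndarray  # per-base Phred integers
    cigar: list[tuple[str, int]]  # ops in {M,I,D,S,H,=,X,N}
    md: str | None = None
    mate: int = 0  # 0 for first-in-pair, 1 for second
    is_duplicate: bool = False
    is_reverse: bool = False
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    mate_start: int = -1
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.qname}: seq/qual length mismatch")
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if self.cigar and qlen != len(self.seq):
            raise ValueError(f"{self.qname}: CIGAR does not span the sequence")
        if self.mapq < 0:
            raise ValueError(f"{self.qname}: negative MAPQ")
        self._end = self.start + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self._end

    @property
    def read_id(self) -> tuple[str, int]:
        return (self.qname, self.mate)

    @property
    def lead_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def tail_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @classmethod
    def from_pysam(cls, aln) -> "AlignedRead":
        cigar = [("MIDNSHP=XB"[op], n) for op, n in (aln.cigartuples or [])]
        tags = dict(aln.get_tags())
        md = tags.pop("MD", None)
        quals = aln.query_qualities
        if quals is None:
            quals = np.full(len(aln.query_sequence or ""), 30, dtype=np.int16)
        return cls(
            qname=aln.query_name,
            chrom=aln.reference_name,
            start=aln.reference_start,
            mapq=aln.mapping_quality,
            seq=aln.query_sequence or "",
            quals=np.asarray(quals, dtype=np.int16),
            cigar=cigar,
            md=md,
            mate=1 if aln.is_read2 else 0,
            is_duplicate=aln.is_duplicate,
            is_reverse=aln.is_reverse,
            is_unmapped=aln.is_unmapped,
            is_secondary=aln.is_secondary,
            is_supplementary=aln.is_supplementary,
            mate_start=aln.next_reference_start,
            tags=tags,
        )


@dataclass
class ReadSelectionParams:
    """Tumor-side read-selection thresholds."""

    min_mapq: int = 15
    as_xs_delta: int = 5
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


def _overlaps_window(read: AlignedRead, start: int, end: int) -> bool:
    # Soft-clip anchors extend the effective span so that clipped evidence
    # at the window boundary is retained for active-region detection.
    s = read.start - read.lead_clip
    e = read.end + read.tail_clip
    return s < end and e > start


class ReadIndex:
    """Coordinate index over an in-memory read list for windowed fetches."""

    def __init__(self, reads: Iterable[AlignedRead]) -> None:
        from bisect import bisect_left

        self._bisect = bisect_left
        by_chrom: dict[str, list[AlignedRead]] = {}
        for r in reads:
            if r.is_unmapped or r.is_secondary or r.is_supplementary:
                continue
            by_chrom.setdefault(r.chrom, []).append(r)
        self._reads: dict[str, list[AlignedRead]] = {}
        self._starts: dict[str, list[int]] = {}
        self._max_span: dict[str, int] = {}
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: (r.start, r.qname, r.mate))
            self._reads[chrom] = rs
            self._starts[chrom] = [r.start for r in rs]
            self._max_span[chrom] = max(
                (r.end + r.tail_clip) - (r.start - r.lead_clip) for r in rs
            )

    def fetch(self, chrom: str, start: int, end: int) -> list[AlignedRead]:
        rs = self._reads.get(chrom)
        if rs is None:
            return []
        lo = self._bisect(self._starts[chrom], start - self._max_span[chrom])
        hi = self._bisect(self._starts[chrom], end)
        return [r for r in rs[lo:hi] if _overlaps_window(r, start, end)]


def fetch_reads(source, window) -> list[AlignedRead]:
    """Primary, mapped reads overlapping a half-open window, coordinate order.

    ``source`` is a ``pysam.AlignmentFile`` (index required), a
    :class:`ReadIndex`, or an iterable of :class:`AlignedRead`. Secondary and
    supplementary records are excluded.
    """
    chrom, start, end = window.chrom, window.start, window.end
    if isinstance(source, ReadIndex):
        return source.fetch(chrom, start, end)
    if hasattr(source, "fetch"):  # pysam.AlignmentFile
        if chrom not in source.references:
            raise ContigNotFoundError(chrom)
        try:
            it = source.fetch(chrom, start, end)
        except ValueError as exc:
            raise IndexRequiredError(str(exc)) from exc
        out = []
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            out.append(AlignedRead.from_pysam(aln))
        return out
    reads = [
        r
        for r in source
        if r.chrom == chrom
        and not (r.is_unmapped or r.is_secondary or r.is_supplementary)
        and _overlaps_window(r, start, end)
    ]
    reads.sort(key=lambda r: (r.start, r.qname, r.mate))
    return reads


def is_multimapped(read: AlignedRead, delta: int = 5) -> bool:
    """Heuristic multi-mapping test.

    True when the best and second-best alignment scores are within ``delta``
    (BWA-MEM AS/XS tags), when the read is tagged as a repeat hit (BWA-ALN
    XT == 'R'), or when alternative hits are listed in XA.
    """
    tags = read.tags
    a, x = tags.get("AS"), tags.get("XS")
    if a is not None and x is not None and abs(a - x) <= delta:
        return True
    if tags.get("XT") == "R":
        return True
    if tags.get("XA"):
        return True
    return False


def select_tumor_reads(
    reads: Sequence[AlignedRead], params: ReadSelectionParams | None = None
) -> list[AlignedRead]:
    """Apply the tumor-side selection rules, preserving input order.

    Excludes marked duplicates, low-MAPQ reads and likely multi-mapped reads.
    Normal-sample reads must not pass through this filter.
    """
    p = params or ReadSelectionParams()
    out = []
    for r in reads:
        if p.drop_duplicates and r.is_duplicate:
            continue
        if r.mapq < p.min_mapq:
            continue
        # a negative delta disables the multi-mapping heuristic altogether
        if p.as_xs_delta >= 0 and is_multimapped(r, p.as_xs_delta):
            continue
        out.append(r)
    return out
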