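"""Window decomposition and active-region detection.

The target space is tiled with overlapping fixed-size windows (default
600 bp, stepping by half a window so every locus sits well inside at least
one window). A window is worth assembling ("active") only when at least N
distinct reads support a mismatch, indel or soft-clip at the same locus in
the tumor or in the normal; everything else is skipped, as is any window
with a pathological pile-up of reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .sam_io import AlignedRead

__all__ = [
    "Window",
    "EvidenceLocus",
    "make_windows",
    "read_evidence",
    "is_active",
    "is_overmapped",
]

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int
    ref_seq: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty window")
        if len(self.ref_seq) != self.end - self.start:
            raise ValueError("ref_seq length does not match window span")


@dataclass(frozen=True)
class EvidenceLocus:
    pos: int  # 0-based genomic coordinate
    kind: str  # mismatch | insertion | deletion | softclip
    read_id: tuple[str, int]


class MalformedRecordError(ValueError):
    """CIGAR/MD string could not be parsed; message names the read."""


def make_windows(
    intervals: Iterable[tuple[str, int, int]],
    ref,
    window_size: int = 600,
    step: int | None = None,
) -> list[Window]:
    """Tile half-open intervals with overlapping windows.

    ``ref`` maps contig names to sequences (a dict or ``pysam.FastaFile``).
    Adjacent windows overlap by ``window_size - step``; the final window of
    each interval is clipped to the interval end.
    """
    if step is None:
        step = window_size // 2
    if not (0 < step <= window_size):
        raise ValueError("require 0 < step <= window_size")

    def contig_len(chrom: str) -> int:
        if hasattr(ref, "get_reference_length"):
            return ref.get_reference_length(chrom)
        return len(ref[chrom])

    def fetch(chrom: str, s: int, e: int) -> str:
        if hasattr(ref, "fetch"):
            return ref.fetch(chrom, s, e).upper()
        return ref[chrom][s:e].upper()

    out: list[Window] = []
    for chrom, start, end in intervals:
        clen = contig_len(chrom)
        if start < 0 or end > clen:
            raise ValueError(f"interval {chrom}:{start}-{end} exceeds contig length {clen}")
        if end <= start:
            continue
        pos = start
        while True:
            wend = min(pos + window_size, end)
            out.append(Window(chrom, pos, wend, fetch(chrom, pos, wend)))
            if wend >= end:
                break
            pos += step
    return out


def _md_mismatch_offsets(md: str, qname: str) -> list[int]:
    """Reference offsets (from alignment start) of MD-reported mismatches."""
    offsets: list[int] = []
    ref_off = 0
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise MalformedRecordError(f"bad MD string {md!r} for read {qname}")
        pos = m.end()
        num, dele, sub = m.groups()
        if num is not None:
            ref_off += int(num)
        elif dele is not None:
            ref_off += len(dele) - 1
        else:
            offsets.append(ref_off)
            ref_off += 1
    if pos != len(md):
        raise MalformedRecordError(f"bad MD string {md!r} for read {qname}")
    return offsets


def read_evidence(read: AlignedRead, window: Window | None = None) -> list[EvidenceLocus]:
    """Evidence loci (mismatch/indel/softclip) for one read.

    Mismatches come from the MD tag when present; otherwise, when the read's
    window is supplied, from direct comparison against the window reference.
    Indels are anchored at the reference base preceding the op; soft clips
    at the clip boundary.
    """
    loci: list[EvidenceLocus] = []
    rid = read.read_id
    ref_pos = read.start
    q_pos = 0
    n_m = 0
    for op, n in read.cigar:
        if op in "M=X":
            if op == "X":
                for i in range(n):
                    loci.append(EvidenceLocus(ref_pos + i, "mismatch", rid))
            if window is not None and read.md is None and op in "M=":
                ws, we = window.start, window.end
                for i in range(n):
                    g = ref_pos + i
                    if ws <= g < we and window.ref_seq[g - ws] != read.seq[q_pos + i]:
                        loci.append(EvidenceLocus(g, "mismatch", rid))
            n_m += n
            ref_pos += n
            q_pos += n
        elif op == "I":
            loci.append(EvidenceLocus(ref_pos - 1, "insertion", rid))
            q_pos += n
        elif op == "D":
            loci.append(EvidenceLocus(ref_pos - 1, "deletion", rid))
            ref_pos += n
        elif op == "N":
            ref_pos += n
        elif op == "S":
            # leading clip anchors at the alignment start, trailing at the end
            loci.append(EvidenceLocus(read.start if q_pos == 0 else ref_pos, "softclip", rid))
            q_pos += n
        elif op in "HP":
            continue
        else:
            raise MalformedRecordError(f"unknown CIGAR op {op!r} in read {read.qname}")
    if read.md is not None:
        if read.md != str(n_m):  # fast path: all-match MD
            base = read.start
            for off in _md_mismatch_offsets(read.md, read.qname):
                loci.append(EvidenceLocus(base + off, "mismatch", rid))
    return loci


def _has_supported_locus(reads: Sequence[AlignedRead], window: Window, n_min: int) -> bool:
    support: dict[tuple[int, str], set] = {}
    for r in reads:
        for loc in read_evidence(r, window):
            key = (loc.pos, loc.kind)
            s = support.setdefault(key, set())
            s.add(loc.read_id)
            if len(s) >= n_min:
                return True
    return False


def is_active(
    tumor_reads: Sequence[AlignedRead],
    normal_reads: Sequence[AlignedRead],
    window: Window,
    n_min: int = 3,
) -> bool:
    """True iff some (pos, kind) locus is supported by >= n_min distinct reads
    in the tumor or in the normal sample."""
    return _has_supported_locus(tumor_reads, window, n_min) or _has_supported_locus(
        normal_reads, window, n_min
    )


def is_overmapped(reads: Sequence[AlignedRead], max_reads: int = 10000) -> bool:
    """True iff strictly more than ``max_reads`` reads map to the window."""
    return len(reads) > max_reads
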