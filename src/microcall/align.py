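"""Affine-gap alignment of haplotypes to the window reference and variant
signature extraction.

Haplotypes span anchor k-mer to anchor k-mer, so they are aligned end-to-end
(free end gaps are allowed on the reference side only). The Gotoh
three-matrix recurrence is used; a gap of length L costs
``gap_open + L * gap_extend``. Mismatch columns become SNVs, maximal gap
runs become single insertions/deletions with a one-base left anchor, and
indels are shifted to their leftmost equivalent representation before
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._dna import encode

__all__ = [
    "AlignScoring",
    "Alignment",
    "RawVariant",
    "AlleleCounts",
    "swg_align",
    "extract_variants",
    "left_normalize",
    "count_support",
]


@dataclass(frozen=True)
class AlignScoring:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass
class Alignment:
    hap_aln: str
    ref_aln: str
    score: int
    ref_start: int  # offset of the first aligned reference base


_DIAG, _FROM_E, _FROM_F = 0, 1, 2


@njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_ext, free_ref_ends):
    """Gotoh DP, global on a (haplotype), optionally free end gaps on b."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (consumes a)
    TH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    TE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extension
    TF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    H[0, 0] = 0
    for j in range(1, m + 1):
        if free_ref_ends:
            H[0, j] = 0
        else:
            E[0, j] = gap_open + j * gap_ext
            H[0, j] = E[0, j]
            TH[0, j] = _FROM_E
            if j > 1:
                TE[0, j] = 1
    for i in range(1, n + 1):
        F[i, 0] = gap_open + i * gap_ext
        H[i, 0] = F[i, 0]
        TH[i, 0] = _FROM_F
        if i > 1:
            TF[i, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + sub
            e_open = H[i, j - 1] + gap_open + gap_ext
            e_ext = E[i, j - 1] + gap_ext
            if e_ext > e_open:
                E[i, j] = e_ext
                TE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open + gap_ext
            f_ext = F[i - 1, j] + gap_ext
            if f_ext > f_open:
                F[i, j] = f_ext
                TF[i, j] = 1
            else:
                F[i, j] = f_open
            best = diag
            tb = _DIAG
            if E[i, j] > best:
                best = E[i, j]
                tb = _FROM_E
            if F[i, j] > best:
                best = F[i, j]
                tb = _FROM_F
            H[i, j] = best
            TH[i, j] = tb
    if free_ref_ends:
        end_j = m
        best = H[n, m]
        for j in range(m, -1, -1):
            if H[n, j] > best:
                best = H[n, j]
                end_j = j
        score = best
    else:
        end_j = m
        score = H[n, m]
    # traceback: ops 0 = diag, 1 = consume ref only, 2 = consume hap only
    ops = np.empty(n + m + 2, dtype=np.uint8)
    nops = 0
    i, j = n, end_j
    while i > 0 or j > 0:
        if i == 0 and free_ref_ends:
            break
        state = TH[i, j]
        if i == 0:
            state = _FROM_E
        elif j == 0:
            state = _FROM_F
        if state == _DIAG:
            ops[nops] = 0
            nops += 1
            i -= 1
            j -= 1
        elif state == _FROM_E:
            while j > 0 and TE[i, j] == 1:
                ops[nops] = 1
                nops += 1
                j -= 1
            ops[nops] = 1
            nops += 1
            j -= 1
        else:
            while i > 0 and TF[i, j] == 1:
                ops[nops] = 2
                nops += 1
                i -= 1
            ops[nops] = 2
            nops += 1
            i -= 1
    return score, ops[:nops][::-1].copy(), j, end_j


def swg_align(hap_seq: str, ref_seq: str, scoring: AlignScoring | None = None,
              free_ref_ends: bool = True) -> Alignment:
    """Optimal affine-gap alignment of a haplotype against the reference
    window, end-to-end on the haplotype."""
    if not hap_seq or not ref_seq:
        raise ValueError("empty sequence")
    sc = scoring or AlignScoring()
    a = encode(hap_seq).astype(np.int16)
    b = encode(ref_seq).astype(np.int16)
    score, ops, ref_start, _ = _gotoh(
        a, b, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend, free_ref_ends
    )
    hap_parts = []
    ref_parts = []
    i, j = 0, ref_start
    for op in ops:
        if op == 0:
            hap_parts.append(hap_seq[i])
            ref_parts.append(ref_seq[j])
            i += 1
            j += 1
        elif op == 1:
            hap_parts.append("-")
            ref_parts.append(ref_seq[j])
            j += 1
        else:
            hap_parts.append(hap_seq[i])
            ref_parts.append("-")
            i += 1
    return Alignment("".join(hap_parts), "".join(ref_parts), int(score), int(ref_start))


@dataclass
class RawVariant:
    """A normalized-representation-ready variant signature."""

    chrom: str
    pos: int  # 0-based genomic coordinate of the first ref allele base
    ref_allele: str
    alt_allele: str
    vtype: str  # SNV | INS | DEL
    haplotype_id: int = 0
    hap_start: int = 0  # alt-allele span within the haplotype (incl. anchor)
    hap_end: int = 0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def extract_variants(
    alignment: Alignment,
    window,
    ref_offset: int = 0,
    haplotype_id: int = 0,
) -> list[RawVariant]:
    """Parse an alignment into SNV/INS/DEL signatures in genomic coordinates.

    ``ref_offset`` is the window-relative offset at which the aligned
    reference slice begins (the source anchor position).
    """
    out: list[RawVariant] = []
    ha, ra = alignment.hap_aln, alignment.ref_aln
    base = window.start + ref_offset + alignment.ref_start
    ref_pos = 0  # consumed ref bases
    hap_pos = 0
    col = 0
    ncol = len(ha)
    while col < ncol:
        h, r = ha[col], ra[col]
        if h != "-" and r != "-":
            if h != r:
                out.append(
                    RawVariant(
                        window.chrom,
                        base + ref_pos,
                        r,
                        h,
                        "SNV",
                        haplotype_id,
                        hap_start=hap_pos,
                        hap_end=hap_pos + 1,
                    )
                )
            ref_pos += 1
            hap_pos += 1
            col += 1
        elif r == "-":  # insertion in haplotype
            run = col
            while run < ncol and ra[run] == "-":
                run += 1
            ins = ha[col:run]
            if ref_pos > 0 and hap_pos > 0:
                anchor = ra[_last_ref_col(ra, col)]
                out.append(
                    RawVariant(
                        window.chrom,
                        base + ref_pos - 1,
                        anchor,
                        anchor + ins,
                        "INS",
                        haplotype_id,
                        hap_start=hap_pos - 1,
                        hap_end=hap_pos + len(ins),
                    )
                )
            hap_pos += run - col
            col = run
        else:  # deletion in haplotype
            run = col
            while run < ncol and ha[run] == "-":
                run += 1
            dele = ra[col:run]
            if ref_pos > 0 and hap_pos > 0:
                anchor_col = _last_hap_col(ha, col)
                anchor = ha[anchor_col]
                out.append(
                    RawVariant(
                        window.chrom,
                        base + ref_pos - 1,
                        anchor + dele,
                        anchor,
                        "DEL",
                        haplotype_id,
                        hap_start=hap_pos - 1,
                        hap_end=hap_pos,
                    )
                )
            ref_pos += run - col
            col = run
    return out


def _last_ref_col(ra: str, col: int) -> int:
    j = col - 1
    while j >= 0 and ra[j] == "-":
        j -= 1
    return j


def _last_hap_col(ha: str, col: int) -> int:
    j = col - 1
    while j >= 0 and ha[j] == "-":
        j -= 1
    return j


def left_normalize(v: RawVariant, ref_fetch) -> RawVariant:
    """Shift an indel to its leftmost equivalent representation.

    ``ref_fetch(chrom, start, end)`` returns reference sequence. SNVs are
    returned unchanged; the operation is idempotent.
    """
    if v.vtype == "SNV":
        return v
    pos, ref, alt = v.pos, v.ref_allele, v.alt_allele
    changed = True
    while changed:
        changed = False
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        elif (len(ref) == 1 or len(alt) == 1) and ref[-1] == alt[-1] and pos > 0:
            b = ref_fetch(v.chrom, pos - 1, pos)
            if not b:
                break
            ref, alt = b + ref[:-1], b + alt[:-1]
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return RawVariant(
        v.chrom, pos, ref, alt, v.vtype, v.haplotype_id, v.hap_start, v.hap_end
    )


@dataclass
class AlleleCounts:
    """Strand-split graph-derived allele support in both samples."""

    alt_t: int = 0
    alt_tf: int = 0
    alt_tr: int = 0
    ref_t: int = 0
    alt_n: int = 0
    alt_nf: int = 0
    alt_nr: int = 0
    ref_n: int = 0

    @property
    def vaf_t(self) -> float:
        d = self.alt_t + self.ref_t
        return self.alt_t / d if d else 0.0

    @property
    def vaf_n(self) -> float:
        d = self.alt_n + self.ref_n
        return self.alt_n / d if d else 0.0

    @property
    def depth_t(self) -> int:
        return self.alt_t + self.ref_t

    @property
    def depth_n(self) -> int:
        return self.alt_n + self.ref_n


def _union_counts(
    graph, kmers, novel_only: bool = False
) -> tuple[tuple[int, int, int], tuple[int, int, int]] | None:
    """Distinct-fragment (total, forward, reverse) per sample over k-mers.

    With ``novel_only`` k-mers also present on the reference path are
    excluded (they carry no allele-specific evidence); returns None when no
    usable k-mer remains.
    """
    nodes = []
    for km in kmers:
        if not km or not graph.has_node(km):
            continue
        node = graph.node(km)
        if novel_only and node.is_ref:
            continue
        nodes.append(node)
    if novel_only and not nodes:
        return None
    out = []
    for attr in ("rt", "rn"):
        strands: dict[str, bool] = {}
        for node in nodes:
            for q, bits in getattr(node, attr).items():
                if q not in strands:
                    strands[q] = bool(bits & 0b100)
        rev = sum(strands.values())
        out.append((len(strands), len(strands) - rev, rev))
    return out[0], out[1]


def count_support(v: RawVariant, haplotype, cg, window, graph=None) -> AlleleCounts:
    """Allele support as per-base read coverage at the variant locus.

    Any read covering a base contains at least one k-mer containing that
    base, so the distinct-fragment union over the variant-spanning k-mers of
    the alt haplotype equals the read-level alt allele count (mate overlaps
    deduplicated by fragment name); reference support is the same union over
    the reference-path k-mers covering the locus. Strand splits attribute
    each fragment to the strand of its first covering mate.

    When the raw graph is unavailable, counts fall back to the k-mer count
    of the node centered on the locus, a close per-fragment approximation.
    """
    k = cg.k
    hs = v.hap_start
    he = v.hap_end
    nk_h = len(haplotype.seq) - k + 1
    # evidence k-mers must reach PAD bases beyond every junction edge: a
    # k-mer with a thinner anchor is within the repeat screen's mismatch
    # tolerance of a reference k-mer and can be spelled by a lone
    # sequencing error in either sample
    pad = 3
    if v.vtype == "SNV":
        idxs = list(range(hs - k + 1, hs + 1))  # k-mers containing the base
    elif v.vtype == "INS":
        ins_lo, ins_hi = hs + 1, he  # inserted bases in haplotype coords

        def ins_ok(i: int) -> bool:
            ins_in_kmer = min(i + k, ins_hi) - max(i, ins_lo)
            if i <= ins_lo - pad and i + k >= ins_hi + pad:
                return True  # brackets the whole insertion with pad anchors
            if i <= ins_lo - pad and ins_in_kmer >= pad:
                return True  # left junction, enough novel content
            if i + k >= ins_hi + pad and ins_in_kmer >= pad:
                return True  # right junction, enough novel content
            return ins_lo <= i and i + k <= ins_hi  # fully inside insertion

        idxs = [i for i in range(ins_lo - k, ins_hi + 1) if ins_ok(i)]
    else:  # DEL: k-mers bracketing the junction with pad on each side
        idxs = [i for i in range(hs + 1 + pad - k, hs + 2 - pad)]
    idxs = [i for i in idxs if 0 <= i < nk_h]
    lo, hi = (min(idxs), max(idxs) + 1) if idxs else (0, 0)

    w_off = v.pos - window.start
    nk_r = len(window.ref_seq) - k + 1
    if v.vtype == "SNV":
        rlo, rhi = w_off - k + 1, w_off + 1
    elif v.vtype == "DEL":
        rlo, rhi = w_off + 2 - k, w_off + len(v.ref_allele)
    else:  # INS: reference fragments spanning the insertion point
        rlo, rhi = w_off + 2 - k, w_off + 1
    rlo, rhi = max(rlo, 0), min(rhi, nk_r)

    alt_union = None
    if graph is not None:
        alt_kmers = [haplotype.seq[i : i + k] for i in idxs]
        # only k-mers absent from the reference window carry allele-specific
        # evidence (indels in repetitive context spell reference k-mers
        # across their junction)
        alt_union = _union_counts(graph, alt_kmers, novel_only=True)
    if alt_union is not None:
        ref_kmers = [window.ref_seq[i : i + k] for i in range(rlo, rhi)]
        (alt_t, alt_tf, alt_tr), (alt_n, alt_nf, alt_nr) = alt_union
        (ref_t, _, _), (ref_n, _, _) = _union_counts(graph, ref_kmers)
    else:
        def node_at(arr, idx, a, b):
            if b <= a:
                return 0
            return int(arr[min(max(idx, a), b - 1)])

        idx = (lo + hi - 1) // 2
        ridx = (rlo + rhi - 1) // 2
        talt = haplotype.tf + haplotype.tr
        nalt = haplotype.nf + haplotype.nr
        alt_t = node_at(talt, idx, lo, hi)
        alt_tf = node_at(haplotype.tf, idx, lo, hi)
        alt_tr = node_at(haplotype.tr, idx, lo, hi)
        alt_n = node_at(nalt, idx, lo, hi)
        alt_nf = node_at(haplotype.nf, idx, lo, hi)
        alt_nr = node_at(haplotype.nr, idx, lo, hi)
        tref = cg.ref_tf + cg.ref_tr
        nref = cg.ref_nf + cg.ref_nr
        ref_t = node_at(tref, ridx, rlo, rhi)
        ref_n = node_at(nref, ridx, rlo, rhi)
    return AlleleCounts(
        alt_t=alt_t,
        alt_tf=alt_tf,
        alt_tr=alt_tr,
        ref_t=ref_t,
        alt_n=alt_n,
        alt_nf=alt_nf,
        alt_nr=alt_nr,
        ref_n=ref_n,
    )
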