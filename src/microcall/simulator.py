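"""Synthetic paired-end tumor/normal data with known somatic variants.

Two layers are provided:

* a read simulator that samples fragments uniformly from an (optionally
  edited) haplotype, applies a uniform per-base substitution error, and
  emits alignment records with exact CIGAR/MD strings against the original
  reference (placement is known, so no external mapper is involved);
* a virtual-tumor builder that emulates read swapping between a homozygous
  variant donor and a homozygous reference recipient: at each selected
  locus, N ~ Binomial(n covering fragments, mu) recipient fragments are
  replaced with donor fragments, yielding somatic variants at controlled
  allele fractions with a matching truth set.

Mate strands alternate with the covering mate, so both strands support real
variants; a single-strand mode reproduces a pathological strand-bias
scenario for filter testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._dna import revcomp
from .sam_io import AlignedRead

__all__ = [
    "Edit",
    "SpikeSpec",
    "TruthEntry",
    "build_haplotype",
    "design_spike_panel",
    "simulate_reads",
    "spike_virtual_tumor",
    "make_virtual_tumor",
    "write_truth",
    "write_sam",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Edit:
    """One haplotype edit in anchored VCF-style representation."""

    pos: int  # 0-based reference coordinate of the first ref-allele base
    ref_allele: str
    alt_allele: str

    @property
    def vtype(self) -> str:
        if len(self.ref_allele) == len(self.alt_allele) == 1:
            return "SNV"
        return "INS" if len(self.alt_allele) > len(self.ref_allele) else "DEL"


@dataclass(frozen=True)
class SpikeSpec:
    chrom: str
    edit: Edit
    target_vaf_mean: float  # binomial mean mu
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.target_vaf_mean <= 1):
            raise ValueError("mu must be in [0, 1]")


@dataclass(frozen=True)
class TruthEntry:
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    spiked_fraction: float


def build_haplotype(ref_seq: str, edits: Sequence[Edit]):
    """Apply non-overlapping edits; return (haplotype, segments).

    Segments are ``(hap_start, hap_end, ref_start, kind)`` with kind 'M'
    (reference-aligned, SNVs included) or 'I' (haplotype-only insertion).
    """
    edits = sorted(edits, key=lambda e: e.pos)
    parts: list[str] = []
    segs: list[tuple[int, int, int, str]] = []
    r = 0
    h = 0

    def emit_m(upto: int, override: str | None = None) -> None:
        nonlocal r, h
        if upto <= r:
            return
        s = ref_seq[r:upto] if override is None else override
        parts.append(s)
        segs.append((h, h + len(s), r, "M"))
        h += len(s)
        r = upto

    last_end = -1
    for e in edits:
        if e.pos <= last_end:
            raise ValueError(f"overlapping edits near position {e.pos}")
        if ref_seq[e.pos : e.pos + len(e.ref_allele)] != e.ref_allele:
            raise ValueError(f"ref allele mismatch at {e.pos}")
        if e.vtype == "SNV":
            emit_m(e.pos)
            emit_m(e.pos + 1, override=e.alt_allele)
            last_end = e.pos
        elif e.vtype == "INS":
            emit_m(e.pos + 1)
            ins = e.alt_allele[1:]
            parts.append(ins)
            segs.append((h, h + len(ins), e.pos + 1, "I"))
            h += len(ins)
            last_end = e.pos
        else:  # DEL
            emit_m(e.pos + 1)
            r = e.pos + len(e.ref_allele)
            last_end = e.pos + len(e.ref_allele) - 1
    emit_m(len(ref_seq))
    # merge adjacent M segments contiguous in both coordinate systems
    merged: list[tuple[int, int, int, str]] = []
    for seg in segs:
        if (
            merged
            and merged[-1][3] == seg[3] == "M"
            and merged[-1][1] == seg[0]
            and merged[-1][2] + (merged[-1][1] - merged[-1][0]) == seg[2]
        ):
            merged[-1] = (merged[-1][0], seg[1], merged[-1][2], "M")
        else:
            merged.append(seg)
    return "".join(parts), merged


def _project(segs, s: int, e: int):
    """CIGAR pieces and reference start for a haplotype interval [s, e)."""
    pieces = []  # (kind 'M'|'I', length, ref_start)
    for h0, h1, r0, kind in segs:
        lo, hi = max(s, h0), min(e, h1)
        if hi <= lo:
            continue
        pieces.append((kind, hi - lo, r0 + (lo - h0) if kind == "M" else r0))
    # soft-clip haplotype-only sequence at the read ends
    while pieces and pieces[0][0] == "I":
        pieces[0] = ("S", pieces[0][1], pieces[0][2])
        break
    while pieces and pieces[-1][0] == "I":
        pieces[-1] = ("S", pieces[-1][1], pieces[-1][2])
        break
    if not any(k == "M" for k, _, _ in pieces):
        return None
    cigar: list[tuple[str, int]] = []
    md_parts: list[tuple[str, int, int]] = []  # ('M', ref_start, len) | ('D', ref_start, len)
    ref_start = None
    last_m_end = None
    for kind, length, r0 in pieces:
        if kind == "M":
            if last_m_end is not None and r0 > last_m_end:
                cigar.append(("D", r0 - last_m_end))
                md_parts.append(("D", last_m_end, r0 - last_m_end))
            cigar.append(("M", length))
            md_parts.append(("M", r0, length))
            if ref_start is None:
                ref_start = r0
            last_m_end = r0 + length
        elif kind == "I":
            cigar.append(("I", length))
        else:
            cigar.append(("S", length))
    # merge consecutive identical ops (e.g. M segments abutting an SNV)
    squashed: list[tuple[str, int]] = []
    for op, n in cigar:
        if squashed and squashed[-1][0] == op:
            squashed[-1] = (op, squashed[-1][1] + n)
        else:
            squashed.append((op, n))
    return squashed, md_parts, ref_start


def _md_string(read_seq: str, cigar, md_parts, ref_seq: str) -> str:
    """MD tag computed by comparing aligned read bases to the reference."""
    out: list[str] = []
    count = 0
    q = 0
    mi = 0
    for op, n in cigar:
        if op in "SI":
            q += n
            continue
        if op == "D":
            kind, r0, length = md_parts[mi]
            while kind != "D":
                mi += 1
                kind, r0, length = md_parts[mi]
            out.append(str(count))
            out.append("^" + ref_seq[r0 : r0 + length])
            count = 0
            mi += 1
            continue
        # op == 'M': may span several md_parts after cigar squashing
        left = n
        while left > 0:
            kind, r0, length = md_parts[mi]
            take = min(left, length)
            for i in range(take):
                if read_seq[q + i] == ref_seq[r0 + i]:
                    count += 1
                else:
                    out.append(str(count))
                    out.append(ref_seq[r0 + i])
                    count = 0
            if take == length:
                mi += 1
            else:
                md_parts[mi] = (kind, r0 + take, length - take)
            q += take
            left -= take
    out.append(str(count))
    return "".join(out)


def simulate_reads(
    ref_seq: str,
    edits: Sequence[Edit],
    depth: float,
    read_len: int = 150,
    frag_mean: int = 400,
    frag_sd: int = 50,
    err_rate: float = 0.001,
    seed: int = 0,
    chrom: str = "chr1",
    sample_prefix: str = "sim",
    single_strand: bool = False,
) -> list[AlignedRead]:
    """Paired reads sampled uniformly from the edited haplotype.

    Records carry exact CIGAR/MD strings against the unedited reference
    (haplotype-only sequence is soft-clipped). Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    hap, segs = build_haplotype(ref_seq, edits)
    if frag_mean < read_len:
        raise ValueError("frag_mean must be >= read_len")
    if frag_mean > len(hap):
        raise ValueError("fragment longer than haplotype")
    rng = np.random.default_rng(seed)
    # calibrate to the fragment-feasible span so that *interior* per-base
    # coverage matches the requested depth (fragment ends under-cover edges)
    span = max(len(hap) - frag_mean, read_len)
    n_pairs = int(round(depth * span / (2 * read_len)))
    frags = np.clip(
        rng.normal(frag_mean, frag_sd, n_pairs).round().astype(int), read_len, len(hap)
    )
    starts = rng.integers(0, len(hap) - frags + 1)
    err_mask = rng.random((n_pairs, 2, read_len)) < err_rate
    err_base = rng.integers(1, 4, (n_pairs, 2, read_len))
    qual_pick = rng.random((n_pairs, 2, read_len)) < 0.9
    reads: list[AlignedRead] = []
    for i in range(n_pairs):
        p, fl = int(starts[i]), int(frags[i])
        qname = f"{sample_prefix}:{i}"
        spans = [(p, p + read_len), (p + fl - read_len, p + fl)]
        mates = []
        for m, (s, e) in enumerate(spans):
            proj = _project(segs, s, e)
            if proj is None:
                mates.append(None)
                continue
            cigar, md_parts, ref_start = proj
            raw = hap[s:e]
            mask = err_mask[i, m]
            if mask.any():
                arr = np.frombuffer(raw.encode(), dtype=np.uint8).copy()
                codes = np.searchsorted(_BASES, arr)
                codes = (codes + err_base[i, m]) % 4
                arr[mask] = _BASES[codes[mask]]
                raw = arr.tobytes().decode()
            md = _md_string(raw, cigar, [list(x) for x in map(tuple, md_parts)], ref_seq)
            quals = np.where(qual_pick[i, m], 37, 12).astype(np.int16)
            mates.append((s, raw, cigar, md, quals, ref_start))
        if mates[0] is None or mates[1] is None:
            continue  # a mate fell entirely inside an insertion
        left_rev = False if single_strand else (i % 2 == 1)
        for m, mate in enumerate(mates):
            _, raw, cigar, md, quals, ref_start = mate
            is_reverse = left_rev if m == 0 else not left_rev
            other = mates[1 - m]
            reads.append(
                AlignedRead(
                    qname=qname,
                    chrom=chrom,
                    start=ref_start,
                    mapq=60,
                    seq=raw,
                    quals=quals,
                    cigar=cigar,
                    md=md,
                    mate=(i + m) % 2,
                    is_reverse=is_reverse,
                    mate_start=other[5],
                    tags={"AS": read_len * 2, "XS": 0},
                )
            )
    reads.sort(key=lambda r: (r.start, r.qname, r.mate))
    return reads


def _covers(read: AlignedRead, lo: int, hi: int) -> bool:
    return read.start < hi and read.end > lo


def spike_virtual_tumor(
    donor_reads: Sequence[AlignedRead],
    recipient_reads: Sequence[AlignedRead],
    spec: SpikeSpec,
    normal_reads: Sequence[AlignedRead] | None = None,
    rng: np.random.Generator | None = None,
):
    """Swap fragments between donor and recipient pools at one locus.

    The donor pool is homozygous for the alternative allele, the recipient
    homozygous reference. N ~ Binomial(n covering recipient fragments, mu)
    whole fragments are replaced with covering donor fragments; the normal
    pool passes through untouched. Returns (tumor_reads, normal_reads,
    truth_entry) where the truth entry records the realized read fraction.
    """
    rng = rng or np.random.default_rng(spec.seed)
    e = spec.edit
    lo, hi = e.pos, e.pos + len(e.ref_allele)
    rec_pairs: dict[str, list[AlignedRead]] = {}
    for r in recipient_reads:
        rec_pairs.setdefault(r.qname, []).append(r)
    covering = sorted(q for q, rs in rec_pairs.items() if any(_covers(r, lo, hi) for r in rs))
    n = sum(1 for q in covering for r in rec_pairs[q] if _covers(r, lo, hi))
    n_pairs = len(covering)
    N = int(rng.binomial(n_pairs, spec.target_vaf_mean)) if n_pairs else 0
    don_pairs: dict[str, list[AlignedRead]] = {}
    for r in donor_reads:
        don_pairs.setdefault(r.qname, []).append(r)
    don_covering = sorted(
        q for q, rs in don_pairs.items() if any(_covers(r, lo, hi) for r in rs)
    )
    if N > len(don_covering):
        raise ValueError(f"insufficient donor fragments covering {spec.chrom}:{e.pos}")
    removed = set(rng.choice(covering, size=N, replace=False)) if N else set()
    picked = list(rng.choice(don_covering, size=N, replace=False)) if N else []
    tumor = [r for r in recipient_reads if r.qname not in removed]
    swapped = [r for q in picked for r in don_pairs[q]]
    tumor.extend(swapped)
    tumor.sort(key=lambda r: (r.start, r.qname, r.mate))
    cov_after = sum(1 for r in tumor if _covers(r, lo, hi))
    alt_after = sum(1 for q in picked for r in don_pairs[q] if _covers(r, lo, hi))
    frac = alt_after / cov_after if cov_after else 0.0
    truth = TruthEntry(spec.chrom, e.pos, e.ref_allele, e.alt_allele, e.vtype, frac)
    return tumor, list(normal_reads) if normal_reads is not None else None, truth


def make_virtual_tumor(
    ref_seq: str,
    specs: Sequence[SpikeSpec],
    depth_t: float = 80,
    depth_n: float = 40,
    err_rate: float = 0.001,
    seed: int = 0,
    chrom: str = "chr1",
    read_len: int = 150,
    frag_mean: int = 400,
    frag_sd: int = 50,
    single_strand: bool = False,
):
    """Full virtual-tumor construction over many loci.

    Returns (tumor_reads, normal_reads, truth) where truth contains one
    entry per locus with a non-zero realized fraction.
    """
    edits = [s.edit for s in specs]
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(0, 2**31 - 1, 3))
    common = dict(
        read_len=read_len,
        frag_mean=frag_mean,
        frag_sd=frag_sd,
        err_rate=err_rate,
        chrom=chrom,
        single_strand=single_strand,
    )
    recipient = simulate_reads(ref_seq, [], depth_t, seed=s1, sample_prefix="rec", **common)
    normal = simulate_reads(ref_seq, [], depth_n, seed=s2, sample_prefix="nrm", **common)
    donor = simulate_reads(ref_seq, edits, depth_t, seed=s3, sample_prefix="don", **common)

    # batch form of spike_virtual_tumor: loci are spaced beyond the fragment
    # span, so per-locus swaps are independent and can share one pass
    def pair_table(reads):
        pairs: dict[str, list[AlignedRead]] = {}
        for r in reads:
            pairs.setdefault(r.qname, []).append(r)
        names = sorted(pairs)
        lo = np.array([min(r.start for r in pairs[q]) for q in names])
        hi = np.array([max(r.end for r in pairs[q]) for q in names])
        return pairs, np.array(names), lo, hi

    rec_pairs, rec_names, rec_lo, rec_hi = pair_table(recipient)
    don_pairs, don_names, don_lo, don_hi = pair_table(donor)
    removed: set[str] = set()
    picked: dict[int, list[str]] = {}
    truth: list[TruthEntry] = []
    ordered = sorted(specs, key=lambda s: s.edit.pos)
    for spec in ordered:
        e = spec.edit
        lo, hi = e.pos, e.pos + len(e.ref_allele)
        cov_mask = (rec_lo < hi) & (rec_hi > lo)
        covering = rec_names[cov_mask]
        N = int(rng.binomial(len(covering), spec.target_vaf_mean)) if len(covering) else 0
        don_cov = don_names[(don_lo < hi) & (don_hi > lo)]
        if N > len(don_cov):
            raise ValueError(f"insufficient donor fragments covering {spec.chrom}:{e.pos}")
        chosen = list(rng.choice(covering, size=N, replace=False)) if N else []
        removed.update(chosen)
        picked[e.pos] = list(rng.choice(don_cov, size=N, replace=False)) if N else []
    tumor = [r for r in recipient if r.qname not in removed]
    for names in picked.values():
        for q in names:
            tumor.extend(don_pairs[q])
    tumor.sort(key=lambda r: (r.start, r.qname, r.mate))
    for spec in ordered:
        e = spec.edit
        lo, hi = e.pos, e.pos + len(e.ref_allele)
        swapped = picked[e.pos]
        alt_after = sum(1 for q in swapped for r in don_pairs[q] if _covers(r, lo, hi))
        rec_cov = sum(
            1
            for q in rec_names[(rec_lo < hi) & (rec_hi > lo)]
            if q not in removed
            for r in rec_pairs[q]
            if _covers(r, lo, hi)
        )
        cov_after = rec_cov + alt_after
        frac = alt_after / cov_after if cov_after else 0.0
        if frac > 0:
            truth.append(
                TruthEntry(spec.chrom, e.pos, e.ref_allele, e.alt_allele, e.vtype, frac)
            )
    return tumor, normal, truth


def design_spike_panel(
    ref_seq: str,
    chrom: str,
    n_snv: int,
    n_indel: int,
    mus: Sequence[float],
    rng: np.random.Generator,
    max_ins: int = 13,
    max_del: int = 35,
    spacing: int = 700,
    margin: int = 350,
) -> list[SpikeSpec]:
    """Lay out a ladder of spike loci along a reference.

    Loci are spaced so each sits alone well inside its windows, and are drawn
    away from microsatellite context (slippage-prone sites confound the
    separate STR score threshold and are benchmarked separately in practice).
    Target allele-fraction means cycle through ``mus``. Insertions are capped
    at ``max_ins`` bp and deletions at ``max_del`` bp. Edits are emitted in
    left-normalized representation so they can serve directly as truth.
    """
    from .scoring import MicrosatelliteParams, find_str_intervals

    strs = find_str_intervals(ref_seq, MicrosatelliteParams())
    bases = "ACGT"
    n_total = n_snv + n_indel
    positions: list[int] = []
    guard = max(max_ins, max_del) + 10
    limit = len(ref_seq) - margin

    def blocked(p: int) -> bool:
        return any(s - guard < p + max_del and e + guard > p for s, e, _ in strs)

    pos = margin
    while len(positions) < n_total:
        p = pos + int(rng.integers(0, 100))
        while p < limit and blocked(p):
            p += 13  # slide past the microsatellite's guard zone
        if p >= limit:
            break
        positions.append(p)
        pos = p + spacing
    if len(positions) < n_total:
        raise ValueError("reference too short for the requested panel")
    # interleave SNVs and indels so every mu group receives both types
    kinds = ["SNV"] * n_snv + ["INDEL"] * n_indel
    rng.shuffle(kinds)
    specs: list[SpikeSpec] = []
    for i, (p, kind) in enumerate(zip(positions, kinds)):
        if kind == "SNV":
            alt = str(rng.choice([b for b in bases if b != ref_seq[p]]))
            edit = Edit(p, ref_seq[p], alt)
        elif rng.random() < 0.5:
            ln = int(rng.integers(1, max_ins + 1))
            ins = "".join(rng.choice(list(bases), ln))
            edit = Edit(p, ref_seq[p], ref_seq[p] + ins)
        else:
            ln = int(rng.integers(1, max_del + 1))
            edit = Edit(p, ref_seq[p : p + ln + 1], ref_seq[p])
        edit = _left_normalized_edit(edit, ref_seq)
        mu = mus[i % len(mus)]
        specs.append(SpikeSpec(chrom, edit, mu, seed=int(rng.integers(0, 2**31 - 1))))
    return specs


def _left_normalized_edit(e: Edit, ref_seq: str) -> Edit:
    from .align import RawVariant, left_normalize

    v = RawVariant("x", e.pos, e.ref_allele, e.alt_allele, e.vtype)
    nv = left_normalize(v, lambda c, s, en: ref_seq[s:en])
    return Edit(nv.pos, nv.ref_allele, nv.alt_allele)


def write_truth(entries: Sequence[TruthEntry], contigs: dict[str, int] | None = None) -> str:
    """Minimal truth VCF (4.1) consumable by the benchmark module."""
    lines = ["##fileformat=VCFv4.1", "##source=microcall-simulator"]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##INFO=<ID=VAF,Number=1,Type=Float,Description="Realized spiked read fraction">')
    lines.append('##INFO=<ID=TYPE,Number=1,Type=String,Description="SNV, INS or DEL">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for e in sorted(entries, key=lambda x: (x.chrom, x.pos)):
        lines.append(
            f"{e.chrom}\t{e.pos + 1}\t.\t{e.ref}\t{e.alt}\t.\tPASS\t"
            f"VAF={e.spiked_fraction:.4f};TYPE={e.vtype}"
        )
    return "\n".join(lines) + "\n"


def write_sam(
    reads: Sequence[AlignedRead], contigs: dict[str, int], path: str, sample: str = "sample"
) -> None:
    """Write reads as a coordinate-sorted SAM file via pysam."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contigs.items()],
        "RG": [{"ID": sample, "SM": sample}],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in sorted(reads, key=lambda x: (tid[x.chrom], x.start, x.qname, x.mate)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.qname
            a.query_sequence = r.seq
            a.flag = (
                0x1
                | 0x2
                | (0x10 if r.is_reverse else 0)
                | (0x20 if not r.is_reverse else 0)
                | (0x40 if r.mate == 0 else 0x80)
            )
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            a.next_reference_id = tid[r.chrom]
            a.next_reference_start = r.mate_start if r.mate_start >= 0 else r.start
            a.template_length = 0
            a.query_qualities = list(map(int, r.quals))
            tags = [("RG", sample)]
            if r.md is not None:
                tags.append(("MD", r.md))
            tags.extend((k, v) for k, v in r.tags.items())
            a.set_tags(tags)
            out.write(a)


def write_fastq(reads: Sequence[AlignedRead], path_r1: str, path_r2: str) -> None:
    """Export read pairs as FASTQ for users who prefer real mapping."""
    pairs: dict[str, dict[int, AlignedRead]] = {}
    for r in reads:
        pairs.setdefault(r.qname, {})[r.mate] = r
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for qname in sorted(pairs):
            p = pairs[qname]
            if set(p) != {0, 1}:
                continue
            for mate, fh in ((0, f1), (1, f2)):
                r = p[mate]
                seq = revcomp(r.seq) if r.is_reverse else r.seq
                quals = r.quals[::-1] if r.is_reverse else r.quals
                qual = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{qname}/{mate + 1}\n{seq}\n+\n{qual}\n")
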