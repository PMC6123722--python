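"""Variant scoring, classification, filtering and VCF output.

Somatic support is scored with a Phred-scaled two-sided Fisher's exact test
on the tumor/normal x ref/alt contingency table: p is the sum of the exact
hypergeometric probabilities of all tables (with the observed margins) no
more probable than the observed one, and the score is -10*log10(p), or 0
when p == 1. The p-value is computed in exact integer arithmetic.

Microsatellite (STR) context is annotated on the fly, and a separate, more
stringent score threshold applies to STR variants, which are prone to
replication-slippage artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .align import AlleleCounts, RawVariant

__all__ = [
    "ContingencyTable",
    "MicrosatelliteParams",
    "FilterThresholds",
    "VariantCall",
    "fet_score",
    "find_str_intervals",
    "flag_str",
    "classify",
    "apply_filters",
    "write_vcf",
]

FILTER_NAMES = (
    "LowCovNormal",
    "LowCovTumor",
    "LowVafTumor",
    "HighVafNormal",
    "LowAltCntTumor",
    "HighAltCntNormal",
    "LowFetScore",
    "StrandBias",
)


@dataclass(frozen=True)
class ContingencyTable:
    tumor_ref: int
    tumor_alt: int
    normal_ref: int
    normal_alt: int

    def __post_init__(self) -> None:
        if min(self.tumor_ref, self.tumor_alt, self.normal_ref, self.normal_alt) < 0:
            raise ValueError("negative cell count")


def fet_score(t: ContingencyTable, two_sided: bool = True) -> float:
    """Phred-scaled Fisher's exact test score of a 2x2 table.

    Exact integer enumeration over the hypergeometric support; two-sided by
    default (all tables with point probability <= the observed one), with a
    one-sided (observed tail) variant exposed via ``two_sided=False``.
    """
    m1 = t.tumor_ref + t.tumor_alt
    m2 = t.normal_ref + t.normal_alt
    n = t.tumor_alt + t.normal_alt
    N = m1 + m2
    if N == 0:
        return 0.0
    lo, hi = max(0, n - m2), min(n, m1)
    nums = [math.comb(m1, a) * math.comb(m2, n - a) for a in range(lo, hi + 1)]
    obs = nums[t.tumor_alt - lo]
    if two_sided:
        p_num = sum(x for x in nums if x <= obs)
    else:
        idx = t.tumor_alt - lo
        mean_num = n * m1  # compare a*N vs n*m1 to pick the observed tail
        if t.tumor_alt * N >= mean_num:
            p_num = sum(nums[idx:])
        else:
            p_num = sum(nums[: idx + 1])
    denom = math.comb(N, n)
    if p_num >= denom:
        return 0.0
    p = p_num / denom
    return -10.0 * math.log10(p)


@dataclass(frozen=True)
class MicrosatelliteParams:
    min_total_len: int = 7
    motif_min: int = 1
    motif_max: int = 4
    min_repeats: int = 3
    proximity: int = 1

    def __post_init__(self) -> None:
        if self.motif_min > self.motif_max or min(
            self.min_total_len, self.motif_min, self.min_repeats, self.proximity + 1
        ) <= 0:
            raise ValueError("invalid microsatellite parameters")


def find_str_intervals(
    seq: str, params: MicrosatelliteParams | None = None
) -> list[tuple[int, int, str]]:
    """Tandem-repeat intervals (start, end, motif) in a sequence.

    A microsatellite is a run of a 1-4 bp motif repeated at least three
    times with total length >= 7 bp; partial trailing copies count toward
    the total length.
    """
    p = params or MicrosatelliteParams()
    out = []
    n = len(seq)
    for u in range(p.motif_min, p.motif_max + 1):
        i = 0
        while i + u < n:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            j = i
            while j + u < n and seq[j] == seq[j + u]:
                j += 1
            total = (j - i) + u
            if total >= p.min_total_len and total / u >= p.min_repeats:
                out.append((i, i + total, seq[i : i + u]))
            i = j + 1
    out.sort()
    return out


def flag_str(
    ref_context: str,
    context_start: int,
    v: RawVariant,
    params: MicrosatelliteParams | None = None,
) -> str | None:
    """Microsatellite annotation for a variant, or None.

    Returns ``"motif:copies"`` when an STR lies within, or within
    ``proximity`` bp of, the variant locus. ``context_start`` is the genomic
    coordinate of ``ref_context[0]``.
    """
    p = params or MicrosatelliteParams()
    v_lo = v.pos - context_start
    v_hi = v_lo + max(len(v.ref_allele), 1)
    best = None
    for s, e, motif in find_str_intervals(ref_context, p):
        if s < v_hi + p.proximity and e > v_lo - p.proximity:
            copies = (e - s) // len(motif)
            if best is None or len(motif) < len(best[0]):
                best = (motif, copies)
    if best is None:
        return None
    return f"{best[0]}:{best[1]}"


SOMATIC, GERMLINE, SHARED, NORMAL_ONLY = "SOMATIC", "GERMLINE", "SHARED", "NORMAL_ONLY"


def classify(
    v: RawVariant,
    counts: AlleleCounts,
    max_alt_normal: int = 0,
    max_vaf_normal: float = 0.0,
) -> str:
    """Somatic/germline status from tumor and normal allele support."""
    if counts.alt_t > 0 and counts.alt_n <= max_alt_normal and counts.vaf_n <= max_vaf_normal:
        return SOMATIC
    if counts.alt_t == 0 and counts.alt_n > 0:
        return NORMAL_ONLY
    if counts.alt_t > 0 and counts.alt_n > 0:
        return SHARED
    return GERMLINE


@dataclass(frozen=True)
class FilterThresholds:
    min_cov_normal: int = 10
    min_cov_tumor: int = 4
    min_vaf_tumor: float = 0.04
    max_vaf_normal: float = 0.0
    min_alt_tumor: int = 3
    max_alt_normal: int = 0
    min_fet_nonstr: float = 5.0
    min_fet_str: float = 25.0
    min_strand_count: int = 1


@dataclass
class VariantCall:
    variant: RawVariant
    counts: AlleleCounts
    fet: float
    kmer_size: int
    str_flag: str | None = None
    status: str = GERMLINE
    filters: set = field(default_factory=set)

    @property
    def is_pass(self) -> bool:
        return not self.filters

    @property
    def key(self) -> tuple:
        return self.variant.key


def apply_filters(
    call: VariantCall,
    th: FilterThresholds | None = None,
    strand_bias_on: bool = True,
) -> set:
    """Filter-name set for one scored call (empty set means PASS)."""
    th = th or FilterThresholds()
    c = call.counts
    f: set = set()
    if c.depth_n < th.min_cov_normal:
        f.add("LowCovNormal")
    if c.depth_t < th.min_cov_tumor:
        f.add("LowCovTumor")
    if c.vaf_t < th.min_vaf_tumor:
        f.add("LowVafTumor")
    if c.vaf_n > th.max_vaf_normal:
        f.add("HighVafNormal")
    if c.alt_t < th.min_alt_tumor:
        f.add("LowAltCntTumor")
    if c.alt_n > th.max_alt_normal:
        f.add("HighAltCntNormal")
    min_fet = th.min_fet_str if call.str_flag else th.min_fet_nonstr
    if call.fet < min_fet:
        f.add("LowFetScore")
    if strand_bias_on and (
        c.alt_tf < th.min_strand_count or c.alt_tr < th.min_strand_count
    ):
        f.add("StrandBias")
    return f


_VCF_HEADER_META = [
    '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Variant private to the tumor">',
    '##INFO=<ID=STATUS,Number=1,Type=String,Description="SOMATIC, GERMLINE, SHARED or NORMAL_ONLY">',
    '##INFO=<ID=FETS,Number=1,Type=Float,Description="Phred-scaled Fisher exact test score">',
    '##INFO=<ID=KMERSIZE,Number=1,Type=Integer,Description="k-mer size used to assemble the window">',
    '##INFO=<ID=MS,Number=1,Type=String,Description="Microsatellite motif:copies at or near the locus">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref and alt supporting fragment counts">',
    '##FORMAT=<ID=FAC,Number=1,Type=Integer,Description="Alt support on the forward strand">',
    '##FORMAT=<ID=RAC,Number=1,Type=Integer,Description="Alt support on the reverse strand">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Ref+alt supporting count">',
]

_FILTER_DESCR = {
    "LowCovNormal": "Normal coverage below threshold",
    "LowCovTumor": "Tumor coverage below threshold",
    "LowVafTumor": "Tumor variant allele fraction below threshold",
    "HighVafNormal": "Normal variant allele fraction above threshold",
    "LowAltCntTumor": "Tumor alternative allele count below threshold",
    "HighAltCntNormal": "Normal alternative allele count above threshold",
    "LowFetScore": "Fisher exact test score below threshold",
    "StrandBias": "Alt support missing from one strand",
}


def write_vcf(
    calls,
    sample_names: tuple[str, str] = ("NORMAL", "TUMOR"),
    contigs: dict[str, int] | None = None,
    source: str = "microcall",
) -> str:
    """Render calls as VCF 4.1 text (0-based input positions become 1-based).

    Calls must be deduplicated and sorted by (chrom, pos); QUAL carries the
    Fisher's exact test score.
    """
    lines = ["##fileformat=VCFv4.1", f"##source={source}"]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    for name in FILTER_NAMES:
        lines.append(f'##FILTER=<ID={name},Description="{_FILTER_DESCR[name]}">')
    lines.extend(_VCF_HEADER_META)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    prev = None
    for c in calls:
        v = c.variant
        if prev is not None and (v.chrom, v.pos) < prev:
            raise ValueError("calls are not coordinate sorted")
        prev = (v.chrom, v.pos)
        info = []
        if c.status == SOMATIC:
            info.append("SOMATIC")
        info.append(f"STATUS={c.status}")
        info.append(f"FETS={c.fet:.2f}")
        info.append(f"KMERSIZE={c.kmer_size}")
        if c.str_flag:
            info.append(f"MS={c.str_flag}")
        filt = "PASS" if not c.filters else ";".join(sorted(c.filters))
        cnt = c.counts
        normal = f"{cnt.ref_n},{cnt.alt_n}:{cnt.alt_nf}:{cnt.alt_nr}:{cnt.depth_n}"
        tumor = f"{cnt.ref_t},{cnt.alt_t}:{cnt.alt_tf}:{cnt.alt_tr}:{cnt.depth_t}"
        cols = {"NORMAL": normal, "TUMOR": tumor}
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos + 1),
                    ".",
                    v.ref_allele,
                    v.alt_allele,
                    f"{c.fet:.2f}",
                    filt,
                    ";".join(info),
                    "AD:FAC:RAC:DP",
                    cols[sample_names[0]],
                    cols[sample_names[1]],
                ]
            )
        )
    return "\n".join(lines) + "\n"
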