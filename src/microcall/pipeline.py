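"""End-to-end somatic calling: windows -> assembly -> haplotypes -> calls.

Windows are independent work units; results are merged and deduplicated by
(chrom, pos, ref, alt) keeping the highest-scoring record, so any execution
order produces output identical to a serial scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

from . import sam_io
from .align import (
    AlignScoring,
    count_support,
    extract_variants,
    left_normalize,
    swg_align,
)
from .cdbg import assemble_window
from .regions import Window, is_active, is_overmapped, make_windows
from .sam_io import AlignedRead, ReadSelectionParams, select_tumor_reads
from .scoring import (
    ContingencyTable,
    FilterThresholds,
    MicrosatelliteParams,
    VariantCall,
    apply_filters,
    classify,
    fet_score,
    find_str_intervals,
    flag_str,
    write_vcf,
)

__all__ = ["CallerConfig", "WindowLog", "call_window", "call_regions", "run_call"]


@dataclass
class CallerConfig:
    """All tunables of the calling pipeline (defaults follow the method)."""

    window_size: int = 600
    step: int | None = None  # default window_size // 2
    min_mapq: int = 15
    as_xs_delta: int = 5
    drop_duplicates: bool = True
    active_region_on: bool = True
    min_alt_count_tumor: int = 3  # doubles as active-region N
    max_window_reads: int = 10000
    k_min: int = 11
    k_max: int = 101
    max_mismatch_repeats: int = 2
    min_node_count: int = 1
    min_cov_ratio: float = 0.01
    tip_len: int = 11
    tip_mode: str = "long"
    short_link_m: int | None = None
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    max_path_len_factor: int = 4
    max_alt_count_normal: int = 0
    max_vaf_normal: float = 0.0
    min_vaf_tumor: float = 0.04
    min_coverage_tumor: int = 4
    min_coverage_normal: int = 10
    min_phred_fisher: float = 5.0
    min_phred_fisher_str: float = 25.0
    strand_bias_on: bool = True
    ms_min_total_len: int = 7
    ms_motif_min: int = 1
    ms_motif_max: int = 4
    ms_min_repeats: int = 3
    ms_proximity: int = 1
    seed: int = 0

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            min_cov_normal=self.min_coverage_normal,
            min_cov_tumor=self.min_coverage_tumor,
            min_vaf_tumor=self.min_vaf_tumor,
            max_vaf_normal=self.max_vaf_normal,
            min_alt_tumor=self.min_alt_count_tumor,
            max_alt_normal=self.max_alt_count_normal,
            min_fet_nonstr=self.min_phred_fisher,
            min_fet_str=self.min_phred_fisher_str,
        )

    def ms_params(self) -> MicrosatelliteParams:
        return MicrosatelliteParams(
            min_total_len=self.ms_min_total_len,
            motif_min=self.ms_motif_min,
            motif_max=self.ms_motif_max,
            min_repeats=self.ms_min_repeats,
            proximity=self.ms_proximity,
        )

    def scoring(self) -> AlignScoring:
        return AlignScoring(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def read_selection(self) -> ReadSelectionParams:
        return ReadSelectionParams(
            min_mapq=self.min_mapq,
            as_xs_delta=self.as_xs_delta,
            drop_duplicates=self.drop_duplicates,
        )

    @classmethod
    def from_file(cls, path: str) -> "CallerConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key not in known:
                    raise ValueError(f"unknown config key {key!r}")
                ftype = known[key].type
                if val in ("none", "None", ""):
                    kwargs[key] = None
                elif "bool" in str(ftype):
                    kwargs[key] = val.lower() in ("1", "true", "yes", "on")
                elif "float" in str(ftype):
                    kwargs[key] = float(val)
                elif "int" in str(ftype):
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


@dataclass
class WindowLog:
    chrom: str
    start: int
    end: int
    status: str
    k: int = 0
    n_paths: int = 0
    n_variants: int = 0


def call_window(
    tumor_reads: Sequence[AlignedRead],
    normal_reads: Sequence[AlignedRead],
    window: Window,
    cfg: CallerConfig | None = None,
) -> tuple[list[VariantCall], WindowLog]:
    """Run the full per-window workflow on pre-fetched reads.

    Tumor reads are filtered by the read-selection rules here; normal reads
    are used unfiltered.
    """
    cfg = cfg or CallerConfig()
    log = WindowLog(window.chrom, window.start, window.end, "called")
    if is_overmapped(list(tumor_reads) + list(normal_reads), cfg.max_window_reads):
        log.status = "overmapped"
        return [], log
    tumor = select_tumor_reads(tumor_reads, cfg.read_selection())
    if cfg.active_region_on and not is_active(
        tumor, normal_reads, window, cfg.min_alt_count_tumor
    ):
        log.status = "inactive"
        return [], log
    ms = cfg.ms_params()
    str_intervals = [(s, e) for s, e, _ in find_str_intervals(window.ref_seq, ms)]
    res = assemble_window(
        tumor,
        normal_reads,
        window,
        k_min=cfg.k_min,
        k_max=cfg.k_max,
        max_mm=cfg.max_mismatch_repeats,
        min_node_count=cfg.min_node_count,
        min_cov_ratio=cfg.min_cov_ratio,
        tip_len=cfg.tip_len,
        tip_mode=cfg.tip_mode,
        short_link_m=cfg.short_link_m,
        str_intervals=str_intervals,
        max_path_len=cfg.max_path_len_factor * (window.end - window.start),
    )
    log.k = res.k
    if res.status != "ok":
        log.status = res.status
        return [], log
    cg, anchors = res.graph, res.anchors
    src_off = anchors.source_ref_pos
    ref_slice = window.ref_seq[src_off : anchors.sink_ref_pos + cg.k]
    scoring = cfg.scoring()
    log.n_paths = len(res.haplotypes)

    best: dict[tuple, tuple] = {}  # raw-variant key -> (counts, hap)
    for hid, hap in enumerate(res.haplotypes):
        if hap.seq == ref_slice:
            continue
        aln = swg_align(hap.seq, ref_slice, scoring)
        ncols = len(aln.hap_aln)
        if ncols and (aln.hap_aln.count("-") + aln.ref_aln.count("-")) > ncols / 2:
            continue  # mostly-gap artifact
        for v in extract_variants(aln, window, ref_offset=src_off, haplotype_id=hid):
            counts = count_support(v, hap, cg, window, graph=res.raw_graph)
            prev = best.get(v.key)
            if prev is None or counts.alt_t > prev[0].alt_t:
                best[v.key] = (counts, v)

    calls: list[VariantCall] = []
    ws = window.start
    ctx = window.ref_seq
    for counts, v in best.values():
        nv = left_normalize(v, lambda c, s, e: ctx[s - ws : e - ws] if s >= ws else "")
        table = ContingencyTable(counts.ref_t, counts.alt_t, counts.ref_n, counts.alt_n)
        fet = fet_score(table)
        sflag = flag_str(ctx, ws, nv, ms)
        call = VariantCall(
            variant=nv,
            counts=counts,
            fet=fet,
            kmer_size=res.k,
            str_flag=sflag,
            status=classify(nv, counts, cfg.max_alt_count_normal, cfg.max_vaf_normal),
        )
        call.filters = apply_filters(call, cfg.thresholds(), cfg.strand_bias_on)
        calls.append(call)
    log.n_variants = len(calls)
    return calls, log


def call_regions(
    tumor_source,
    normal_source,
    ref,
    intervals: Sequence[tuple[str, int, int]],
    cfg: CallerConfig | None = None,
) -> tuple[list[VariantCall], list[WindowLog]]:
    """Call somatic variants over target intervals.

    Sources are pysam alignment files or in-memory read lists; ``ref`` is a
    pysam FastaFile or a chrom -> sequence dict. Calls discovered in
    overlapping windows are deduplicated keeping the max-score record.
    """
    cfg = cfg or CallerConfig()
    step = cfg.step or cfg.window_size // 2
    windows = make_windows(intervals, ref, cfg.window_size, step)
    if isinstance(tumor_source, (list, tuple)):
        tumor_source = sam_io.ReadIndex(tumor_source)
    if isinstance(normal_source, (list, tuple)):
        normal_source = sam_io.ReadIndex(normal_source)
    merged: dict[tuple, VariantCall] = {}
    logs: list[WindowLog] = []
    for win in windows:
        tumor = sam_io.fetch_reads(tumor_source, win)
        normal = sam_io.fetch_reads(normal_source, win)
        try:
            calls, log = call_window(tumor, normal, win, cfg)
        except Exception as exc:  # pragma: no cover - defensive per-window guard
            logs.append(WindowLog(win.chrom, win.start, win.end, f"error:{exc}"))
            continue
        logs.append(log)
        for c in calls:
            prev = merged.get(c.key)
            if prev is None or c.fet > prev.fet or (
                c.fet == prev.fet and c.counts.alt_t > prev.counts.alt_t
            ):
                merged[c.key] = c
    out = sorted(merged.values(), key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.alt_allele))
    return out, logs


def run_call(
    tumor_path: str,
    normal_path: str,
    ref_path: str,
    out_vcf: str,
    bed_path: str | None = None,
    cfg: CallerConfig | None = None,
) -> tuple[list[VariantCall], list[WindowLog]]:
    """File-based entry point: SAM/BAM + FASTA in, VCF out.

    Unindexed SAM inputs are loaded fully into memory (regional analyses);
    indexed BAMs are fetched per window.
    """
    import pysam

    cfg = cfg or CallerConfig()
    ref = pysam.FastaFile(ref_path)
    contigs = dict(zip(ref.references, ref.lengths))
    if bed_path:
        intervals = []
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
    else:
        intervals = [(c, 0, l) for c, l in contigs.items()]

    def open_source(path: str):
        af = pysam.AlignmentFile(path)
        if af.has_index():
            return af
        reads = [
            sam_io.AlignedRead.from_pysam(a)
            for a in af
            if not (a.is_unmapped or a.is_secondary or a.is_supplementary)
        ]
        af.close()
        return reads

    tumor_source = open_source(tumor_path)
    normal_source = open_source(normal_path)
    calls, logs = call_regions(tumor_source, normal_source, ref, intervals, cfg)
    text = write_vcf(calls, contigs=contigs)
    with open(out_vcf, "w") as fh:
        fh.write(text)
    return calls, logs
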