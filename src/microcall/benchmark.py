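"""Precision/recall benchmarking of a call set against a truth set.

Matching is exact on (chromosome, start position, ref allele, alt allele)
after left normalization of both sides; the precision/recall curve is
computed by sweeping the quality score from highest to lowest, counting
every call with score >= threshold, with tied scores entering together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "BenchCall",
    "CurvePoint",
    "MetricSummary",
    "match_calls",
    "pr_curve",
    "metrics",
    "load_vcf_calls",
    "virtual_tumor_experiment",
]

Key = tuple  # (chrom, pos, ref, alt)


@dataclass(frozen=True)
class BenchCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    score: float = 0.0

    @property
    def key(self) -> Key:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CurvePoint:
    score_threshold: float
    tp: int
    fp: int
    precision: float
    recall: float


@dataclass(frozen=True)
class MetricSummary:
    n_calls: int
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    fdr: float
    f1: float
    max_f1: float = 0.0
    undefined_precision: bool = False


def _keys(items: Sequence) -> list[Key]:
    out = []
    for it in items:
        out.append(it.key if hasattr(it, "key") else tuple(it))
    return out


def match_calls(calls: Sequence, truth: Sequence):
    """One-to-one exact matching; returns (tp, fp, fn) key sets."""
    ckeys = _keys(calls)
    tkeys = _keys(truth)
    if len(set(ckeys)) != len(ckeys):
        raise ValueError("duplicate (chrom,pos,ref,alt) in call set")
    if len(set(tkeys)) != len(tkeys):
        raise ValueError("duplicate (chrom,pos,ref,alt) in truth set")
    cset, tset = set(ckeys), set(tkeys)
    tp = cset & tset
    return tp, cset - tset, tset - cset


def pr_curve(calls: Sequence[BenchCall], truth: Sequence) -> list[CurvePoint]:
    """Descending-score sweep, one point per distinct threshold."""
    tset = set(_keys(truth))
    if not tset and not calls:
        return []
    ordered = sorted(calls, key=lambda c: -c.score)
    points: list[CurvePoint] = []
    tp = fp = 0
    i = 0
    n = len(ordered)
    truth_size = len(tset)
    while i < n:
        thr = ordered[i].score
        while i < n and ordered[i].score == thr:
            if ordered[i].key in tset:
                tp += 1
            else:
                fp += 1
            i += 1
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / truth_size if truth_size else 0.0
        points.append(CurvePoint(thr, tp, fp, prec, rec))
    return points


def metrics(
    n_calls: int,
    tp: int,
    fp: int,
    fn: int,
    curve: Sequence[CurvePoint] | None = None,
) -> MetricSummary:
    """Recall, precision, FDR and F1 from the confusion counts.

    ``max_f1`` is the maximum F1 over the supplied precision/recall curve
    (falls back to the final-threshold F1 when no curve is given).
    """
    if n_calls != tp + fp:
        raise ValueError("n_calls must equal tp + fp")
    truth_size = tp + fn
    undefined = n_calls == 0
    precision = tp / n_calls if n_calls else 0.0
    recall = tp / truth_size if truth_size else 0.0
    fdr = fp / n_calls if n_calls else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if curve:
        max_f1 = max(
            (
                2 * p.precision * p.recall / (p.precision + p.recall)
                for p in curve
                if p.precision + p.recall
            ),
            default=f1,
        )
        max_f1 = max(max_f1, f1)
    else:
        max_f1 = f1
    return MetricSummary(
        n_calls=n_calls,
        tp=tp,
        fp=fp,
        fn=fn,
        recall=recall,
        precision=precision,
        fdr=fdr,
        f1=f1,
        max_f1=max_f1,
        undefined_precision=undefined,
    )


def virtual_tumor_experiment(
    seed: int,
    n_snv: int = 200,
    n_indel: int = 100,
    mus: Sequence[float] = (0.05, 0.1, 0.2, 0.3),
    depth_t: float = 80,
    depth_n: float = 40,
    err_rate: float = 0.001,
    run_control: bool = True,
) -> dict:
    """Virtual-tumor spike-in/recovery experiment, end to end.

    Builds a random reference carrying a ladder of spiked SNVs and indels
    (insertions <= 13 bp, deletions <= 35 bp) at binomial allele-fraction
    means ``mus``, runs the full caller, and evaluates exact-allele recovery
    of PASS somatic calls plus VAF rank correlation. When ``run_control`` is
    set, the unspiked tumor pool is also called against the normal as a
    false-positive control.
    """
    import numpy as np
    from scipy.stats import spearmanr

    from .pipeline import call_regions
    from .simulator import design_spike_panel, make_virtual_tumor, simulate_reads

    rng = np.random.default_rng(seed)
    n_total = n_snv + n_indel
    spacing = 700
    ref = "".join(rng.choice(list("ACGT"), n_total * (spacing + 100) + 2 * spacing))
    specs = design_spike_panel(ref, "chr1", n_snv, n_indel, list(mus), rng, spacing=spacing)
    mu_by_pos = {s.edit.pos: s.target_vaf_mean for s in specs}
    tumor, normal, truth = make_virtual_tumor(
        ref, specs, depth_t, depth_n, err_rate, seed=int(rng.integers(0, 2**31 - 1))
    )
    intervals = [("chr1", 0, len(ref))]
    calls, logs = call_regions(tumor, normal, {"chr1": ref}, intervals)
    pass_somatic = {
        c.key: c for c in calls if c.is_pass and c.status == "SOMATIC"
    }
    matched_any = {c.key: c for c in calls}
    recov: dict[float, list[int]] = {mu: [] for mu in mus}
    realized_hi = []  # recovery among loci whose realized read fraction >= 0.1
    vaf_pairs = []
    for t in truth:
        key = ("chr1", t.pos, t.ref, t.alt)
        mu = mu_by_pos[t.pos]
        got = 1 if key in pass_somatic else 0
        recov[mu].append(got)
        if t.spiked_fraction >= 0.1:
            realized_hi.append(got)
        c = matched_any.get(key)
        if c is not None:
            vaf_pairs.append((t.spiked_fraction, c.counts.vaf_t))
    def rate(vals):
        return sum(vals) / len(vals) if vals else 0.0

    hi = [x for mu in mus if mu >= 0.1 for x in recov[mu]]
    rho = float(spearmanr([a for a, _ in vaf_pairs], [b for _, b in vaf_pairs])[0])
    out = {
        "n_truth": len(truth),
        "n_pass_somatic": len(pass_somatic),
        "false_pass_somatic": sum(
            1 for k in pass_somatic if k not in {("chr1", t.pos, t.ref, t.alt) for t in truth}
        ),
        "recovery_by_mu": {mu: rate(v) for mu, v in recov.items()},
        "n_by_mu": {mu: len(v) for mu, v in recov.items()},
        "recovery_mu_ge_10": rate(hi),
        "n_mu_ge_10": len(hi),
        "recovery_realized_ge_10": rate(realized_hi),
        "n_realized_ge_10": len(realized_hi),
        "vaf_spearman": rho,
        "window_logs": logs,
        "truth": truth,
        "calls": calls,
    }
    if run_control:
        ctrl_seed = int(rng.integers(0, 2**31 - 1))
        ctrl_tumor = simulate_reads(
            ref, [], depth_t, err_rate=err_rate, seed=ctrl_seed, sample_prefix="ctl"
        )
        ctrl_calls, _ = call_regions(ctrl_tumor, normal, {"chr1": ref}, intervals)
        out["control_pass_somatic"] = sum(
            1 for c in ctrl_calls if c.is_pass and c.status == "SOMATIC"
        )
    return out


def load_vcf_calls(
    path: str,
    score_field: str = "FETS",
    pass_only: bool = True,
    somatic_only: bool = False,
    contigs: Sequence[str] | None = None,
) -> list[BenchCall]:
    """Load a VCF into benchmark records (first ALT allele per record)."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if contigs is not None and rec.chrom not in contigs:
                continue
            if pass_only and "PASS" not in rec.filter and len(rec.filter) > 0:
                continue
            if somatic_only and "SOMATIC" not in rec.info:
                continue
            if score_field == "QUAL":
                score = rec.qual if rec.qual is not None else 0.0
            else:
                val = rec.info.get(score_field, 0.0)
                score = float(val[0] if isinstance(val, tuple) else val)
            out.append(BenchCall(rec.chrom, rec.pos - 1, rec.ref, rec.alts[0], score))
    return out
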