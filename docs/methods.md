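# Methods

`microcall` detects somatic SNVs and short indels from a tumor / matched
normal pair by joint local assembly. This note documents the model, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, what the simulator does and does not emulate, and
known limitations.

## Model and workflow

The genome (or target set) is tiled with overlapping windows (default
600 bp, stepping half a window, so every locus lies at least 150 bp inside
some window). For each window:

1. **Read selection.** Tumor reads are dropped if they are marked
   duplicates, have mapping quality < 15, or look multi-mapped
   (|AS−XS| ≤ 5, an XT:R tag, or an XA tag). Normal reads are used
   unfiltered: any allele evidence in the normal should count against a
   somatic interpretation, so the normal side must be maximally sensitive.
2. **Active-region screen.** A window is assembled only if ≥ N reads
   (default 3, the somatic minimum alternative count) support a mismatch,
   indel or soft-clip at the same locus in the tumor or the normal, as
   determined by cheap MD/CIGAR parsing. Windows with more than 10,000
   reads (tumor + normal combined) are skipped as unassemblable pile-ups;
   the combined count is our reading of an "excessive number of mapped
   reads" — the sample is not specified in the method description.
3. **Colored de Bruijn graph.** Tumor, normal and reference k-mers are
   collected into a bi-directed graph: nodes are canonical k-mers carrying
   per-sample, per-strand counts, read-identity sets and minimum base
   quality; edges connect k-mers overlapping by k−1 and every edge carries
   its reverse-complement mirror. K-mers from the overlapping segment of
   two mates of one fragment are counted once (detected via shared QNAME).
   Base qualities are recorded and exported but do not gate any default
   filter.
4. **Clean-up.** Low-coverage nodes (total sample count ≤ 1, or coverage
   ratio below 0.01 of the window mean over covered nodes) are removed;
   reference-path nodes are always retained so the window stays anchored.
   Dead-end chains ("tips") of n ≥ 11 uniquely linked non-reference nodes
   are removed; a `tip_mode="short"` flag offers the conventional
   shorter-than-n semantics instead. Short links — connections of at most
   m ≈ k/2 nodes whose minimum coverage is below √(mean window coverage) —
   are removed unless they sit at a microsatellite, where tiny bubbles can
   represent true slippage alleles and are kept. Finally maximal uniquely
   linked chains are compressed into super-nodes that retain per-position
   count profiles.
5. **Repeat-driven k selection.** A window is only analyzed with a k for
   which (a) the reference window has no two length-k substrings within 2
   mismatches of each other, (b) the graph is acyclic, and (c) no
   enumerated source-to-sink path revisits two k-mers within 2 mismatches.
   Only odd k in [11, 101] are used (odd k cannot equal its own reverse
   complement). Because screen (a) is monotone in k — a near-repeat pair at
   length k implies one at every shorter k — the iteration starts directly
   at the smallest odd k passing (a) and escalates further only when (b) or
   (c) fires; this yields the same final k as naive escalation from 11 with
   fewer graph builds. Windows with no admissible k ≤ 101 are reported as
   skipped.
6. **Anchoring and traversal.** The source (sink) anchor is the first
   k-mer from the window's 5′ (3′) end that occurs exactly once in the
   reference window, exactly once across the graph's spelled sequences, and
   is uniquely linked at its super-node boundary (a junction k-mer admits
   several upstream/downstream contexts and cannot pin down a walk).
   Haplotypes are enumerated by repeatedly taking the BFS-shortest
   source-to-sink walk that crosses at least one not-yet-covered edge,
   until every edge on any source-to-sink walk is covered. Each iteration
   covers ≥ 1 new edge, so the number of walks is bounded by the edge
   count; ties between equal-length walks break lexicographically for
   determinism. Dead-end edges lie on no source-to-sink walk and are never
   spelled.
7. **Alignment and variant extraction.** Each haplotype (trimmed
   anchor-to-anchor) is aligned to the corresponding reference slice with
   an affine-gap Gotoh DP (numba-compiled): match +2, mismatch −4, gap
   open −6, gap extend −1, a length-L gap costing open + L·extend. The
   alignment is global on the haplotype with free end gaps on the
   reference; since both sequences share exact anchors this is effectively
   end-to-end, but free reference ends make the mode robust if an anchor
   context shifts. These scores consolidate indels into single gaps rather
   than scattering mismatches, which signature extraction requires.
   Mismatch columns become SNVs; each maximal gap run becomes one
   insertion/deletion with a one-base left anchor. Haplotypes whose
   alignment is more than half gap columns are discarded as artifacts.
   Indels are left-normalized (shifted to the leftmost equivalent
   representation); the operation is idempotent and collapses any
   right-shifted representation of the same edit.
8. **Support counting.** Every node keeps a per-sample registry of the
   fragments (QNAMEs) that deposited it, so per-base read coverage can be
   recovered from the graph. Alt support is the distinct-fragment union
   over the variant's *evidence k-mers*: the k-mers containing the
   mismatched base for SNVs, and for indels the k-mers spanning the novel
   sequence with at least max_mm+1 = 3 bases beyond every junction edge —
   a junction k-mer with a thinner anchor lies within the repeat screen's
   mismatch tolerance of a reference k-mer and can be spelled by a single
   sequencing error in either sample. K-mers also present in the reference
   window are excluded (in repetitive context an indel junction spells
   reference sequence and carries no allele-specific evidence; if no novel
   k-mer remains the count falls back to the k-mer count of the node
   centered on the locus). Reference support is the same union over the
   reference-path k-mers covering the locus. Because any read covering a
   base contains at least one k-mer containing that base, these unions
   reproduce read-level allele counts with mate overlaps deduplicated by
   fragment name; strand splits attribute each fragment to the strand of
   its first covering mate. Alternatives considered: the minimum over all
   variant-touching k-mers discards every read that covers the variant but
   not the full ±(k−1) neighborhood, shrinking allele counts by roughly
   (L−2k)/L at read length L and pushing genuine 10%-fraction events onto
   the score threshold. VAF = alt/(alt+ref) on these counts, with 0/0
   defined as 0.
9. **Scoring, classification, filters.** The tumor/normal × ref/alt table
   is scored with a Phred-scaled two-sided Fisher's exact test,
   S = −10·log10(p) (0 if p = 1), where p sums the exact hypergeometric
   probabilities of all tables with the observed margins that are no more
   probable than the observed table. The p-value is computed in exact
   integer arithmetic (binomial-coefficient numerators over a common
   denominator), so no floating-point tie tolerance is needed; a one-sided
   variant is available by flag. A variant is SOMATIC iff the tumor has alt
   support and the normal alt count and VAF are within the configured
   ceilings (both 0 by default); shared and normal-only variants are also
   exported with their status. The filter stack (each independently
   toggleable, names fixed): LowCovNormal (< 10), LowCovTumor (< 4),
   LowVafTumor (< 0.04), HighVafNormal (> 0), LowAltCntTumor (< 3),
   HighAltCntNormal (> 0), LowFetScore (< 5 non-STR, < 25 STR), StrandBias
   (either-strand alt support < 1; off with `--no-strand-bias-filter`).
   An empty filter set renders as PASS.
10. **Microsatellite annotation.** A variant is STR-flagged when a tandem
    run of a 1–4 bp motif, repeated ≥ 3 times with total length ≥ 7 bp
    (partial trailing copies count toward the length), lies within 1 bp of
    the locus. The same definition drives the short-link STR exemption in
    clean-up.
11. **Output.** Calls from overlapping windows are deduplicated by
    (chrom, pos, ref, alt) keeping the highest-scoring record, sorted, and
    written as VCF 4.1 with QUAL = FET score and INFO fields SOMATIC,
    STATUS, FETS, KMERSIZE, MS. Windows are independent work units; any
    scheduling must reproduce the serial output.

Two-sided FET was chosen as the default because the score expresses a
generic non-random association between sample and allele counts; note that
the two-sided p-value is not strictly monotone in the tumor alt count at
fixed margins (the opposite-tail inclusion set changes discretely), while
the one-sided variant is.

## Simulator

The simulator provides ground truth without external data.

* `simulate_reads` samples fragments (normal length, default 400 ± 50)
  uniformly from an optionally edited haplotype and emits paired 150 bp
  records with exact CIGAR/MD computed from the known placement —
  haplotype-only sequence is soft-clipped, so no external aligner is
  involved and output is byte-deterministic under a seed. The pair count is
  calibrated to the fragment-feasible span so interior per-base coverage
  matches the requested depth. Sequencing error is a uniform per-base
  substitution (default 0.1%, the Illumina ballpark) with Phred qualities
  drawn from a two-point mixture (Q37 90% / Q12 10%); real
  quality-dependent, position-dependent error profiles are deliberately not
  modelled — the uniform rate is sufficient to exercise graph clean-up.
  Mate strands alternate with the covering mate so true variants are
  supported on both strands; `single_strand=True` reproduces a pathological
  one-strand scenario for exercising the strand-bias filter.
* `spike_virtual_tumor` emulates read swapping between a homozygous-variant
  donor and a homozygous-reference recipient: N ~ Binomial(n covering
  fragments, μ) whole fragments (mate pairs are never split) are replaced
  by donor fragments at the locus; the normal pool is untouched; the truth
  entry records the realized read fraction, which scatters around μ exactly
  as the binomial design implies.
* `design_spike_panel` lays loci ≥ 700 bp apart (one variant per window
  neighborhood), in left-normalized representation, with insertions ≤ 13 bp
  and deletions ≤ 35 bp, and draws loci away from microsatellite context.
  The STR exclusion is a deliberate generator condition: common-variant
  panels used for virtual tumors are dominated by non-STR sites, and
  STR indel calling is governed by a separate, stricter score threshold
  that warrants its own stratified analysis rather than contaminating the
  headline recovery rate.

What passing the simulator-based tests does **not** show: robustness to
alignment artifacts around real repeats, quality-correlated error bursts,
coverage biases (GC, mappability), contamination, or tumor heterogeneity
beyond a single allele fraction per locus.

## Verification harness

`scripts/acceptance.py` (and the mirrored acceptance tests) recompute, from
scratch at run time: the summary metrics for the published virtual-tumor
confusion counts; exact-test agreement with an independent exhaustive
enumeration over all 2×2 tables with row margins ≤ 40; path-cover
agreement with brute-force reachability on 200 random DAGs of ≤ 30 nodes;
alignment-score agreement with a naive affine DP on 1000 pairs ≤ 50 bp;
end-to-end recovery of 200 spiked SNVs + 100 indels at μ ∈
{0.05, 0.1, 0.2, 0.3} and 80×/40× coverage with a no-spike control and VAF
rank correlation; and k-escalation on windows with planted 30 bp tandem
duplications. Recovery is reported per target spike mean and additionally
binned by the realized read fraction recorded in the truth set — the
recall-vs-VAF axis — because the binomial swap regularly realizes 4–6%
events at a 10% target mean, and those belong in the bin of what was
actually spiked. The problem sizes (300 loci, ~220 kb reference, 200 random
graphs, 1000 alignment pairs) are the package's chosen verification scale:
large enough for the rates to be stable at the stated thresholds, small
enough to run on one CPU in minutes.

Expected behaviour at these conditions: recovery is limited at μ = 0.05
(mean alt support 4 at 80×, sitting below the default count/VAF/score
thresholds most of the time — these thresholds exist precisely to suppress
error-rate-level signal), and the dominant loss modes at μ = 0.1 are
binomial draws whose realized fraction falls well under 0.1 and the
occasional normal-sample read carrying the alt allele by sequencing error,
which the default zero-tolerance normal gate rightly treats as
disqualifying.

## Degenerate inputs and numerical notes

* Empty windows, windows shorter than k, and all-N stretches contribute no
  k-mers; non-ACGT k-mers are skipped everywhere.
* A window whose graph loses source/sink connectivity, or that has no
  unique anchor pair, is skipped with a logged reason rather than called.
* The exact-test p-value is exact rational arithmetic until the final
  division; scores are reproducible to machine precision.
* Left-normalization stops at the window edge (position 0 of the fetched
  context); windows overlap by 300 bp so a shifted representation is always
  rediscovered by the neighbouring window before the edge matters.
* Haplotype length is capped at 4× the window size to guard against
  pathological graphs.

## Limitations

* Pure local assembly: events larger than a window (long deletions,
  insertions beyond the anchor span, structural variants, mobile elements)
  are out of reach by construction.
* One tumor / one normal; no trio or multi-sample joint calling, no
  MNV/complex-event merging (adjacent mismatch columns stay separate SNVs).
* The Python implementation targets regional analyses and verification at
  desk scale, not 30× whole-genome production runs; windows are
  embarrassingly parallel but the shipped driver is serial.
* Support counting is k-window-fragment-based, so reported depths are
  slightly below raw pileup depths near window-edge loci.
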