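"""Localized colored de Bruijn graph: construction, clean-up, compression.

Nodes are canonical k-mers carrying per-sample, per-strand counts and color
labels (tumor / normal / reference). The graph is bi-directed: every edge
between oriented k-mers has a mirror between the reverse complements, so a
single structure represents both strands. Clean-up removes sequencing-error
debris (low-coverage nodes, dead-end tips, spurious short links) while the
reference path is always preserved; maximal uniquely-linked chains are then
compressed into super-nodes for traversal.

The k-mer size is escalated over odd values until the window is free of
perfect and near-perfect repeats, which would otherwise introduce false
bubbles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._dna import (
    canonical,
    find_all,
    is_acgt,
    kmers_near_repeat,
    min_odd_repeat_free_k,
    ref_near_repeat,
    revcomp,
    sliding_min,
)
from .sam_io import AlignedRead

__all__ = [
    "KmerNode",
    "ColoredDBG",
    "SuperNode",
    "CompressedGraph",
    "build_graph",
    "remove_low_coverage",
    "remove_dead_ends",
    "remove_short_links",
    "compress",
    "has_repeats",
    "assemble_window",
    "AssemblyResult",
]

TUMOR, NORMAL, REFERENCE = "TUMOR", "NORMAL", "REFERENCE"


_MATE_BITS = 0b011
_REV_BIT = 0b100


class KmerNode:
    """Counts, read registry and labels for one canonical k-mer.

    ``rt``/``rn`` map tumor/normal fragment names to a small bitfield
    (which mates contributed, and the strand of the first contribution), so
    per-base read coverage can be recovered as distinct-fragment unions."""

    __slots__ = ("tf", "tr", "nf", "nr", "is_ref", "rt", "rn", "min_qual")

    def __init__(self) -> None:
        self.tf = 0  # tumor forward-strand count
        self.tr = 0  # tumor reverse-strand count
        self.nf = 0  # normal forward-strand count
        self.nr = 0  # normal reverse-strand count
        self.is_ref = False
        self.rt: dict[str, int] = {}
        self.rn: dict[str, int] = {}
        self.min_qual = 255

    @property
    def total(self) -> int:
        return self.tf + self.tr + self.nf + self.nr

    @property
    def tumor(self) -> int:
        return self.tf + self.tr

    @property
    def normal(self) -> int:
        return self.nf + self.nr

    @property
    def colors(self) -> frozenset:
        c = set()
        if self.tumor > 0:
            c.add(TUMOR)
        if self.normal > 0:
            c.add(NORMAL)
        if self.is_ref:
            c.add(REFERENCE)
        return frozenset(c)

    @property
    def reads(self) -> frozenset:
        return frozenset(self.rt) | frozenset(self.rn)

    def add_occurrence(self, sample: str, is_reverse: bool, qname: str, mate: int, qual: int) -> None:
        if qual < self.min_qual:
            self.min_qual = qual
        d = self.rt if sample == "t" else self.rn
        mask = d.get(qname, 0)
        bit = 1 << mate
        if mask == 0:
            d[qname] = bit | (_REV_BIT if is_reverse else 0)
        else:
            d[qname] = mask | bit
            if (mask & _MATE_BITS) & ~bit:
                # the other mate already deposited this k-mer: the two reads
                # overlap here, count one copy only
                return
        if sample == "t":
            if is_reverse:
                self.tr += 1
            else:
                self.tf += 1
        else:
            if is_reverse:
                self.nr += 1
            else:
                self.nf += 1


class ColoredDBG:
    """Bi-directed colored de Bruijn graph over one genomic window."""

    def __init__(self, k: int, ref_seq: str) -> None:
        if k % 2 == 0 or not (11 <= k <= 101):
            raise ValueError(f"k must be odd and in [11, 101], got {k}")
        self.k = k
        self.ref_seq = ref_seq
        self.nodes: dict[str, KmerNode] = {}
        self.succ: dict[str, set] = {}
        self.pred: dict[str, set] = {}
        self.ref_path: list[str] = []
        self.ref_index: dict[str, int] = {}

    # -- construction ---------------------------------------------------

    def _node(self, canon: str) -> KmerNode:
        n = self.nodes.get(canon)
        if n is None:
            n = KmerNode()
            self.nodes[canon] = n
        return n

    def _add_edge(self, a: str, b: str, ra: str | None = None, rb: str | None = None) -> None:
        s = self.succ.get(a)
        if s is None:
            self.succ[a] = s = set()
        if b in s:  # edge (and its mirror) already present
            return
        s.add(b)
        self.pred.setdefault(b, set()).add(a)
        if ra is None:
            ra = revcomp(a)
        if rb is None:
            rb = revcomp(b)
        self.succ.setdefault(rb, set()).add(ra)
        self.pred.setdefault(ra, set()).add(rb)

    def add_read(self, read: AlignedRead, sample: str) -> None:
        seq = read.seq
        k = self.k
        if len(seq) < k:
            return
        rc = revcomp(seq)
        L = len(seq)
        clean = is_acgt(seq)
        qmins = sliding_min(np.asarray(read.quals, dtype=np.int16), k)
        prev = prev_rc = None
        for i in range(L - k + 1):
            kmer = seq[i : i + k]
            if not clean and not is_acgt(kmer):
                prev = None
                continue
            rck = rc[L - k - i : L - i]
            canon = kmer if kmer <= rck else rck
            self._node(canon).add_occurrence(
                sample, read.is_reverse, read.qname, read.mate, int(qmins[i])
            )
            if prev is not None:
                self._add_edge(prev, kmer, prev_rc, rck)
            prev = kmer
            prev_rc = rck

    def add_reference(self) -> None:
        k = self.k
        seq = self.ref_seq
        if len(seq) < k:
            return
        prev = None
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not is_acgt(kmer):
                prev = None
                self.ref_path.append("")
                continue
            canon = canonical(kmer)
            self._node(canon).is_ref = True
            self.ref_index.setdefault(kmer, i)
            if prev is not None:
                self._add_edge(prev, kmer)
            prev = kmer
            self.ref_path.append(kmer)

    # -- queries / mutation ---------------------------------------------

    def has_node(self, kmer: str) -> bool:
        return canonical(kmer) in self.nodes

    def node(self, kmer: str) -> KmerNode:
        return self.nodes[canonical(kmer)]

    def out_edges(self, kmer: str) -> set:
        return self.succ.get(kmer, set())

    def in_edges(self, kmer: str) -> set:
        return self.pred.get(kmer, set())

    def oriented(self) -> Iterable[str]:
        for canon in self.nodes:
            yield canon
            yield revcomp(canon)

    def edge_set(self) -> set:
        return {(a, b) for a, nbrs in self.succ.items() for b in nbrs}

    def remove_node(self, canon: str) -> None:
        for o in (canon, revcomp(canon)):
            for s in self.succ.pop(o, ()):  # drop edges out of o
                self.pred.get(s, set()).discard(o)
            for p in self.pred.pop(o, ()):
                self.succ.get(p, set()).discard(o)
        del self.nodes[canon]

    def sample_mean_coverage(self) -> float:
        totals = [n.total for n in self.nodes.values() if n.total > 0]
        return float(np.mean(totals)) if totals else 0.0


def build_graph(
    tumor_reads: Sequence[AlignedRead],
    normal_reads: Sequence[AlignedRead],
    ref_seq: str,
    k: int,
) -> ColoredDBG:
    """Build the joint tumor/normal/reference graph for one window."""
    g = ColoredDBG(k, ref_seq)
    for r in tumor_reads:
        g.add_read(r, "t")
    for r in normal_reads:
        g.add_read(r, "n")
    g.add_reference()
    return g


# -- clean-up ------------------------------------------------------------


def remove_low_coverage(g: ColoredDBG, min_count: int = 1, min_ratio: float = 0.01) -> ColoredDBG:
    """Delete nodes with sample count <= min_count or coverage ratio below
    min_ratio (ratio = node total / window mean over covered nodes).
    Reference-colored nodes are always retained."""
    mean = g.sample_mean_coverage()
    doomed = []
    for canon, node in g.nodes.items():
        if node.is_ref:
            continue
        t = node.total
        if t <= min_count or (mean > 0 and t / mean < min_ratio):
            doomed.append(canon)
    for canon in doomed:
        g.remove_node(canon)
    return g


def _walk_tip(g: ColoredDBG, start: str) -> list[str] | None:
    """Maximal uniquely-linked chain starting at the dangling end ``start``
    (an oriented k-mer with no predecessors), or None if it is not a tip."""
    chain = []
    seen = set()
    cur = start
    while True:
        canon = canonical(cur)
        if g.nodes[canon].is_ref or canon in seen:
            return chain or None
        chain.append(canon)
        seen.add(canon)
        nxt = g.succ.get(cur, set())
        if len(nxt) == 0:
            return chain  # isolated chain
        if len(nxt) > 1:
            return chain[:-1] or None  # current node is a junction, keep it
        (v,) = nxt
        if len(g.pred.get(v, set())) > 1:
            return chain  # reconnects at a junction
        cur = v


def remove_dead_ends(g: ColoredDBG, n: int = 11, mode: str = "long") -> ColoredDBG:
    """Remove dead-end chains (tips) of uniquely linked non-reference nodes.

    ``mode='long'`` removes tips formed by n or more nodes (the default
    documented behaviour); ``mode='short'`` removes tips shorter than n
    (the conventional assembler semantic), exposed for experimentation.
    """
    if mode not in ("long", "short"):
        raise ValueError("mode must be 'long' or 'short'")
    changed = True
    while changed:
        changed = False
        for x in sorted(o for o in g.oriented() if not g.pred.get(o)):
            canon = canonical(x)
            if canon not in g.nodes or g.nodes[canon].is_ref:
                continue
            if g.pred.get(x):
                continue
            chain = _walk_tip(g, x)
            if not chain:
                continue
            hit = len(chain) >= n if mode == "long" else len(chain) < n
            if hit:
                for c in chain:
                    if c in g.nodes:
                        g.remove_node(c)
                changed = True
    return g


def _link_chains(g: ColoredDBG) -> list[list[str]]:
    """Maximal uniquely-linked chains of non-reference nodes that connect to
    the rest of the graph at both ends (candidate short links)."""
    chains = []
    consumed = set()
    for x in sorted(g.oriented()):
        canon = canonical(x)
        if canon in consumed or g.nodes[canon].is_ref:
            continue
        preds = g.pred.get(x, set())
        # chain head: unique predecessor that is a junction or reference node
        if len(preds) != 1:
            continue
        (p,) = preds
        p_is_break = len(g.succ.get(p, set())) > 1 or g.nodes[canonical(p)].is_ref
        if not p_is_break:
            continue
        chain = [x]
        cur = x
        ok = False
        while True:
            nxt = g.succ.get(cur, set())
            if len(nxt) != 1:
                break
            (v,) = nxt
            if len(g.pred.get(v, set())) != 1:
                ok = True  # rejoins a junction
                break
            vc = canonical(v)
            if g.nodes[vc].is_ref:
                ok = True
                break
            if vc in {canonical(c) for c in chain}:
                break
            chain.append(v)
            cur = v
        if ok:
            chains.append([canonical(c) for c in chain])
            consumed.update(chains[-1])
    return chains


def remove_short_links(
    g: ColoredDBG,
    m: int | None = None,
    c_avg: float | None = None,
    str_intervals: Sequence[tuple[int, int]] = (),
) -> ColoredDBG:
    """Remove spurious short connections caused by local sequence homology.

    A connection of <= m uniquely linked nodes whose minimum node coverage is
    below sqrt(c_avg) is deleted, unless it lies at a microsatellite site
    (``str_intervals``, window-relative), where tiny bubbles may represent
    true replication-slippage alleles and must be kept.
    """
    if m is None:
        m = max(1, g.k // 2)
    if c_avg is None:
        c_avg = g.sample_mean_coverage()
    thresh = math.sqrt(c_avg) if c_avg > 0 else 0.0

    def near_str(chain: list[str]) -> bool:
        if not str_intervals:
            return False
        # locate the chain through any reference-flank k-mer position
        for canon in chain:
            for o in (canon, revcomp(canon)):
                for nbr in list(g.succ.get(o, ())) + list(g.pred.get(o, ())):
                    idx = g.ref_index.get(nbr)
                    if idx is None:
                        idx = g.ref_index.get(revcomp(nbr))
                    if idx is not None:
                        lo, hi = idx - 1, idx + g.k + 1
                        for s, e in str_intervals:
                            if s < hi and e > lo:
                                return True
        return False

    for chain in _link_chains(g):
        if len(chain) > m:
            continue
        if not all(c in g.nodes for c in chain):
            continue
        cmin = min(g.nodes[c].total for c in chain)
        if cmin >= thresh:
            continue
        if near_str(chain):
            continue
        for c in chain:
            if c in g.nodes:
                g.remove_node(c)
    return g


# -- compression ---------------------------------------------------------


@dataclass
class SuperNode:
    """A maximal uniquely-linked chain spelled as one sequence.

    Per-k-mer count profiles are kept positionally so that allele support can
    be computed as a minimum over variant-spanning k-mers after traversal.
    """

    sid: int
    seq: str
    kmers: list[str]
    tf: np.ndarray
    tr: np.ndarray
    nf: np.ndarray
    nr: np.ndarray
    is_ref: np.ndarray  # bool per k-mer
    min_qual: int

    @property
    def tumor(self) -> int:
        return int(self.tf.sum() + self.tr.sum())

    @property
    def normal(self) -> int:
        return int(self.nf.sum() + self.nr.sum())

    @property
    def has_ref(self) -> bool:
        return bool(self.is_ref.any())

    def color(self) -> str:
        """Display color following the shared/private palette."""
        t, n = self.tumor > 0, self.normal > 0
        if t and n:
            return "blue"
        if t:
            return "red"
        if n:
            return "green"
        return "white"


class CompressedGraph:
    """Chain-compressed view of a :class:`ColoredDBG`."""

    def __init__(self, k: int, ref_seq: str) -> None:
        self.k = k
        self.ref_seq = ref_seq
        self.snodes: dict[int, SuperNode] = {}
        self.csucc: dict[tuple[int, str], tuple] = {}
        self.loc: dict[str, tuple[int, str, int]] = {}
        # per-window reference k-mer count profiles (for ref-allele support)
        self.ref_tf = np.empty(0, dtype=np.int32)
        self.ref_tr = np.empty(0, dtype=np.int32)
        self.ref_nf = np.empty(0, dtype=np.int32)
        self.ref_nr = np.empty(0, dtype=np.int32)

    def out_edges(self, onode: tuple[int, str]) -> tuple:
        return self.csucc.get(onode, ())

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.csucc.values())

    def oriented_seq(self, sid: int, ori: str) -> str:
        s = self.snodes[sid].seq
        return s if ori == "+" else revcomp(s)

    def oriented_counts(self, sid: int, ori: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        n = self.snodes[sid]
        if ori == "+":
            return n.tf, n.tr, n.nf, n.nr
        return n.tf[::-1], n.tr[::-1], n.nf[::-1], n.nr[::-1]

    def occurrences(self, kmer: str) -> list[tuple[int, str, int]]:
        """All (sid, ori, offset) where the oriented super-node spells kmer."""
        out = []
        rc = revcomp(kmer)
        for sid, sn in self.snodes.items():
            for off in find_all(sn.seq, kmer):
                out.append((sid, "+", off))
            for off in find_all(sn.seq, rc):
                out.append((sid, "-", len(sn.seq) - self.k - off))
        return out

    def spell(self, path: Sequence[tuple[int, str]]) -> tuple[str, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Sequence and concatenated per-k-mer count profiles of a path."""
        k = self.k
        parts = []
        counts = [[], [], [], []]
        for i, (sid, ori) in enumerate(path):
            s = self.oriented_seq(sid, ori)
            parts.append(s if i == 0 else s[k - 1 :])
            for j, arr in enumerate(self.oriented_counts(sid, ori)):
                counts[j].append(arr)
        seq = "".join(parts)
        tf, tr, nf, nr = (np.concatenate(c) if c else np.empty(0, np.int32) for c in counts)
        return seq, tf, tr, nf, nr

    def has_cycle(self) -> bool:
        import networkx as nx

        dg = nx.DiGraph()
        dg.add_nodes_from((sid, o) for sid in self.snodes for o in "+-")
        for u, vs in self.csucc.items():
            for v in vs:
                dg.add_edge(u, v)
        return not nx.is_directed_acyclic_graph(dg)

    def to_dot(self, title: str = "window") -> str:
        fill = {"blue": "lightblue", "red": "salmon", "green": "palegreen", "white": "white"}
        lines = [f'digraph "{title}" {{', "  node [style=filled];"]
        for sid, sn in sorted(self.snodes.items()):
            label = sn.seq if len(sn.seq) <= 2 * self.k else f"len={len(sn.seq)}"
            tip = f"T:{sn.tumor} N:{sn.normal} ref:{int(sn.has_ref)} minQ:{sn.min_qual}"
            lines.append(
                f'  n{sid} [label="{label}", fillcolor={fill[sn.color()]}, tooltip="{tip}"];'
            )
        seen = set()
        for (sid, ori), targets in sorted(self.csucc.items()):
            for tid, tori in targets:
                key = frozenset({(sid, ori, tid, tori), (tid, _flip(tori), sid, _flip(ori))})
                if key in seen:
                    continue
                seen.add(key)
                lines.append(f'  n{sid} -> n{tid} [label="{ori}{tori}"];')
        lines.append("}")
        return "\n".join(lines)


def _flip(ori: str) -> str:
    return "-" if ori == "+" else "+"


def compress(g: ColoredDBG) -> CompressedGraph:
    """Merge maximal uniquely-linked chains into super-nodes.

    The multiset of spelled source-to-sink sequences is preserved: chain
    interiors have unique in/out linkage in both orientations, so every edge
    crossing a chain boundary lands on a chain head.
    """
    cg = CompressedGraph(g.k, g.ref_seq)
    if not g.nodes:
        return cg

    def outdeg(x: str) -> int:
        return len(g.succ.get(x, ()))

    def indeg(x: str) -> int:
        return len(g.pred.get(x, ()))

    def is_head(x: str) -> bool:
        if indeg(x) != 1:
            return True
        (p,) = g.pred[x]
        return outdeg(p) != 1

    heads = [x for x in g.oriented() if is_head(x)]
    consumed: set[str] = set()
    chains: list[list[str]] = []
    for h in sorted(heads):
        if canonical(h) in consumed:
            continue
        chain = [h]
        cur = h
        while outdeg(cur) == 1:
            (v,) = g.succ[cur]
            if is_head(v):
                break
            chain.append(v)
            cur = v
        chains.append(chain)
        consumed.update(canonical(c) for c in chain)
    # pure cycles (no head): consume from an arbitrary start
    for x in sorted(g.oriented()):
        if canonical(x) in consumed:
            continue
        chain = [x]
        consumed.add(canonical(x))
        cur = x
        while outdeg(cur) == 1:
            (v,) = g.succ[cur]
            if canonical(v) in consumed or v == x:
                break
            chain.append(v)
            consumed.add(canonical(v))
            cur = v
        chains.append(chain)

    k = g.k
    for sid, chain in enumerate(chains):
        seq = chain[0] + "".join(x[-1] for x in chain[1:])
        nodes = [g.nodes[canonical(x)] for x in chain]
        sn = SuperNode(
            sid=sid,
            seq=seq,
            kmers=list(chain),
            tf=np.array([n.tf for n in nodes], dtype=np.int32),
            tr=np.array([n.tr for n in nodes], dtype=np.int32),
            nf=np.array([n.nf for n in nodes], dtype=np.int32),
            nr=np.array([n.nr for n in nodes], dtype=np.int32),
            is_ref=np.array([n.is_ref for n in nodes], dtype=bool),
            min_qual=min(n.min_qual for n in nodes),
        )
        cg.snodes[sid] = sn
        L = len(chain)
        for i, x in enumerate(chain):
            cg.loc[x] = (sid, "+", i)
            cg.loc[revcomp(x)] = (sid, "-", L - 1 - i)

    for sid, sn in cg.snodes.items():
        for ori in "+-":
            kmers = sn.kmers if ori == "+" else [revcomp(x) for x in reversed(sn.kmers)]
            last = kmers[-1]
            targets = []
            for t in sorted(g.succ.get(last, ())):
                tid, tori, toff = cg.loc[t]
                if toff != 0:
                    raise RuntimeError("compression boundary landed mid-chain")
                targets.append((tid, tori))
            if targets:
                cg.csucc[(sid, ori)] = tuple(targets)

    # reference k-mer count profiles for ref-allele support
    prof = [[], [], [], []]
    for kmer in g.ref_path:
        if kmer and g.has_node(kmer):
            n = g.node(kmer)
            vals = (n.tf, n.tr, n.nf, n.nr)
        else:
            vals = (0, 0, 0, 0)
        for j, v in enumerate(vals):
            prof[j].append(v)
    cg.ref_tf, cg.ref_tr, cg.ref_nf, cg.ref_nr = (
        np.array(p, dtype=np.int32) for p in prof
    )
    return cg


# -- repeat analysis and window assembly ----------------------------------


def has_repeats(
    ref_seq: str,
    cg: CompressedGraph,
    k: int,
    max_mm: int = 2,
    paths: Sequence[str] | None = None,
) -> bool:
    """Repeat screen for the current k.

    True if the reference window contains two length-k substrings within
    ``max_mm`` mismatches, the graph contains a cycle, or any supplied
    source-to-sink path sequence revisits two k-mers within ``max_mm``.
    """
    if ref_near_repeat(ref_seq, k, max_mm):
        return True
    if cg.has_cycle():
        return True
    if paths:
        for seq in paths:
            kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
            if kmers_near_repeat(kmers, max_mm):
                return True
    return False


@dataclass
class AssemblyResult:
    status: str  # ok | skipped-repeat | no-anchor | disconnected
    graph: CompressedGraph | None = None
    k: int = 0
    anchors: object = None
    haplotypes: list = field(default_factory=list)
    raw_graph: ColoredDBG | None = None  # cleaned k-mer graph (read registry)


def assemble_window(
    tumor_reads: Sequence[AlignedRead],
    normal_reads: Sequence[AlignedRead],
    window,
    k_min: int = 11,
    k_max: int = 101,
    max_mm: int = 2,
    min_node_count: int = 1,
    min_cov_ratio: float = 0.01,
    tip_len: int = 11,
    tip_mode: str = "long",
    short_link_m: int | None = None,
    str_intervals: Sequence[tuple[int, int]] = (),
    max_path_len: int | None = None,
) -> AssemblyResult:
    """Iteratively assemble one window, escalating k until repeat-free.

    Only odd k values are used (a k-mer can never equal its own reverse
    complement). The reference-sequence repeat screen is monotone in k, so
    the iteration starts at the smallest odd repeat-free k and escalates
    further only if the graph itself shows cycles or near-repeat paths.
    """
    from .traversal import anchor_graph, enumerate_paths

    ref_seq = window.ref_seq
    k0 = min_odd_repeat_free_k(ref_seq, k_min, k_max, max_mm)
    if k0 is None:
        return AssemblyResult("skipped-repeat", k=k_max)
    k = k0
    while k <= k_max:
        g = build_graph(tumor_reads, normal_reads, ref_seq, k)
        remove_low_coverage(g, min_node_count, min_cov_ratio)
        remove_dead_ends(g, tip_len, tip_mode)
        remove_short_links(g, short_link_m, None, str_intervals)
        cg = compress(g)
        anchors = anchor_graph(cg, ref_seq)
        if anchors is None:
            return AssemblyResult("no-anchor", cg, k)
        if cg.has_cycle():
            k += 2
            continue
        haps = enumerate_paths(cg, anchors, max_path_len=max_path_len)
        if haps is None:
            return AssemblyResult("disconnected", cg, k)
        if has_repeats(ref_seq, cg, k, max_mm, paths=[h.seq for h in haps]):
            k += 2
            continue
        return AssemblyResult("ok", cg, k, anchors, haps, raw_graph=g)
    return AssemblyResult("skipped-repeat", k=k_max)
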