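"""Reference anchoring and haplotype enumeration.

The cleaned, compressed graph is anchored to the window reference by a
*source* and a *sink* k-mer that occur exactly once in the graph and once in
the reference. Haplotypes are then enumerated with an Edmonds–Karp-flavored
scheme: repeatedly take the shortest source-to-sink walk that crosses at
least one not-yet-covered edge, until every edge lying on any source-to-sink
walk has been covered. The number of walks is at most the number of edges,
and no bubble branch can be missed because each branch edge must be covered
by some returned walk.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np

from ._dna import find_all, revcomp

__all__ = ["Anchors", "Haplotype", "anchor_graph", "cover_paths", "enumerate_paths"]


@dataclass
class Anchors:
    source_kmer: str
    sink_kmer: str
    source_ref_pos: int  # window-relative offset of the source k-mer
    sink_ref_pos: int
    source_loc: tuple[int, str, int]  # (sid, ori, offset in oriented seq)
    sink_loc: tuple[int, str, int]

    @property
    def ref_span(self) -> tuple[int, int]:
        """Window-relative half-open span covered by anchored haplotypes."""
        return self.source_ref_pos, self.sink_ref_pos + len(self.sink_kmer)


@dataclass
class Haplotype:
    """One assembled source-to-sink sequence with per-k-mer support."""

    seq: str
    nodes: list[tuple[int, str]]
    k: int
    tf: np.ndarray
    tr: np.ndarray
    nf: np.ndarray
    nr: np.ndarray

    @property
    def min_support(self) -> dict:
        t = self.tf + self.tr
        n = self.nf + self.nr
        return {
            "tumor": int(t.min()) if len(t) else 0,
            "normal": int(n.min()) if len(n) else 0,
        }


def _graph_occurrence_count(cg, kmer: str) -> int:
    rc = revcomp(kmer)
    count = 0
    for sn in cg.snodes.values():
        count += len(find_all(sn.seq, kmer))
        if rc != kmer:
            count += len(find_all(sn.seq, rc))
        if count > 1:
            return count
    return count


def anchor_graph(cg, ref_seq: str):
    """Select source and sink anchor k-mers, or None when no anchor exists.

    The source is the first k-mer from the 5' end of the window that occurs
    exactly once in the graph and once in the reference; the sink is chosen
    symmetrically from the 3' end and must lie after the source.
    """
    k = cg.k
    n = len(ref_seq)
    if n < k or not cg.snodes:
        return None

    indeg: dict = {}
    for u, targets in cg.csucc.items():
        for v in targets:
            indeg[v] = indeg.get(v, 0) + 1

    def uniquely_linked(loc) -> bool:
        # a junction k-mer admits several contexts and cannot anchor a walk
        sid, ori, off = loc
        n_k = len(cg.snodes[sid].seq) - k + 1
        if off == 0 and indeg.get((sid, ori), 0) > 1:
            return False
        if off == n_k - 1 and len(cg.out_edges((sid, ori))) > 1:
            return False
        return True

    def unique(i: int):
        q = ref_seq[i : i + k]
        if len(find_all(ref_seq, q)) != 1:
            return None
        if _graph_occurrence_count(cg, q) != 1:
            return None
        occ = cg.occurrences(q)
        if len(occ) != 1 or not uniquely_linked(occ[0]):
            return None
        return occ[0]

    source = None
    for i in range(n - k + 1):
        loc = unique(i)
        if loc is not None:
            source = (i, ref_seq[i : i + k], loc)
            break
    if source is None:
        return None
    sink = None
    for i in range(n - k, source[0], -1):
        loc = unique(i)
        if loc is not None:
            sink = (i, ref_seq[i : i + k], loc)
            break
    if sink is None:
        return None
    return Anchors(
        source_kmer=source[1],
        sink_kmer=sink[1],
        source_ref_pos=source[0],
        sink_ref_pos=sink[0],
        source_loc=source[2],
        sink_loc=sink[2],
    )


def _shortest_augmenting(
    adj: Callable[[Hashable], Sequence],
    source: Hashable,
    sink: Hashable,
    covered: set,
) -> list | None:
    """BFS shortest source->sink path crossing >= 1 uncovered edge.

    State space is (node, crossed-new-edge flag); neighbor expansion is in
    sorted order so tie-breaking among equal-length paths is deterministic.
    """
    start = (source, False)
    parent: dict = {start: None}
    q = deque([start])
    goal = (sink, True)
    while q:
        state = q.popleft()
        if state == goal:
            break
        node, flag = state
        for nbr in adj(node):
            nflag = flag or (node, nbr) not in covered
            nstate = (nbr, nflag)
            if nstate not in parent:
                parent[nstate] = state
                q.append(nstate)
    if goal not in parent:
        return None
    path = []
    cur = goal
    while cur is not None:
        path.append(cur[0])
        cur = parent[cur]
    path.reverse()
    return path


def cover_paths(
    adj: Mapping | Callable,
    source: Hashable,
    sink: Hashable,
    max_edges: int | None = None,
) -> tuple[list[list], int]:
    """Edge-covering set of source-to-sink paths plus the iteration count.

    Every edge reachable on some source-to-sink walk is covered by at least
    one returned path; each augmenting iteration covers at least one new
    edge, so iterations never exceed the edge count.
    """
    if callable(adj) and not isinstance(adj, Mapping):
        adj_fn = adj
    else:
        mapping = adj

        def adj_fn(u):
            return sorted(mapping.get(u, ()))

    covered: set = set()
    paths: list[list] = []
    iters = 0
    while True:
        p = _shortest_augmenting(adj_fn, source, sink, covered)
        if p is None:
            break
        paths.append(p)
        iters += 1
        for e in zip(p, p[1:]):
            covered.add(e)
        if max_edges is not None and iters > max_edges + 1:
            raise RuntimeError("path enumeration exceeded its edge-count bound")
    if not paths and source == sink:
        paths = [[source]]
    return paths, iters


def enumerate_paths(cg, anchors: Anchors, max_path_len: int | None = None):
    """Spell and trim the covering source-to-sink haplotypes of a window.

    Returns None when the sink is unreachable from the source (the window is
    then skipped), otherwise the list of trimmed haplotypes with per-k-mer
    count profiles.
    """
    k = cg.k
    src_sid, src_ori, src_off = anchors.source_loc
    snk_sid, snk_ori, snk_off = anchors.sink_loc
    source = (src_sid, src_ori)
    sink = (snk_sid, snk_ori)
    node_paths, _ = cover_paths(cg.csucc, source, sink, max_edges=cg.n_edges)
    if source == sink and node_paths == [[source]] and src_off > snk_off:
        return None
    if not node_paths:
        return None
    out = []
    seen_seqs = set()
    for path in node_paths:
        seq, tf, tr, nf, nr = cg.spell(path)
        last_len = len(cg.oriented_seq(*path[-1]))
        start = src_off
        end = len(seq) - last_len + snk_off + k
        if end - start < k or end > len(seq):
            continue
        trimmed = seq[start:end]
        if not (trimmed.startswith(anchors.source_kmer) and trimmed.endswith(anchors.sink_kmer)):
            continue  # walk re-entered an anchor context inconsistently
        if max_path_len is not None and len(trimmed) > max_path_len:
            continue
        if trimmed in seen_seqs:
            continue
        seen_seqs.add(trimmed)
        sl = slice(start, end - k + 1)
        out.append(
            Haplotype(
                seq=trimmed,
                nodes=path,
                k=k,
                tf=tf[sl],
                tr=tr[sl],
                nf=nf[sl],
                nr=nr[sl],
            )
        )
    return out if out else None
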