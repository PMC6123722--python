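"""Colored de Bruijn graph construction, clean-up, compression, repeats."""

import numpy as np
import pytest

from microcall._dna import canonical, revcomp
from microcall.cdbg import (
    assemble_window,
    build_graph,
    compress,
    has_repeats,
    remove_dead_ends,
    remove_low_coverage,
    remove_short_links,
)
from microcall.regions import Window
from microcall.simulator import Edit, simulate_reads

from conftest import make_read, random_seq


def kmer_multiset(seqs, k):
    """Brute-force canonical k-mer counts from a list of sequences."""
    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            c = canonical(s[i : i + k])
            counts[c] = counts.get(c, 0) + 1
    return counts


def spelled_strings(g_or_reads, cg, source, sink):
    """All source-to-sink strings by exhaustive simple-path enumeration on
    the compressed graph (independent of cover_paths)."""
    out = set()

    def dfs(node, path):
        if node == sink:
            out.add(cg.spell(path)[0])
            return
        for nxt in cg.out_edges(node):
            if nxt not in path:
                dfs(nxt, path + [nxt])

    dfs(source, [source])
    return out


class TestBuildGraph:
    def test_tiny_read(self):
        seq = "ACGTACGTACGTA"  # 13 bp; canonical k-mer set from brute force
        r = make_read(seq=seq, qname="a")
        g = build_graph([r], [], seq, 11)
        assert set(g.nodes) == set(kmer_multiset([seq], 11))
        assert all(n.is_ref for n in g.nodes.values())

    def test_k_validation(self):
        with pytest.raises(ValueError):
            build_graph([], [], "A" * 50, 12)
        with pytest.raises(ValueError):
            build_graph([], [], "A" * 50, 9)

    def test_non_acgt_kmers_skipped(self, rng):
        seq = random_seq(rng, 30)
        seq = seq[:15] + "N" + seq[16:]
        r = make_read(seq=seq, qname="a")
        g = build_graph([r], [], random_seq(rng, 11), 11)
        for canon in g.nodes:
            assert "N" not in canon

    def test_revcomp_invariance(self, rng):
        seqs = [random_seq(rng, 60) for _ in range(5)]
        ref = random_seq(rng, 40)
        fwd = [make_read(seq=s, qname=f"r{i}") for i, s in enumerate(seqs)]
        rev = [
            make_read(seq=revcomp(s), qname=f"r{i}", is_reverse=True)
            for i, s in enumerate(seqs)
        ]
        g1 = build_graph(fwd, [], ref, 11)
        g2 = build_graph(rev, [], ref, 11)
        assert set(g1.nodes) == set(g2.nodes)
        for c in g1.nodes:
            assert g1.nodes[c].total == g2.nodes[c].total

    def test_counts_match_bruteforce_multiset(self, rng):
        k = 11
        seqs = [random_seq(rng, 50) for _ in range(8)]
        reads = [make_read(seq=s, qname=f"q{i}") for i, s in enumerate(seqs)]
        g = build_graph(reads, [], random_seq(rng, 30), k)
        expect = kmer_multiset(seqs, k)
        got = {c: n.total for c, n in g.nodes.items() if n.total > 0}
        assert got == expect

    def test_mate_overlap_counted_once(self, rng):
        k = 11
        ref = random_seq(rng, 100)
        # two mates of one fragment overlapping by 20 bp
        m1 = make_read(seq=ref[0:60], qname="frag", mate=0)
        m2 = make_read(seq=ref[40:100], start=40, qname="frag", mate=1)
        g = build_graph([m1, m2], [], "T" * 20, k)
        # brute force with QNAME dedup: count max over mates per k-mer
        c1 = kmer_multiset([ref[0:60]], k)
        c2 = kmer_multiset([ref[40:100]], k)
        expect = {c: max(c1.get(c, 0), c2.get(c, 0)) for c in set(c1) | set(c2)}
        got = {c: n.total for c, n in g.nodes.items() if n.total > 0}
        assert got == expect
        # the 10 k-mers fully inside the overlap have count 1, not 2
        inside = [ref[i : i + k] for i in range(40, 50)]
        assert all(g.node(x).total == 1 for x in inside)

    def test_tumor_private_matches_normal_only_graph(self, rng):
        ref = random_seq(rng, 80)
        alt = ref[:40] + ("A" if ref[40] != "A" else "C") + ref[41:]
        treads = [make_read(seq=alt, qname="t1"), make_read(seq=ref, qname="t2")]
        nreads = [make_read(seq=ref, qname="n1")]
        joint = build_graph(treads, nreads, ref, 11)
        normal_only = build_graph([], nreads, ref, 11)
        for canon, node in joint.nodes.items():
            if node.tumor > 0 and node.normal == 0 and not node.is_ref:
                assert canon not in normal_only.nodes or normal_only.nodes[canon].total == 0


class TestCleanup:
    def test_low_coverage_removed(self, rng):
        ref = random_seq(rng, 60)
        err = random_seq(rng, 30)
        reads = [make_read(seq=ref, qname=f"r{i}") for i in range(5)]
        reads.append(make_read(seq=err, qname="e"))
        g = build_graph(reads, [], ref, 11)
        n_before = len(g.nodes)
        remove_low_coverage(g, min_count=1)
        # count-1 error nodes gone, ref-path (count 5) intact
        assert all(g.has_node(ref[i : i + 11]) for i in range(len(ref) - 10))
        assert len(g.nodes) < n_before
        assert all(n.total > 1 or n.is_ref for n in g.nodes.values())

    def test_reference_only_node_kept_at_zero_coverage(self, rng):
        ref = random_seq(rng, 40)
        g = build_graph([], [], ref, 11)
        remove_low_coverage(g, min_count=1)
        assert len(g.nodes) == len({canonical(ref[i : i + 11]) for i in range(30)})

    def _tip_graph(self, rng, tip_nodes):
        """Reads spelling the reference plus a divergent dangling branch."""
        ref = random_seq(rng, 80)
        k = 11
        branch_point = 30
        tip_seq = ref[: branch_point + k] + random_seq(rng, tip_nodes)
        reads = [make_read(seq=ref, qname=f"r{i}") for i in range(3)]
        reads += [make_read(seq=tip_seq, qname=f"t{i}") for i in range(3)]
        g = build_graph(reads, [], ref, k)
        return g, ref, tip_seq

    def test_long_tip_removed_short_kept(self, rng):
        g, ref, tip_seq = self._tip_graph(rng, 12)
        assert g.has_node(tip_seq[-11:])
        remove_dead_ends(g, n=11, mode="long")
        assert not g.has_node(tip_seq[-11:])
        g2, ref2, tip2 = self._tip_graph(rng, 3)
        remove_dead_ends(g2, n=11, mode="long")
        assert g2.has_node(tip2[-11:])  # 3-node tip below threshold is kept

    def test_short_mode_inverts_predicate(self, rng):
        g, ref, tip_seq = self._tip_graph(rng, 3)
        remove_dead_ends(g, n=11, mode="short")
        assert not g.has_node(tip_seq[-11:])

    def test_linear_graph_unchanged(self, rng):
        ref = random_seq(rng, 60)
        reads = [make_read(seq=ref, qname=f"r{i}") for i in range(3)]
        g = build_graph(reads, [], ref, 11)
        nodes = set(g.nodes)
        remove_dead_ends(g, n=11)
        assert set(g.nodes) == nodes

    def _link_graph(self, rng, link_cov, main_cov=100):
        """Homology-induced short link: two loci share an 8 bp stretch, so a
        chimeric junction read creates only two novel k-mers bridging them."""
        k, h = 11, 8
        base = random_seq(rng, 120)
        ref = base[:72] + base[30 - h : 30] + base[80:]  # ref[72:80] == ref[22:30]
        bridge = ref[10:30] + ref[80:110]
        reads = [make_read(seq=ref, qname=f"m{i}") for i in range(main_cov)]
        reads += [make_read(seq=bridge, qname=f"l{i}") for i in range(link_cov)]
        g = build_graph(reads, [], ref, k)
        novel = [
            bridge[o : o + k]
            for o in range(len(bridge) - k + 1)
            if bridge[o : o + k] not in ref and revcomp(bridge[o : o + k]) not in ref
        ]
        assert 1 <= len(novel) <= g.k // 2
        return g, ref, novel

    def test_weak_short_link_removed(self, rng):
        g, ref, novel = self._link_graph(rng, link_cov=2, main_cov=100)
        remove_low_coverage(g, 1)
        assert all(g.has_node(x) for x in novel)
        remove_short_links(g)  # c=2 < sqrt(~100)
        assert not any(g.has_node(x) for x in novel)
        # reference path intact
        assert all(g.has_node(ref[i : i + 11]) for i in range(len(ref) - 10))

    def test_strong_short_link_kept(self, rng):
        g, ref, novel = self._link_graph(rng, link_cov=60, main_cov=30)
        remove_short_links(g)  # c=60 >= sqrt(mean)
        assert all(g.has_node(x) for x in novel)

    def test_str_site_bubble_kept(self, rng):
        # heterozygous contraction inside a homopolymer: tiny bubble at an STR
        k = 11
        left = random_seq(rng, 40)
        right = random_seq(rng, 40)
        ref = left + "A" * 12 + right
        alt = left + "A" * 11 + right
        reads = [make_read(seq=ref, qname=f"r{i}") for i in range(30)]
        reads += [make_read(seq=alt, qname=f"a{i}") for i in range(2)]
        g = build_graph(reads, [], ref, k)
        alt_kmers = {alt[i : i + k] for i in range(len(alt) - k + 1)}
        ref_kmers = {ref[i : i + k] for i in range(len(ref) - k + 1)}
        private = {x for x in alt_kmers - ref_kmers if g.has_node(x)}
        from microcall.scoring import find_str_intervals

        strs = [(s, e) for s, e, _ in find_str_intervals(ref)]
        remove_short_links(g, str_intervals=strs)
        for x in private:
            assert g.has_node(x)


class TestCompress:
    def test_linear_chain_single_supernode(self, rng):
        ref = random_seq(rng, 60)
        g = build_graph([make_read(seq=ref, qname="r")], [], ref, 11)
        cg = compress(g)
        assert len(cg.snodes) == 1
        sn = cg.snodes[0]
        assert sn.seq in (ref, revcomp(ref))

    def test_snv_bubble_four_supernodes(self, rng):
        ref = random_seq(rng, 80)
        alt = ref[:40] + ("G" if ref[40] != "G" else "T") + ref[41:]
        reads = [make_read(seq=ref, qname="r"), make_read(seq=alt, qname="a")]
        g = build_graph(reads, [], ref, 11)
        cg = compress(g)
        assert len(cg.snodes) == 4

    def test_empty_graph(self):
        g = build_graph([], [], "", 11)
        cg = compress(g)
        assert cg.snodes == {}

    def test_compress_preserves_spelled_strings(self, rng):
        # source-to-sink string set identical on raw and compressed graphs
        for trial in range(5):
            ref = random_seq(rng, 70)
            variants = [ref]
            p = 20 + 7 * trial
            variants.append(ref[:p] + ("C" if ref[p] != "C" else "A") + ref[p + 1 :])
            reads = [make_read(seq=s, qname=f"v{i}") for i, s in enumerate(variants)]
            g = build_graph(reads, [], ref, 11)
            cg = compress(g)
            src_k, snk_k = ref[:11], ref[-11:]
            # raw-graph exhaustive enumeration
            raw = set()

            def dfs(cur, seq):
                if cur == snk_k:
                    raw.add(seq)
                    return
                for nxt in g.out_edges(cur):
                    dfs(nxt, seq + nxt[-1])

            dfs(src_k, src_k)
            occ_src = cg.occurrences(src_k)
            occ_snk = cg.occurrences(snk_k)
            assert len(occ_src) == 1 and len(occ_snk) == 1
            sid, ori, off = occ_src[0]
            tid, tori, toff = occ_snk[0]
            comp = set()
            for s in spelled_strings(None, cg, (sid, ori), (tid, tori)):
                L = len(cg.oriented_seq(tid, tori))
                trimmed = s[off : len(s) - L + toff + 11]
                comp.add(trimmed)
            assert raw == comp


class TestHasRepeats:
    def _cg(self, reads, ref, k):
        return compress(build_graph(reads, [], ref, k))

    def test_homopolymer_reference(self):
        ref = "A" * 40
        assert has_repeats(ref, self._cg([], ref, 11), 11)

    def test_unique_window_no_repeat(self, rng):
        # search for a window with all 11-mers pairwise Hamming > 2 and
        # verify against brute force
        from itertools import combinations

        for _ in range(50):
            ref = random_seq(rng, 60)
            kmers = [ref[i : i + 11] for i in range(len(ref) - 10)]
            ok = all(
                sum(a != b for a, b in zip(x, y)) > 2 for x, y in combinations(kmers, 2)
            )
            if ok:
                cg = self._cg([make_read(seq=ref, qname="r")], ref, 11)
                assert not has_repeats(ref, cg, 11, paths=[ref])
                return
        pytest.skip("no repeat-free window found in 50 draws")

    def test_ref_near_repeat_agrees_with_bruteforce(self, rng):
        from microcall._dna import ref_near_repeat

        for _ in range(30):
            seq = random_seq(rng, 50)
            k = 11
            brute = any(
                sum(a != b for a, b in zip(seq[i : i + k], seq[j : j + k])) <= 2
                for i in range(len(seq) - k + 1)
                for j in range(i + 1, len(seq) - k + 1)
            )
            assert ref_near_repeat(seq, k, 2) == brute

    def test_cycle_is_repeat(self, rng):
        seed = random_seq(rng, 30)
        ref = seed + seed[:15]  # cyclic structure in the kmer graph
        cg = self._cg([make_read(seq=ref, qname="r")], random_seq(rng, 20), 11)
        assert cg.has_cycle()
        assert has_repeats(random_seq(rng, 20), cg, 11)


class TestAssembleWindow:
    def _window(self, ref):
        return Window("chr1", 0, len(ref), ref)

    def test_clean_window_first_k(self, rng):
        # find a reference whose repeat-free minimum is k=11
        from microcall._dna import min_odd_repeat_free_k

        while True:
            ref = random_seq(rng, 200)
            if min_odd_repeat_free_k(ref, 11, 101) == 11:
                break
        reads = [
            make_read(seq=ref[i : i + 100], start=i, qname=f"r{i}")
            for i in range(0, 101, 10)
        ]
        res = assemble_window(reads, [], self._window(ref))
        assert res.status == "ok"
        assert res.k == 11

    def test_tandem_duplication_escalates_k(self, rng):
        from microcall._dna import min_odd_repeat_free_k

        left = random_seq(rng, 250)
        unit = random_seq(rng, 30)
        right = random_seq(rng, 250)
        ref = left + unit + unit + right
        kmin_brute = min_odd_repeat_free_k(ref, 11, 101)
        assert kmin_brute is not None and kmin_brute > 31
        reads = [
            make_read(seq=ref[i : i + 150], start=i, qname=f"r{i}")
            for i in range(0, len(ref) - 150, 25)
        ]
        res = assemble_window(reads, [], self._window(ref))
        assert res.status == "ok"
        assert res.k >= kmin_brute
        assert res.k % 2 == 1 and 11 <= res.k <= 101

    def test_all_a_window_skipped(self):
        ref = "A" * 300
        res = assemble_window([], [], self._window(ref))
        assert res.status == "skipped-repeat"
        assert res.k == 101

    def test_short_reads_contribute_nothing(self, rng):
        ref = random_seq(rng, 200)
        reads = [make_read(seq=ref[:9], qname="tiny")]  # shorter than k
        res = assemble_window(reads, [], self._window(ref))
        # assembles from the reference alone
        if res.status == "ok":
            assert all(sn.tumor == 0 for sn in res.graph.snodes.values())
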