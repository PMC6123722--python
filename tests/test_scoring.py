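"""Fisher's exact test scoring, STR annotation, filters and VCF output."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact

from microcall.align import AlleleCounts, RawVariant
from microcall.scoring import (
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


def exact_fet_pvalue(tr, ta, nr, na) -> Fraction:
    """Independent oracle: exact rational two-sided hypergeometric p-value."""
    m1, m2, n = tr + ta, nr + na, ta + na
    N = m1 + m2
    if N == 0:
        return Fraction(1)
    denom = math.comb(N, n)
    obs = Fraction(math.comb(m1, ta) * math.comb(m2, na), denom)
    p = Fraction(0)
    for a in range(max(0, n - m2), min(n, m1) + 1):
        q = Fraction(math.comb(m1, a) * math.comb(m2, n - a), denom)
        if q <= obs:
            p += q
    return min(p, Fraction(1))


def oracle_score(tr, ta, nr, na) -> float:
    p = exact_fet_pvalue(tr, ta, nr, na)
    return 0.0 if p == 1 else -10.0 * math.log10(float(p))


class TestFetScore:
    def test_balanced_table_scores_zero(self):
        assert fet_score(ContingencyTable(10, 0, 10, 0)) == 0.0

    def test_known_table_against_enumeration_oracle(self):
        # (5,5,10,0): p = 504/15504 by direct enumeration
        got = fet_score(ContingencyTable(5, 5, 10, 0))
        assert got == pytest.approx(oracle_score(5, 5, 10, 0), rel=1e-12)
        assert got == pytest.approx(14.8801322, abs=1e-6)

    def test_symmetric_in_rows(self):
        a = fet_score(ContingencyTable(12, 7, 30, 1))
        b = fet_score(ContingencyTable(30, 1, 12, 7))
        assert a == pytest.approx(b, rel=1e-12)

    def test_all_zero_table(self):
        assert fet_score(ContingencyTable(0, 0, 0, 0)) == 0.0

    def test_random_tables_match_scipy(self, rng):
        for _ in range(100):
            tr, ta, nr, na = (int(x) for x in rng.integers(0, 40, 4))
            got = fet_score(ContingencyTable(tr, ta, nr, na))
            p = fisher_exact([[tr, ta], [nr, na]])[1]
            expect = 0.0 if p >= 1 else -10 * math.log10(p)
            assert got == pytest.approx(expect, rel=1e-6, abs=1e-6)

    def test_monotone_in_tumor_alt_on_vaf_ladder(self):
        """Score grows with tumor alt count at fixed 80x/40x depths.

        The one-sided tail probability is strictly monotone. The two-sided
        p-value admits small discrete dips when the opposite-tail inclusion
        set changes (confirmed against scipy), so it is asserted monotone at
        lag 2.
        """
        two = [fet_score(ContingencyTable(80 - a, a, 40, 0)) for a in range(1, 41)]
        one = [
            fet_score(ContingencyTable(80 - a, a, 40, 0), two_sided=False)
            for a in range(1, 41)
        ]
        assert all(b > a for a, b in zip(one, one[1:]))
        assert all(two[i] > two[i - 2] for i in range(2, len(two)))

    def test_one_sided_leq_two_sided_complement(self):
        t = ContingencyTable(70, 10, 40, 0)
        one = fet_score(t, two_sided=False)
        two = fet_score(t)
        assert one >= two  # one-sided p is never larger here

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestFindStr:
    def test_homopolymer_seven(self):
        hits = find_str_intervals("GG" + "A" * 7 + "GG")
        assert any(m == "A" and e - s == 7 for s, e, m in hits)

    def test_six_bp_dinucleotide_not_flagged(self):
        assert not any(m == "AC" for _, _, m in find_str_intervals("TTACACACGG"))

    def test_eight_bp_dinucleotide_flagged(self):
        hits = find_str_intervals("TTACACACACGG")
        assert any(m == "AC" and e - s == 8 for s, e, m in hits)

    def test_partial_trailing_copy_counts(self):
        # ACACACA: 3.5 copies, 7 bp total
        hits = find_str_intervals("GGACACACAGG")
        assert any(m == "AC" and e - s == 7 for s, e, m in hits)


class TestFlagStr:
    def test_variant_inside_homopolymer(self):
        ctx = "GGCT" + "A" * 7 + "TCGG"
        v = RawVariant("chr1", 1006, "A", "T", "SNV")
        flag = flag_str(ctx, 1000, v)
        assert flag is not None and flag.startswith("A:")

    def test_variant_adjacent_within_proximity(self):
        ctx = "TTGCA" + "ACACACAC" + "GTTGC"
        # variant one bp left of the STR start (STR starts at offset 5)
        v = RawVariant("chr1", 2004, ctx[4], "T", "SNV")
        assert flag_str(ctx, 2000, v) == "AC:4"

    def test_far_variant_not_flagged(self):
        ctx = "TTGC" + "ACACACAC" + "GTCGATTGCC"
        v = RawVariant("chr1", 3018, ctx[18], "T", "SNV")
        assert flag_str(ctx, 3000, v) is None

    def test_short_tract_not_flagged(self):
        ctx = "TTGCGACACACGTTGAC"  # ACACAC is only 6 bp
        v = RawVariant("chr1", 8, ctx[8], "T", "SNV")
        assert flag_str(ctx, 0, v) is None


class TestClassify:
    def _v(self):
        return RawVariant("chr1", 10, "A", "G", "SNV")

    def test_clean_somatic(self):
        c = AlleleCounts(alt_t=10, ref_t=70, alt_n=0, ref_n=40)
        assert classify(self._v(), c) == "SOMATIC"

    def test_shared_is_not_somatic(self):
        c = AlleleCounts(alt_t=10, ref_t=70, alt_n=5, ref_n=35)
        assert classify(self._v(), c) in ("GERMLINE", "SHARED")

    def test_contaminated_normal_allowance(self):
        c = AlleleCounts(alt_t=10, ref_t=70, alt_n=1, ref_n=39)
        assert classify(self._v(), c) != "SOMATIC"
        assert classify(self._v(), c, max_alt_normal=2, max_vaf_normal=0.05) == "SOMATIC"

    def test_normal_only(self):
        c = AlleleCounts(alt_t=0, ref_t=80, alt_n=6, ref_n=34)
        assert classify(self._v(), c) == "NORMAL_ONLY"


def _call(counts, fet, str_flag=None):
    v = RawVariant("chr1", 100, "A", "G", "SNV")
    return VariantCall(variant=v, counts=counts, fet=fet, kmer_size=11, str_flag=str_flag)


def run_filter_truth_table() -> int:
    """Exercise the full filter stack over a 64-combination grid.

    Expected filter-name sets are derived independently from the documented
    default thresholds, including the STR-specific FET cutoff (25 vs 5).
    Returns the number of combinations checked.
    """
    th = FilterThresholds()
    cases = [
        (depth_n, alt_t, fet, alt_n, split, is_str)
        for depth_n in (8, 40)
        for alt_t in (2, 20)
        for fet in (3.0, 60.0)
        for alt_n in (0, 1)
        for split in (True, False)
        for is_str in (True, False)
    ]
    assert len(cases) == 64
    for depth_n, alt_t, fet, alt_n, split, is_str in cases:
        ref_t = 80 - alt_t
        c = AlleleCounts(
            alt_t=alt_t,
            alt_tf=alt_t // 2 if split else alt_t,
            alt_tr=alt_t - alt_t // 2 if split else 0,
            ref_t=ref_t,
            alt_n=alt_n,
            ref_n=depth_n - alt_n,
        )
        expected = set()
        if depth_n < 10:
            expected.add("LowCovNormal")
        if alt_t + ref_t < 4:
            expected.add("LowCovTumor")
        if alt_t / (alt_t + ref_t) < 0.04:
            expected.add("LowVafTumor")
        if alt_n / depth_n > 0.0:
            expected.add("HighVafNormal")
        if alt_t < 3:
            expected.add("LowAltCntTumor")
        if alt_n > 0:
            expected.add("HighAltCntNormal")
        if fet < (25.0 if is_str else 5.0):
            expected.add("LowFetScore")
        if not split or alt_t // 2 < 1:
            expected.add("StrandBias")
        got = apply_filters(_call(c, fet, "A:8" if is_str else None), th)
        assert got == expected, (depth_n, alt_t, fet, alt_n, split, is_str)
    return len(cases)


class TestApplyFilters:
    def test_clean_pass(self):
        c = AlleleCounts(alt_t=20, alt_tf=10, alt_tr=10, ref_t=60, ref_n=40)
        assert apply_filters(_call(c, 60.0)) == set()

    def test_low_alt_count(self):
        c = AlleleCounts(alt_t=2, alt_tf=1, alt_tr=1, ref_t=78, ref_n=40)
        assert "LowAltCntTumor" in apply_filters(_call(c, 60.0))

    def test_str_specific_fet_threshold(self):
        c = AlleleCounts(alt_t=20, alt_tf=10, alt_tr=10, ref_t=60, ref_n=40)
        assert apply_filters(_call(c, 10.0, str_flag="A:8")) == {"LowFetScore"}
        assert apply_filters(_call(c, 10.0, str_flag=None)) == set()
        assert apply_filters(_call(c, 30.0, str_flag="A:8")) == set()

    def test_strand_bias_toggle(self):
        c = AlleleCounts(alt_t=20, alt_tf=20, alt_tr=0, ref_t=60, ref_n=40)
        assert "StrandBias" in apply_filters(_call(c, 60.0))
        assert "StrandBias" not in apply_filters(_call(c, 60.0), strand_bias_on=False)

    def test_truth_table_over_threshold_grid(self):
        """64 count/score combinations hit exactly the expected filter sets."""
        run_filter_truth_table()


class TestWriteVcf:
    def _calls(self):
        v1 = RawVariant("chr1", 99, "A", "G", "SNV")
        c1 = VariantCall(
            variant=v1,
            counts=AlleleCounts(alt_t=20, alt_tf=10, alt_tr=10, ref_t=60, ref_n=40),
            fet=48.65,
            kmer_size=13,
            status="SOMATIC",
        )
        v2 = RawVariant("chr1", 200, "CT", "C", "DEL")
        c2 = VariantCall(
            variant=v2,
            counts=AlleleCounts(alt_t=2, ref_t=78, alt_n=1, ref_n=39),
            fet=1.2,
            kmer_size=13,
            str_flag="T:5",
            status="SHARED",
            filters={"LowAltCntTumor", "HighAltCntNormal", "LowFetScore"},
        )
        return [c1, c2]

    def test_empty_callset_header_only(self):
        text = write_vcf([], contigs={"chr1": 1000})
        body = [l for l in text.splitlines() if not l.startswith("#")]
        assert body == []
        assert text.startswith("##fileformat=VCFv4.1")

    def test_unsorted_input_rejected(self):
        calls = list(reversed(self._calls()))
        with pytest.raises(ValueError):
            write_vcf(calls, contigs={"chr1": 1000})

    def test_roundtrip_through_pysam(self, tmp_path):
        import pysam

        text = write_vcf(self._calls(), contigs={"chr1": 1000})
        path = tmp_path / "out.vcf"
        path.write_text(text)
        recs = list(pysam.VariantFile(str(path)))
        assert len(recs) == 2
        r1, r2 = recs
        assert (r1.chrom, r1.pos, r1.ref, r1.alts) == ("chr1", 100, "A", ("G",))
        assert "SOMATIC" in r1.info
        assert list(r1.filter) == ["PASS"]
        assert r1.qual == pytest.approx(48.65, abs=0.01)
        assert r1.info["KMERSIZE"] == 13
        assert set(r2.filter) == {"LowAltCntTumor", "HighAltCntNormal", "LowFetScore"}
        assert r2.info["MS"] == "T:5"
        assert r1.samples["TUMOR"]["AD"] == (60, 20)
        assert r1.samples["NORMAL"]["AD"] == (40, 0)
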