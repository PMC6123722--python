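"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from microcall.sam_io import AlignedRead


def make_read(
    seq: str = "ACGTACGTACGT",
    start: int = 0,
    qname: str = "r1",
    chrom: str = "chr1",
    mapq: int = 60,
    cigar=None,
    md: str | None = None,
    mate: int = 0,
    quals=None,
    **flags,
) -> AlignedRead:
    cigar = cigar if cigar is not None else [("M", len(seq))]
    if quals is None:
        quals = np.full(len(seq), 37, dtype=np.int16)
    tags = flags.pop("tags", {})
    return AlignedRead(
        qname=qname,
        chrom=chrom,
        start=start,
        mapq=mapq,
        seq=seq,
        quals=quals,
        cigar=cigar,
        md=md,
        mate=mate,
        tags=tags,
        **flags,
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180322)


@pytest.fixture
def small_ref(rng) -> str:
    return random_seq(rng, 1200)
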