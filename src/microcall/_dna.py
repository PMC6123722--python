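"""Low-level DNA sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> 0..3 code; anything else -> 255
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def is_acgt(seq: str) -> bool:
    return _ACGT.issuperset(seq)


def encode(seq: str) -> np.ndarray:
    """2-bit-style encoding: A,C,G,T -> 0..3, other -> 255 (uint8 array)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def ref_near_repeat(seq: str, k: int, max_mm: int = 2) -> bool:
    """True iff two length-k substrings at distinct positions differ by <= max_mm.

    Vectorized over all position offsets d: mismatch counts between seq[i:i+k]
    and seq[i+d:i+d+k] are sliding-window sums of the per-base inequality.
    """
    n = len(seq)
    if n < k + 1:
        return False
    arr = encode(seq)
    for d in range(1, n - k + 1):
        diff = (arr[:-d] != arr[d:]).astype(np.int32)
        if diff.size < k:
            break
        c = np.cumsum(diff)
        win = c[k - 1 :].copy()
        win[1:] -= c[:-k]
        if (win <= max_mm).any():
            return True
    return False


def min_odd_repeat_free_k(seq: str, k_min: int, k_max: int, max_mm: int = 2) -> int | None:
    """Smallest odd k in [k_min, k_max] for which the sequence has no near repeat."""
    k = k_min if k_min % 2 == 1 else k_min + 1
    while k <= k_max:
        if not ref_near_repeat(seq, k, max_mm):
            return k
        k += 2
    return None


def kmers_near_repeat(kmers: list[str], max_mm: int = 2, chunk: int = 128) -> bool:
    """True iff any two k-mers in the list (distinct indices) are within
    Hamming distance max_mm. Identical k-mers at distinct indices count."""
    p = len(kmers)
    if p < 2:
        return False
    mat = np.stack([encode(s) for s in kmers])
    for lo in range(0, p, chunk):
        block = mat[lo : lo + chunk]
        ham = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
        rows, cols = np.indices(ham.shape)
        ham[rows + lo == cols] = mat.shape[1] + 1  # mask self comparisons
        if (ham <= max_mm).any():
            return True
    return False


def sliding_min(values: np.ndarray, k: int) -> np.ndarray:
    """Minimum over every length-k window of a 1-D array."""
    if len(values) < k:
        return np.empty(0, dtype=values.dtype)
    return np.lib.stride_tricks.sliding_window_view(values, k).min(axis=1)


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence offsets of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out
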