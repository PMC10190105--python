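"""64-bit k-mer hashing.

Canonical k-mers (k <= 32) are packed into a 64-bit integer with two bits
per base (A=0, C=1, G=2, T=3, most-significant base first) and passed
through the MurmurHash3 ``fmix64`` finalizer; the seed enters via one
splitmix64 round XORed into the packed value.  The finalizer is a bijection
on 64-bit words, so distinct k-mers of the same length never collide, and
its avalanche behaviour gives the uniformity that MinHash sampling needs.
The same arithmetic is exposed both as a scalar function and as a
vectorized numpy kernel; they are bit-identical by construction.
"""

from __future__ import annotations

import numpy as np

_MASK = (1 << 64) - 1

# MurmurHash3 fmix64 constants
_C1 = 0xFF51AFD7ED558CCD
_C2 = 0xC4CEB9FE1A85EC53

# splitmix64 constants
_GOLDEN = 0x9E3779B97F4A7C15
_S1 = 0xBF58476D1CE4E5B9
_S2 = 0x94D049BB133111EB

#: byte -> 2-bit code lookup; 255 marks non-ACGT characters
CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    CODE_TABLE[_b] = _i
    CODE_TABLE[_b + 32] = _i  # lowercase


def splitmix64(x: int) -> int:
    z = (x + _GOLDEN) & _MASK
    z = ((z ^ (z >> 30)) * _S1) & _MASK
    z = ((z ^ (z >> 27)) * _S2) & _MASK
    return z ^ (z >> 31)


def fmix64(x: int) -> int:
    x &= _MASK
    x = ((x ^ (x >> 33)) * _C1) & _MASK
    x = ((x ^ (x >> 33)) * _C2) & _MASK
    return x ^ (x >> 33)


def seed_salt(seed: int) -> int:
    """Per-seed 64-bit salt mixed into every packed k-mer."""
    return splitmix64(seed & _MASK)


def hash_packed(packed: int, seed: int) -> int:
    return fmix64(packed ^ seed_salt(seed))


def pack_kmer(kmer: str) -> int:
    """Pack an ACGT string (len <= 32) into a 64-bit integer."""
    if len(kmer) > 32:
        raise ValueError("k-mer hashing supports k <= 32, got k=%d" % len(kmer))
    v = 0
    for ch in kmer:
        c = int(CODE_TABLE[ord(ch) & 0xFF]) if ord(ch) < 256 else 255
        if c > 3:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer")
        v = (v << 2) | c
    return v


def hash_packed_array(packed: np.ndarray, seed: int) -> np.ndarray:
    """Vectorized fmix64 over a uint64 array (bit-identical to hash_packed)."""
    x = packed.astype(np.uint64, copy=True)
    x ^= np.uint64(seed_salt(seed))
    x ^= x >> np.uint64(33)
    x *= np.uint64(_C1)
    x ^= x >> np.uint64(33)
    x *= np.uint64(_C2)
    x ^= x >> np.uint64(33)
    return x


def packed_canonical_windows(seq: str | bytes, k: int) -> np.ndarray:
    """All canonical k-mer windows of ``seq`` as packed uint64 values.

    Windows containing a non-ACGT character are dropped.  The canonical
    form is the lexicographically smaller of the window and its reverse
    complement, which for the 2-bit big-endian packing coincides with the
    numerically smaller packed value.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 32:
        raise ValueError("k-mer hashing supports k <= 32, got k=%d" % k)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    codes = CODE_TABLE[np.frombuffer(seq, dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = codes > 3
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        valid = (cs[k:] - cs[:-k]) == 0
        codes = np.where(bad, 0, codes)
    else:
        valid = None
    c = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd <<= np.uint64(2)
        fwd |= c[j : j + n]
        rev |= (np.uint64(3) - c[j : j + n]) << np.uint64(2 * j)
    can = np.minimum(fwd, rev)
    if valid is not None:
        can = can[valid]
    return can
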