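"""Low-level sequence kernels shared across the package.

Sequences travel between modules as plain Python strings; performance-critical
code converts them once to 2-bit numpy arrays (A=0, C=1, G=2, T=3).  Because
the alphabet ordering matches lexicographic ordering of the letters, integer
comparison of packed k-mer codes is equivalent to string comparison, which is
what makes canonical k-mer selection cheap.
"""

from __future__ import annotations

import numpy as np

# byte -> 2-bit code; anything that is not ACGT (either case) maps to 255
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE_LUT[_b] = _i

_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A",
               "a": "t", "c": "g", "g": "c", "t": "a", "N": "N", "n": "n"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array of 2-bit codes (255 = non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(arr: np.ndarray) -> str:
    """Decode a 2-bit code array back to an upper-case DNA string."""
    if arr.size and arr.max() > 3:
        raise ValueError("cannot decode array containing non-ACGT codes")
    return _DECODE_LUT[arr].tobytes().decode("ascii")


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of a 2-bit code array (complement = 3 - code)."""
    return (3 - arr)[::-1]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform i.i.d. ACGT string of length n."""
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit codes of every k-mer window of a 1-D code array.

    Requires k <= 31 so the code fits a uint64.  The caller is responsible
    for masking windows that contain non-ACGT bases (see ``valid_windows``).
    """
    if k > 31:
        raise ValueError("k must be <= 31 for packed 64-bit k-mer codes")
    n = arr.shape[-1]
    m = n - k + 1
    if m <= 0:
        return np.empty(arr.shape[:-1] + (0,), dtype=np.uint64)
    a = np.where(arr > 3, 0, arr).astype(np.uint64)
    h = np.zeros(arr.shape[:-1] + (m,), dtype=np.uint64)
    for j in range(k):
        h = (h << np.uint64(2)) | a[..., j : j + m]
    return h


def valid_windows(arr: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of k-mer windows composed only of ACGT bases."""
    bad = (arr > 3).astype(np.int64)
    n = arr.shape[-1]
    m = n - k + 1
    if m <= 0:
        return np.empty(arr.shape[:-1] + (0,), dtype=bool)
    c = np.cumsum(bad, axis=-1)
    lead = c[..., k - 1 : n]
    prev = np.concatenate(
        [np.zeros(arr.shape[:-1] + (1,), dtype=np.int64), c[..., : n - k]], axis=-1
    )
    return (lead - prev) == 0


def canonical_kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Canonical (min of forward / reverse-complement) packed k-mer codes.

    Works on 1-D or 2-D (batch of equal-length sequences) code arrays.
    """
    fwd = kmer_codes(arr, k)
    comp_rev = (3 - np.where(arr > 3, np.uint8(0), arr))[..., ::-1]
    rc = kmer_codes(comp_rev, k)[..., ::-1]
    return np.minimum(fwd, rc)


def decode_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit k-mer code back to its string."""
    out = np.empty(k, dtype=np.uint8)
    c = int(code)
    for i in range(k - 1, -1, -1):
        out[i] = c & 3
        c >>= 2
    return decode(out)


def encode_kmer(kmer: str) -> int:
    arr = encode(kmer)
    if arr.size and arr.max() > 3:
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    code = 0
    for v in arr:
        code = (code << 2) | int(v)
    return code


def minimal_rotation(s: str) -> str:
    """Lexicographically minimal rotation of s (Booth's algorithm)."""
    if not s:
        return s
    t = s + s
    n = len(t)
    f = [-1] * n
    kmin = 0
    for j in range(1, n):
        sj = t[j]
        i = f[j - kmin - 1]
        while i != -1 and sj != t[kmin + i + 1]:
            if sj < t[kmin + i + 1]:
                kmin = j - i - 1
            i = f[i]
        if sj != t[kmin + i + 1]:
            if sj < t[kmin]:
                kmin = j
            f[j - kmin] = -1
        else:
            f[j - kmin] = i + 1
    return t[kmin : kmin + len(s)]


def canonical_rotation(s: str) -> str:
    """Minimal rotation over both strands: identity of a circular unit."""
    if not s:
        return s
    return min(minimal_rotation(s), minimal_rotation(revcomp(s)))


def minimal_period(s: str) -> int:
    """Smallest p such that s is (s[:p]) repeated; len(s) if aperiodic."""
    n = len(s)
    if n == 0:
        return 0
    p = (s + s).find(s, 1)
    if p != -1 and n % p == 0:
        return p
    return n


def minimal_cyclic_period(s: str) -> int:
    """Smallest divisor p of len(s) such that rotating s by p is a no-op."""
    n = len(s)
    for p in range(1, n + 1):
        if n % p == 0 and s[p:] + s[:p] == s:
            return p
    return n
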