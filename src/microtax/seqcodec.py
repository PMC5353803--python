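"""Nucleotide integer encoding and K-mer index enumeration/counting.

Sequences are mapped to integer vectors (A=0, C=1, G=2, T/U=3; anything
else, including IUPAC ambiguity codes, becomes a large negative sentinel).
K-mer indices are computed by sliding a window of length K along the
integer vector and taking the inner product with [4^(K-1), ..., 4, 1]; any
window touching a sentinel yields a negative inner product and is
discarded.  This keeps the counting logic branch-free and is exact for
K <= 15 because the sentinel magnitude (4^15) dominates any positive
contribution of the remaining window positions.
"""

from __future__ import annotations

import numpy as np

#: Sentinel for non-ACGTU symbols: -4**15.  Any window containing it has a
#: negative inner product for K <= 15.
SENTINEL: int = -(4**15)

#: Largest supported word length.  The sentinel trick is valid to K=15 but
#: 4^K columns become impractical well before that; 4^12 ~ 1.7e7.
K_MAX: int = 12

_LUT = np.full(256, SENTINEL, dtype=np.int64)
for _i, _ch in enumerate("ACGT"):
    _LUT[ord(_ch)] = _i
    _LUT[ord(_ch.lower())] = _i
_LUT[ord("U")] = 3
_LUT[ord("u")] = 3


def encode_sequence(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string as an int64 vector.

    A/C/G/T (or U) map to 0..3, case-insensitively; every other character
    maps to the sentinel ``-4**15``.  Output length equals input length.

    Raises
    ------
    ValueError
        If `seq` is empty.
    """
    if isinstance(seq, str):
        seq = seq.encode("ascii", errors="replace")
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    raw = np.frombuffer(seq, dtype=np.uint8)
    return _LUT[raw]


def decode_sequence(values: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` for valid bases; sentinel -> 'N'."""
    values = np.asarray(values)
    out = np.full(values.shape, ord("N"), dtype=np.uint8)
    valid = (values >= 0) & (values <= 3)
    out[valid] = np.frombuffer(b"ACGT", dtype=np.uint8)[values[valid]]
    return out.tobytes().decode("ascii")


def reverse_complement(enc: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded sequence; sentinels stay sentinels."""
    valid = (enc >= 0) & (enc <= 3)
    rc = np.where(valid, 3 - enc, SENTINEL)
    return rc[::-1].copy()


def _check_k(k: int) -> None:
    if not (1 <= int(k) <= K_MAX):
        raise ValueError(f"word length K must be in [1, {K_MAX}], got {k}")


def kmer_weights(k: int) -> np.ndarray:
    """Positional weights [4^(K-1), ..., 4, 1] used for the inner product."""
    _check_k(k)
    return 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)


def kmer_indices(enc: np.ndarray, k: int) -> np.ndarray:
    """Indices in [0, 4^K) of all valid K-mer windows, in sequence order.

    Windows containing any sentinel produce a negative inner product and
    are dropped.  A sequence shorter than K yields an empty vector.
    """
    _check_k(k)
    enc = np.asarray(enc, dtype=np.int64)
    if enc.size == 0:
        raise ValueError("empty encoded sequence")
    if enc.size < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    idx = windows @ kmer_weights(k)
    return idx[idx >= 0]


def count_kmers(enc: np.ndarray, k: int) -> np.ndarray:
    """Counting vector of length 4^K; entry j = occurrences of K-mer j."""
    idx = kmer_indices(enc, k)
    return np.bincount(idx, minlength=4**k).astype(np.int64)
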