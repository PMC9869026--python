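"""Vectorised 2-bit k-mer encoding, canonicalisation and 64-bit hashing.

All genome-scale k-mer work in the package (MinHash sketches, ANI seeding,
minimizer read assignment, 16S anchor scanning) goes through these helpers.
Sequences are ASCII ACGT strings; k-mers are packed into uint64 codes
(2 bits/base, k <= 31) and hashed with the splitmix64 finalizer, which is
deterministic across platforms.
"""

from __future__ import annotations

import numpy as np

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 array in {0..3}; non-ACGT bases map to 255."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit codes of all k-mers of an encoded sequence.

    k-mers containing non-ACGT bases are masked to the sentinel value
    2**64 - 1 (never a valid code for k <= 31).
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = arr > 3
    a = np.where(bad, 0, arr).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | a[j : j + n]
    if bad.any():
        # flag any window overlapping a bad base
        bad_win = np.convolve(bad.astype(np.int8), np.ones(k, dtype=np.int8))[
            k - 1 : k - 1 + n
        ]
        codes[bad_win > 0] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return codes


def canonical_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-collapsed) codes: elementwise min(fwd, revcomp)."""
    fwd = kmer_codes(arr, k)
    rc_arr = (3 - arr) % np.uint8(4)
    rc_arr[arr > 3] = 255
    rev = kmer_codes(rc_arr[::-1], k)[::-1]
    return np.minimum(fwd, rev)


def splitmix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer; uint64 wrap-around arithmetic is intended."""
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x += np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
    return x


def canonical_kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Hashes of all valid canonical k-mers of a sequence (with duplicates)."""
    codes = canonical_codes(encode(seq), k)
    codes = codes[codes != np.uint64(0xFFFFFFFFFFFFFFFF)]
    return splitmix64(codes)


def minimizers(seq: str, k: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """(w,k)-minimizers of a sequence.

    Returns (hash values, start positions) of the minimum-hash k-mer in every
    window of w consecutive k-mers, deduplicated by position.
    """
    codes = canonical_codes(encode(seq), k)
    valid = codes != np.uint64(0xFFFFFFFFFFFFFFFF)
    h = splitmix64(codes)
    h[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)
    if h.size < w:
        if not valid.any():
            return np.empty(0, np.uint64), np.empty(0, np.int64)
        pos = np.array([int(np.argmin(h))], dtype=np.int64)
        return h[pos], pos
    win = np.lib.stride_tricks.sliding_window_view(h, w)
    rel = np.argmin(win, axis=1)
    pos = rel + np.arange(win.shape[0])
    keep = np.ones(pos.size, dtype=bool)
    keep[1:] = pos[1:] != pos[:-1]
    pos = np.unique(pos[keep])
    sel = valid[pos]
    pos = pos[sel]
    return h[pos], pos.astype(np.int64)
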