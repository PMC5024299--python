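"""2-bit DNA encoding shared across modules.

Bases map A=0, C=1, G=2, T=3; a k-mer is the big-endian base-4 integer of
its digits, so code space is ``range(4**k)`` and lexicographic order of
k-mer strings equals numeric order of codes.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def is_dna(s: str) -> bool:
    """True if ``s`` is non-empty and contains only A/C/G/T (case-insensitive)."""
    return len(s) > 0 and all(c in "ACGTacgt" for c in s)


def encode_seq(s: str) -> np.ndarray:
    """Encode one sequence to a uint8 vector of 2-bit base codes."""
    arr = _LUT[np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = s[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def encode_seqs(seqs, length: int | None = None) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, length or 0), dtype=np.uint8)
    L = len(seqs[0]) if length is None else length
    out = np.empty((len(seqs), L), dtype=np.uint8)
    for i, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError(f"sequence {i} has length {len(s)}, expected {L}")
        out[i] = encode_seq(s)
    return out


def decode(arr: np.ndarray) -> str:
    return "".join(BASES[int(b)] for b in arr)


def kmer_to_code(kmer: str) -> int:
    code = 0
    for c in kmer.upper():
        code = code * 4 + BASES.index(c)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s.upper()))


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement on k-mer codes."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = out * 4 + (3 - (tmp & 3))
        tmp >>= 2
    return out


def window_codes(matrix: np.ndarray, k: int) -> np.ndarray:
    """Codes of all overlapping k-windows, one row per input sequence.

    ``matrix`` is an (n, L) uint8 base matrix; returns (n, L - k + 1) int64.
    """
    if matrix.shape[1] < k:
        raise ValueError(f"k={k} exceeds sequence length {matrix.shape[1]}")
    windows = np.lib.stride_tricks.sliding_window_view(matrix, k, axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows.astype(np.int64) @ powers
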