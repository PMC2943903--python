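"""Shared sequence utilities: alphabet handling and integer encoding.

Bases are encoded A=0, C=1, G=2, T=3, N=4 throughout; k-mers over {A,C,G,T}
are packed into base-4 integers (lexicographic order, A < C < G < T).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
ACGT = "ACGT"
N_CODE = 4

# Any byte that is not an uppercase/lowercase ACGT maps to N (code 4);
# IUPAC ambiguity codes other than N are deliberately collapsed to N.
_ENCODE = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(ACGT):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.int8)].tobytes().decode("ascii")


def sanitize(seq: str) -> str:
    """Uppercase a sequence and map non-ACGTN characters to N."""
    return decode(encode(seq))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_to_index(kmer: str) -> int:
    """Pack a k-mer over {A,C,G,T} into a base-4 integer."""
    idx = 0
    for ch in kmer:
        code = "ACGT".find(ch)
        if code < 0:
            raise ValueError(f"k-mer {kmer!r} contains non-ACGT character")
        idx = idx * 4 + code
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(ACGT[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    return [index_to_kmer(i, k) for i in range(4**k)]


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all length-k windows of a code array.

    Returns (window_index, valid) where ``valid`` is False for windows
    containing an N. Invalid windows carry an unspecified index.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = c[j : j + n]
        valid &= col != N_CODE
        idx = idx * 4 + np.where(col == N_CODE, 0, col)
    return idx, valid
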