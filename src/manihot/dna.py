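"""Encoded DNA sequences and k-mer machinery.

Sequences are held as ``numpy.uint8`` arrays with A=0, C=1, G=2, T=3 and
N=4.  All heavy per-base work (k-mer codes, reverse complements, read
extraction) is vectorised on these arrays; plain Python strings appear only
at I/O boundaries.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_ALPHABET = np.frombuffer(b"ACGTN", dtype=np.uint8)

# byte -> code lookup (unknown characters map to N)
_DECODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _DECODE_LUT[_b] = _i
for _i, _b in enumerate(b"acgtn"):
    _DECODE_LUT[_b] = _i

# complement: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _DECODE_LUT[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 code array back into an upper-case DNA string."""
    return _ALPHABET[arr].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence."""
    return _COMP[arr][::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random A/C/G/T sequence."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes of every k-mer of ``arr``.

    Returns ``(codes, valid)`` where ``codes`` has length ``len(arr)-k+1``
    and ``valid`` is False for windows containing N.  Requires ``k <= 31``
    so codes fit in uint64.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    a = arr.astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes <<= np.uint64(2)
        # N (4) would corrupt the code; mask below removes those windows
        codes |= a[j : j + n] & np.uint64(3)
    isn = arr >= 4
    if isn.any():
        bad = np.convolve(isn.astype(np.int32), np.ones(k, dtype=np.int32))[
            k - 1 : k - 1 + n
        ]
        valid = bad == 0
    else:
        valid = np.ones(n, dtype=bool)
    return codes, valid


# 256-entry LUT reversing the order of the four 2-bit bases within a byte
_REV_BYTE = np.empty(256, dtype=np.uint8)
for _b in range(256):
    _REV_BYTE[_b] = (
        ((_b & 0x03) << 6) | ((_b & 0x0C) << 2) | ((_b & 0x30) >> 2) | ((_b & 0xC0) >> 6)
    )


def revcomp_code(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes, vectorised.

    Complements the 2k low bits (A<->T, C<->G are bitwise complements under
    this coding), then reverses base order via byteswap plus a per-byte
    base-reversal lookup — a handful of linear passes instead of a 2k-step
    shift loop.
    """
    mask = np.uint64((1 << (2 * k)) - 1) if k < 32 else np.uint64(0xFFFFFFFFFFFFFFFF)
    x = (~codes) & mask
    x = (x << np.uint64(64 - 2 * k)).byteswap()
    b = _REV_BYTE[x.view(np.uint8)]
    return b.view(np.uint64)


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic minimum of each k-mer code and its reverse complement."""
    rc = revcomp_code(codes, k)
    return np.minimum(codes, rc)


def row_kmer_code(rows: np.ndarray, offset: int, k: int) -> np.ndarray:
    """Packed k-mer code at a fixed column offset of a 2-D read array."""
    n = rows.shape[0]
    codes = np.zeros(n, dtype=np.uint64)
    sub = rows[:, offset : offset + k].astype(np.uint64)
    for j in range(k):
        codes <<= np.uint64(2)
        codes |= sub[:, j] & np.uint64(3)
    return codes


def revcomp_rows(rows: np.ndarray) -> np.ndarray:
    """Reverse complement each row of a 2-D encoded read array."""
    return _COMP[rows][:, ::-1]


# --- codon / translation helpers -------------------------------------------

BASES = "ACGT"

CODON_TABLE: dict[str, str] = {}
_AA = (
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLLEDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
)
for _i in range(64):
    _codon = BASES[(_i >> 4) & 3] + BASES[(_i >> 2) & 3] + BASES[_i & 3]
    CODON_TABLE[_codon] = _AA[_i]

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))
START_CODON = "ATG"


def translate(cds: str) -> str:
    """Translate an in-frame CDS (no ambiguity codes) to protein."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))
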