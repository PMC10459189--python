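"""Two-bit base encoding shared by the simulator, aligner and k-mer counter.

Bases A, C, G, T are coded 0..3 so that complement(x) == 3 - x; any other
character (N and IUPAC ambiguity codes) maps to code 4 and never matches a
reference base.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
N_CODE = np.uint8(4)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence into a uint8 code array (A=0, C=1, G=2, T=3, other=4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    joined = "".join(seqs).encode("ascii")
    arr = _ENCODE[np.frombuffer(joined, dtype=np.uint8)]
    if arr.size != len(seqs) * length:
        raise ValueError("sequences are not all the same length")
    return arr.reshape(len(seqs), length)


def decode_matrix(codes: np.ndarray) -> list[str]:
    """Decode an (n, L) code matrix back to a list of strings."""
    chars = _DECODE[codes]
    return [row.tobytes().decode("ascii") for row in chars]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, codes).astype(np.uint8)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis."""
    return complement_codes(codes)[..., ::-1]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every length-k window of a 1-D code array into a uint64.

    Windows containing non-ACGT codes produce meaningless values; callers
    must mask them out (see :func:`window_has_n`).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= c[j : j + n] & np.uint64(3)
    return out


def window_has_n(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over length-k windows that contain a non-ACGT code."""
    is_n = (codes >= 4).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(is_n)])
    return (cum[k:] - cum[: codes.size - k + 1]) > 0
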