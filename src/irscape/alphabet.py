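"""Nucleotide encoding shared across the package.

Chromosome sequences are held as ``uint8`` code arrays (A=0, C=1, G=2, T=3,
N=4) so genome-scale scans and shuffles stay vectorised.  ``N`` never pairs
with anything: its complement code is a sentinel outside the alphabet.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: Watson-Crick partner of each code; N (4) maps to 255 so it never matches.
COMPLEMENT = np.array([T, G, C, A, 255], dtype=np.uint8)

_CHARS = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array.

    Raises ``ValueError`` on any character outside {A,C,G,T,N} (case
    insensitive) — the usual symptom of a malformed FASTA.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = sorted({chr(b) for b in raw[codes == 255]})
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _CHARS[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N stays N)."""
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = COMPLEMENT[codes[::-1]]
    out[out == 255] = N  # restore N instead of the non-pairing sentinel
    return out
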