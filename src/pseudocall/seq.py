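"""Nucleotide-sequence helpers shared across the toolkit.

Sequences travel as plain upper-case strings at module boundaries and as
``uint8`` code arrays (A=0, C=1, G=2, T=3, anything else=4) in numeric hot
paths.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a nucleotide string."""
    return _DEC[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-random nucleotide string of the given length."""
    if length < 0:
        raise ValueError("length must be non-negative")
    return decode(rng.integers(0, 4, length, dtype=np.uint8))


def gc_content(seq: str) -> float:
    arr = encode(seq)
    if arr.size == 0:
        return 0.0
    return float(np.count_nonzero((arr == 1) | (arr == 2))) / arr.size
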