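"""Low-level DNA string helpers shared across the package.

Sequences are plain upper-case strings over the alphabet ACGTN. All
coordinate systems used elsewhere (1-based repeat coordinates, 0-based
alignment offsets) are documented at the point of use; this module is
coordinate-free.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def validate_dna(seq: str, allow_n: bool = True) -> str:
    """Upper-case *seq* and reject characters outside ACGT(N)."""
    seq = seq.upper()
    allowed = set(DNA_ALPHABET) | ({"N"} if allow_n else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-DNA symbols in sequence: {sorted(bad)}")
    return seq


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of *length* drawn from *rng*."""
    idx = rng.integers(0, 4, size=length)
    lut = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    return lut[idx].tobytes().decode()


def encode(seq: str) -> np.ndarray:
    """Byte-encode a DNA string for vectorised comparison."""
    return np.frombuffer(seq.encode(), dtype=np.uint8)
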