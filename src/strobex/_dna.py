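"""Low-level DNA string/array helpers shared across the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: byte -> 2-bit code; 255 marks an ambiguous/non-ACGT byte
ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    ENCODE[ord(_b)] = _i
    ENCODE[ord(_b.lower())] = _i

BASES = "ACGT"


class AmbiguousBaseError(ValueError):
    """A sequence contained a non-ACGT character where one is not allowed."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit codes for *seq* (255 for ambiguous bases)."""
    return ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_packed(value: int, length: int) -> str:
    """Expand a 2-bit packed integer back into a DNA string of *length* bases."""
    out = []
    for shift in range(2 * (length - 1), -2, -2):
        out.append(BASES[(value >> shift) & 3])
    return "".join(out)
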