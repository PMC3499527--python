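"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# uint8 lookup: A/C/G/T -> 0..3, everything else (N, *, gaps, lower case is
# upper-cased before use) -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0,C=1,G=2,T=3, other=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """A<->G and C<->T are transitions; all other base pairs transversions."""
    return {a, b} in ({"A", "G"}, {"C", "T"})


def transversion_partners(base: str) -> tuple[str, str]:
    """The two transversion substitutions of a base, in a fixed order."""
    return {
        "A": ("C", "T"),
        "C": ("A", "G"),
        "G": ("T", "C"),
        "T": ("G", "A"),
    }[base]
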