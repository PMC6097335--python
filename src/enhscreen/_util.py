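"""Small shared helpers: sequence alphabet handling and validation."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: index of each base in PWM rows; anything else maps to 4 ("ambiguous")
_BASE_INDEX = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N and case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode DNA into integer indices A=0 C=1 G=2 T=3, ambiguous=4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_INDEX[raw]


def check_dna(seq: str, name: str = "sequence") -> None:
    if not seq or any(c not in "ACGT" for c in seq.upper()):
        raise ValueError(f"{name} must be a non-empty string over A/C/G/T, got {seq!r}")
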