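"""Small DNA helpers shared across modules.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3, N=4; any other byte
also maps to 4 so ambiguity codes behave like N during alignment.
"""
from __future__ import annotations

import numpy as np

N_CODE = 4

_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0..T=3, everything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
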