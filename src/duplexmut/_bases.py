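"""Byte-level base encoding shared across the package.

Sequences are held as ``numpy.uint8`` arrays of ASCII codes. Two sentinel
codes extend the A/C/G/T alphabet:

* ``N`` (78) — no observation / masked base,
* ``CONFLICT`` (``'?'``, 63) — the two mates of one read pair overlapped and
  disagreed; unlike ``N`` this observation vetoes any consensus base.

``CONFLICT`` sorts below 'A', which the vectorised consensus exploits.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 65, 67, 71, 84
N = 78
CONFLICT = 63  # '?'

BASES = "ACGT"
BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

# code -> 0..3 index; 255 for anything else
BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(BASE_CODES):
    BASE_INDEX[_c] = _i

COMPLEMENT = np.arange(256, dtype=np.uint8)
for _x, _y in ((A, T), (C, G)):
    COMPLEMENT[_x], COMPLEMENT[_y] = _y, _x
# N and CONFLICT are their own complements (identity already)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMP_STR = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """ASCII-encode a base string to a uint8 array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def complement(arr: np.ndarray) -> np.ndarray:
    return COMPLEMENT[arr]


def comp_base(b: str) -> str:
    return _COMP_STR[b]


def revcomp(seq: str) -> str:
    return "".join(_COMP_STR[b] for b in reversed(seq))
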