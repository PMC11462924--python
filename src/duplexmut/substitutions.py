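"""Substitution classes, strand folding, and the 96-channel convention.

Single-base substitutions are reported at three resolutions:

* 12 strand-resolved types ``"C>G"``, ``"G>C"``, ... — the raw reference-
  strand observation, kept for asymmetry diagnostics (some platforms miscall
  C→G far more often than G→C);
* 6 base-pair classes ``"G:C>T:A"`` etc. — the strand-folded convention of
  mutagenesis reporting, where G→T and C→A are the same duplex event;
* 96 trinucleotide channels — pyrimidine-centred substitutions (C or T)
  stratified by the 5' and 3' flanking reference bases, in COSMIC order:
  substitution blocks C>A, C>G, C>T, T>A, T>C, T>G, contexts within a block
  sorted alphabetically by (5' flank, 3' flank).

The module also precomputes lookup tables used by the vectorised simulator
and caller: ``CHANNEL_TABLE[code64, alt_index]`` maps a reference
trinucleotide (two-bit encoded, 0..63) plus alternate base to its channel,
and ``TRINUC_FOLD[code64]`` maps a trinucleotide to its pyrimidine-centred
index (0..31) used for frequency denominators.
"""

from __future__ import annotations

import itertools

import numpy as np

from ._bases import BASES, comp_base

__all__ = [
    "CLASSES",
    "STRAND_TYPES",
    "SUBSTITUTIONS",
    "CONTEXTS",
    "CHANNELS",
    "TRINUC32",
    "class_of",
    "strand_type",
    "fold_strand_type",
    "channel_index",
    "channel_label",
    "CHANNEL_TABLE",
    "TRINUC_FOLD",
    "CHANNEL_TRINUC",
    "class_rate_matrix",
]

#: strand-folded base-pair classes, in the customary reporting order
CLASSES = (
    "G:C>T:A",
    "G:C>C:G",
    "G:C>A:T",
    "A:T>T:A",
    "A:T>C:G",
    "A:T>G:C",
)

#: pyrimidine-centred substitution blocks of the 96-channel convention
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 16 flank contexts per block, alphabetical by (5', 3')
CONTEXTS = tuple(f"{l}_{r}" for l in BASES for r in BASES)

#: the 96 channel labels in COSMIC style, e.g. "A[C>A]A"
CHANNELS = tuple(
    f"{l}[{sub}]{r}"
    for sub in SUBSTITUTIONS
    for l in BASES
    for r in BASES
)

#: 32 pyrimidine-centred reference trinucleotides (denominator bins)
TRINUC32 = tuple(
    f"{l}{c}{r}" for c in "CT" for l in BASES for r in BASES
)

#: the 12 strand-resolved substitution types
STRAND_TYPES = tuple(
    f"{a}>{b}" for a, b in itertools.permutations(BASES, 2)
)

# pyrimidine-centred representation of each (ref, alt) pair
_PYR_FOLD: dict[tuple[str, str], tuple[str, str]] = {}
for _ref, _alt in itertools.permutations(BASES, 2):
    if _ref in "CT":
        _PYR_FOLD[(_ref, _alt)] = (_ref, _alt)
    else:
        _PYR_FOLD[(_ref, _alt)] = (comp_base(_ref), comp_base(_alt))

_CLASS_OF_SUB = {
    "C>A": "G:C>T:A",
    "C>G": "G:C>C:G",
    "C>T": "G:C>A:T",
    "T>A": "A:T>T:A",
    "T>G": "A:T>C:G",
    "T>C": "A:T>G:C",
}


def strand_type(ref: str, alt: str) -> str:
    """Raw reference-strand substitution label, e.g. ('G','T') -> 'G>T'."""
    if ref == alt or ref not in BASES or alt not in BASES:
        raise ValueError(f"not a substitution: {ref!r}->{alt!r}")
    return f"{ref}>{alt}"


def fold_strand_type(ref: str, alt: str) -> str:
    """Pyrimidine-centred substitution, e.g. ('G','T') -> 'C>A'."""
    pref, palt = _PYR_FOLD[(ref, alt)]
    return f"{pref}>{palt}"


def class_of(ref: str, alt: str) -> str:
    """Strand-folded base-pair class of a substitution."""
    return _CLASS_OF_SUB[fold_strand_type(ref, alt)]


def class_members(cls: str) -> tuple[tuple[str, str], ...]:
    """The two (ref, alt) strand-resolved members of a base-pair class."""
    return tuple(
        (r, a) for (r, a), p in _PYR_FOLD.items() if _CLASS_OF_SUB[f"{p[0]}>{p[1]}"] == cls
    )


def channel_index(context5: str, ref: str, alt: str, context3: str) -> int:
    """96-channel index of a substitution with its reference flanks.

    Purine-centred observations are reverse-complemented (flanks swapped and
    complemented) into the pyrimidine convention.
    """
    if ref in "AG":
        context5, ref, alt, context3 = (
            comp_base(context3),
            comp_base(ref),
            comp_base(alt),
            comp_base(context5),
        )
    sub = f"{ref}>{alt}"
    s = SUBSTITUTIONS.index(sub)
    return s * 16 + BASES.index(context5) * 4 + BASES.index(context3)


def channel_label(index: int) -> str:
    return CHANNELS[index]


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    channel = np.full((64, 4), -1, dtype=np.int16)
    fold = np.zeros(64, dtype=np.int16)
    for li, l in enumerate(BASES):
        for ci, c in enumerate(BASES):
            for ri, r in enumerate(BASES):
                code = li * 16 + ci * 4 + ri
                if c in "CT":
                    pl, pc, pr = l, c, r
                else:
                    pl, pc, pr = comp_base(r), comp_base(c), comp_base(l)
                fold[code] = ("CT".index(pc)) * 16 + BASES.index(pl) * 4 + BASES.index(pr)
                for ai, a in enumerate(BASES):
                    if a == c:
                        continue
                    channel[code, ai] = channel_index(l, c, a, r)
    # trinucleotide bin feeding each channel's denominator
    chan_trinuc = np.zeros(96, dtype=np.int16)
    for s, sub in enumerate(SUBSTITUTIONS):
        center = "CT".index(sub[0])
        for ctx in range(16):
            chan_trinuc[s * 16 + ctx] = center * 16 + ctx
    return channel, fold, chan_trinuc


CHANNEL_TABLE, TRINUC_FOLD, CHANNEL_TRINUC = _build_tables()


def class_rate_matrix(class_rates: dict[str, float]) -> np.ndarray:
    """Expand 6 base-pair class rates to a 4x4 per-base (ref, alt) matrix.

    A class rate r means each reference base pair of that class converts at
    probability r; on reference-strand coordinates both strand-resolved
    members (e.g. G→T and C→A for G:C>T:A) carry the full rate r, because a
    base pair is observed through exactly one of them at any given site.
    """
    m = np.zeros((4, 4))
    for cls, rate in class_rates.items():
        if cls not in CLASSES:
            raise ValueError(f"unknown substitution class {cls!r}")
        if rate < 0:
            raise ValueError(f"negative rate for {cls!r}")
        for ref, alt in class_members(cls):
            m[BASES.index(ref), BASES.index(alt)] = rate
    return m
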