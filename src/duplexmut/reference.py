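"""Reference sequences: in-memory container, FASTA I/O, random generation.

The reference plays the role the mouse genome plays in a real duplex
sequencing run: it supplies the base every dsDCS observation is compared
against and the trinucleotide context of every call. Contigs are plain
uppercase A/C/G/T strings; anything else (IUPAC codes, soft-masked bases)
must be resolved upstream.
"""

from __future__ import annotations

import os
from typing import Iterator, Mapping

import numpy as np
import pyfaidx

from ._bases import BASE_CODES, BASE_INDEX, decode, encode

__all__ = ["ReferenceGenome", "make_reference"]


class ReferenceGenome:
    """Ordered collection of named contigs with cached uint8 views.

    Parameters
    ----------
    contigs
        Mapping of contig name to uppercase base string. Order is preserved
        and names must be unique (guaranteed by the mapping) and sequences
        at least 3 bp so every internal base has a trinucleotide context.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("reference needs at least one contig")
        self._arrays: dict[str, np.ndarray] = {}
        for name, seq in contigs.items():
            arr = encode(seq)
            if arr.size < 3:
                raise ValueError(f"contig {name!r} shorter than 3 bp")
            if (BASE_INDEX[arr] == 255).any():
                bad = decode(arr[BASE_INDEX[arr] == 255][:5])
                raise ValueError(
                    f"contig {name!r} contains non-ACGT characters: {bad!r}"
                )
            self._arrays[name] = arr

    @property
    def contig_names(self) -> list[str]:
        return list(self._arrays)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: arr.size for name, arr in self._arrays.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._arrays

    def array(self, contig: str) -> np.ndarray:
        """Whole contig as a read-only uint8 array (do not mutate)."""
        return self._arrays[contig]

    def sequence(self, contig: str) -> str:
        return decode(self._arrays[contig])

    def slice(self, contig: str, start: int, end: int) -> np.ndarray:
        """0-based half-open slice; bounds-checked."""
        arr = self._arrays[contig]
        if start < 0 or end > arr.size or start >= end:
            raise ValueError(
                f"slice [{start}, {end}) outside contig {contig!r} "
                f"of length {arr.size}"
            )
        return arr[start:end]

    def gc_fraction(self, contig: str | None = None) -> float:
        arrs = (
            [self._arrays[contig]] if contig else list(self._arrays.values())
        )
        gc = sum(int(np.isin(a, BASE_CODES[[1, 2]]).sum()) for a in arrs)
        total = sum(a.size for a in arrs)
        return gc / total

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self._arrays.items())

    # -- FASTA boundary -------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        fa = pyfaidx.Fasta(str(path), sequence_always_upper=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    def to_fasta(self, path: str | os.PathLike, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, arr in self._arrays.items():
                fh.write(f">{name}\n")
                seq = decode(arr)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def make_reference(
    length: int, gc_fraction: float, seed: int, contig_name: str = "sim1"
) -> ReferenceGenome:
    """Draw a single-contig random reference with a target G+C content.

    Bases are i.i.d. with P(G) = P(C) = gc_fraction/2 and
    P(A) = P(T) = (1-gc_fraction)/2, so the realised G+C fraction is a
    Binomial(length, gc_fraction) proportion — within a few tenths of a
    percentage point of the target for genome-scale lengths.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,  # C
            gc_fraction / 2,  # G
            (1 - gc_fraction) / 2,  # T
        ]
    )
    idx = rng.choice(4, size=length, p=p)
    return ReferenceGenome({contig_name: decode(BASE_CODES[idx])})
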