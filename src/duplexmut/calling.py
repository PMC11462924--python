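"""Mutation calling on dsDCS output: masks, calls, and frequency tables.

A mutation call is simply a duplex consensus base that differs from the
reference at a position not masked by a known-variant list — the duplex
consensus itself is the caller; there is no statistical model on top.

Frequencies follow the read-base convention: every non-N duplex base at an
unmasked position contributes once to the denominator of its reference
class (G:C or A:T), and each class's mutation count is divided by its own
denominator and scaled to events per 1e6 base pairs. The overall mutation
(OM) frequency pools counts over pooled denominators. Masked or N positions
contribute to neither numerator nor denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._bases import BASE_INDEX, N
from .consensus import DuplexConsensusPair
from .reference import ReferenceGenome
from .substitutions import (
    CLASSES,
    STRAND_TYPES,
    TRINUC32,
    TRINUC_FOLD,
    class_of,
)

__all__ = [
    "PositionMask",
    "MutationCall",
    "Denominators",
    "FrequencyTable",
    "load_position_mask",
    "call_mutations",
    "compute_frequency_table",
    "write_calls_vcf",
]

logger = logging.getLogger(__name__)

_GC_IDX = (1, 2)  # C, G in ACGT indexing


class PositionMask:
    """Set of masked (contig, 0-based position) sites with provenance.

    Mirrors the removal of known SNP positions and historically suspect
    sites before counting: masked positions never contribute calls or
    denominator bases.
    """

    def __init__(
        self,
        positions: dict[str, np.ndarray] | None = None,
        sources: Sequence[str] = (),
    ):
        self._pos = {
            contig: np.unique(np.asarray(arr, dtype=np.int64))
            for contig, arr in (positions or {}).items()
        }
        self.sources = list(sources)

    def __len__(self) -> int:
        return sum(arr.size for arr in self._pos.values())

    def __contains__(self, site: tuple[str, int]) -> bool:
        contig, pos = site
        arr = self._pos.get(contig)
        if arr is None:
            return False
        i = np.searchsorted(arr, pos)
        return i < arr.size and arr[i] == pos

    def positions(self, contig: str) -> np.ndarray:
        return self._pos.get(contig, np.empty(0, dtype=np.int64))

    def local_indices(self, contig: str, start: int, end: int) -> np.ndarray:
        """Masked positions inside [start, end), as offsets from start."""
        arr = self._pos.get(contig)
        if arr is None or arr.size == 0:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(arr, (start, end))
        return arr[lo:hi] - start

    def union(self, other: "PositionMask") -> "PositionMask":
        merged: dict[str, np.ndarray] = {}
        for contig in set(self._pos) | set(other._pos):
            merged[contig] = np.union1d(
                self.positions(contig), other.positions(contig)
            )
        return PositionMask(merged, self.sources + other.sources)

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_bed(cls, path: str | Path) -> "PositionMask":
        """Expand BED intervals (0-based half-open) to single positions."""
        acc: dict[str, list[np.ndarray]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                try:
                    contig, start, end = fields[0], int(fields[1]), int(fields[2])
                    if start < 0 or end <= start:
                        raise ValueError
                except (IndexError, ValueError):
                    raise ValueError(
                        f"{path}: malformed BED row at line {lineno}: {line!r}"
                    ) from None
                acc.setdefault(contig, []).append(
                    np.arange(start, end, dtype=np.int64)
                )
        return cls(
            {c: np.concatenate(v) for c, v in acc.items()}, [str(path)]
        )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "PositionMask":
        """Collect VCF record positions (1-based POS -> 0-based)."""
        acc: dict[str, list[int]] = {}
        try:
            with pysam.VariantFile(str(path)) as vf:
                for rec in vf:
                    acc.setdefault(rec.chrom, []).append(rec.pos - 1)
        except (OSError, ValueError) as exc:
            raise ValueError(f"{path}: cannot parse VCF: {exc}") from exc
        return cls(
            {c: np.asarray(v, dtype=np.int64) for c, v in acc.items()},
            [str(path)],
        )


def load_position_mask(paths: Iterable[str | Path]) -> PositionMask:
    """Union BED and/or VCF mask files (duplicates collapse naturally)."""
    mask = PositionMask()
    for path in paths:
        p = str(path)
        if p.endswith((".vcf", ".vcf.gz")):
            part = PositionMask.from_vcf(p)
        else:
            part = PositionMask.from_bed(p)
        mask = mask.union(part)
    return mask


@dataclass(frozen=True)
class MutationCall:
    """One dsDCS base differing from the reference at an unmasked site."""

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    cls: str  # strand-folded base-pair class
    depth_plus: int
    depth_minus: int

    @property
    def strand_type(self) -> str:
        """Raw reference-strand substitution, e.g. 'C>G' (vs folded cls)."""
        return f"{self.ref}>{self.alt}"


@dataclass
class Denominators:
    """Sequenced duplex base counts feeding the frequency denominators."""

    gc_bases: int = 0
    at_bases: int = 0
    #: per-trinucleotide (pyrimidine-centred, 32 bins) duplex base counts;
    #: sites on contig edges lack a context and are excluded here only
    trinuc: np.ndarray = field(default_factory=lambda: np.zeros(32, np.int64))

    @property
    def total(self) -> int:
        return self.gc_bases + self.at_bases

    def add(self, other: "Denominators") -> None:
        self.gc_bases += other.gc_bases
        self.at_bases += other.at_bases
        self.trinuc += other.trinuc

    def trinuc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trinucleotide": TRINUC32, "duplex_bases": self.trinuc}
        )


def call_mutations(
    duplexes: Iterable[DuplexConsensusPair],
    ref: ReferenceGenome,
    mask: PositionMask | None = None,
) -> tuple[list[MutationCall], Denominators]:
    """Compare dsDCS bases against the reference.

    Emits a call wherever the duplex base is a real base differing from the
    reference at an unmasked position. Every non-N duplex base at an
    unmasked position is counted in the denominators, split by the reference
    base class; masked and N positions count nowhere. A consensus
    overhanging its contig aborts.
    """
    mask = mask if mask is not None else PositionMask()
    calls: list[MutationCall] = []
    denoms = Denominators()
    for d in duplexes:
        carr = ref.array(d.contig)  # KeyError for unknown contigs
        if d.start < 0 or d.end > carr.size:
            raise ValueError(
                f"consensus [{d.start}, {d.end}) overhangs contig "
                f"{d.contig!r} of length {carr.size}"
            )
        refarr = carr[d.start : d.end]
        valid = d.bases != N
        local_masked = mask.local_indices(d.contig, d.start, d.end)
        if local_masked.size:
            valid = valid.copy()
            valid[local_masked] = False

        ridx = BASE_INDEX[refarr]
        is_gc = (ridx == _GC_IDX[0]) | (ridx == _GC_IDX[1])
        denoms.gc_bases += int((valid & is_gc).sum())
        denoms.at_bases += int((valid & ~is_gc).sum())

        # trinucleotide denominators need both flanks on the contig
        has_flanks = valid.copy()
        if d.start == 0:
            has_flanks[0] = False
        if d.end == carr.size:
            has_flanks[-1] = False
        idxs = np.nonzero(has_flanks)[0]
        if idxs.size:
            g = idxs + d.start
            codes = (
                BASE_INDEX[carr[g - 1]].astype(np.int64) * 16
                + ridx[idxs] * 4
                + BASE_INDEX[carr[g + 1]]
            )
            denoms.trinuc += np.bincount(TRINUC_FOLD[codes], minlength=32)

        mism = np.nonzero(valid & (d.bases != refarr))[0]
        for p in mism:
            rb, ab = chr(refarr[p]), chr(d.bases[p])
            calls.append(
                MutationCall(
                    d.contig,
                    d.start + int(p),
                    rb,
                    ab,
                    class_of(rb, ab),
                    d.n_plus,
                    d.n_minus,
                )
            )
    return calls, denoms


@dataclass
class FrequencyTable:
    """Counts, denominators and frequencies per 1e6 G:C / A:T base pairs."""

    class_counts: dict[str, int]
    strand_counts: dict[str, int]
    gc_bases: int
    at_bases: int
    #: sites called in more than `recurrence_k` independent families —
    #: possible clonal events, flagged but not collapsed
    recurrent_sites: dict[tuple[str, int], int] = field(default_factory=dict)

    def denominator_for(self, cls: str) -> int:
        return self.gc_bases if cls.startswith("G:C") else self.at_bases

    def class_frequency(self, cls: str) -> float:
        count = self.class_counts[cls]
        denom = self.denominator_for(cls)
        if denom == 0:
            if count:
                raise ValueError(f"nonzero count for {cls} with zero denominator")
            warnings.warn(f"zero denominator for {cls}; frequency set to 0")
            return 0.0
        return count / denom * 1e6

    @property
    def frequencies(self) -> dict[str, float]:
        return {cls: self.class_frequency(cls) for cls in CLASSES}

    @property
    def total_count(self) -> int:
        return sum(self.class_counts.values())

    @property
    def om_frequency(self) -> float:
        """Pooled counts over pooled denominators, per 1e6 bp."""
        denom = self.gc_bases + self.at_bases
        if denom == 0:
            if self.total_count:
                raise ValueError("nonzero counts with zero total denominator")
            warnings.warn("zero total denominator; OM frequency set to 0")
            return 0.0
        return self.total_count / denom * 1e6

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": cls,
                "count": self.class_counts[cls],
                "denominator_bp": self.denominator_for(cls),
                "frequency_per_1e6": self.class_frequency(cls)
                if self.denominator_for(cls)
                else 0.0,
            }
            for cls in CLASSES
        ]
        rows.append(
            {
                "class": "OM",
                "count": self.total_count,
                "denominator_bp": self.gc_bases + self.at_bases,
                "frequency_per_1e6": self.om_frequency
                if self.gc_bases + self.at_bases
                else 0.0,
            }
        )
        return pd.DataFrame(rows)

    def strand_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strand_type": list(STRAND_TYPES),
                "count": [self.strand_counts[s] for s in STRAND_TYPES],
            }
        )

    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        by_class = df.set_index("class")
        gc = int(by_class.loc["G:C>T:A", "denominator_bp"])
        at = int(by_class.loc["A:T>T:A", "denominator_bp"])
        counts = {c: int(by_class.loc[c, "count"]) for c in CLASSES}
        return cls(counts, {s: 0 for s in STRAND_TYPES}, gc, at)


def compute_frequency_table(
    calls: Sequence[MutationCall],
    denominators: Denominators,
    recurrence_k: int = 2,
) -> FrequencyTable:
    """Aggregate calls into the six-class frequency table plus diagnostics.

    The 12 strand-resolved counts (C>G vs G>C separately) are retained for
    asymmetry diagnostics and always fold back onto the 6 classes. Sites
    called in more than ``recurrence_k`` families are flagged as possibly
    clonal but still counted individually.
    """
    class_counts = {cls: 0 for cls in CLASSES}
    strand_counts = {s: 0 for s in STRAND_TYPES}
    site_counts: dict[tuple[str, int], int] = {}
    for call in calls:
        class_counts[call.cls] += 1
        strand_counts[call.strand_type] += 1
        site = (call.contig, call.pos)
        site_counts[site] = site_counts.get(site, 0) + 1
    recurrent = {
        site: n for site, n in site_counts.items() if n > recurrence_k
    }
    if recurrent:
        logger.info(
            "%d site(s) recur in > %d families (possible clonal expansion)",
            len(recurrent),
            recurrence_k,
        )
    for cls in CLASSES:
        if class_counts[cls] and denominators.gc_bases + denominators.at_bases == 0:
            raise ValueError("calls present but denominators are zero")
    return FrequencyTable(
        class_counts,
        strand_counts,
        denominators.gc_bases,
        denominators.at_bases,
        recurrent,
    )


def write_calls_vcf(
    calls: Sequence[MutationCall],
    path: str | Path,
    contig_lengths: dict[str, int],
    comment: str | None = None,
) -> None:
    """Write calls as a minimal VCF (CHROM, POS, REF, ALT + class INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if comment:
            fh.write(f"##duplexmut={comment}\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            '##INFO=<ID=CLASS,Number=1,Type=String,'
            'Description="Strand-folded base-pair substitution class">\n'
        )
        fh.write(
            '##INFO=<ID=STRAND,Number=1,Type=String,'
            'Description="Reference-strand substitution">\n'
        )
        fh.write(
            '##INFO=<ID=DP2,Number=2,Type=Integer,'
            'Description="Supporting read pairs (plus,minus orientation)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
            info = (
                f"CLASS={c.cls.replace('>', '-')};"
                f"STRAND={c.strand_type.replace('>', '-')};"
                f"DP2={c.depth_plus},{c.depth_minus}"
            )
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n"
            )


def calls_from_tsv(path: str | Path) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MutationCall(
            str(r.contig),
            int(r.pos0),
            str(r.ref),
            str(r.alt),
            class_of(str(r.ref), str(r.alt)),
            int(r.depth_plus),
            int(r.depth_minus),
        )
        for r in df.itertuples(index=False)
    ]


def calls_to_frame(calls: Sequence[MutationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.contig,
                "pos0": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "class": c.cls,
                "strand_type": c.strand_type,
                "depth_plus": c.depth_plus,
                "depth_minus": c.depth_minus,
            }
            for c in calls
        ],
        columns=[
            "contig",
            "pos0",
            "ref",
            "alt",
            "class",
            "strand_type",
            "depth_plus",
            "depth_minus",
        ],
    )
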