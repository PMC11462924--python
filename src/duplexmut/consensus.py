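"""Duplex consensus: same-position groups (SP-G) and dsDCS construction.

The error-correction logic works on paired-end fragments, not single reads.
All read pairs mapping to identical fragment coordinates (contig, start,
end) form a *same position group*; within an SP-G the two R1 orientations
distinguish the two physical strands of the original duplex. A
single-strand consensus is built per orientation subgroup, and only SP-Gs
observed in **both** orientations yield a double-stranded DNA consensus
sequence (dsDCS): a base is emitted where the two strand consensuses agree,
and ``N`` anywhere a read disagreed, coverage was missing, or the strands
contradict each other. A sequencing or PCR error lives on one strand only
and is therefore masked, while a genuine mutation — present on both strands
of the fragment before amplification — survives.

Coordinates are 0-based half-open throughout; SAM's 1-based convention is
handled exclusively at the pysam boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from ._bases import BASE_CODES, CONFLICT, N, decode

__all__ = [
    "AlignedReadPair",
    "SamePositionGroup",
    "StrandConsensus",
    "DuplexConsensusPair",
    "ConsensusSummary",
    "group_same_position",
    "build_strand_consensus",
    "build_duplex_consensus",
    "read_alignments",
    "consensus_pipeline",
]

logger = logging.getLogger(__name__)

RULES = ("unanimity", "majority")


@dataclass
class AlignedReadPair:
    """One paired-end fragment observation.

    ``mates`` holds the one or two aligned mate windows as
    ``(ref_start, bases)`` with bases already on the forward reference
    strand (as SAM stores them). The merged per-position observation is
    materialised lazily: positions covered by neither mate are ``N``;
    positions where the mates overlap and disagree become the ``CONFLICT``
    sentinel, which downstream consensus always turns into ``N``.
    """

    pair_id: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    r1_forward: bool
    mates: tuple[tuple[int, np.ndarray], ...]
    _obs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"pair {self.pair_id!r}: start {self.start} >= end {self.end}"
            )
        for mstart, mbases in self.mates:
            if mstart < self.start or mstart + mbases.size > self.end:
                raise ValueError(
                    f"pair {self.pair_id!r}: mate window outside fragment"
                )

    @property
    def orientation(self) -> str:
        """'R1F' if read 1 aligned forward, else 'R1R'."""
        return "R1F" if self.r1_forward else "R1R"

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    @property
    def obs(self) -> np.ndarray:
        """Merged observation over [start, end): base, N, or CONFLICT."""
        if self._obs is None:
            obs = np.full(self.end - self.start, N, dtype=np.uint8)
            for mstart, mbases in self.mates:
                o = mstart - self.start
                seg = obs[o : o + mbases.size]
                both = (seg != N) & (mbases != N)
                np.copyto(seg, mbases, where=(seg == N))
                seg[both & (seg != mbases)] = CONFLICT
            self._obs = obs
        return self._obs

    def observed_base(self, pos: int) -> str:
        """Observed base at a 0-based reference position ('N' if uncovered)."""
        if not self.start <= pos < self.end:
            return "N"
        b = int(self.obs[pos - self.start])
        return "N" if b == N else chr(b)


@dataclass
class SamePositionGroup:
    """All read pairs sharing one exact (contig, start, end) key."""

    key: tuple[str, int, int]
    members: list[AlignedReadPair]

    def subgroup(self, r1_forward: bool) -> list[AlignedReadPair]:
        return [p for p in self.members if p.r1_forward is r1_forward]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class StrandConsensus:
    key: tuple[str, int, int]
    bases: np.ndarray  # uint8, A/C/G/T or N
    depth: np.ndarray  # int, covering read pairs per position


@dataclass
class DuplexConsensusPair:
    """dsDCS for one fragment position; the unit of mutation counting."""

    contig: str
    start: int
    end: int
    bases: np.ndarray  # uint8, A/C/G/T or N
    n_plus: int  # R1-forward pairs supporting the call
    n_minus: int  # R1-reverse pairs

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    @property
    def sequence(self) -> str:
        return decode(self.bases)


def group_same_position(
    pairs: Iterable[AlignedReadPair],
) -> list[SamePositionGroup]:
    """Partition read pairs by exact fragment coordinates.

    Every input pair lands in exactly one group; groups preserve first-seen
    order, members preserve input order.
    """
    groups: dict[tuple[str, int, int], list[AlignedReadPair]] = {}
    for pair in pairs:
        if pair.start >= pair.end:  # defensive: stream may bypass the ctor
            raise ValueError(f"pair {pair.pair_id!r} has start >= end")
        groups.setdefault(pair.key, []).append(pair)
    return [SamePositionGroup(k, v) for k, v in groups.items()]


def build_strand_consensus(
    subgroup: Sequence[AlignedReadPair], rule: str = "unanimity"
) -> StrandConsensus:
    """Collapse one orientation subgroup to a single-strand consensus.

    Under ``unanimity`` a position gets a base only when every covering
    read pair observed that same base; any disagreement, any mate-conflict
    observation, or zero coverage yields ``N``. Under ``majority`` the
    strictly most frequent observed base wins (ties -> N); a mate-conflict
    observation still forces ``N``.
    """
    if not subgroup:
        raise ValueError("empty subgroup")
    orientations = {p.r1_forward for p in subgroup}
    if len(orientations) != 1:
        raise ValueError("subgroup mixes R1 orientations")
    if rule not in RULES:
        raise ValueError(f"unknown consensus rule {rule!r}")

    mat = np.stack([p.obs for p in subgroup])  # (m, L)
    covered = mat != N
    depth = covered.sum(axis=0)

    if rule == "unanimity":
        masked = np.where(covered, mat, 0)
        cand = masked.max(axis=0)  # CONFLICT ('?') sorts below 'A'
        agree = (masked == np.where(covered, cand, 0)).all(axis=0)
        bases = np.where(
            (depth > 0) & agree & (cand != CONFLICT), cand, N
        ).astype(np.uint8)
    else:  # majority
        counts = np.stack([(mat == b).sum(axis=0) for b in BASE_CODES])
        conflicts = (mat == CONFLICT).sum(axis=0)
        order = np.sort(counts, axis=0)
        top, second = order[-1], order[-2]
        winner = BASE_CODES[np.argmax(counts, axis=0)]
        ok = (top > second) & (top > 0) & (conflicts == 0)
        bases = np.where(ok, winner, N).astype(np.uint8)

    return StrandConsensus(subgroup[0].key, bases, depth)


def build_duplex_consensus(
    group: SamePositionGroup,
    min_pairs_per_strand: int = 1,
    rule: str = "unanimity",
) -> DuplexConsensusPair | None:
    """Combine the two strand consensuses of an SP-G into a dsDCS.

    Returns ``None`` unless both orientation subgroups have at least
    ``min_pairs_per_strand`` members — the both-strands requirement that
    makes the consensus double-stranded. Where the strand consensuses agree
    on a real base, that base is emitted; everywhere else ``N``.
    """
    plus = group.subgroup(True)
    minus = group.subgroup(False)
    if len(plus) < max(1, min_pairs_per_strand) or len(minus) < max(
        1, min_pairs_per_strand
    ):
        return None
    cons_p = build_strand_consensus(plus, rule=rule)
    cons_m = build_strand_consensus(minus, rule=rule)
    bases = np.where(
        (cons_p.bases == cons_m.bases) & (cons_p.bases != N), cons_p.bases, N
    ).astype(np.uint8)
    contig, start, end = group.key
    return DuplexConsensusPair(contig, start, end, bases, len(plus), len(minus))


@dataclass
class ConsensusSummary:
    """Per-run bookkeeping mirroring a per-sample sequencing summary row."""

    input_records: int = 0
    input_pairs: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_unpaired: int = 0
    skipped_cigar: int = 0
    n_groups: int = 0
    n_duplex: int = 0


_MATCH_OPS = {0, 7, 8}  # M, =, X


def read_alignments(
    path: str | Path, summary: ConsensusSummary | None = None
) -> list[AlignedReadPair]:
    """Load primary, mapped, properly paired records from SAM/BAM.

    Records are collated by query name internally, so coordinate- and
    name-ordered files are both accepted. Unmapped, secondary and
    supplementary records, widowed mates, and non-all-match CIGARs are
    skipped with logged counts.
    """
    summary = summary if summary is not None else ConsensusSummary()
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            summary.input_records += 1
            if rec.is_secondary or rec.is_supplementary:
                summary.skipped_secondary += 1
                continue
            if rec.is_unmapped or rec.reference_name is None:
                summary.skipped_unmapped += 1
                continue
            if any(op not in _MATCH_OPS for op, _ in (rec.cigartuples or [])):
                summary.skipped_cigar += 1
                continue
            by_name.setdefault(rec.query_name, []).append(rec)

    pairs: list[AlignedReadPair] = []
    for name, recs in by_name.items():
        if len(recs) != 2:
            summary.skipped_unpaired += len(recs)
            continue
        r1 = next((r for r in recs if r.is_read1), recs[0])
        r2 = recs[1] if recs[0] is r1 else recs[0]
        if r1.reference_name != r2.reference_name:
            summary.skipped_unpaired += 2
            continue
        start = min(r.reference_start for r in recs)
        end = max(r.reference_end for r in recs)
        mates = tuple(
            (
                r.reference_start,
                np.frombuffer(
                    r.query_sequence.upper().encode("ascii"), dtype=np.uint8
                ).copy(),
            )
            for r in recs
        )
        pairs.append(
            AlignedReadPair(
                pair_id=name,
                contig=r1.reference_name,
                start=start,
                end=end,
                r1_forward=not r1.is_reverse,
                mates=mates,
            )
        )
    summary.input_pairs = len(pairs)
    skipped = (
        summary.skipped_unmapped
        + summary.skipped_secondary
        + summary.skipped_unpaired
        + summary.skipped_cigar
    )
    if skipped:
        logger.info(
            "read_alignments: %d record(s) skipped "
            "(unmapped=%d secondary=%d unpaired=%d cigar=%d)",
            skipped,
            summary.skipped_unmapped,
            summary.skipped_secondary,
            summary.skipped_unpaired,
            summary.skipped_cigar,
        )
    return pairs


def consensus_pipeline(
    alignments: str | Path | Iterable[AlignedReadPair],
    min_pairs_per_strand: int = 1,
    rule: str = "unanimity",
) -> tuple[list[DuplexConsensusPair], ConsensusSummary]:
    """Run grouping and duplex consensus over a SAM/BAM file or pair stream.

    Returns all dsDCS pairs passing the both-orientation and
    ``min_pairs_per_strand`` thresholds, plus summary counts (input pairs,
    SP-G count, dsDCS count).
    """
    summary = ConsensusSummary()
    if isinstance(alignments, (str, Path)):
        pairs: Iterable[AlignedReadPair] = read_alignments(alignments, summary)
    else:
        pairs = list(alignments)
        summary.input_pairs = len(pairs)  # type: ignore[arg-type]

    groups = group_same_position(pairs)
    summary.n_groups = len(groups)
    duplexes: list[DuplexConsensusPair] = []
    for group in groups:
        d = build_duplex_consensus(
            group, min_pairs_per_strand=min_pairs_per_strand, rule=rule
        )
        if d is not None:
            duplexes.append(d)
    summary.n_duplex = len(duplexes)
    logger.info(
        "consensus: %d pairs -> %d SP-G -> %d dsDCS",
        summary.input_pairs,
        summary.n_groups,
        summary.n_duplex,
    )
    return duplexes, summary


def iter_duplex_tsv(
    duplexes: Iterable[DuplexConsensusPair],
) -> Iterator[tuple]:
    """Rows (contig, start, end, n_plus, n_minus, sequence) for TSV export."""
    for d in duplexes:
        yield (d.contig, d.start, d.end, d.n_plus, d.n_minus, d.sequence)


_DUPLEX_COLUMNS = ("contig", "start", "end", "n_plus", "n_minus", "sequence")


def write_duplex_tsv(
    duplexes: Iterable[DuplexConsensusPair],
    path: str | Path,
    comment: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(_DUPLEX_COLUMNS) + "\n")
        for row in iter_duplex_tsv(duplexes):
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_duplex_tsv(path: str | Path) -> list[DuplexConsensusPair]:
    duplexes = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if tuple(header) != _DUPLEX_COLUMNS:
                    raise ValueError(f"{path}: unexpected dsDCS TSV header")
                continue
            contig, start, end, n_plus, n_minus, seq = line.split("\t")
            duplexes.append(
                DuplexConsensusPair(
                    contig,
                    int(start),
                    int(end),
                    np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy(),
                    int(n_plus),
                    int(n_minus),
                )
            )
    return duplexes
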