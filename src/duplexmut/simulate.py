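"""Synthetic duplex read families with platform-specific error profiles.

The generator emulates what a duplex-sequencing library looks like after
alignment, so the whole downstream pipeline can be exercised without real
data:

* fragments are drawn from the reference with a normal length distribution
  around the sonication peak (350 bp by default);
* *true* mutations are planted on the fragment before any reads are made —
  they sit on both strands and therefore survive duplex consensus;
* *platform errors* are drawn independently per read per strand from a
  12-entry substitution-rate profile, applied in strand-local coordinates
  (minus-strand reads are complemented, mutated, complemented back), so a
  strand-asymmetric rate such as an elevated C→G miscall produces the
  asymmetry it should;
* each family yields a configurable number of read pairs per strand, and a
  configurable fraction of families is observed in only one orientation
  (those can never form a dsDCS).

Everything is driven by one ``numpy`` generator, so a fixed seed fixes every
emitted byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import pysam

from ._bases import BASE_CODES, BASE_INDEX, BASES, complement
from .consensus import AlignedReadPair
from .reference import ReferenceGenome
from .substitutions import (
    CHANNEL_TABLE,
    CLASSES,
    SUBSTITUTIONS,
    _CLASS_OF_SUB,
    class_of,
    class_rate_matrix,
)

__all__ = [
    "PlatformErrorProfile",
    "MutationModel",
    "TruthRecord",
    "TruthTable",
    "SimulatedReadSet",
    "simulate_family_set",
    "write_alignments",
    "read_reference_mismatch_rate",
    "preset_profile",
    "PRESET_PROFILES",
]

MAX_ERROR_RATE = 0.01


def _sub_machine(rate_matrix: np.ndarray):
    """Precompute (totals, cumulative alt rates, alt codes) for fast draws."""
    alts = np.zeros((4, 3), dtype=np.uint8)
    rates = np.zeros((4, 3))
    for i in range(4):
        cols = [j for j in range(4) if j != i]
        alts[i] = BASE_CODES[cols]
        rates[i] = rate_matrix[i, cols]
    total = rates.sum(axis=1)
    if (total > 1).any():
        raise ValueError("per-base substitution rates sum above 1")
    return total, np.cumsum(rates, axis=1), alts


def apply_substitutions(
    arr: np.ndarray, machine, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mutate an A/C/G/T array in one vectorised pass.

    Each position converts with its base-specific total rate; conditional on
    converting, the alternate base is chosen proportionally to the three
    per-substitution rates. Returns (mutated copy, hit mask).
    """
    total, cum, alts = machine
    flat = arr.ravel()
    idx = BASE_INDEX[flat]
    u = rng.random(flat.size)
    hit = u < total[idx]
    out = arr.copy()
    if hit.any():
        h = np.nonzero(hit)[0]
        b = idx[h]
        j = (u[h][:, None] >= cum[b]).sum(axis=1)
        out.ravel()[h] = alts[b, j]
    return out, hit.reshape(arr.shape)


@dataclass
class PlatformErrorProfile:
    """Per-strand, per-substitution sequencing error rates for one platform.

    ``strand_error_rates`` maps (from-base, to-base) to a probability per
    sequenced base per strand, in strand-local coordinates. All 12 entries
    are independently settable; missing entries default to 0. Raw platform
    error rates are of order 1e-3 to 1e-4 per base, so rates are capped at
    0.01.
    """

    name: str
    strand_error_rates: dict[tuple[str, str], float]
    read_length: int = 150

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        for (a, b), rate in self.strand_error_rates.items():
            if a not in BASES or b not in BASES or a == b:
                raise ValueError(f"invalid substitution ({a!r}, {b!r})")
            if not 0.0 <= rate <= MAX_ERROR_RATE:
                raise ValueError(
                    f"rate {rate} for {a}->{b} outside [0, {MAX_ERROR_RATE}]"
                )

    @classmethod
    def uniform(
        cls, name: str, rate: float, read_length: int = 150
    ) -> "PlatformErrorProfile":
        """All 12 substitutions at the same per-strand rate."""
        rates = {
            (a, b): rate for a in BASES for b in BASES if a != b
        }
        return cls(name, rates, read_length)

    def rate_matrix(self) -> np.ndarray:
        m = np.zeros((4, 4))
        for (a, b), rate in self.strand_error_rates.items():
            m[BASES.index(a), BASES.index(b)] = rate
        return m

    def total_rate(self) -> float:
        """Mean per-base error rate over an equal-composition strand."""
        return float(self.rate_matrix().sum() / 4)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "read_length": self.read_length,
            "strand_error_rates": {
                f"{a}>{b}": rate
                for (a, b), rate in sorted(self.strand_error_rates.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlatformErrorProfile":
        rates = {
            (k[0], k[2]): float(v)
            for k, v in d.get("strand_error_rates", {}).items()
        }
        return cls(d["name"], rates, int(d.get("read_length", 150)))


@dataclass
class MutationModel:
    """True (pre-amplification) mutation rates per base pair.

    ``class_rates`` maps the six strand-folded classes to a probability per
    eligible base pair. ``context_weights`` optionally redistributes a
    class's rate over its 16 trinucleotide contexts (non-negative, summing
    to 1 per class); with uniform weights (1/16 each) the per-site rate is
    unchanged, and in general a site of context c carries rate
    ``16 * w_c * class_rate``.
    """

    class_rates: dict[str, float] = field(default_factory=dict)
    context_weights: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for cls, rate in self.class_rates.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if rate < 0:
                raise ValueError(f"negative rate for {cls!r}")
        if self.context_weights is not None:
            for cls, w in self.context_weights.items():
                w = np.asarray(w, dtype=float)
                if w.shape != (16,) or (w < 0).any():
                    raise ValueError(
                        f"context weights for {cls!r} must be 16 non-negative values"
                    )
                if abs(w.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"context weights for {cls!r} must sum to 1"
                    )
                self.context_weights[cls] = w

    def rate_matrix(self) -> np.ndarray:
        return class_rate_matrix(self.class_rates)

    def channel_factor(self) -> np.ndarray:
        """Per-channel multiplier (length 96): 16*w_c for weighted classes."""
        factor = np.ones(96)
        if self.context_weights:
            for s, sub in enumerate(SUBSTITUTIONS):
                cls = _CLASS_OF_SUB[sub]
                if cls in self.context_weights:
                    factor[s * 16 : (s + 1) * 16] = (
                        16 * self.context_weights[cls]
                    )
        return factor

    def to_dict(self) -> dict:
        d: dict = {"class_rates": dict(self.class_rates)}
        if self.context_weights is not None:
            d["context_weights"] = {
                cls: [float(x) for x in w]
                for cls, w in self.context_weights.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MutationModel":
        weights = d.get("context_weights")
        return cls(
            {k: float(v) for k, v in d.get("class_rates", {}).items()},
            {k: np.asarray(v, dtype=float) for k, v in weights.items()}
            if weights
            else None,
        )


class TruthRecord(NamedTuple):
    family_id: str
    contig: str
    pos0: int
    ref: str
    alt: str
    cls: str


class TruthTable:
    """Planted ground-truth mutations, one record per (family, site)."""

    COLUMNS = ("family_id", "contig", "pos0", "ref", "alt", "class")

    def __init__(self, records: Iterable[TruthRecord] = ()):
        self.records: list[TruthRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def append(self, rec: TruthRecord) -> None:
        self.records.append(rec)

    def class_counts(self) -> dict[str, int]:
        counts = {cls: 0 for cls in CLASSES}
        for rec in self.records:
            counts[rec.cls] += 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=self.COLUMNS)

    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            fh.write("\t".join(self.COLUMNS) + "\n")
            for rec in self.records:
                fh.write("\t".join(str(x) for x in rec) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        casts = (str, str, int, str, str, str)
        return cls(
            TruthRecord(*[t(v) for t, v in zip(casts, row)])
            for row in df.itertuples(index=False)
        )


@dataclass
class SimulatedReadSet:
    """Aligned read pairs + planted truth + provenance of one simulation."""

    pairs: list[AlignedReadPair]
    truth: TruthTable
    seed: int
    profile: PlatformErrorProfile
    model: MutationModel
    contig_lengths: dict[str, int]
    n_families: int


def _draw_reads_per_strand(
    spec: tuple, size: int, rng: np.random.Generator
) -> np.ndarray:
    if not spec or len(spec) != 2:
        raise ValueError("reads_per_strand spec must be (kind, value)")
    kind, value = spec
    if kind == "fixed":
        n = int(value)
        if n < 1:
            raise ValueError("fixed reads_per_strand must be >= 1")
        return np.full(size, n, dtype=np.int64)
    if kind == "geometric":
        mean = float(value)
        if mean < 1:
            raise ValueError("geometric mean must be >= 1")
        return rng.geometric(p=1.0 / mean, size=size)
    raise ValueError(f"unknown reads_per_strand kind {kind!r}")


def _plant_mutations(
    frag: np.ndarray,
    carr: np.ndarray,
    start: int,
    machine,
    factor96: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Plant true mutations on a fragment; context-weighted when requested."""
    if factor96 is None:
        return apply_substitutions(frag, machine, rng)
    total, cum, alts = machine
    L = frag.size
    idx = BASE_INDEX[frag]
    # reference trinucleotide codes; fragment-edge sites fall back to factor 1
    g0, g1 = start, start + L
    left = carr[max(g0 - 1, 0) : g1 - 1]
    right = carr[g0 + 1 : min(g1 + 1, carr.size)]
    factors = np.ones((L, 3))
    lo = 1 if g0 == 0 else 0
    hi = L - 1 if g1 == carr.size else L
    if hi > lo:
        li = BASE_INDEX[carr[g0 + lo - 1 : g0 + hi - 1]]
        ri = BASE_INDEX[carr[g0 + lo + 1 : g0 + hi + 1]]
        code = li * 16 + idx[lo:hi] * 4 + ri
        for j in range(3):
            aj = BASE_INDEX[alts[idx[lo:hi], j]]
            factors[lo:hi, j] = factor96[CHANNEL_TABLE[code, aj]]
    # per-site alt rates, rebuilt from the machine's cumulative form
    base_rates = np.diff(np.concatenate([np.zeros((4, 1)), cum], axis=1), axis=1)
    rates3 = base_rates[idx] * factors
    tot = np.minimum(rates3.sum(axis=1), 1.0)
    c3 = np.cumsum(rates3, axis=1)
    u = rng.random(L)
    hit = u < tot
    out = frag.copy()
    if hit.any():
        h = np.nonzero(hit)[0]
        j = (u[h][:, None] >= c3[h]).sum(axis=1)
        out[h] = alts[idx[h], j]
    return out, hit


def simulate_family_set(
    ref: ReferenceGenome,
    n_families: int,
    *,
    fragment_length: tuple[float, float] = (350.0, 50.0),
    reads_per_strand: tuple = ("geometric", 2.0),
    both_strand_prob: float = 0.8,
    model: MutationModel | None = None,
    profile: PlatformErrorProfile | None = None,
    seed: int = 0,
) -> SimulatedReadSet:
    """Simulate duplex read families over a reference.

    Each family is a fragment with fixed (contig, start, end); its true
    mutations are shared by every read of the family on both strands, while
    platform errors are independent per read. With probability
    ``1 - both_strand_prob`` a family is observed in only one orientation
    and can never yield a dsDCS.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0.0 <= both_strand_prob <= 1.0:
        raise ValueError("both_strand_prob must lie in [0, 1]")
    model = model if model is not None else MutationModel()
    profile = (
        profile
        if profile is not None
        else PlatformErrorProfile.uniform("null", 0.0)
    )
    rl = profile.read_length
    mean_len, sd_len = fragment_length
    names = ref.contig_names
    lengths = ref.lengths
    min_contig = min(lengths.values())
    if mean_len > min_contig:
        raise ValueError("mean fragment length exceeds a contig length")

    rng = np.random.default_rng(seed)
    err_machine = _sub_machine(profile.rate_matrix())
    mut_machine = _sub_machine(model.rate_matrix())
    factor96 = (
        model.channel_factor() if model.context_weights else None
    )

    # per-family draws, batched for speed and determinism
    if len(names) == 1:
        contig_idx = np.zeros(n_families, dtype=np.int64)
    else:
        p = np.array([lengths[n] for n in names], dtype=float)
        contig_idx = rng.choice(len(names), size=n_families, p=p / p.sum())
    frag_lens = np.rint(
        rng.normal(mean_len, sd_len, size=n_families)
    ).astype(np.int64)
    frag_lens = np.clip(frag_lens, max(3, min(rl, min_contig)), None)
    start_u = rng.random(n_families)
    both = rng.random(n_families) < both_strand_prob
    lone_is_plus = rng.random(n_families) < 0.5
    n_reads = np.stack(
        [
            _draw_reads_per_strand(reads_per_strand, n_families, rng),
            _draw_reads_per_strand(reads_per_strand, n_families, rng),
        ],
        axis=1,
    )

    pairs: list[AlignedReadPair] = []
    truth = TruthTable()
    arrays = {name: ref.array(name) for name in names}

    for f in range(n_families):
        contig = names[contig_idx[f]]
        carr = arrays[contig]
        L = int(min(frag_lens[f], carr.size))
        start = int(start_u[f] * (carr.size - L + 1))
        frag = carr[start : start + L]
        fam_id = f"fam{f:07d}"

        mut, hits = _plant_mutations(
            frag, carr, start, mut_machine, factor96, rng
        )
        if hits.any():
            for p in np.nonzero(hits)[0]:
                rb, ab = chr(frag[p]), chr(mut[p])
                truth.append(
                    TruthRecord(
                        fam_id, contig, start + int(p), rb, ab, class_of(rb, ab)
                    )
                )

        strands = (
            (True, False) if both[f] else ((True,) if lone_is_plus[f] else (False,))
        )
        w = min(rl, L)
        for si, plus in enumerate(strands):
            n_r = int(n_reads[f, 0 if plus else 1])
            strandlocal = mut if plus else complement(mut)
            block = np.empty((n_r, 2 * w), dtype=np.uint8)
            block[:, :w] = strandlocal[:w]
            block[:, w:] = strandlocal[L - w :]
            eblock, _ = apply_substitutions(block, err_machine, rng)
            if not plus:
                eblock = complement(eblock)
            tag = "F" if plus else "R"
            for k in range(n_r):
                mates = (
                    (start, eblock[k, :w].copy()),
                    (start + L - w, eblock[k, w:].copy()),
                )
                pairs.append(
                    AlignedReadPair(
                        pair_id=f"{fam_id}.{tag}{k}",
                        contig=contig,
                        start=start,
                        end=start + L,
                        r1_forward=plus,
                        mates=mates,
                    )
                )

    return SimulatedReadSet(
        pairs=pairs,
        truth=truth,
        seed=seed,
        profile=profile,
        model=model,
        contig_lengths=dict(lengths),
        n_families=n_families,
    )


def write_alignments(readset: SimulatedReadSet, path: str | Path) -> None:
    """Emit the read set as SAM (or BAM if the path ends in .bam).

    Mates carry proper-pair flags, 1-based POS, all-match CIGARs and mate
    coordinates; the generating seed and profile are recorded in a header
    comment so runs stay attributable.
    """
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in readset.contig_lengths.items()
        ],
        "CO": [
            f"duplexmut simulate seed={readset.seed} "
            f"profile={readset.profile.name} families={readset.n_families}"
        ],
    }
    tids = {
        name: i for i, name in enumerate(readset.contig_lengths)
    }
    mode = "wb" if path.endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for pair in readset.pairs:
            (ls, la), (rs, ra) = pair.mates
            frag_len = pair.end - pair.start
            if pair.r1_forward:
                mate_rows = [(ls, la, False, True), (rs, ra, True, False)]
            else:
                mate_rows = [(rs, ra, True, True), (ls, la, False, False)]
            for (pos, bases, is_rev, is_r1) in mate_rows:
                other = mate_rows[1] if is_r1 else mate_rows[0]
                a = pysam.AlignedSegment()
                a.query_name = pair.pair_id
                a.reference_id = tids[pair.contig]
                a.reference_start = pos
                a.query_sequence = bases.tobytes().decode("ascii")
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * bases.size
                )
                a.cigartuples = [(0, bases.size)]
                a.mapping_quality = 60
                a.is_paired = True
                a.is_proper_pair = True
                a.is_reverse = is_rev
                a.mate_is_reverse = other[2]
                a.is_read1 = is_r1
                a.is_read2 = not is_r1
                a.next_reference_id = tids[pair.contig]
                a.next_reference_start = other[0]
                if pos < other[0] or (pos == other[0] and is_r1):
                    a.template_length = frag_len
                else:
                    a.template_length = -frag_len
                out.write(a)


def read_reference_mismatch_rate(
    readset: SimulatedReadSet, ref: ReferenceGenome
) -> float:
    """Fraction of emitted read bases differing from the reference.

    With a zero-rate mutation model this is a direct estimate of the raw
    (pre-consensus) platform error rate.
    """
    mism = 0
    total = 0
    for pair in readset.pairs:
        carr = ref.array(pair.contig)
        for mstart, mbases in pair.mates:
            mism += int((mbases != carr[mstart : mstart + mbases.size]).sum())
            total += mbases.size
    return mism / total if total else 0.0


def _preset(name: str, base: float, overrides: dict[str, float] | None = None,
            read_length: int = 150) -> PlatformErrorProfile:
    rates = {(a, b): base for a in BASES for b in BASES if a != b}
    for key, rate in (overrides or {}).items():
        rates[(key[0], key[2])] = rate
    return PlatformErrorProfile(name, rates, read_length)


#: Illustrative per-strand profiles. Raw per-base error totals sit in the
#: reported 1e-3..1e-4 band; the NextSeq-like preset carries the elevated
#: strand-local C→G miscall rate characteristic of two-colour chemistry.
PRESET_PROFILES = {
    "hiseq-like": lambda: _preset("hiseq-like", 1.0e-4, read_length=100),
    "novaseq-like": lambda: _preset("novaseq-like", 1.3e-4),
    "nextseq-like": lambda: _preset("nextseq-like", 1.0e-4, {"C>G": 6.0e-4}),
    "dnbseq-like": lambda: _preset("dnbseq-like", 1.1e-4),
}


def preset_profile(name: str) -> PlatformErrorProfile:
    try:
        return PRESET_PROFILES[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESET_PROFILES)}"
        ) from None
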