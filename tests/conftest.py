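"""Shared fixtures and independent mini-oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from duplexmut import make_reference
from duplexmut._bases import encode
from duplexmut.consensus import AlignedReadPair
from duplexmut.spectra import fixture_signatures


@pytest.fixture(scope="session")
def ref_small():
    """50 kb random reference at 42% GC, fixed seed."""
    return make_reference(50_000, 0.42, seed=7)


@pytest.fixture(scope="session")
def signatures():
    return fixture_signatures()


def make_pair(
    pair_id: str,
    seq: str,
    start: int = 0,
    contig: str = "sim1",
    r1_forward: bool = True,
    split: int | None = None,
) -> AlignedReadPair:
    """Build a fully covering read pair from a base string.

    With ``split`` the sequence is emitted as two overlapping mates
    ([0, split+1) and [split, end)) to exercise mate merging; otherwise one
    mate covers everything and a zero-length second window is omitted.
    """
    arr = encode(seq)
    end = start + arr.size
    if split is None:
        mates = ((start, arr),)
    else:
        mates = (
            (start, arr[: split + 1].copy()),
            (start + split, arr[split:].copy()),
        )
    return AlignedReadPair(pair_id, contig, start, end, r1_forward, mates)


# ---------------------------------------------------------------------------
# independent consensus oracle: a direct, per-position transcription of the
# unanimity / majority and duplex rules, built from the raw mate windows


def oracle_pair_observation(pair: AlignedReadPair, pos: int) -> str | None:
    """Merged observation of one pair at a position, from its mates only."""
    seen = []
    for mstart, mbases in pair.mates:
        if mstart <= pos < mstart + mbases.size:
            b = chr(mbases[pos - mstart])
            if b != "N":
                seen.append(b)
    if not seen:
        return None
    if len(set(seen)) > 1:
        return "?"
    return seen[0]


def oracle_strand_base(pairs, pos: int, rule: str = "unanimity") -> str:
    obs = [oracle_pair_observation(p, pos) for p in pairs]
    obs = [o for o in obs if o is not None]
    if not obs:
        return "N"
    if rule == "unanimity":
        if "?" in obs or len(set(obs)) > 1:
            return "N"
        return obs[0]
    # majority: strict plurality among real bases; any conflict vetoes
    if "?" in obs:
        return "N"
    counts = {b: obs.count(b) for b in set(obs)}
    best = max(counts.values())
    winners = [b for b, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else "N"


def oracle_duplex(
    group_pairs, start: int, end: int, min_pairs: int = 1, rule: str = "unanimity"
) -> str | None:
    plus = [p for p in group_pairs if p.r1_forward]
    minus = [p for p in group_pairs if not p.r1_forward]
    if len(plus) < min_pairs or len(minus) < min_pairs:
        return None
    out = []
    for pos in range(start, end):
        a = oracle_strand_base(plus, pos, rule)
        b = oracle_strand_base(minus, pos, rule)
        out.append(a if (a == b and a != "N") else "N")
    return "".join(out)


# ---------------------------------------------------------------------------
# independent decomposition oracle: exhaustive simplex grid search


def grid_search_weights(
    target: np.ndarray, matrix: np.ndarray, step: float = 0.01
) -> tuple[np.ndarray, float]:
    """Best weights (sum <= 1, resolution ``step``) minimising SSE, K <= 3."""
    k = matrix.shape[1]
    assert k <= 3, "grid oracle is exponential; keep K small"
    ticks = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    best_w, best_sse = None, np.inf
    for combo in itertools.product(ticks, repeat=k):
        if sum(combo) > 1.0 + 1e-9:
            continue
        w = np.asarray(combo)
        resid = target - matrix @ w
        sse = float(resid @ resid)
        if sse < best_sse:
            best_sse, best_w = sse, w
    return best_w, best_sse
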