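"""96-channel trinucleotide spectra, cosine similarity, decomposition.

Each single-base substitution is classified by its mutated base (folded to
the pyrimidine strand) and its 5'/3' reference flanks, giving the standard
96-channel mutational-signature representation. Channel frequencies divide
each channel's count by the number of sequenced duplex bases whose
reference trinucleotide matches that channel's context, scaled to events
per 1e6 — the same read-base accounting as the 6-class table.

Spectra are compared by cosine similarity and decomposed into non-negative
mixtures of reference signatures (e.g. COSMIC SBS columns) by greedy
forward selection with non-negative least-squares refitting — an
independent implementation of the approach popularised by deconstructSigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .calling import Denominators, MutationCall
from .reference import ReferenceGenome
from .substitutions import (
    CHANNELS,
    CHANNEL_TRINUC,
    channel_index,
)

__all__ = [
    "Spectrum96",
    "SignatureMatrix",
    "DecompositionResult",
    "classify_trinucleotide",
    "build_spectrum96",
    "cosine_similarity",
    "decompose_spectrum",
    "fixture_signatures",
]

logger = logging.getLogger(__name__)


def classify_trinucleotide(ref: ReferenceGenome, call: MutationCall) -> int:
    """96-channel index of a call, using reference flanks.

    Purine-centred calls are folded to the pyrimidine convention (base and
    flanks complemented, flanks swapped). Raises ``ValueError`` when a
    flank falls off the contig.
    """
    carr = ref.array(call.contig)
    if call.pos < 1 or call.pos > carr.size - 2:
        raise ValueError(
            f"call at {call.contig}:{call.pos} lacks a flanking base"
        )
    left = chr(carr[call.pos - 1])
    right = chr(carr[call.pos + 1])
    return channel_index(left, call.ref, call.alt, right)


@dataclass
class Spectrum96:
    """Counts, denominators and frequencies over the 96 channels."""

    counts: np.ndarray  # (96,) int
    denominators: np.ndarray  # (96,) int, matching-trinucleotide duplex bases
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.denominators = np.asarray(self.denominators, dtype=np.int64)
        if self.counts.shape != (96,) or self.denominators.shape != (96,):
            raise ValueError("Spectrum96 needs 96 counts and 96 denominators")

    @property
    def frequencies(self) -> np.ndarray:
        """Per-channel frequency per 1e6 matching duplex bases."""
        freq = np.zeros(96)
        nz = self.denominators > 0
        freq[nz] = self.counts[nz] / self.denominators[nz] * 1e6
        if (~nz & (self.counts > 0)).any():
            raise ValueError("channel with calls but zero denominator")
        return freq

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def vector(self, on: str = "frequencies") -> np.ndarray:
        if on == "frequencies":
            return self.frequencies
        if on == "counts":
            return self.counts.astype(float)
        raise ValueError("on must be 'frequencies' or 'counts'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": CHANNELS,
                "count": self.counts,
                "denominator_bp": self.denominators,
                "frequency_per_1e6": self.frequencies,
            }
        )

    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "") -> "Spectrum96":
        df = pd.read_csv(path, sep="\t", comment="#")
        if list(df["channel"]) != list(CHANNELS):
            raise ValueError(f"{path}: channels not in canonical order")
        return cls(
            df["count"].to_numpy(),
            df["denominator_bp"].to_numpy(),
            name or str(path),
        )


def build_spectrum96(
    calls,
    ref: ReferenceGenome,
    trinuc_denominators: Denominators | np.ndarray,
    name: str = "",
) -> Spectrum96:
    """Accumulate calls into a Spectrum96.

    Calls whose flanks fall off the contig are excluded with a logged
    count. Channel denominators are the 32 pyrimidine-centred trinucleotide
    duplex-base totals, broadcast to the three channels sharing each
    context (they must come from the same dsDCS bases as the calls).
    """
    trinuc = (
        trinuc_denominators.trinuc
        if isinstance(trinuc_denominators, Denominators)
        else np.asarray(trinuc_denominators, dtype=np.int64)
    )
    if trinuc.shape != (32,):
        raise ValueError("trinucleotide denominators must have 32 bins")
    counts = np.zeros(96, dtype=np.int64)
    excluded = 0
    for call in calls:
        try:
            counts[classify_trinucleotide(ref, call)] += 1
        except ValueError:
            excluded += 1
    if excluded:
        logger.info(
            "build_spectrum96: %d call(s) excluded (flank off contig)",
            excluded,
        )
    denominators = trinuc[CHANNEL_TRINUC]
    zero = (denominators == 0) & (counts == 0)
    if zero.any():
        logger.warning(
            "build_spectrum96: %d channel(s) have zero denominator",
            int(zero.sum()),
        )
    return Spectrum96(counts, denominators, name)


def cosine_similarity(a, b, on: str = "frequencies") -> float:
    """Cosine of two spectra (or raw 96-vectors): symmetric, scale-free."""
    va = a.vector(on) if isinstance(a, Spectrum96) else np.asarray(a, float)
    vb = b.vector(on) if isinstance(b, Spectrum96) else np.asarray(b, float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero spectrum")
    return float(np.dot(va, vb) / (na * nb))


@dataclass
class SignatureMatrix:
    """96 x K non-negative reference signatures, columns summing to 1."""

    names: list[str]
    matrix: np.ndarray  # (96, K)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError("signature matrix must be 96 x K")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column labels do not match matrix width")
        if (self.matrix < 0).any():
            raise ValueError("signatures must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("each signature column must sum to 1 (±1e-6)")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def subset(self, names: list[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.matrix[:, idx])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        if list(df.iloc[:, 0]) != list(CHANNELS):
            raise ValueError(f"{path}: first column must list the 96 channels")
        names = list(df.columns[1:])
        return cls(names, df.iloc[:, 1:].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.names)
        df.insert(0, "channel", CHANNELS)
        df.to_csv(path, sep="\t", index=False)


def fixture_signatures() -> SignatureMatrix:
    """The packaged synthetic signature fixture (no download needed)."""
    with resources.as_file(
        resources.files("duplexmut.data") / "signatures_synthetic.tsv"
    ) as p:
        return SignatureMatrix.from_tsv(p)


@dataclass
class DecompositionResult:
    """Outcome of the greedy non-negative signature decomposition."""

    names: list[str]
    weights: np.ndarray  # (K,), non-negative, sum <= 1
    reconstruction: np.ndarray  # (96,)
    rss: float
    inclusion_order: list[str]
    cosine: float  # cosine(input, reconstruction)

    @property
    def unassigned(self) -> float:
        return max(0.0, 1.0 - float(self.weights.sum()))

    def weight(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"signature": self.names, "weight": self.weights})


def _nnls_fit(
    target: np.ndarray, sigs: SignatureMatrix, selected: list[int]
) -> tuple[np.ndarray, float]:
    """Non-negative least squares with total weight constrained to <= 1.

    Plain NNLS first; if the unconstrained optimum exceeds total weight 1,
    the optimum of the constrained problem lies on the boundary, so refit
    with a heavy penalty row enforcing sum(w) = 1.
    """
    A = sigs.matrix[:, selected]
    w, _ = nnls(A, target)
    if w.sum() > 1.0:
        lam = 1e4
        A_aug = np.vstack([A, np.full((1, A.shape[1]), np.sqrt(lam))])
        b_aug = np.concatenate([target, [np.sqrt(lam)]])
        w, _ = nnls(A_aug, b_aug)
        if w.sum() > 1.0:
            w = w / w.sum()
    resid = target - A @ w
    return w, float(resid @ resid)


def decompose_spectrum(
    spectrum,
    sigs: SignatureMatrix,
    weight_cutoff: float = 0.06,
    tol: float = 1e-3,
    on: str = "counts",
) -> DecompositionResult:
    """Greedy forward selection of signatures with NNLS refitting.

    The input spectrum is normalised to sum 1. Starting from the empty set,
    the signature whose inclusion (with a full non-negative least-squares
    refit of all included weights) most reduces the residual sum of squares
    is added, until the relative improvement falls below ``tol``. Weights
    below ``weight_cutoff`` are then zeroed and the remainder refit once.
    """
    if sigs.k == 0:
        raise ValueError("signature matrix has no columns")
    vec = (
        spectrum.vector(on)
        if isinstance(spectrum, Spectrum96)
        else np.asarray(spectrum, dtype=float)
    )
    total = vec.sum()
    if total <= 0:
        raise ValueError("cannot decompose an empty spectrum")
    target = vec / total

    selected: list[int] = []
    rss = float(target @ target)
    order: list[str] = []
    while len(selected) < sigs.k:
        best = None
        for j in range(sigs.k):
            if j in selected:
                continue
            _, r = _nnls_fit(target, sigs, selected + [j])
            if best is None or r < best[1]:
                best = (j, r)
        assert best is not None
        j, new_rss = best
        if rss > 0 and (rss - new_rss) / rss < tol:
            break
        selected.append(j)
        order.append(sigs.names[j])
        rss = new_rss
        if rss <= 0:
            break

    weights = np.zeros(sigs.k)
    if selected:
        w, rss = _nnls_fit(target, sigs, selected)
        keep = [s for s, wi in zip(selected, w) if wi >= weight_cutoff]
        if keep != selected:
            if keep:
                w, rss = _nnls_fit(target, sigs, keep)
            else:
                w, rss = np.empty(0), float(target @ target)
            selected = keep
        for s, wi in zip(selected, w):
            weights[s] = wi

    recon = sigs.matrix @ weights
    cos = (
        cosine_similarity(target, recon)
        if np.linalg.norm(recon) > 0
        else 0.0
    )
    return DecompositionResult(
        names=list(sigs.names),
        weights=weights,
        reconstruction=recon,
        rss=float((target - recon) @ (target - recon)),
        inclusion_order=order,
        cosine=cos,
    )


def spectrum_barplot(spectrum: Spectrum96, path: str | Path) -> None:
    """Optional 96-channel bar chart export (matplotlib, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = ["#03bcee", "#010101", "#e32926", "#cac9c9", "#a1ce63", "#ebc6c4"]
    fig, ax = plt.subplots(figsize=(14, 3.5))
    freq = spectrum.frequencies
    for s in range(6):
        sl = slice(s * 16, (s + 1) * 16)
        ax.bar(np.arange(96)[sl], freq[sl], color=colors[s], width=0.8)
    ax.set_xticks(range(96))
    ax.set_xticklabels(
        [c.replace("[", "\n[") for c in CHANNELS], fontsize=4, rotation=90
    )
    ax.set_ylabel("frequency / 1e6 bp")
    if spectrum.name:
        ax.set_title(spectrum.name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
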