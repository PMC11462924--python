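"""End-to-end driver: simulate → consensus → call → spectrum → report.

One function runs the whole chain from a :class:`~duplexmut.config.RunConfig`
and writes every intermediate as a commented TSV/SAM/FASTA/VCF into the
output directory. All randomness flows from the config seed, so two runs of
the same config are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__
from .calling import (
    calls_to_frame,
    call_mutations,
    compute_frequency_table,
    load_position_mask,
    write_calls_vcf,
)
from .config import RunConfig
from .consensus import consensus_pipeline, write_duplex_tsv
from .reference import ReferenceGenome, make_reference
from .simulate import (
    MutationModel,
    PlatformErrorProfile,
    preset_profile,
    simulate_family_set,
    write_alignments,
)
from .spectra import build_spectrum96
from .substitutions import TRINUC32

logger = logging.getLogger(__name__)


def profile_from_config(spec) -> PlatformErrorProfile:
    if isinstance(spec, str):
        return preset_profile(spec)
    return PlatformErrorProfile.from_dict(spec)


def model_from_config(spec) -> MutationModel:
    return MutationModel.from_dict(spec or {})


def reference_from_config(cfg: RunConfig) -> ReferenceGenome:
    spec = cfg.reference
    if "fasta" in spec:
        return ReferenceGenome.from_fasta(spec["fasta"])
    return make_reference(
        int(spec["length"]), float(spec["gc_fraction"]), seed=cfg.seed
    )


def header_comment(cfg: RunConfig) -> str:
    return f"duplexmut {__version__} config={cfg.hash()} seed={cfg.seed}"


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run all stages; returns the in-memory objects keyed by stage name."""
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    comment = header_comment(cfg)
    cfg.to_yaml(out / "effective_config.yaml")

    ref = reference_from_config(cfg)
    ref.to_fasta(out / "reference.fa")

    sim = cfg.simulate
    readset = simulate_family_set(
        ref,
        int(sim["n_families"]),
        fragment_length=(float(sim["fragment_mean"]), float(sim["fragment_sd"])),
        reads_per_strand=tuple(sim["reads_per_strand"]),
        both_strand_prob=float(sim["both_strand_prob"]),
        model=model_from_config(sim.get("model")),
        profile=profile_from_config(sim.get("profile", "hiseq-like")),
        seed=cfg.seed,
    )
    sam_path = out / "reads.sam"
    write_alignments(readset, sam_path)
    readset.truth.to_tsv(out / "truth.tsv", comment=comment)

    duplexes, summary = consensus_pipeline(
        sam_path,
        min_pairs_per_strand=int(cfg.consensus["min_pairs_per_strand"]),
        rule=cfg.consensus["rule"],
    )
    write_duplex_tsv(duplexes, out / "dsdcs.tsv", comment=comment)
    with open(out / "consensus_summary.tsv", "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write("metric\tvalue\n")
        for key, value in vars(summary).items():
            fh.write(f"{key}\t{value}\n")

    mask = load_position_mask(cfg.calling.get("mask_paths", []))
    calls, denoms = call_mutations(duplexes, ref, mask)
    table = compute_frequency_table(
        calls, denoms, recurrence_k=int(cfg.calling.get("recurrence_k", 2))
    )
    with open(out / "calls.tsv", "w") as fh:
        fh.write(f"# {comment}\n")
        calls_to_frame(calls).to_csv(fh, sep="\t", index=False)
    write_calls_vcf(calls, out / "calls.vcf", ref.lengths, comment)
    table.to_tsv(out / "frequency_table.tsv", comment=comment)
    with open(out / "trinuc_denominators.tsv", "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write("trinucleotide\tduplex_bases\n")
        for label, count in zip(TRINUC32, denoms.trinuc):
            fh.write(f"{label}\t{int(count)}\n")

    spectrum = build_spectrum96(calls, ref, denoms, name="pipeline")
    spectrum.to_tsv(out / "spectrum96.tsv", comment=comment)

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"{comment}\n")
        fh.write(
            f"families={readset.n_families} pairs={summary.input_pairs} "
            f"spg={summary.n_groups} dsdcs={summary.n_duplex} "
            f"calls={len(calls)} om_per_1e6={table.om_frequency:.6g}\n"
        )
    logger.info("pipeline complete: %d dsDCS, %d calls", summary.n_duplex, len(calls))
    return {
        "reference": ref,
        "readset": readset,
        "duplexes": duplexes,
        "summary": summary,
        "calls": calls,
        "denominators": denoms,
        "frequency_table": table,
        "spectrum": spectrum,
        "outdir": out,
    }
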