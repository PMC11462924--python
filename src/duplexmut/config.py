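"""Run configuration: one serialisable object covering every stage."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters of a full simulate→consensus→call→spectrum→report run.

    Everything round-trips through plain YAML; the effective configuration
    of a run is echoed into its output directory and its hash stamped into
    every output table header.
    """

    seed: int = 0
    outdir: str = "duplexmut_run"
    reference: dict = field(
        default_factory=lambda: {"length": 200_000, "gc_fraction": 0.42}
    )
    simulate: dict = field(
        default_factory=lambda: {
            "n_families": 2000,
            "fragment_mean": 350.0,
            "fragment_sd": 50.0,
            "reads_per_strand": ["geometric", 2.0],
            "both_strand_prob": 0.8,
            "profile": "nextseq-like",
            "model": {"class_rates": {"G:C>T:A": 2.0e-6}},
        }
    )
    consensus: dict = field(
        default_factory=lambda: {"min_pairs_per_strand": 1, "rule": "unanimity"}
    )
    calling: dict = field(
        default_factory=lambda: {"mask_paths": [], "recurrence_k": 2}
    )
    spectrum: dict = field(default_factory=lambda: {"on": "frequencies"})
    decompose: dict = field(
        default_factory=lambda: {
            "tol": 1e-3,
            "weight_cutoff": 0.06,
            "signatures": "fixture",
        }
    )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                merged = dict(getattr(cfg, key))
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        """Short stable digest of the analysis parameters.

        The output directory is excluded: where results are written must not
        change what they contain, so two runs differing only in ``outdir``
        share a hash (and hence produce byte-identical tables).
        """
        d = self.to_dict()
        d.pop("outdir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
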