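"""Pipeline configuration: SL definitions, thresholds, file paths."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for an invalid or incomplete pipeline configuration."""


@dataclass
class Thresholds:
    """All tunable cutoffs, with their documented defaults."""

    motif_window: int = 100          # nt of 5' end searched for the SL motif
    min_classifiable: int = 15       # nt of SLe needed to call a type
    consensus_threshold: float = 0.60
    scan_min_pid: float = 0.95       # SLe identity for genomic loci
    min_intron: int = 40             # nt after the exon before contig end
    polyt_window: int = 120          # nt after the donor searched for poly-T
    upstream_window: int = 200       # genomic 5'UTR window for the cis check
    verify_min_pid: float = 0.95
    overlap_min_pid: float = 0.98
    overlap_min_len: int = 50
    n_perm: int = 100_000
    alpha: float = 0.05

    def validate(self):
        checks = [
            self.motif_window >= 8, 0 < self.consensus_threshold <= 1,
            0 < self.scan_min_pid <= 1, self.min_intron >= 0,
            self.polyt_window >= 6, self.upstream_window >= 0,
            0 < self.verify_min_pid <= 1, 0 < self.overlap_min_pid <= 1,
            self.overlap_min_len >= 1, self.n_perm >= 1, 0 < self.alpha < 1,
        ]
        if not all(checks):
            raise ConfigError("a threshold lies outside its documented range")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    system: str = "psinerae"         # SL system kind (see synthetic module)
    transcripts: str | None = None   # FASTA path (None -> simulate)
    genome: str | None = None
    counts: str | None = None
    go: str | None = None
    out: str = "slsplice_out"
    seed: int = 0
    simulate: bool = False
    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self):
        if self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        self.thresholds.validate()
        if not self.simulate and self.transcripts is None:
            raise ConfigError("transcripts path required unless simulating")
        for label, p in [("transcripts", self.transcripts),
                         ("genome", self.genome), ("counts", self.counts),
                         ("go", self.go)]:
            if not self.simulate and p is not None and not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**data.pop("thresholds", {}))
        return cls(thresholds=thr, **data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
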