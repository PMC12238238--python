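"""Run configuration: every stage threshold in one validated object.

Unknown keys in a YAML config are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml


@dataclasses.dataclass
class RunConfig:
    # inputs
    genomes_dir: str
    phenotype_tsv: str
    outdir: str
    seed: int = 0
    labels_tsv: str | None = None
    target_label: str = "OYE"
    marker_label: str = "marker"
    partner_label: str = "partner"
    reads_dir: str | None = None
    metadata_tsv: str | None = None
    group_a: str = "female"
    group_b: str = "male"
    # orthogroup screen
    min_bits: float = 50.0
    # alignment trimming / profile construction
    max_gap_frac: float = 0.95
    min_len: int = 0
    match_occupancy: float = 0.5
    pseudocount: float = 1.0
    evalue_ceiling: float = 1e-5
    null_n: int = 300
    # genomic context
    window_genes: int = 8
    window_bp: int = 10_000
    # phylogeny
    anchor_map: dict[str, list[str]] | None = None
    outgroup_genes: list[str] | None = None
    positions: list[int] = dataclasses.field(default_factory=list)
    # metagenome profiling
    kmer_size: int = 21
    theta: float = 0.3
    cpm_threshold: float = 1.0
    qc_min_reads: int = 1_000_000
    continuity: bool = True

    def __post_init__(self):
        checks = [
            (0.0 <= self.max_gap_frac <= 1.0, "max_gap_frac must be in [0, 1]"),
            (0.0 < self.match_occupancy <= 1.0, "match_occupancy must be in (0, 1]"),
            (self.pseudocount >= 0, "pseudocount must be non-negative"),
            (self.evalue_ceiling > 0, "evalue_ceiling must be positive"),
            (self.null_n >= 200, "null_n must be at least 200"),
            (self.window_genes >= 0, "window_genes must be non-negative"),
            (self.window_bp >= 0, "window_bp must be non-negative"),
            (0.0 < self.theta <= 1.0, "theta must be in (0, 1]"),
            (self.kmer_size >= 4, "kmer_size must be at least 4"),
            (self.cpm_threshold >= 0, "cpm_threshold must be non-negative"),
            (self.qc_min_reads >= 0, "qc_min_reads must be non-negative"),
            (self.min_len >= 0, "min_len must be non-negative"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full configuration (for output provenance)."""
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
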