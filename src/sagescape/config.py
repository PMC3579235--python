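"""Declarative pipeline configuration (YAML) with strict validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Every stage parameter with its study-derived default.

    Unknown keys in a config file are rejected; omitted keys fall back to
    these defaults.
    """

    # global
    seed: int = 0
    out_dir: str = "sagescape_out"

    # inputs (empty -> synthesize the study)
    fastq_dir: str = ""
    reference_fasta: str = ""
    design_tsv: str = ""
    annotation_tsv: str = ""
    go_obo: str = ""

    # synthetic study
    n_genes: int = 300
    variants_per_gene_rate: float = 0.3
    mean_len: int = 400
    frac_without_anchor: float = 0.1
    baseline_mean: float = 20.0
    dispersion: float = 0.2
    n_go_terms: int = 40
    n_immune_genes: int = 30
    immune_log2fc: float = 2.0
    n_river_down_genes: int = 30
    river_down_log2fc: float = 2.0
    error_rate: float = 0.0
    pcr_duplication_rate: float = 0.3

    # extraction
    barcode_len: int = 8
    tag_len: int = 26
    anchor: str = "CATG"

    # filtering
    artifact_ratio: float = 100.0
    min_libraries: int = 7

    # mapping
    max_mismatch: int = 1

    # multivariate statistics
    n_permutations: int = 999
    nmds_dims: int = 2
    nmds_starts: int = 20

    # differential expression
    alpha: float = 0.05
    prior_count: float = 0.125
    shrinkage_weight: float = 10.0

    # enrichment
    min_genes: int = 5

    def validate(self) -> "PipelineConfig":
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.min_libraries < 1:
            raise ValueError("min_libraries must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if self.tag_len <= len(self.anchor):
            raise ValueError("tag_len must exceed the anchor length")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.pcr_duplication_rate < 1:
            raise ValueError("pcr_duplication_rate must be in [0, 1)")
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def validate_config(path: str | Path | None = None,
                    overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Load a YAML config; unknown keys raise, defaults fill the rest."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a key-value mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return PipelineConfig(**data).validate()
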