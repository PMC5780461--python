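"""Pipeline configuration: a single YAML file, schema-validated.

Unknown keys are rejected; defaults are the conventional analysis
thresholds (local r=3 cpm / s=4 / alpha 0.05; distal r=25 cpm / s=10 /
FDR 0.01; 1000 permutations; enrichment and phenotype FDR 0.1). All
randomness derives from the global seed via named per-stage substreams.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThresholdBlock(_Strict):
    r_cpm: float
    s_min: int
    alpha: float
    mtc: str = "none"


class CompensationBlock(_Strict):
    n_boot: int = 10_000
    ci_level: float = 0.95
    s_min: int = 4


class EnrichmentBlock(_Strict):
    n_perm: int = 1000
    fdr: float = 0.1
    promoter_up: int = -2000
    promoter_down: int = 500


class PhenoBlock(_Strict):
    s_min: int = 10
    fdr: float = 0.1


class FinemapBlock(_Strict):
    bin_width: int = 10_000
    min_len: int = 1_000
    max_len: int = 1_000_000
    max_q0: float = 0.5
    min_quality: float = 10.0


class SimulateBlock(_Strict):
    n_sires: int = 9
    offspring_per_sire: int = 20
    n_genes: int = 1000


class PathsBlock(_Strict):
    calls: str | None = None
    regions: str | None = None
    counts: str | None = None
    annotation: str | None = None
    gebvs: str | None = None
    feature_track: str | None = None
    gene_sets: str | None = None
    chrom_sizes: str | None = None
    outdir: str = "cnvx_out"


class PipelineConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    min_overlap_frac: float = 0.5
    local: ThresholdBlock = Field(
        default_factory=lambda: ThresholdBlock(r_cpm=3.0, s_min=4, alpha=0.05, mtc="none"))
    distal: ThresholdBlock = Field(
        default_factory=lambda: ThresholdBlock(r_cpm=25.0, s_min=10, alpha=0.01, mtc="BH"))
    compensation: CompensationBlock = Field(default_factory=CompensationBlock)
    enrichment: EnrichmentBlock = Field(default_factory=EnrichmentBlock)
    pheno: PhenoBlock = Field(default_factory=PhenoBlock)
    finemap: FinemapBlock = Field(default_factory=FinemapBlock)
    simulate: SimulateBlock | None = None
    paths: PathsBlock = Field(default_factory=PathsBlock)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
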