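"""Pipeline configuration: YAML-backed, strictly validated.

Unknown keys are rejected rather than silently ignored, and every stochastic
stage draws its seed from the single global seed, so a config fully
determines the run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .containers import ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateBlock(_Strict):
    n_genes: int = 600
    n_cells_per_population: int = 120
    n_populations: int = 3
    n_markers: int = 30
    marker_log2fc: float = 3.0
    baseline_mean: float = 2.0
    dispersion: float = 0.2
    n_replicates: int = 2
    batch_sd: float = 0.3
    cycle_fraction: float = 0.15
    cycle_gene_count: int = 30
    contaminant_cells: int = 30
    reference_cells_per_population: int = 200
    reference_populations: int = 2  # first N populations present in the atlas


class PreprocessBlock(_Strict):
    min_genes: int = 50
    hvg_fraction: float = 0.05
    g2m_threshold: float = 0.2
    size_factor_method: str = "pooled"


class IntegrateBlock(_Strict):
    d: int = 30
    k: int = 20


class ClusterBlock(_Strict):
    resolution: float = 1.0
    snn_k: int = 10
    snn_d: int = 30
    min_cells: int = 10
    imbalance_threshold: float = 0.9


class TrajectoryBlock(_Strict):
    n_comps: int = 10
    k: int = 20


class DeBlock(_Strict):
    p_cut: float = 0.05
    fc_cut: float = 1.5
    top_n: int = 478
    max_clusters: int = 2  # marker tables for the largest N retained clusters


class TransferBlock(_Strict):
    k: int = 50
    confidence_threshold: float = 0.5
    distance_threshold: str | float = "quantile:99"
    min_cluster: int = 10
    hvg_fraction_ref: float = 0.10
    d: int = 30


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "cardiomap_out"
    simulate: SimulateBlock = Field(...)
    preprocess: PreprocessBlock = Field(...)
    integrate: IntegrateBlock = Field(...)
    cluster: ClusterBlock = Field(...)
    trajectory: TrajectoryBlock = Field(...)
    de: DeBlock = Field(...)
    transfer: TransferBlock = Field(...)

    def stage_seed(self, stage_index: int) -> int:
        return (self.seed * 1000003 + 7919 * stage_index + 1) % (2**31)


def default_config(seed: int = 0, outdir: str = "cardiomap_out") -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        simulate=SimulateBlock(),
        preprocess=PreprocessBlock(),
        integrate=IntegrateBlock(),
        cluster=ClusterBlock(),
        trajectory=TrajectoryBlock(),
        de=DeBlock(),
        transfer=TransferBlock(),
    )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(data)
    except PydanticValidationError as e:
        missing = [
            ".".join(str(x) for x in err["loc"])
            for err in e.errors()
            if err["type"] == "missing"
        ]
        if missing:
            raise ValidationError(f"config missing required block(s): {missing}") from e
        raise ValidationError(str(e)) from e


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
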