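"""Run configuration and provenance manifests.

A :class:`RunConfig` gathers the per-stage settings of the two pipelines
(training-time: simulate -> profile -> train; inference-time: debias ->
classify -> evaluate), round-trips losslessly through YAML, and derives
every stage seed deterministically from the global seed and the stage
name.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .utils import derive_seed, stable_digest


@dataclass
class SimulatorConfig:
    n_sources: int = 2
    n_batches_per_source: int = 2
    n_plates_per_batch: int = 1
    plate_rows: int = 4
    plate_cols: int = 6
    fovs_per_well: int = 1
    n_compounds: int = 12
    n_moa_classes: int = 3
    n_target_labels: int = 6
    allocation_bias: float = 2.0
    phenotype_dim: int = 7
    embedding_dim: int = 64
    phenotype_noise_sd: float = 0.3
    compound_scale: float = 2.0
    confounder_phenotype_scale: float = 0.6
    confounder_observation_scale: float = 0.5
    image_size: int = 64


@dataclass
class ProfilingConfig:
    illumination_radius: int = 7
    expected_radius: float = 4.0
    max_saturation: float = 0.5
    variance_floor: float = 1e-6
    correlation_ceiling: float = 0.95


@dataclass
class DiffusionStageConfig:
    num_train_steps: int = 250
    beta_start: float = 0.0015
    beta_end: float = 0.0205
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    hidden_dim: int = 384
    num_inference_steps: int = 50
    autoencoder_mode: str = "pca"


@dataclass
class AdjustmentStageConfig:
    n_combinations: int = 10
    images_per_combination: int = 1


@dataclass
class SubprofileConfig:
    threshold: float = 0.85
    n_ref_per_class: int = 3
    n_folds: int = 4
    min_class_size: int = 4


@dataclass
class MetricsConfig:
    n_permutations: int = 50


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/desk"
    log_level: str = "INFO"
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    diffusion: DiffusionStageConfig = field(default_factory=DiffusionStageConfig)
    adjustment: AdjustmentStageConfig = field(default_factory=AdjustmentStageConfig)
    subprofile: SubprofileConfig = field(default_factory=SubprofileConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for name, sub_cls in (
            ("simulator", SimulatorConfig),
            ("profiling", ProfilingConfig),
            ("diffusion", DiffusionStageConfig),
            ("adjustment", AdjustmentStageConfig),
            ("subprofile", SubprofileConfig),
            ("metrics", MetricsConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub_cls(**kwargs[name])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        return stable_digest(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        )


@dataclass
class RunManifest:
    config_digest: str
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    tool_version: str = "0.1.0"

    def record_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = stable_digest(path.read_bytes())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
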