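"""Run configuration: one dataclass per stage plus the global RunConfig.

Defaults are the method's reference hyperparameters: semantic decay delta=0.5,
kernel bandwidth scale mu'=0.5, autoencoder batch 128 / 100 epochs,
boosting depth 3 / 1200 trees / learning rate 0.1 / seed 0, hold-out split
8:2. YAML round-trip is supported for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from lncboost.autoencoder import AeTrainConfig
from lncboost.gradient_boosting import GbmConfig
from lncboost.profile_sim import GipConfig
from lncboost.semantic_sim import SemanticConfig


@dataclass
class FeatureConfig:
    layout: str = "FHN"
    mask_target: bool | None = None  # None: ON in strict mode, OFF in paper_faithful
    interaction_blocks: str = "both"  # both | disease_row | lncrna_col


@dataclass
class SamplingConfig:
    n_negatives: int | None = None  # None: balanced 1:1 with positives
    seed: int = 0


@dataclass
class EvalConfig:
    threshold: float = 0.5
    holdout_ratio: float = 0.8
    k_folds: int = 10
    stratified: bool = True


@dataclass
class RunConfig:
    semantic: SemanticConfig = field(default_factory=SemanticConfig)
    gip: GipConfig = field(default_factory=GipConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    autoencoder: AeTrainConfig = field(default_factory=AeTrainConfig)
    gbm: GbmConfig = field(default_factory=GbmConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    mode: str = "strict"  # strict | paper_faithful
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "paper_faithful"):
            raise ValueError("mode must be 'strict' or 'paper_faithful'")

    @property
    def mask_target(self) -> bool:
        if self.features.mask_target is not None:
            return self.features.mask_target
        return self.mode == "strict"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resolved_mask_target"] = self.mask_target
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("resolved_mask_target", None)
        return cls(
            semantic=SemanticConfig(**d.pop("semantic", {})),
            gip=GipConfig(**d.pop("gip", {})),
            features=FeatureConfig(**d.pop("features", {})),
            autoencoder=AeTrainConfig(**d.pop("autoencoder", {})),
            gbm=GbmConfig(**d.pop("gbm", {})),
            sampling=SamplingConfig(**d.pop("sampling", {})),
            evaluation=EvalConfig(**d.pop("evaluation", {})),
            **d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
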