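"""Structured pipeline configuration (YAML in, dataclasses out).

One file is the single source of every tunable; the effective config is
embedded in outputs for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import CnnConfig
from .preprocess import DEFAULT_FALLBACKS, DEFAULT_PAIRS, MontageSpec
from .tfd import DEVELOPMENT_KERNEL, VALIDATION_KERNEL, TfdKernelParams
from .train import TrainConfig

__all__ = ["PipelineConfig", "KERNEL_PRESETS"]

KERNEL_PRESETS = {
    "development": DEVELOPMENT_KERNEL,
    "validation": VALIDATION_KERNEL,
}


@dataclass
class PipelineConfig:
    montage_pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_PAIRS])
    montage_fallbacks: dict = field(default_factory=lambda: dict(DEFAULT_FALLBACKS))
    lowpass_hz: float = 30.0
    fir_taps: int = 4001
    target_fs: float = 64.0
    tfd_preset: str = "development"
    voting_scheme: str = "two-step"
    tie_rule: str = "severe"
    channels: int = 8
    stage1_threshold_uv: float = 300.0
    stage1_collar_s: float = 10.0
    stage2_threshold_uv: float = 100.0
    stage2_collar_s: float = 3.0
    lr0: float = 0.01
    lr_decay: float = 0.8
    decay_every: int = 5
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tfd_preset not in KERNEL_PRESETS:
            raise ValueError(
                f"tfd_preset must be one of {sorted(KERNEL_PRESETS)}"
            )
        if self.voting_scheme not in ("one-step", "two-step"):
            raise ValueError("voting_scheme must be 'one-step' or 'two-step'")
        self.kernel()  # validates window/grid constraints

    def kernel(self) -> TfdKernelParams:
        return KERNEL_PRESETS[self.tfd_preset]

    def montage(self) -> MontageSpec:
        return MontageSpec(
            pairs=[tuple(p) for p in self.montage_pairs],
            fallbacks=dict(self.montage_fallbacks),
        )

    def cnn(self) -> CnnConfig:
        return CnnConfig(seed=self.seed)

    def train(self) -> TrainConfig:
        return TrainConfig(
            lr0=self.lr0,
            lr_decay=self.lr_decay,
            decay_every=self.decay_every,
            momentum=self.momentum,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
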