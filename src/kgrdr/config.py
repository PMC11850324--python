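"""Run configuration: one flat key set covering every stage.

Two built-in profiles: ``desk`` (small dimensions/epochs for laptop-scale
fixtures, the default) and ``paper`` (the published full-scale settings).
Unknown keys are rejected; every run writes its resolved config next to its
outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError

VARIANTS = ("full", "no_kg", "no_gri", "no_kg_gri")


@dataclass
class RunConfig:
    # predictor
    epoch: int = 300
    embedding_dim: int = 32
    learning_rate: float = 5e-2
    layer_num: int = 2
    topk: int = 15
    dropout: float = 0.4
    edge_dropout: float = 0.2
    optimizer: str = "adam"
    # similarity integration
    GR_dim: int = 32
    alpha: float = 0.8
    lambda_reg: float = 10.0
    K_neighbors: int = 20
    entropy_quantile: float = 0.75
    redundancy_threshold: float = 0.8
    gip_gamma: float = 1.0
    # knowledge-graph embedding
    KG_dim: int = 32
    KG_lr: float = 0.1
    KG_regularization: float = 1e-7
    KG_epochs: int = 200
    KG_n_neg: int = 2
    KG_batch_size: int = 512
    dd_relation: str = "drug:disease"
    # fusion
    channels: int = 16
    ratio: int = 4
    # evaluation / orchestration
    folds: int = 10
    variant: str = "full"
    profile: str = "desk"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.optimizer.lower() != "adam":
            raise ConfigError(f"only the adam optimizer is supported, got {self.optimizer!r}")
        if self.KG_dim % 2 != 0:
            raise ConfigError("KG_dim must be even (real+imaginary concatenation)")
        if self.variant == "full" and self.GR_dim != self.KG_dim:
            raise ConfigError(
                "fusion requires equal feature widths: set GR_dim == KG_dim "
                f"(got {self.GR_dim} vs {self.KG_dim})"
            )

    @property
    def kg_k(self) -> int:
        """Complex embedding dimension (feature width is 2k)."""
        return self.KG_dim // 2

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **overrides) -> "RunConfig":
        data = self.to_dict()
        data.update(overrides)
        return RunConfig.from_dict(data)


PROFILES: dict[str, dict] = {
    "desk": {},  # dataclass defaults
    "paper": {
        "epoch": 4096,
        "embedding_dim": 128,
        "learning_rate": 5e-2,
        "layer_num": 2,
        "topk": 15,
        "dropout": 0.4,
        "edge_dropout": 0.2,
        "GR_dim": 500,
        "KG_dim": 500,
        "KG_lr": 0.1,
        "KG_regularization": 1e-7,
    },
}


def _known_keys() -> set[str]:
    return {f.name for f in fields(RunConfig)}


def config_from_dict(data: dict, profile: str = "desk") -> RunConfig:
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    unknown = set(data) - _known_keys()
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(PROFILES[profile], profile=profile)
    merged.update(data)
    return RunConfig(**merged)


# keep the classmethod-style entry point on the dataclass too
RunConfig.from_dict = staticmethod(config_from_dict)  # type: ignore[attr-defined]


def load_config(path: str | Path | None, profile: str = "desk", **overrides) -> RunConfig:
    """Load a flat YAML key-value file; CLI overrides beat file values."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return config_from_dict(data, profile=profile)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
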