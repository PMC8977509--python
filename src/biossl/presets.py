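"""Named network configs, run configuration and hyperparameter presets."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .model_core import ConfigurationError

_CONFIG_DIR = Path(__file__).parent / "configs"

NETWORK_CONFIGS = {p.stem: p for p in sorted(_CONFIG_DIR.glob("*.yaml"))}

TRAINERS = ("e2e", "gll", "rll", "dtp")
RULES = ("bp", "rf", "urf")


def network_config(name_or_path) -> dict:
    """Load a network config by preset name or YAML/JSON file path."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml", ".json") and p.exists():
        return yaml.safe_load(p.read_text())
    if str(name_or_path) in NETWORK_CONFIGS:
        return yaml.safe_load(NETWORK_CONFIGS[str(name_or_path)].read_text())
    raise ConfigurationError(
        f"unknown network config {name_or_path!r}; "
        f"available presets: {sorted(NETWORK_CONFIGS)}"
    )


@dataclass
class RunConfig:
    """Full description of a pretraining run; every run is reproducible
    from this object plus its seed (no wall-clock seeding anywhere)."""

    network: str = "synth_small"
    loss: str = "hinge"  # hinge | simclr (simclr: evaluation-only baseline)
    m1: float = 1.0
    m2: float = 1.5
    T: int = 5
    block_gradient: bool = True
    calibrate_margins: bool = False  # derive m1/m2 from initial histograms
    trainer: str = "e2e"  # e2e | gll | rll | dtp
    rule: str = "bp"  # bp | rf | urf (ignored by dtp)
    optimizer: str = "adam"
    lr: float = 1e-3
    inverse_lr: float = 1e-3  # dtp autoencoder learning rate
    steps: int = 200
    batch_size: int = 32
    embed_dim: int = 64
    seed: int = 0
    crop_size: int = 28
    crop_scale: tuple = (0.5, 1.0)
    flip_prob: float = 0.5
    jitter: tuple = (0.4, 0.4, 0.0, 0.0)
    grayscale_prob: float = 0.0

    def validate(self) -> "RunConfig":
        if self.trainer not in TRAINERS:
            raise ConfigurationError(f"trainer must be one of {TRAINERS}")
        if self.rule not in RULES:
            raise ConfigurationError(f"rule must be one of {RULES}")
        if self.trainer == "dtp" and self.rule in ("rf", "urf"):
            raise ConfigurationError(
                "DTP has its own credit assignment; it cannot be combined "
                "with random-feedback rules"
            )
        if self.loss == "simclr":
            raise ConfigurationError(
                "the SimCLR loss is an evaluation-only baseline here; "
                "pretraining uses the contrastive hinge loss"
            )
        if self.loss != "hinge":
            raise ConfigurationError(f"unknown loss {self.loss!r}")
        return self

    def as_dict(self) -> dict:
        d = asdict(self)
        d["crop_scale"] = list(self.crop_scale)
        d["jitter"] = list(self.jitter)
        return d


# run presets mirroring the published hyperparameters at their scale plus a
# desk-scale default; the CIFAR/MNIST presets assume externally supplied data
RUN_PRESETS = {
    "cifar-hinge-gll": dict(
        network="cifar_encoder", m1=1.0, m2=3.0, T=5, trainer="gll",
        rule="bp", optimizer="adam", lr=1e-4, batch_size=500, crop_size=32,
        crop_scale=(0.2, 1.0), jitter=(0.4, 0.4, 0.4, 0.1), grayscale_prob=0.1,
    ),
    "cifar-hinge-e2e": dict(
        network="cifar_encoder", m1=1.0, m2=3.0, T=5, trainer="e2e",
        rule="bp", optimizer="adam", lr=1e-4, batch_size=500, crop_size=32,
        crop_scale=(0.2, 1.0), jitter=(0.4, 0.4, 0.4, 0.1), grayscale_prob=0.1,
    ),
    "cifar-hinge-dtp": dict(
        network="cifar_encoder", m1=1.0, m2=3.0, T=5, trainer="dtp",
        optimizer="adam", lr=1e-4, inverse_lr=1e-3, batch_size=500,
        crop_size=32, crop_scale=(0.2, 1.0), jitter=(0.4, 0.4, 0.4, 0.1),
        grayscale_prob=0.1,
    ),
    "mnist-hinge-e2e": dict(
        network="mnist_encoder", m1=1.0, m2=1.5, T=5, trainer="e2e",
        rule="bp", optimizer="adam", lr=1e-4, batch_size=1000, crop_size=28,
    ),
    "synth-quick": dict(
        network="synth_small", trainer="e2e", rule="bp", optimizer="adam",
        lr=1e-3, steps=200, batch_size=32, calibrate_margins=True,
    ),
}


def run_config(preset: str | None = None, **overrides) -> RunConfig:
    if preset and preset not in RUN_PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; available: {sorted(RUN_PRESETS)}"
        )
    base = dict(RUN_PRESETS[preset]) if preset else {}
    base.update(overrides)
    return RunConfig(**base).validate()
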