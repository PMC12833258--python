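"""Configuration objects pinning every architectural and training choice.

The published architecture leaves several widths unstated (LoRA rank,
adapter bottleneck, decoder channels); they are pinned here in one place
and exposed through YAML config files so experiments stay reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class BlockConfig:
    """Transformer-encoder dimensions and fine-tuning widths."""
    depth: int = 12
    embed_dim: int = 768
    num_heads: int = 12
    patch_size: int = 16
    in_channels: int = 1
    mlp_ratio: int = 4
    tap_depths: tuple[int, ...] = (3, 6, 9, 12)
    lora_rank: int = 4
    adapter_bottleneck: int = 64
    adapter_variant: str = "mlp_residual"   # or "serial_adapter"
    use_lora: bool = True
    use_adapter: bool = True
    input_size: int = 224

    def __post_init__(self):
        if self.embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        if any(t > self.depth or t < 1 for t in self.tap_depths):
            raise ValueError(f"tap depths {self.tap_depths} exceed depth {self.depth}")
        if list(self.tap_depths) != sorted(set(self.tap_depths)):
            raise ValueError("tap depths must be strictly increasing")
        if self.adapter_variant not in ("mlp_residual", "serial_adapter"):
            raise ValueError(f"unknown adapter variant '{self.adapter_variant}'")
        if self.lora_rank > self.embed_dim:
            raise ValueError("LoRA rank exceeds embedding dimension")


@dataclass
class MhpmConfig:
    """Multi-scale hypercolumn processing: four dilated branches + attention."""
    in_channels: int = 768
    dilations: tuple[int, ...] = (1, 1, 2, 3)
    kernels: tuple[int, ...] = (1, 3, 3, 3)
    deconv_stride: int = 2
    out_channels: int = 256

    def __post_init__(self):
        if len(self.dilations) != 4 or len(self.kernels) != 4:
            raise ValueError("exactly four dilated branches are required")
        if self.in_channels % 4:
            raise ValueError("in_channels must be divisible by 4 (quarter reduction)")


@dataclass
class HfmConfig:
    """Hierarchical fusion: global gate, k regional group gates, local projection."""
    channels: int = 256
    groups: int = 4

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError("groups must be >= 1")
        if self.channels % self.groups:
            raise ValueError(
                f"channels ({self.channels}) not divisible by groups ({self.groups})")


@dataclass
class ModelConfig:
    encoder: BlockConfig = field(default_factory=BlockConfig)
    mhpm: MhpmConfig = field(default_factory=MhpmConfig)
    hfm: HfmConfig = field(default_factory=HfmConfig)
    num_classes: int = 3
    use_mhpm: bool = True
    use_hfm: bool = True
    use_decoder: bool = True          # the hierarchical-fusion pyramid decoder
    supervise_fused: bool = True

    def __post_init__(self):
        if self.mhpm.in_channels != self.encoder.embed_dim:
            raise ValueError("mhpm.in_channels must equal encoder embed_dim")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 0.1
    lr_drop_every: int = 20
    lr_drop_factor: float = 0.1
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0
    augment: bool = True
    multi_scale_loss: bool = True
    max_steps: int | None = None

    def __post_init__(self):
        if self.lr <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("lr, epochs and batch_size must all be positive")


# Ablation ladder: each named preset switches one more component on, from the
# frozen backbone with a bare linear head (A) up to the full model (G).
_ABLATION_FLAGS = ("lora", "adapter", "decoder", "hfm", "mhpm", "multi_loss")

ABLATION_PRESETS = {
    "A": dict(lora=False, adapter=False, decoder=False, hfm=False, mhpm=False, multi_loss=False),
    "B": dict(lora=True, adapter=False, decoder=False, hfm=False, mhpm=False, multi_loss=False),
    "C": dict(lora=True, adapter=True, decoder=False, hfm=False, mhpm=False, multi_loss=False),
    "D": dict(lora=True, adapter=True, decoder=True, hfm=False, mhpm=False, multi_loss=False),
    "E": dict(lora=True, adapter=True, decoder=True, hfm=True, mhpm=False, multi_loss=False),
    "F": dict(lora=True, adapter=True, decoder=True, hfm=True, mhpm=True, multi_loss=False),
    "G": dict(lora=True, adapter=True, decoder=True, hfm=True, mhpm=True, multi_loss=True),
}


@dataclass
class AblationConfig:
    lora: bool = True
    adapter: bool = True
    decoder: bool = True
    hfm: bool = True
    mhpm: bool = True
    multi_loss: bool = True

    def __post_init__(self):
        if self.hfm and not self.decoder:
            raise ValueError("hfm requires decoder")
        if self.multi_loss and not self.decoder:
            raise ValueError("multi_loss requires decoder")

    @classmethod
    def preset(cls, name: str) -> "AblationConfig":
        if name not in ABLATION_PRESETS:
            raise ValueError(f"unknown ablation preset '{name}' (use A..G)")
        return cls(**ABLATION_PRESETS[name])


def tiny_model_config() -> ModelConfig:
    """CPU-sized preset: depth stays 12 so the usual taps remain valid."""
    enc = BlockConfig(depth=12, embed_dim=96, num_heads=3, patch_size=16,
                      lora_rank=4, adapter_bottleneck=16, input_size=64)
    # deconv factor 4: at a 64-px input the decoder then sits on a 16×16 grid,
    # fine enough to represent the smallest lesions the phantom spec draws
    return ModelConfig(encoder=enc,
                       mhpm=MhpmConfig(in_channels=96, out_channels=32,
                                       deconv_stride=4),
                       hfm=HfmConfig(channels=32, groups=4))


def base_model_config() -> ModelConfig:
    """ViT-B-sized preset (the published backbone scale)."""
    return ModelConfig()


PRESETS = {"tiny": tiny_model_config, "base": base_model_config}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _tupled(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(model: ModelConfig, train: TrainConfig, path: str | Path):
    with open(path, "w") as fh:
        yaml.safe_dump({"model": _to_plain(model), "train": _to_plain(train)}, fh,
                       sort_keys=False)


def load_config(path: str | Path) -> tuple[ModelConfig, TrainConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    m = raw.get("model", {})
    model = ModelConfig(
        encoder=_tupled(BlockConfig, m.get("encoder", {})),
        mhpm=_tupled(MhpmConfig, m.get("mhpm", {})),
        hfm=_tupled(HfmConfig, m.get("hfm", {})),
        **{k: v for k, v in m.items() if k not in ("encoder", "mhpm", "hfm")},
    )
    train = _tupled(TrainConfig, raw.get("train", {}))
    return model, train
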