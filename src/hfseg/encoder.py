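"""Frozen ViT image encoder with LoRA and bottleneck-adapter fine-tuning.

The backbone is a plain pre-norm ViT: patch embedding, learned positional
embedding, then ``depth`` transformer blocks of multi-head self-attention
and an MLP.  All backbone weights are frozen; the only trainable pieces
are low-rank (LoRA) corrections on the Query and Value projections of
every block and a small bottleneck adapter (down-project, ReLU,
up-project) after each MLP.  Token sequences are tapped at configurable
block depths and reshaped into spatial feature maps for the decoder.

LoRA up-projections and adapter up-projections are zero-initialised, so a
freshly built model computes exactly the frozen backbone's function
("identity at initialisation") — the property that makes frozen-backbone
fine-tuning start from the pretrained behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import BlockConfig
from .nn import Tensor
from .nn.tensor import softmax


class LoraLinear(nn.Module):
    """Frozen linear projection plus a trainable low-rank correction.

    y = W x + U (D x): W (frozen, D_out×D_in), D (r×D_in, small-normal
    init), U (D_out×r, zero init).  With U = 0 the layer is exactly the
    base projection.
    """

    def __init__(self, in_features: int, out_features: int, rank: int,
                 rng: np.random.Generator, enabled: bool = True):
        super().__init__()
        if rank > min(in_features, out_features):
            raise ValueError(f"LoRA rank {rank} exceeds min(D_in, D_out)")
        self.base = nn.Linear(in_features, out_features, rng)
        self.enabled = enabled
        if enabled:
            self.lora_down = Tensor(rng.normal(0.0, 0.02, (rank, in_features)),
                                    requires_grad=True)
            self.lora_up = Tensor(np.zeros((out_features, rank)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        y = self.base(x)
        if self.enabled:
            y = y + (x @ self.lora_down.transpose(1, 0)) @ self.lora_up.transpose(1, 0)
        return y


class Adapter(nn.Module):
    """Bottleneck adapter: up(ReLU(down(x))), up-projection zero-initialised."""

    def __init__(self, dim: int, bottleneck: int, rng: np.random.Generator):
        super().__init__()
        self.adapter_down = nn.Linear(dim, bottleneck, rng)
        self.adapter_up = nn.Linear(bottleneck, dim, rng)
        self.adapter_up.weight.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return self.adapter_up(self.adapter_down(x).relu())


class EncoderBlock(nn.Module):
    """Pre-norm transformer block with LoRA on Q/V and a post-MLP adapter."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        d, h = cfg.embed_dim, cfg.num_heads
        self.num_heads = h
        self.head_dim = d // h
        self.variant = cfg.adapter_variant
        self.ln1 = nn.LayerNorm(d)
        self.q_proj = LoraLinear(d, d, cfg.lora_rank, rng, enabled=cfg.use_lora)
        self.k_proj = nn.Linear(d, d, rng)          # Key carries no low-rank term
        self.v_proj = LoraLinear(d, d, cfg.lora_rank, rng, enabled=cfg.use_lora)
        self.out_proj = nn.Linear(d, d, rng)
        self.ln2 = nn.LayerNorm(d)
        self.fc1 = nn.Linear(d, d * cfg.mlp_ratio, rng)
        self.fc2 = nn.Linear(d * cfg.mlp_ratio, d, rng)
        self.adapter = Adapter(d, cfg.adapter_bottleneck, rng) if cfg.use_adapter else None

    def attention(self, x: Tensor) -> Tensor:
        """Multi-head self-attention sub-block with residual (x_bar)."""
        b, n, d = x.shape
        h = self.ln1(x)
        q = self.q_proj(h)
        k = self.k_proj(h)
        v = self.v_proj(h)

        def split(t):  # (B, N, D) -> (B, heads, N, head_dim)
            return t.reshape(b, n, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

        qh, kh, vh = split(q), split(k), split(v)
        logits = (qh @ kh.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5)
        if not np.isfinite(logits.data).all():
            raise FloatingPointError("non-finite attention logits")
        att = softmax(logits, axis=-1)
        ctx = (att @ vh).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.out_proj(ctx) + x

    def forward(self, x: Tensor) -> Tensor:
        x_bar = self.attention(x)
        x_hat = self.fc2(self.fc1(self.ln2(x_bar)).gelu())
        if self.adapter is None:
            return x_bar + x_hat
        if self.variant == "mlp_residual":
            return x_bar + x_hat + self.adapter(x_hat)
        # "serial_adapter": the adapter output replaces the MLP residual path
        return self.adapter(x_hat) + x_bar


class PatchEmbed(nn.Module):
    """Non-overlapping patch flattening + linear projection."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        self.patch = cfg.patch_size
        self.in_ch = cfg.in_channels
        self.proj = nn.Linear(cfg.in_channels * self.patch ** 2, cfg.embed_dim, rng)

    def tokens(self, image: Tensor) -> Tensor:
        """(B, C, H, W) -> (B, N, C*p*p) patch vectors, row-major patch order."""
        b, c, hh, ww = image.shape
        p = self.patch
        if hh % p or ww % p:
            raise ValueError(f"image size {hh}x{ww} not divisible by patch {p}")
        gh, gw = hh // p, ww // p
        t = image.reshape(b, c, gh, p, gw, p).transpose(0, 2, 4, 1, 3, 5)
        return t.reshape(b, gh * gw, c * p * p)

    def forward(self, image: Tensor) -> Tensor:
        return self.proj(self.tokens(image))


@dataclass
class EncoderTaps:
    """Spatial feature maps tapped at increasing block depths.

    All maps share one spatial resolution (H/patch × W/patch), so the
    decoder never needs to resample them before fusing.
    """
    maps: dict[int, Tensor]

    def __post_init__(self):
        depths = list(self.maps)
        if depths != sorted(depths):
            raise ValueError("tap depths must be increasing")
        shapes = {m.shape[2:] for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError(f"tapped maps disagree in spatial shape: {shapes}")

    def __getitem__(self, depth: int) -> Tensor:
        return self.maps[depth]

    @property
    def depths(self) -> tuple[int, ...]:
        return tuple(self.maps)

    @property
    def spatial(self) -> tuple[int, int]:
        first = next(iter(self.maps.values()))
        return first.shape[2], first.shape[3]


class ViTEncoder(nn.Module):
    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.patch_embed = PatchEmbed(cfg, rng)
        n_tokens = (cfg.input_size // cfg.patch_size) ** 2
        self.pos_embed = Tensor(rng.normal(0.0, 0.02, (1, n_tokens, cfg.embed_dim)),
                                requires_grad=True)
        self.blocks = nn.ModuleList(EncoderBlock(cfg, rng) for _ in range(cfg.depth))
        set_freeze_policy(self)

    def forward(self, image: Tensor | np.ndarray) -> EncoderTaps:
        return self.encode(image)

    def encode(self, image: Tensor | np.ndarray) -> EncoderTaps:
        """Run the blocks and collect tapped token maps as (B, D, h, w) grids."""
        if not isinstance(image, Tensor):
            image = Tensor(image)
        b = image.shape[0]
        p = self.cfg.patch_size
        gh, gw = image.shape[2] // p, image.shape[3] // p
        x = self.patch_embed(image)
        if x.shape[1] != self.pos_embed.shape[1]:
            raise ValueError(
                f"got {x.shape[1]} tokens but positional embedding holds "
                f"{self.pos_embed.shape[1]} (configured input size "
                f"{self.cfg.input_size})")
        x = x + self.pos_embed
        taps: dict[int, Tensor] = {}
        want = set(self.cfg.tap_depths)
        for i, block in enumerate(self.blocks, start=1):
            x = block(x)
            if i in want:
                taps[i] = x.transpose(0, 2, 1).reshape(b, self.cfg.embed_dim, gh, gw)
        return EncoderTaps(taps)


@dataclass
class FreezeReport:
    frozen: int
    trainable: int

    @property
    def total(self) -> int:
        return self.frozen + self.trainable


_TRAINABLE_MARKERS = ("lora_down", "lora_up", "adapter_down", "adapter_up")


def set_freeze_policy(encoder: nn.Module) -> FreezeReport:
    """Freeze every backbone weight; leave LoRA and adapter weights trainable.

    Patch embedding, positional embedding, layer norms and all attention /
    MLP base projections are frozen; returns per-category counts.
    """
    frozen = trainable = 0
    for name, p in encoder.named_parameters():
        if any(marker in name for marker in _TRAINABLE_MARKERS):
            p.requires_grad = True
            trainable += p.size
        else:
            p.requires_grad = False
            frozen += p.size
    return FreezeReport(frozen=frozen, trainable=trainable)


def load_pretrained(encoder: ViTEncoder, path, name_map=None, strict: bool = False):
    """Optionally import backbone weights from an ``npz`` archive.

    `name_map` translates archive keys to this package's parameter paths.
    Keys absent from the archive are silently left at initialisation
    unless `strict`; shape mismatches always raise.
    """
    archive = np.load(path)
    params = dict(encoder.named_parameters())
    name_map = name_map or {}
    loaded = 0
    for key in archive.files:
        target = name_map.get(key, key)
        if target not in params:
            if strict:
                raise KeyError(f"no parameter named '{target}'")
            continue
        if params[target].data.shape != archive[key].shape:
            raise ValueError(f"shape mismatch for '{target}'")
        params[target].data = archive[key].astype(np.float64)
        loaded += 1
    return loaded
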