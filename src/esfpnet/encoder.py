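"""Mix Transformer (MiT) hierarchical encoder.

The encoder processes an H x H RGB frame through four stages, each built
from an overlapping patch-merging convolution followed by transformer
blocks whose self-attention computes keys/values on a spatially reduced
copy of the token grid (spatial-reduction attention) and whose feed-forward
network carries positional information through a 3x3 depth-wise
convolution (Mix-FFN).  Stage i halves the spatial side relative to stage
i-1, giving feature maps at 1/4, 1/8, 1/16 and 1/32 of the input side with
channel widths C1 < C2 < C3 < C4.

Three pinned variants are provided: B0 (tiny), B2 (standard) and B4
(large).  Channel widths are B0 = (32, 64, 160, 256) and B2/B4 =
(64, 128, 320, 512); depths, head counts and reduction ratios follow the
published SegFormer MiT configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "EncoderVariantSpec",
    "ENCODER_VARIANTS",
    "MiTEncoder",
    "make_encoder",
    "attention_heatmap",
]


@dataclass(frozen=True)
class EncoderVariantSpec:
    """Structural description of one MiT variant."""

    variant_id: str
    stage_channels: tuple[int, int, int, int]
    stage_depths: tuple[int, int, int, int]
    stage_heads: tuple[int, int, int, int] = (1, 2, 5, 8)
    sr_ratios: tuple[int, int, int, int] = (8, 4, 2, 1)
    mlp_ratio: int = 4
    # (kernel, stride, padding) per stage patch embedding
    patch_embed_params: tuple[tuple[int, int, int], ...] = (
        (7, 4, 3),
        (3, 2, 1),
        (3, 2, 1),
        (3, 2, 1),
    )

    def __post_init__(self) -> None:
        c = self.stage_channels
        if len(c) != 4 or not (c[0] < c[1] < c[2] < c[3]):
            raise ValueError("stage channels must be 4 strictly increasing widths")


ENCODER_VARIANTS: dict[str, EncoderVariantSpec] = {
    "B0": EncoderVariantSpec("B0", (32, 64, 160, 256), (2, 2, 2, 2)),
    "B2": EncoderVariantSpec("B2", (64, 128, 320, 512), (3, 4, 6, 3)),
    "B4": EncoderVariantSpec("B4", (64, 128, 320, 512), (3, 8, 27, 3)),
}
# model-size aliases: tiny / standard / large
VARIANT_ALIASES = {"T": "B0", "S": "B2", "L": "B4"}


def resolve_variant(variant: str) -> EncoderVariantSpec:
    key = VARIANT_ALIASES.get(variant.upper(), variant.upper())
    try:
        return ENCODER_VARIANTS[key]
    except KeyError:
        raise ValueError(
            f"unknown encoder variant {variant!r}; expected one of "
            f"{sorted(ENCODER_VARIANTS)} or aliases {sorted(VARIANT_ALIASES)}"
        ) from None


def _seq_to_spatial(x: Tensor, h: int, w: int) -> Tensor:
    b, n, c = x.shape
    return x.reshape(b, h, w, c).transpose(0, 3, 1, 2)


def _spatial_to_seq(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    return x.transpose(0, 2, 3, 1).reshape(b, h * w, c)


class OverlapPatchEmbed(nn.Module):
    def __init__(self, in_ch: int, embed_dim: int, k: int, stride: int, pad: int, rng):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, embed_dim, k, rng, stride=stride, padding=pad)
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, x: Tensor) -> tuple[Tensor, int, int]:
        x = self.proj(x)
        _, _, h, w = x.shape
        return self.norm(_spatial_to_seq(x)), h, w


class EfficientSelfAttention(nn.Module):
    """Multi-head self-attention with spatially reduced keys/values.

    For reduction ratio R > 1 the token grid is downsampled by an RxR
    strided convolution before the key/value projections, shrinking the
    attention matrix from N x N to N x N/R^2.  R = 1 recovers standard
    multi-head self-attention.
    """

    def __init__(self, dim: int, heads: int, sr_ratio: int, rng):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"channels {dim} not divisible by {heads} heads")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim**-0.5
        self.sr_ratio = sr_ratio
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        if sr_ratio > 1:
            self.sr = nn.Conv2d(dim, dim, sr_ratio, rng, stride=sr_ratio)
            self.sr_norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        b, n, c = x.shape
        if n != h * w:
            raise ValueError(f"sequence length {n} does not match grid {h}x{w}")
        q = (
            self.q(x)
            .reshape(b, n, self.heads, self.head_dim)
            .transpose(0, 2, 1, 3)
        )
        if self.sr_ratio > 1:
            xr = self.sr(_seq_to_spatial(x, h, w))
            xr = self.sr_norm(_spatial_to_seq(xr))
        else:
            xr = x
        m = xr.shape[1]
        k = (
            self.k(xr)
            .reshape(b, m, self.heads, self.head_dim)
            .transpose(0, 2, 3, 1)
        )
        v = (
            self.v(xr)
            .reshape(b, m, self.heads, self.head_dim)
            .transpose(0, 2, 1, 3)
        )
        attn = (q.matmul(k) * self.scale).softmax(axis=-1)
        out = attn.matmul(v).transpose(0, 2, 1, 3).reshape(b, n, c)
        return self.proj(out)


class MixFFN(nn.Module):
    """Feed-forward block with a 3x3 depth-wise convolution between the
    expansion and projection layers (implicit positional encoding)."""

    def __init__(self, dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.dwconv = nn.Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        x = self.fc1(x)
        x = _spatial_to_seq(self.dwconv(_seq_to_spatial(x, h, w)))
        return self.fc2(x.gelu())


class TransformerBlock(nn.Module):
    def __init__(self, dim: int, heads: int, sr_ratio: int, mlp_ratio: int, rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = EfficientSelfAttention(dim, heads, sr_ratio, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.ffn = MixFFN(dim, dim * mlp_ratio, rng)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        x = x + self.attn(self.norm1(x), h, w)
        return x + self.ffn(self.norm2(x), h, w)


class MiTEncoder(nn.Module):
    """Four-stage Mix Transformer backbone producing a feature pyramid."""

    def __init__(self, spec: EncoderVariantSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        chans = spec.stage_channels
        in_chs = (3,) + chans[:3]
        self.patch_embeds = [
            OverlapPatchEmbed(in_chs[i], chans[i], *spec.patch_embed_params[i], rng)
            for i in range(4)
        ]
        self.stages = [
            [
                TransformerBlock(
                    chans[i], spec.stage_heads[i], spec.sr_ratios[i], spec.mlp_ratio, rng
                )
                for _ in range(spec.stage_depths[i])
            ]
            for i in range(4)
        ]
        self.norms = [nn.LayerNorm(c) for c in chans]

    # list-of-list stage layout is invisible to Module.children; register
    def children(self):
        for i, pe in enumerate(self.patch_embeds):
            yield f"patch_embed{i + 1}", pe
        for i, blocks in enumerate(self.stages):
            for j, blk in enumerate(blocks):
                yield f"stage{i + 1}.block{j}", blk
        for i, norm in enumerate(self.norms):
            yield f"norm{i + 1}", norm

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return the four-stage pyramid [F1, F2, F3, F4] (NCHW)."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B, 3, H, W) input, got {x.shape}")
        side = x.shape[2]
        if side != x.shape[3]:
            raise ValueError(f"expected square input, got {x.shape[2]}x{x.shape[3]}")
        if side % 32 != 0:
            raise ValueError(
                f"input side {side} must be divisible by 32 so the final stage "
                f"produces an integer-sized map"
            )
        feats = []
        for i in range(4):
            x, h, w = self.patch_embeds[i](x)
            for blk in self.stages[i]:
                x = blk(x, h, w)
            x = self.norms[i](x)
            x = _seq_to_spatial(x, h, w)
            feats.append(x)
        return feats


def make_encoder(variant: str | EncoderVariantSpec, seed: int = 0) -> MiTEncoder:
    """Build a randomly initialised MiT encoder for variant B0/B2/B4 (or
    model-size alias T/S/L)."""
    spec = variant if isinstance(variant, EncoderVariantSpec) else resolve_variant(variant)
    return MiTEncoder(spec, np.random.default_rng(seed))


def attention_heatmap(
    feature_map: Tensor | np.ndarray, invert: bool = False
) -> np.ndarray:
    """Channel-mean heatmap of a feature map, min-max scaled to [0, 255].

    The value at each location is the average over the C computed features;
    ``invert=True`` returns 255 - heatmap, the display convention for
    visualising lesion attention on dark backgrounds.
    """
    data = feature_map.data if isinstance(feature_map, Tensor) else np.asarray(feature_map)
    if data.ndim == 4:
        data = data[0]
    if data.ndim != 3:
        raise ValueError(f"expected (C, H, W) or (B, C, H, W), got shape {data.shape}")
    mean = data.mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi > lo:
        heat = (mean - lo) / (hi - lo) * 255.0
    else:
        heat = np.zeros_like(mean)
    if invert:
        heat = 255.0 - heat
    return heat.astype(np.float32)


def load_pretrained_encoder(encoder: MiTEncoder, state: dict[str, np.ndarray]) -> None:
    """Load weights stored either in this package's native key layout or in
    the published MiT checkpoint layout (torch naming, fused kv projection).

    Published layouts use (out, in) dense-weight orientation and a single
    ``kv`` projection; both are converted on the fly.
    """
    if any(k.startswith("patch_embed1.proj.weight") for k in state):
        state = _convert_published_layout(encoder, state)
    encoder.load_state_dict(state)


def _convert_published_layout(
    encoder: MiTEncoder, src: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    spec = encoder.spec
    for i in range(4):
        p = f"patch_embed{i + 1}"
        out[f"{p}.proj.weight"] = src[f"{p}.proj.weight"]
        out[f"{p}.proj.bias"] = src[f"{p}.proj.bias"]
        out[f"{p}.norm.weight"] = src[f"{p}.norm.weight"]
        out[f"{p}.norm.bias"] = src[f"{p}.norm.bias"]
        out[f"norm{i + 1}.weight"] = src[f"norm{i + 1}.weight"]
        out[f"norm{i + 1}.bias"] = src[f"norm{i + 1}.bias"]
        dim = spec.stage_channels[i]
        for j in range(spec.stage_depths[i]):
            s = f"block{i + 1}.{j}"
            d = f"stage{i + 1}.block{j}"
            for ln in ("norm1", "norm2"):
                out[f"{d}.{ln}.weight"] = src[f"{s}.{ln}.weight"]
                out[f"{d}.{ln}.bias"] = src[f"{s}.{ln}.bias"]
            out[f"{d}.attn.q.weight"] = src[f"{s}.attn.q.weight"].T
            out[f"{d}.attn.q.bias"] = src[f"{s}.attn.q.bias"]
            kvw = src[f"{s}.attn.kv.weight"]  # (2*dim, dim)
            kvb = src[f"{s}.attn.kv.bias"]
            out[f"{d}.attn.k.weight"] = kvw[:dim].T
            out[f"{d}.attn.k.bias"] = kvb[:dim]
            out[f"{d}.attn.v.weight"] = kvw[dim:].T
            out[f"{d}.attn.v.bias"] = kvb[dim:]
            out[f"{d}.attn.proj.weight"] = src[f"{s}.attn.proj.weight"].T
            out[f"{d}.attn.proj.bias"] = src[f"{s}.attn.proj.bias"]
            if spec.sr_ratios[i] > 1:
                out[f"{d}.attn.sr.weight"] = src[f"{s}.attn.sr.weight"]
                out[f"{d}.attn.sr.bias"] = src[f"{s}.attn.sr.bias"]
                out[f"{d}.attn.sr_norm.weight"] = src[f"{s}.attn.norm.weight"]
                out[f"{d}.attn.sr_norm.bias"] = src[f"{s}.attn.norm.bias"]
            out[f"{d}.ffn.fc1.weight"] = src[f"{s}.mlp.fc1.weight"].T
            out[f"{d}.ffn.fc1.bias"] = src[f"{s}.mlp.fc1.bias"]
            out[f"{d}.ffn.dwconv.weight"] = src[f"{s}.mlp.dwconv.dwconv.weight"]
            out[f"{d}.ffn.dwconv.bias"] = src[f"{s}.mlp.dwconv.dwconv.bias"]
            out[f"{d}.ffn.fc2.weight"] = src[f"{s}.mlp.fc2.weight"].T
            out[f"{d}.ffn.fc2.bias"] = src[f"{s}.mlp.fc2.bias"]
    return out
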