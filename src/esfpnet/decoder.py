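"""Efficient Stage-wise Feature Pyramid (ESFP) decoder and full model.

The decoder fuses the four encoder stages from global (deep) to local
(shallow) through four layers:

* **BP** (basic prediction): a channel-preserving per-location linear
  projection of each stage output ``FiBP = LinearLayer(Fi)``.
* **AF** (aggregating fusion): ``FiAF = ConvModule(Concat(FiBP,
  U2(F(i+1)AP)))`` for i = 1, 2 and ``F3AF = ConvModule(Concat(F3BP,
  U2(F4BP)))`` — the deeper stage is upsampled x2, concatenated with the
  local stage and merged back to the local width by a 1x1 convolution
  block.
* **AP** (aggregating prediction): another per-location linear projection
  ``FiAP = LinearLayer(FiAF)`` for i = 1..3; ``F4AP`` is defined as
  ``F4BP`` without computation.
* **MF** (multi-stage fusion): the four AP maps are upsampled to the 1/4
  grid, concatenated (C1+C2+C3+C4 channels) and reduced to a single-channel
  logit map.

The Final Segment step applies sigmoid, thresholds at 0.5, upsamples x4 to
the model grid and reconstructs the native 720 x 720 frame geometry.

Ablation configurations drop whole layers; a dropped layer's consumers read
the rawest available map for that stage (e.g. the "MF" row fuses the raw
encoder pyramid directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, concat, resize_bilinear, resize_nearest
from .encoder import EncoderVariantSpec, MiTEncoder, resolve_variant

__all__ = [
    "ABLATIONS",
    "DecoderSpec",
    "DecoderState",
    "ESFPDecoder",
    "ESFPNet",
    "build_model",
    "final_segment",
    "mask_to_native",
]

# Rows of the decoder-component ablation grid ("full" = complete ESFP).
ABLATIONS = {
    "mf": frozenset({"mf"}),
    "bp+mf": frozenset({"bp", "mf"}),
    "bp+af+mf": frozenset({"bp", "af", "mf"}),
    "af+ap+mf": frozenset({"af", "ap", "mf"}),
    "full": frozenset({"bp", "af", "ap", "mf"}),
}


@dataclass(frozen=True)
class DecoderSpec:
    """Configuration of the ESFP decoder."""

    stage_channels: tuple[int, int, int, int]
    ablation: str = "full"
    upsample_mode: str = "bilinear"

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(
                f"unknown ablation {self.ablation!r}; expected one of {sorted(ABLATIONS)}"
            )
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")

    @property
    def components(self) -> frozenset[str]:
        return ABLATIONS[self.ablation]


@dataclass
class DecoderState:
    """Intermediate decoder maps, retained for heatmap visualisation."""

    bp: list[Tensor] = field(default_factory=list)  # F1BP..F4BP
    af: list[Tensor] = field(default_factory=list)  # F1AF..F3AF
    ap: list[Tensor] = field(default_factory=list)  # F1AP..F3AP (F4AP = F4BP)
    mf: Tensor | None = None  # FMF logits at the 1/4 grid


class LinearLayer(nn.Module):
    """Per-location (1x1) linear projection of an NCHW map, width-preserving."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.linear = nn.Linear(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        y = self.linear(x.transpose(0, 2, 3, 1).reshape(b * h * w, c))
        return y.reshape(b, h, w, c).transpose(0, 3, 1, 2)


class ConvModule(nn.Module):
    """1x1 convolution + batch norm + ReLU fusion block."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 1, rng, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class ESFPDecoder(nn.Module):
    """ESFP decoder; only the layers named by the ablation are built."""

    def __init__(self, spec: DecoderSpec, rng: np.random.Generator):
        super().__init__()
        self.decoder_spec = spec
        c = spec.stage_channels
        comp = spec.components
        if "bp" in comp:
            self.bp_blocks = [LinearLayer(ci, rng) for ci in c]
        if "af" in comp:
            # AF#1..AF#3 merge (Ci + C(i+1)) -> Ci
            self.af_blocks = [ConvModule(c[i] + c[i + 1], c[i], rng) for i in range(3)]
        if "ap" in comp:
            self.ap_blocks = [LinearLayer(c[i], rng) for i in range(3)]
        self.mf_pred = nn.Conv2d(sum(c), 1, 1, rng, bias=True)

    def _up2(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        if self.decoder_spec.upsample_mode == "nearest":
            return Tensor(resize_nearest(x.data, 2 * h, 2 * w))
        return resize_bilinear(x, 2 * h, 2 * w)

    def forward(self, pyramid: list[Tensor]) -> tuple[Tensor, DecoderState]:
        """Fuse the 4-stage pyramid into a single-channel 1/4-grid logit map."""
        if len(pyramid) != 4:
            raise ValueError(f"expected a 4-stage pyramid, got {len(pyramid)} maps")
        for fi, ci in zip(pyramid, self.decoder_spec.stage_channels):
            if fi.shape[1] != ci:
                raise ValueError(
                    f"pyramid channels {[f.shape[1] for f in pyramid]} do not match "
                    f"decoder spec {self.decoder_spec.stage_channels}"
                )
        comp = self.decoder_spec.components
        state = DecoderState()

        maps = list(pyramid)
        if "bp" in comp:
            maps = [blk(f) for blk, f in zip(self.bp_blocks, maps)]
            state.bp = list(maps)

        if "af" in comp:
            # deep-to-shallow fusion; stage 4 passes through untouched
            fused = [None, None, None, maps[3]]
            upper = maps[3]
            for i in (2, 1, 0):
                af = self.af_blocks[i](concat([maps[i], self._up2(upper)], axis=1))
                state.af.insert(0, af)
                if "ap" in comp:
                    ap = self.ap_blocks[i](af)
                    state.ap.insert(0, ap)
                    upper = ap
                else:
                    upper = af
                fused[i] = upper
            maps = fused
        elif "ap" in comp:
            # AP without AF is not a published configuration; guard anyway
            raise ValueError("ap requires af in the ablation graph")

        side = maps[0].shape[2]
        up = [maps[0]]
        for m in maps[1:]:
            if self.decoder_spec.upsample_mode == "nearest":
                up.append(Tensor(resize_nearest(m.data, side, side)))
            else:
                up.append(resize_bilinear(m, side, side))
        fmf = self.mf_pred(concat(up, axis=1))
        state.mf = fmf
        return fmf, state


def final_segment(
    fmf: Tensor | np.ndarray, native: bool = True, threshold: float = 0.5
) -> np.ndarray:
    """Final Segment block: sigmoid, threshold, 4x upsample, native padding.

    `fmf` is the single-channel logit map on the 1/4 grid (H/4 x H/4).  The
    probability map is thresholded first (the deployment ordering), the
    binary map is then upsampled x4 by nearest neighbour to H x H and, if
    ``native``, mapped back onto the 720 x 720 frame geometry.  Returns a
    {0,1} uint8 array (2-D for a single frame, 3-D for a batch).
    """
    from scipy.special import expit

    data = fmf.data if isinstance(fmf, Tensor) else np.asarray(fmf)
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None, None]
    if data.ndim == 3:
        data = data[:, None]
    prob = expit(data[:, 0])
    mask = (prob > threshold).astype(np.uint8)
    h = mask.shape[-1]
    mask = resize_nearest(mask, 4 * h, 4 * h)
    if native:
        mask = mask_to_native(mask)
    return mask[0] if squeeze else mask


def mask_to_native(mask: np.ndarray, native_side: int = 720, crop_side: int = 704) -> np.ndarray:
    """Invert the preprocessing geometry for a model-grid binary mask.

    The H x H mask is upsampled (nearest) to the crop side and zero-padded
    back to the native frame, undoing the centre crop.
    """
    up = resize_nearest(mask, crop_side, crop_side)
    margin = (native_side - crop_side) // 2
    pad = [(0, 0)] * (up.ndim - 2) + [(margin, margin), (margin, margin)]
    return np.pad(up, pad)


class ESFPNet(nn.Module):
    """MiT encoder + ESFP decoder for binary lesion segmentation."""

    def __init__(
        self,
        encoder: MiTEncoder,
        decoder: ESFPDecoder,
    ):
        super().__init__()
        self.encoder = encoder
        self.decoder = decoder
        self.last_state: DecoderState | None = None
        self.last_pyramid: list[Tensor] | None = None

    @property
    def variant(self) -> str:
        return self.encoder.spec.variant_id

    def forward(self, x: Tensor) -> Tensor:
        """Full-resolution (H x H) pre-sigmoid lesion logit map."""
        pyramid = self.encoder(x)
        fmf, state = self.decoder(pyramid)
        self.last_pyramid = pyramid
        self.last_state = state
        side = x.shape[2]
        logits = resize_bilinear(fmf, side, side)
        if not np.isfinite(logits.data).all():
            raise FloatingPointError("non-finite values in the logit map")
        return logits

    def predict(self, x: Tensor, native: bool = False, threshold: float = 0.5):
        """Probability map (H x H) and binary mask for a batch of frames."""
        from scipy.special import expit

        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                pyramid = self.encoder(x)
                fmf, state = self.decoder(pyramid)
                self.last_pyramid = pyramid
                self.last_state = state
                side = x.shape[2]
                prob = expit(resize_bilinear(fmf, side, side).data[:, 0])
                mask = final_segment(fmf, native=native, threshold=threshold)
        finally:
            self.train(was_training)
        return prob, mask

    def trainable_parameters(self, freeze_encoder: bool = False) -> list[Tensor]:
        if freeze_encoder:
            return self.decoder.parameters()
        return self.parameters()


def build_model(
    variant: str = "S",
    seed: int = 0,
    ablation: str = "full",
    upsample_mode: str = "bilinear",
) -> ESFPNet:
    """Construct an ESFPNet-T/S/L (encoder variant B0/B2/B4) instance."""
    enc_spec: EncoderVariantSpec = resolve_variant(variant)
    rng = np.random.default_rng(seed)
    encoder = MiTEncoder(enc_spec, rng)
    decoder = ESFPDecoder(
        DecoderSpec(enc_spec.stage_channels, ablation, upsample_mode), rng
    )
    return ESFPNet(encoder, decoder)
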