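"""Frame and mask preprocessing for the segmentation model.

Native bronchoscopy frames are 720 x 720 RGB.  The input chain is:
centre-crop to 704 x 704 (an 8-pixel margin on each side), downsample by
exactly x1/2 to the model side H = 352 (so 704 = 2H and H = 11 * 32,
keeping the final encoder stage an integer 11 x 11 grid), then normalise
intensities with the standard large-scale natural-image per-channel
statistics used by the pretrained encoders.

Ground-truth masks follow the same geometry with nearest-neighbour
resampling so they stay binary; the inverse mapping (upsample + zero-pad)
lives with the decoder's Final Segment step.

Frames from other sources (e.g. public polyp sets, which are not 720 x 720)
are resized directly to the model side without the crop — the crop exists
to trim the circular-scan frame border.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .nn import Tensor
from .nn.tensor import _resize_matrix

__all__ = [
    "PreprocessSpec",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "center_crop",
    "resize_to_model",
    "normalize",
    "denormalize",
    "preprocess_frame",
    "gt_to_model_scale",
    "load_frame",
    "load_mask",
    "save_mask",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class PreprocessSpec:
    native_side: int = 720
    crop_side: int = 704
    model_side: int = 352
    mean: tuple[float, float, float] = tuple(IMAGENET_MEAN)
    std: tuple[float, float, float] = tuple(IMAGENET_STD)

    def __post_init__(self) -> None:
        # default geometry keeps crop = 2H so the downsample is an exact x1/2;
        # reduced model sides reuse the same 704 crop of the native frame
        if self.crop_side < self.model_side:
            raise ValueError("crop side must be at least the model side")
        if self.model_side % 32 != 0:
            raise ValueError("model side must be divisible by 32")


DEFAULT_SPEC = PreprocessSpec()


def center_crop(frame: np.ndarray, crop_side: int = 704) -> np.ndarray:
    """Symmetric centre crop of a square frame (HW or HWC layout)."""
    h, w = frame.shape[:2]
    if h != w:
        raise ValueError(f"expected a square frame, got {h}x{w}")
    if h < crop_side:
        raise ValueError(f"frame side {h} smaller than crop side {crop_side}")
    off = (h - crop_side) // 2
    return frame[off : off + crop_side, off : off + crop_side]


def _resize_channels_last(img: np.ndarray, out_side: int) -> np.ndarray:
    """Bilinear resize (half-pixel centres) of an HW or HWC float array.

    At an exact x1/2 reduction this reduces to 2x2 block averaging.
    """
    h, w = img.shape[:2]
    r = _resize_matrix(h, out_side)
    c = _resize_matrix(w, out_side)
    moved = img if img.ndim == 2 else np.moveaxis(img, -1, 0)
    out = np.matmul(np.matmul(r, moved), c.T)
    return out if img.ndim == 2 else np.moveaxis(out, 0, -1)


def resize_to_model(cropped: np.ndarray, model_side: int = 352) -> np.ndarray:
    """Downsample a square crop to the model side (bilinear, float output)."""
    h, w = cropped.shape[:2]
    if h != w:
        raise ValueError(f"expected a square image, got {h}x{w}")
    img = np.asarray(cropped, dtype=np.float32)
    if img.max() > 1.5:  # uint8-scale input
        img = img / 255.0
    return _resize_channels_last(img, model_side)


def normalize(img: np.ndarray, spec: PreprocessSpec = DEFAULT_SPEC) -> Tensor:
    """Per-channel standardisation of an HWC float image in [0, 1].

    Returns a CHW model-input tensor.
    """
    img = np.asarray(img, dtype=np.float32)
    if img.min() < -1e-6 or img.max() > 1.0 + 1e-6:
        raise ValueError("expected intensities in [0, 1]; rescale first")
    out = (img - np.asarray(spec.mean)) / np.asarray(spec.std)
    return Tensor(np.moveaxis(out, -1, 0))


def denormalize(x: Tensor | np.ndarray, spec: PreprocessSpec = DEFAULT_SPEC) -> np.ndarray:
    """Inverse of :func:`normalize`; returns an HWC float image."""
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    img = np.moveaxis(data, 0, -1)
    return img * np.asarray(spec.std) + np.asarray(spec.mean)


def preprocess_frame(frame: np.ndarray, spec: PreprocessSpec = DEFAULT_SPEC) -> Tensor:
    """Full input chain: (crop ->) resize -> normalise, giving a CHW tensor.

    The centre crop is applied only to frames at least as large as the crop
    side (the native circular-scan geometry); smaller frames are resized
    directly.
    """
    h, w = frame.shape[:2]
    if h == w and h >= spec.crop_side:
        frame = center_crop(frame, spec.crop_side)
    img = resize_to_model(frame, spec.model_side)
    return normalize(np.clip(img, 0.0, 1.0), spec)


def gt_to_model_scale(mask: np.ndarray, spec: PreprocessSpec = DEFAULT_SPEC) -> np.ndarray:
    """Map a native binary mask through the frame geometry (nearest)."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary {0,1}")
    h, w = mask.shape[:2]
    if h == w and h >= spec.crop_side:
        mask = center_crop(mask, spec.crop_side)
    from .nn import resize_nearest

    return resize_nearest(mask.astype(np.uint8), spec.model_side, spec.model_side)


# ------------------------------------------------------------------ disk I/O
def load_frame(path: str | Path) -> np.ndarray:
    """Read an RGB frame as a uint8 HWC array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise OSError(f"unreadable frame {path}: {exc}") from exc


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG (0/255 on disk) as a {0,1} uint8 array."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise OSError(f"unreadable mask {path}: {exc}") from exc
    return (arr > 127).astype(np.uint8)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit 0/255 PNG."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)
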