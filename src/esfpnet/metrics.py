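"""Training loss, segmentation metrics and region-level detection protocol.

Segmentation quality is scored per frame by the Dice coefficient
``2|A∩B| / (|A|+|B|)`` and intersection-over-union ``|A∩B| / |A∪B|``
between the predicted mask A and ground truth B, plus the pixelwise mean
absolute error.  A pair of empty masks scores 1 by convention (the
prediction agrees perfectly with an all-normal frame); this keeps
normal-frame evaluation well defined and is configurable.

Detection is scored at the region level: connected components of the
predicted mask (8-connectivity) below the significant-region-size
threshold (default 400 px) are discarded; every ground-truth region
overlapped by at least one surviving predicted region is a true positive,
unmatched ground-truth regions are false negatives, and surviving
predicted regions that overlap no ground truth — on lesion or normal
frames alike — are false positives.  Recall = TP/(TP+FN) then measures the
fraction of ground-truth lesions found and precision = TP/(TP+FP) the
fraction of predictions that correspond to lesions.

The training loss is the boundary-weighted IoU + BCE sum: pixel weights
``w = 1 + 5 * |meanpool_31(gt) - gt|`` emphasise mask boundaries, the BCE
term is the w-weighted mean of per-pixel cross-entropy, and the IoU term
is ``1 - (inter + 1) / (union - inter + 1)`` with w-weighted intersection
and union, averaged over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage import measure

from .nn import Tensor, bce_with_logits

__all__ = [
    "LossValue",
    "Region",
    "DetectionCounts",
    "DatasetSummary",
    "weighted_seg_loss",
    "dice",
    "iou",
    "mae",
    "label_regions",
    "filter_significant",
    "match_regions",
    "recall",
    "precision",
    "evaluate_frame",
    "dataset_summary",
]

DEFAULT_MIN_REGION_AREA = 400  # significant-region-size parameter, pixels
BOUNDARY_POOL_SIZE = 31  # mean-pool window of the boundary weight map


# ----------------------------------------------------------------- the loss
@dataclass
class LossValue:
    """Total weighted segmentation loss with its two components.

    ``total`` is differentiable (a graph tensor); the components are
    detached scalars for logging.
    """

    total: Tensor
    wiou: float
    wbce: float

    def item(self) -> float:
        return self.total.item()


def boundary_weights(gt: np.ndarray, k: int = BOUNDARY_POOL_SIZE) -> np.ndarray:
    """Pixel weights 1 + 5*|meanpool_k(gt) - gt| (stride 1, zero padding)."""
    gt = np.asarray(gt, dtype=np.float32)
    pooled = uniform_filter(gt, size=(1, 1, k, k), mode="constant", cval=0.0)
    return 1.0 + 5.0 * np.abs(pooled - gt)


def weighted_seg_loss(logits: Tensor, gt: np.ndarray) -> LossValue:
    """Boundary-weighted IoU + BCE loss on an (B, 1, H, W) logit map."""
    gt = np.asarray(gt, dtype=np.float32)
    if gt.ndim == 2:
        gt = gt[None, None]
    elif gt.ndim == 3:
        gt = gt[:, None]
    if logits.shape != gt.shape:
        raise ValueError(f"logits {logits.shape} vs ground truth {gt.shape}")
    w = boundary_weights(gt)
    wsum = w.sum(axis=(1, 2, 3))

    bce = bce_with_logits(logits, gt)
    wbce = (bce * Tensor(w)).sum(axis=(1, 2, 3)) / Tensor(wsum)

    pred = logits.sigmoid()
    wt = Tensor(w)
    inter = (pred * Tensor(gt) * wt).sum(axis=(1, 2, 3))
    union = ((pred + Tensor(gt)) * wt).sum(axis=(1, 2, 3))
    wiou = 1.0 - (inter + 1.0) / (union - inter + 1.0)

    total = (wbce + wiou).mean()
    return LossValue(
        total=total,
        wiou=float(wiou.data.mean()),
        wbce=float(wbce.data.mean()),
    )


# ------------------------------------------------------- pixelwise metrics
def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.all(np.isin(arr, (0, 1))):
        raise ValueError(f"{name} must be binary {{0,1}}")
    return arr.astype(bool)


def dice(a: np.ndarray, b: np.ndarray, empty_value: float = 1.0) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); both-empty scores `empty_value`."""
    a = _check_binary(a, "A")
    b = _check_binary(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return empty_value
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a: np.ndarray, b: np.ndarray, empty_value: float = 1.0) -> float:
    """Intersection over union |A∩B|/|A∪B|; both-empty scores `empty_value`."""
    a = _check_binary(a, "A")
    b = _check_binary(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return empty_value
    return float(np.logical_and(a, b).sum() / union)


def mae(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean absolute error between a probability (or binary) map and gt."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    return float(np.abs(pred - gt).mean())


# --------------------------------------------------------- region protocol
@dataclass(frozen=True)
class Region:
    """One connected component of a binary mask."""

    label: int
    area: int
    coords: tuple  # (rows, cols) index arrays

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.coords] = True
        return out


@dataclass
class DetectionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


def label_regions(mask: np.ndarray, connectivity: int = 2) -> list[Region]:
    """Connected components of a binary mask (default 8-connectivity)."""
    arr = _check_binary(mask, "mask")
    labelled = measure.label(arr, connectivity=connectivity)
    regions = []
    for lab in range(1, labelled.max() + 1):
        coords = np.nonzero(labelled == lab)
        regions.append(Region(label=lab, area=len(coords[0]), coords=coords))
    return regions


def filter_significant(
    regions: list[Region], min_area: int = DEFAULT_MIN_REGION_AREA
) -> list[Region]:
    """Drop regions smaller than the significant-region-size threshold."""
    return [r for r in regions if r.area >= min_area]


def match_regions(
    pred_regions: list[Region],
    gt_regions: list[Region],
    shape: tuple[int, int] | None = None,
) -> DetectionCounts:
    """Region-level detection bookkeeping.

    A ground-truth region counts as detected (TP) when any predicted region
    overlaps it; undetected ground-truth regions are FN; predicted regions
    overlapping no ground truth are FP.  A single predicted region covering
    two ground-truth regions therefore yields TP = 2 (ground-truth-centric
    counting).
    """
    if shape is None:
        coords = [c for r in pred_regions + gt_regions for c in (r.coords,)]
        if not coords:
            return DetectionCounts()
        side = 1 + max(int(max(c[0].max(), c[1].max())) for c in coords)
        shape = (side, side)
    pred_union = np.zeros(shape, dtype=bool)
    for r in pred_regions:
        pred_union[r.coords] = True
    gt_union = np.zeros(shape, dtype=bool)
    for r in gt_regions:
        gt_union[r.coords] = True

    tp = sum(1 for r in gt_regions if pred_union[r.coords].any())
    fn = len(gt_regions) - tp
    fp = sum(1 for r in pred_regions if not gt_union[r.coords].any())
    return DetectionCounts(tp=tp, fp=fp, fn=fn)


def recall(c: DetectionCounts) -> float:
    """TP/(TP+FN); defined as 1.0 when no ground-truth regions exist."""
    if c.tp + c.fn == 0:
        return 1.0
    return c.tp / (c.tp + c.fn)


def precision(c: DetectionCounts) -> float:
    """TP/(TP+FP); defined as 1.0 when nothing was predicted or matched."""
    if c.tp + c.fp == 0:
        return 1.0
    return c.tp / (c.tp + c.fp)


# ------------------------------------------------------------- aggregation
@dataclass
class DatasetSummary:
    mdice: float
    miou: float
    mae: float
    recall: float
    precision: float
    counts: DetectionCounts
    n_frames: int


def evaluate_frame(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    pred_prob: np.ndarray | None = None,
    min_area: int = DEFAULT_MIN_REGION_AREA,
    connectivity: int = 2,
) -> dict:
    """Per-frame segmentation scores and detection counts.

    The significant-region filter applies to predicted regions only.
    """
    pred_regions = filter_significant(
        label_regions(pred_mask, connectivity), min_area
    )
    gt_regions = label_regions(gt_mask, connectivity)
    counts = match_regions(pred_regions, gt_regions, shape=np.asarray(gt_mask).shape)
    # the filtered prediction is what the detector reports; score that mask
    filtered = np.zeros(np.asarray(pred_mask).shape, dtype=np.uint8)
    for r in pred_regions:
        filtered[r.coords] = 1
    return {
        "dice": dice(filtered, gt_mask),
        "iou": iou(filtered, gt_mask),
        "mae": mae(pred_prob if pred_prob is not None else filtered, gt_mask),
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
    }


def dataset_summary(frame_rows: list[dict]) -> DatasetSummary:
    """Aggregate per-frame rows: unweighted means for the pixel metrics,
    pooled region counts for recall/precision."""
    if not frame_rows:
        raise ValueError("no frames to summarise")
    counts = DetectionCounts(
        tp=sum(r["tp"] for r in frame_rows),
        fp=sum(r["fp"] for r in frame_rows),
        fn=sum(r["fn"] for r in frame_rows),
    )
    return DatasetSummary(
        mdice=float(np.mean([r["dice"] for r in frame_rows])),
        miou=float(np.mean([r["iou"] for r in frame_rows])),
        mae=float(np.mean([r["mae"] for r in frame_rows])),
        recall=recall(counts),
        precision=precision(counts),
        counts=counts,
        n_frames=len(frame_rows),
    )
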