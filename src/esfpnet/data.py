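"""Dataset indexing, case-exclusive splitting and synthetic AFB frames.

A dataset lives in a directory with ``frames/``, ``masks/`` and an
``index.csv`` whose rows are ``frame,mask,case,label,split``.  Lesion
frames must have a non-empty mask; normal frames have an empty or absent
mask.  Splitting is case-exclusive: every frame from one patient exam
lands in the same subset, which prevents leakage between train, validation
and test at the cost of only approximately hitting the target 50/25/25
frame ratios.

The synthetic generator emulates the geometry of circular-scan
autofluorescence bronchoscopy frames: a dark exterior, a circular scan
area of radius 352 px (about 390,000 px) with a green-dominant textured
interior and radial vignette, and zero or more smooth reddish-brown lesion
blobs with areas inside the 800-290,000 px envelope observed in real
exams.  Appearance is deliberately schematic — the point is exercising the
full pipeline (I/O, geometry, class balance, region bookkeeping) without
patient data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.draw import polygon as draw_polygon

from .preprocessing import load_frame, load_mask, save_mask

__all__ = [
    "DatasetRecord",
    "DatasetIndex",
    "SynthSpec",
    "load_dataset",
    "split_by_case",
    "synth_frame",
    "synth_dataset",
]

SPLITS = ("train", "val", "test")
LABELS = ("lesion", "normal")


@dataclass(frozen=True)
class DatasetRecord:
    frame: Path
    mask: Path | None
    case: str
    label: str  # lesion | normal
    split: str | None = None  # train | val | test | None


@dataclass
class DatasetIndex:
    root: Path
    records: list[DatasetRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "DatasetIndex":
        return DatasetIndex(
            self.root, [r for r in self.records if r.split == split]
        )

    def by_label(self, label: str) -> list[DatasetRecord]:
        return [r for r in self.records if r.label == label]

    @property
    def cases(self) -> list[str]:
        return sorted({r.case for r in self.records})

    def case_ids_per_split(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            if r.split is not None:
                out.setdefault(r.split, set()).add(r.case)
        return out

    def to_csv(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path else self.root / "index.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "mask", "case", "label", "split"])
            for r in self.records:
                writer.writerow(
                    [
                        r.frame.relative_to(self.root).as_posix(),
                        r.mask.relative_to(self.root).as_posix() if r.mask else "",
                        r.case,
                        r.label,
                        r.split or "",
                    ]
                )
        return path


def load_dataset(root: str | Path, validate: bool = True) -> DatasetIndex:
    """Read ``index.csv`` under `root` and validate frame/mask pairing."""
    root = Path(root)
    index_path = root / "index.csv"
    if not index_path.exists():
        if not root.exists() or not any(root.iterdir()):
            return DatasetIndex(root)
        raise FileNotFoundError(f"no index.csv under {root}")
    records: list[DatasetRecord] = []
    with open(index_path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["label"]
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r} in {index_path}")
            split = row.get("split") or None
            if split is not None and split not in SPLITS:
                raise ValueError(f"unknown split {split!r} in {index_path}")
            mask = root / row["mask"] if row.get("mask") else None
            if label == "lesion" and mask is None:
                raise ValueError(f"lesion frame {row['frame']} has no mask")
            records.append(
                DatasetRecord(
                    frame=root / row["frame"],
                    mask=mask,
                    case=row["case"],
                    label=label,
                    split=split,
                )
            )
    index = DatasetIndex(root, records)
    if validate:
        _validate(index)
    return index


def _validate(index: DatasetIndex) -> None:
    for r in index.records:
        if not r.frame.exists():
            raise FileNotFoundError(f"missing frame {r.frame}")
        if r.label == "lesion":
            m = load_mask(r.mask)
            if m.sum() == 0:
                raise ValueError(f"lesion mask {r.mask} has no foreground")
    per_split = index.case_ids_per_split()
    splits = list(per_split)
    for i, a in enumerate(splits):
        for b in splits[i + 1 :]:
            shared = per_split[a] & per_split[b]
            if shared:
                raise ValueError(
                    f"case(s) {sorted(shared)} appear in both {a!r} and {b!r}"
                )


def split_by_case(
    index: DatasetIndex,
    ratios: tuple[float, float, float] = (0.50, 0.25, 0.25),
    rng: np.random.Generator | None = None,
) -> tuple[DatasetIndex, dict[str, float]]:
    """Assign whole cases to train/val/test, greedily approaching `ratios`.

    Cases are visited in random order, largest first within the shuffle,
    and each goes to the split with the largest remaining frame deficit.
    Returns the new index and the achieved frame ratios.
    """
    rng = rng or np.random.default_rng()
    cases = index.cases
    if len(cases) < 3:
        raise ValueError(f"need at least 3 cases to split, got {len(cases)}")
    sizes = {c: sum(1 for r in index.records if r.case == c) for c in cases}
    order = list(cases)
    rng.shuffle(order)
    order.sort(key=lambda c: -sizes[c])
    total = len(index)
    targets = {s: ratio * total for s, ratio in zip(SPLITS, ratios)}
    filled = {s: 0 for s in SPLITS}
    assignment: dict[str, str] = {}
    for c in order:
        deficits = {s: targets[s] - filled[s] for s in SPLITS}
        best = max(SPLITS, key=lambda s: deficits[s])
        assignment[c] = best
        filled[best] += sizes[c]
    new_records = [replace(r, split=assignment[r.case]) for r in index.records]
    achieved = {s: filled[s] / total for s in SPLITS}
    return DatasetIndex(index.root, new_records), achieved


# ------------------------------------------------------------------ synthesis
@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic circular-scan frame generator."""

    frame_side: int = 720
    scan_radius: int = 352
    area_range: tuple[int, int] = (800, 290_000)
    lesion_count_probs: tuple[float, ...] = (0.7, 0.3)  # P(1 lesion), P(2), ...
    texture_sigma: float = 40.0  # px, smoothness of the interior texture
    noise_sigma: float = 0.02  # per-pixel intensity noise
    boundary_margin: int = 6  # px kept between a lesion and the scan rim

    def __post_init__(self) -> None:
        lo, hi = self.area_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad area range {self.area_range}")
        if self.scan_radius * 2 > self.frame_side:
            raise ValueError("scan circle does not fit in the frame")


def _scan_geometry(spec: SynthSpec):
    side = spec.frame_side
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = side / 2.0 - 0.5
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return dist, (cy, cx)


def _max_blob_radius(spec: SynthSpec) -> float:
    # star-convex blobs perturb the base radius by up to ~30 %
    return (spec.scan_radius - spec.boundary_margin) / 1.3


def _feasible_area_cap(spec: SynthSpec) -> float:
    return np.pi * _max_blob_radius(spec) ** 2


def _sample_lesion_blob(
    spec: SynthSpec, rng: np.random.Generator
) -> np.ndarray:
    """One star-convex lesion blob as a boolean frame-sized mask."""
    lo, hi = spec.area_range
    cap = _feasible_area_cap(spec)
    if lo > cap:
        raise ValueError(
            f"minimum lesion area {lo} cannot fit inside the scan circle "
            f"(feasible maximum about {int(cap)})"
        )
    hi = min(hi, cap)
    for _ in range(20):
        area = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        r0 = np.sqrt(area / np.pi)
        # smooth periodic radial perturbation -> irregular outline
        raw = rng.standard_normal(96)
        wobble = gaussian_filter1d(raw, sigma=6, mode="wrap")
        wobble = wobble / (np.abs(wobble).max() + 1e-9) * 0.3
        theta = np.linspace(0.0, 2.0 * np.pi, 96, endpoint=False)
        radii = r0 * (1.0 + wobble)
        max_r = radii.max()
        # place the centre so the whole blob stays inside the scan circle
        placement = spec.scan_radius - spec.boundary_margin - max_r
        if placement < 0:
            continue
        rho = np.sqrt(rng.uniform(0.0, 1.0)) * placement
        phi = rng.uniform(0.0, 2.0 * np.pi)
        cy = spec.frame_side / 2.0 - 0.5 + rho * np.sin(phi)
        cx = spec.frame_side / 2.0 - 0.5 + rho * np.cos(phi)
        rows = cy + radii * np.sin(theta)
        cols = cx + radii * np.cos(theta)
        rr, cc = draw_polygon(rows, cols, shape=(spec.frame_side, spec.frame_side))
        blob = np.zeros((spec.frame_side, spec.frame_side), dtype=bool)
        blob[rr, cc] = True
        got = blob.sum()
        if spec.area_range[0] <= got <= spec.area_range[1]:
            return blob
    raise RuntimeError("could not sample a feasible lesion blob")


def synth_frame(
    spec: SynthSpec, rng: np.random.Generator, lesion: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic frame and its mask.

    Returns ``(frame, mask)`` with frame uint8 HWC RGB and mask {0,1} uint8.
    Normal frames (``lesion=False``) get an all-zero mask.
    """
    side = spec.frame_side
    dist, _ = _scan_geometry(spec)
    inside = dist <= spec.scan_radius

    tex = gaussian_filter(rng.standard_normal((side, side)), spec.texture_sigma)
    tex = tex / (np.abs(tex).max() + 1e-9)
    vignette = np.clip(1.0 - 0.55 * (dist / spec.scan_radius) ** 2, 0.0, 1.0)

    frame = np.zeros((side, side, 3), dtype=np.float32)
    # green-dominant fluorescing mucosa
    frame[..., 0] = 0.22 + 0.05 * tex
    frame[..., 1] = 0.52 + 0.10 * tex
    frame[..., 2] = 0.18 + 0.04 * tex
    frame *= (vignette * inside)[..., None]

    mask = np.zeros((side, side), dtype=np.uint8)
    if lesion:
        n = 1 + rng.choice(len(spec.lesion_count_probs), p=spec.lesion_count_probs)
        for _ in range(n):
            blob = _sample_lesion_blob(spec, rng)
            mask |= blob.astype(np.uint8)
        # reddish-brown tint with soft edges
        alpha = gaussian_filter(mask.astype(np.float32), 4.0)
        alpha = np.clip(alpha, 0.0, 1.0) * inside
        frame[..., 0] += 0.28 * alpha
        frame[..., 1] -= 0.30 * alpha
        frame[..., 2] -= 0.05 * alpha

    frame += rng.normal(0.0, spec.noise_sigma, frame.shape).astype(np.float32)
    frame = np.clip(frame, 0.0, 1.0)
    return (frame * 255).astype(np.uint8), mask


def synth_dataset(
    out_root: str | Path,
    n_cases: int = 10,
    frames_per_case: int = 6,
    lesion_fraction: float = 0.3,
    spec: SynthSpec | None = None,
    seed: int = 0,
) -> DatasetIndex:
    """Write a synthetic dataset (frames/, masks/, index.csv) to disk.

    The class mix follows `lesion_fraction` within rounding, mirroring the
    lesion/normal imbalance of a real exam archive.
    """
    spec = spec or SynthSpec()
    rng = np.random.default_rng(seed)
    root = Path(out_root)
    (root / "frames").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    total = n_cases * frames_per_case
    n_lesion = round(total * lesion_fraction)
    flags = np.zeros(total, dtype=bool)
    flags[:n_lesion] = True
    rng.shuffle(flags)

    records: list[DatasetRecord] = []
    for i in range(total):
        case = f"case{i // frames_per_case:03d}"
        name = f"{case}_f{i % frames_per_case:03d}"
        frame, mask = synth_frame(spec, rng, lesion=bool(flags[i]))
        frame_path = root / "frames" / f"{name}.png"
        from PIL import Image

        Image.fromarray(frame).save(frame_path)
        mask_path = None
        if flags[i]:
            mask_path = root / "masks" / f"{name}.png"
            save_mask(mask_path, mask)
        records.append(
            DatasetRecord(
                frame=frame_path,
                mask=mask_path,
                case=case,
                label="lesion" if flags[i] else "normal",
            )
        )
    index = DatasetIndex(root, records)
    index.to_csv()
    return index


def load_pair(record: DatasetRecord) -> tuple[np.ndarray, np.ndarray]:
    """Read a record's frame and its (possibly empty) native-scale mask."""
    frame = load_frame(record.frame)
    if record.mask is not None:
        mask = load_mask(record.mask)
    else:
        mask = np.zeros(frame.shape[:2], dtype=np.uint8)
    return frame, mask
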