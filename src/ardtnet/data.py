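"""Dataset plumbing: the ISIC-style CSV manifest dialect, class balancing by
oversampling, multi-scale center-constrained patch extraction, bilinear
resizing and rigid augmentation.

Manifest dialect
----------------
CSV with an optional header and columns ``image_id, task1[, task2]``. The id
is the ``ISIC_<image_id>`` stem of a PNG/JPEG file in the image directory.
With ``polarity="paper"`` (the default) the first task column stores 0 for a
melanoma and 1 for a benign lesion, and the second stores 0 for a seborrheic
keratosis; both are flipped on read so that in-memory labels are always
1 = positive class (task 1: melanoma; task 2: seborrheic keratosis).
``polarity="standard"`` reads the columns as already being 1 = positive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class ImageRecord:
    image_id: str
    pixels: np.ndarray  # H x W x 3, float32 in [0, 1]
    task1_label: int
    task2_label: int | None = None
    source_id: str | None = None  # original id when duplicated by oversampling

    def __post_init__(self):
        if not self.image_id:
            raise ValueError("image_id must be non-empty")
        if self.source_id is None:
            self.source_id = self.image_id


@dataclass
class Manifest:
    records: list[ImageRecord] = field(default_factory=list)
    label_polarity: str = "paper"

    def __len__(self):
        return len(self.records)

    def labels(self, task: int = 1) -> np.ndarray:
        attr = "task1_label" if task == 1 else "task2_label"
        return np.array([getattr(r, attr) for r in self.records])


def _parse_label(text: str, row: int) -> int:
    value = text.strip()
    if value in ("0", "0.0"):
        return 0
    if value in ("1", "1.0"):
        return 1
    raise ValueError(f"non-binary label {value!r} at manifest row {row}")


def load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0


def save_image(path: Path, pixels: np.ndarray) -> None:
    arr = np.clip(np.asarray(pixels) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def _find_image(image_dir: Path, image_id: str) -> Path:
    for ext in (".png", ".jpg", ".jpeg", ".PNG", ".JPG", ".JPEG"):
        p = image_dir / f"{image_id}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no image file found for id {image_id!r} in {image_dir}")


def read_manifest(csv_path, image_dir, polarity: str = "paper") -> Manifest:
    """Read a manifest CSV and its images; row order is preserved."""
    csv_path, image_dir = Path(csv_path), Path(image_dir)
    records: list[ImageRecord] = []
    with open(csv_path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"empty manifest: {csv_path}")
    start = 0
    try:  # a non-numeric label column marks a header row
        float(rows[0][1])
    except ValueError:
        start = 1
    for idx, row in enumerate(rows[start:], start=start + 1):
        if not row:
            continue
        image_id = row[0].strip()
        t1 = _parse_label(row[1], idx)
        t2 = _parse_label(row[2], idx) if len(row) > 2 and row[2].strip() != "" else None
        if polarity == "paper":
            t1 = 1 - t1
            t2 = None if t2 is None else 1 - t2
        records.append(ImageRecord(image_id, load_image(_find_image(image_dir, image_id)),
                                   t1, t2))
    ids = [r.image_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids in manifest")
    return Manifest(records, label_polarity=polarity)


def write_manifest(csv_path, manifest: Manifest) -> None:
    """Write the CSV half of a manifest in the same dialect read_manifest reads."""
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for r in manifest.records:
            t1, t2 = r.task1_label, r.task2_label
            if manifest.label_polarity == "paper":
                t1 = 1 - t1
                t2 = None if t2 is None else 1 - t2
            row = [r.image_id, t1] + ([] if t2 is None else [t2])
            writer.writerow(row)


# ---------------------------------------------------------------------------
# oversampling

def balance_indices(labels: np.ndarray, seed: int) -> np.ndarray:
    """Indices that balance classes to the majority count: every original kept,
    each minority class replicated whole ``floor(max/n)`` times and topped up
    by sampling without replacement from its originals."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any() or len(classes) == 0:
        raise ValueError("every class must be present at least once")
    target = counts.max()
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        reps, extra = divmod(target, len(idx))
        chunk = np.tile(idx, reps)
        if extra:
            chunk = np.concatenate([chunk, rng.choice(idx, size=extra, replace=False)])
        out.append(chunk)
    return np.concatenate(out)


def oversample_balance(manifest: Manifest, seed: int, task: int = 1) -> Manifest:
    """Balance a manifest by duplicating minority-class records (deterministic
    under ``seed``); duplicates keep their ``source_id`` provenance."""
    labels = manifest.labels(task)
    order = balance_indices(labels, seed)
    seen: dict[str, int] = {}
    records = []
    for i in order:
        r = manifest.records[int(i)]
        n = seen.get(r.image_id, 0)
        seen[r.image_id] = n + 1
        rid = r.image_id if n == 0 else f"{r.image_id}_dup{n}"
        records.append(ImageRecord(rid, r.pixels, r.task1_label, r.task2_label,
                                   source_id=r.image_id))
    return Manifest(records, label_polarity=manifest.label_polarity)


# ---------------------------------------------------------------------------
# patches

DEFAULT_SCALES = (1 / 5, 2 / 5, 3 / 5, 4 / 5)


@dataclass
class PatchSet:
    patches: list[np.ndarray]
    source_id: str
    scale_of_each: list[float]

    def __len__(self):
        return len(self.patches)

    def as_array(self) -> np.ndarray:
        """Stack to NCHW float32 for the network."""
        return np.stack([p.transpose(2, 0, 1) for p in self.patches]).astype(np.float32)


def bilinear_resize(patch: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize to out_size x out_size with corner-aligned sampling:
    output pixel u maps to input coordinate u * (in - 1) / (out - 1), so the
    four corners are sampled exactly."""
    patch = np.asarray(patch, dtype=np.float32)
    if patch.size == 0:
        raise ValueError("empty patch")
    h, w = patch.shape[:2]
    if (h, w) == (out_size, out_size):
        return patch.copy()

    def coords(n_in, n_out):
        if n_out == 1 or n_in == 1:
            return np.zeros(n_out)
        return np.linspace(0.0, n_in - 1.0, n_out)

    yy, xx = coords(h, out_size), coords(w, out_size)
    y0 = np.clip(np.floor(yy).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xx).astype(int), 0, w - 1)
    y1, x1 = np.minimum(y0 + 1, h - 1), np.minimum(x0 + 1, w - 1)
    fy = (yy - y0)[:, None]
    fx = (xx - x0)[None, :]
    if patch.ndim == 3:
        fy, fx = fy[..., None], fx[..., None]
    top = patch[np.ix_(y0, x0)] * (1 - fx) + patch[np.ix_(y0, x1)] * fx
    bot = patch[np.ix_(y1, x0)] * (1 - fx) + patch[np.ix_(y1, x1)] * fx
    return (top * (1 - fy) + bot * fy).astype(np.float32)


def extract_patches(rec: ImageRecord, scales=DEFAULT_SCALES, per_scale: int = 15,
                    out_size: int = 224, seed: int = 0) -> PatchSet:
    """Multi-scale center-constrained random square crops.

    For each scale s the crop side is ``round(s * min(H, W))``; crop placement
    is uniform over all positions that keep the crop inside the image *and*
    cover the image center pixel. Each crop is bilinearly resized to
    ``out_size`` squared. Deterministic under ``seed``.
    """
    img = rec.pixels
    h, w = img.shape[:2]
    short = min(h, w)
    if short * min(scales) < 8:
        raise ValueError(f"image {rec.image_id} too small ({h}x{w}) for scale {min(scales)}")
    rng = np.random.default_rng(seed)
    cr, cc = h // 2, w // 2
    patches, scale_list = [], []
    for s in scales:
        side = int(round(s * short))
        r_lo, r_hi = max(0, cr - side + 1), min(h - side, cr)
        c_lo, c_hi = max(0, cc - side + 1), min(w - side, cc)
        for _ in range(per_scale):
            r0 = int(rng.integers(r_lo, r_hi + 1))
            c0 = int(rng.integers(c_lo, c_hi + 1))
            crop = img[r0 : r0 + side, c0 : c0 + side]
            patches.append(bilinear_resize(crop, out_size))
            scale_list.append(s)
    return PatchSet(patches, rec.image_id, scale_list)


def augment(patch: np.ndarray, seed: int) -> np.ndarray:
    """Rigid augmentation: horizontal flip, vertical flip and a rotation by a
    multiple of 90 degrees, each applied with probability 1/2 under ``seed``.
    The pixel multiset is preserved exactly."""
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("augment expects a square patch")
    rng = np.random.default_rng(seed)
    out = patch
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    if rng.random() < 0.5:
        out = np.rot90(out, k=int(rng.integers(1, 4)))
    return np.ascontiguousarray(out)
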