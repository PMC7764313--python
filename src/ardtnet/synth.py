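"""Synthetic two-class dermoscopy-like image generator.

Each image is a skin-toned background (a base tone plus low-frequency noise)
with one elliptical lesion. The two task-1 classes differ in exactly the cues
a dermatologist's ABCD rule names and that the classifier should learn:

* class 0 ("benign"): near-elliptical boundary (low radial harmonic
  amplitude) and a single, uniform brown palette;
* class 1 ("melanoma-like"): strongly irregular boundary (high-amplitude
  radial harmonics, amplitude ranges disjoint from class 0) and a variegated
  palette of several pigment blobs.

Task 2 is driven by an independent attribute — internal texture variance —
so the two binary tasks are decoupled, mirroring datasets where the two
labellings are distinct.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import ImageRecord, Manifest, read_manifest, save_image, write_manifest

SKIN_TONE = np.array([0.85, 0.66, 0.55])

# pigment palette used for variegated lesions
PIGMENTS = np.array([
    [0.35, 0.22, 0.16],  # dark brown
    [0.12, 0.09, 0.09],  # near-black
    [0.55, 0.28, 0.20],  # red-brown
    [0.35, 0.38, 0.45],  # blue-gray
    [0.60, 0.45, 0.30],  # tan
])


@dataclass
class ClassParams:
    """Lesion appearance parameters for one class."""

    border_amp: tuple[float, float]        # radial harmonic amplitude range
    n_pigments: tuple[int, int]            # number of distinct pigment blobs
    eccentricity: tuple[float, float] = (1.0, 1.6)  # major/minor axis ratio


@dataclass
class SynthConfig:
    n_per_class: int = 10
    image_side: int = 448
    seed: int = 0
    class_params: dict[int, ClassParams] = field(default_factory=lambda: {
        0: ClassParams(border_amp=(0.00, 0.05), n_pigments=(1, 1)),
        1: ClassParams(border_amp=(0.25, 0.40), n_pigments=(3, 5)),
    })

    def __post_init__(self):
        a0, a1 = self.class_params[0].border_amp, self.class_params[1].border_amp
        lo, hi = (a0, a1) if a0[0] <= a1[0] else (a1, a0)
        if lo[1] >= hi[0]:
            raise ValueError("class border-irregularity amplitude ranges must be disjoint")


def _boundary_radius(theta: np.ndarray, base_r: float, amp: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Radius of the lesion boundary as a harmonic perturbation of a circle."""
    if amp == 0.0:
        return np.full_like(theta, base_r)
    pert = np.zeros_like(theta)
    for m in range(2, 8):
        a, b = rng.normal(size=2)
        pert += a * np.cos(m * theta) + b * np.sin(m * theta)
    peak = np.abs(pert).max()
    if peak > 0:
        pert = pert / peak
    return base_r * (1.0 + amp * pert)


def generate_image(class_label: int, cfg: SynthConfig, seed: int) -> ImageRecord:
    """Render one lesion image; byte-identical for identical (class, seed)."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    rng = np.random.default_rng(seed)
    side = cfg.image_side
    p = cfg.class_params[class_label]

    # skin background: base tone + smoothed low-frequency noise
    tone = SKIN_TONE + rng.normal(0, 0.03, size=3)
    noise = gaussian_filter(rng.normal(0, 1.0, size=(side, side)), sigma=side / 10.0)
    noise = noise / (np.abs(noise).max() + 1e-9)
    img = np.clip(tone[None, None, :] + 0.04 * noise[:, :, None], 0, 1)

    # lesion geometry
    cy, cx = (side / 2 + rng.uniform(-side / 12, side / 12),
              side / 2 + rng.uniform(-side / 12, side / 12))
    base_r = side * rng.uniform(0.24, 0.30)
    amp = rng.uniform(*p.border_amp)
    ecc = rng.uniform(*p.eccentricity)
    phi = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame and squash the major axis
    u = (np.cos(phi) * dx + np.sin(phi) * dy) / ecc
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    r_bound = _boundary_radius(theta, base_r, amp, rng)
    alpha = np.clip((r_bound - rho) / 1.5 + 0.5, 0.0, 1.0)  # ~1.5 px soft edge

    # lesion pigmentation
    n_pig = int(rng.integers(p.n_pigments[0], p.n_pigments[1] + 1))
    base_color = PIGMENTS[rng.integers(0, len(PIGMENTS))] + rng.normal(0, 0.02, 3)
    color = np.broadcast_to(base_color, (side, side, 3)).copy()
    for _ in range(max(0, n_pig - 1)):
        pig = PIGMENTS[rng.integers(0, len(PIGMENTS))] + rng.normal(0, 0.02, 3)
        by = cy + rng.uniform(-0.5, 0.5) * base_r
        bx = cx + rng.uniform(-0.5, 0.5) * base_r
        sig = base_r * rng.uniform(0.2, 0.45)
        wgt = np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sig**2))
        color = color * (1 - wgt[:, :, None]) + pig[None, None, :] * wgt[:, :, None]

    # internal texture: the independent attribute that defines the task-2 label
    task2_label = int(rng.integers(0, 2))
    tex_sd = 0.10 if task2_label == 1 else 0.015
    tex = gaussian_filter(rng.normal(0, 1.0, size=(side, side)), sigma=2.0)
    tex = tex / (np.abs(tex).max() + 1e-9)
    color = np.clip(color + tex_sd * tex[:, :, None], 0, 1)

    pixels = (img * (1 - alpha[:, :, None]) + color * alpha[:, :, None]).astype(np.float32)
    return ImageRecord(image_id=f"ISIC_SYN{seed % 10_000_000:07d}", pixels=pixels,
                       task1_label=class_label, task2_label=task2_label)


def make_manifest(cfg: SynthConfig) -> Manifest:
    """Generate ``2 * n_per_class`` records in memory, ids unique,
    deterministic under ``cfg.seed``."""
    records = []
    counter = 0
    for cls in (0, 1):
        ss = np.random.SeedSequence([cfg.seed, cls])
        child_seeds = ss.generate_state(cfg.n_per_class) % (2**31 - 1)
        for i in range(cfg.n_per_class):
            rec = generate_image(cls, cfg, int(child_seeds[i]))
            rec.image_id = f"ISIC_SYN{counter:07d}"
            rec.source_id = rec.image_id
            records.append(rec)
            counter += 1
    return Manifest(records, label_polarity="paper")


def generate_dataset(cfg: SynthConfig, out_dir) -> Manifest:
    """Write images (PNG) and the manifest CSV to ``out_dir`` and return the
    manifest as re-read through :func:`ardtnet.data.read_manifest`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = make_manifest(cfg)
    for rec in manifest.records:
        save_image(out_dir / f"{rec.image_id}.png", rec.pixels)
    csv_path = out_dir / "manifest.csv"
    write_manifest(csv_path, manifest)
    return read_manifest(csv_path, out_dir, polarity="paper")
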