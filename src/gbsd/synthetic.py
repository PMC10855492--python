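"""Synthetic dermoscopy-like image generation.

Every downstream stage of the pipeline (preprocessing, texture descriptors,
classifier, saliency) is exercisable on images produced here, without any
external dataset.  Two visually separable lesion classes are emulated:

* ``benign``    — near-elliptical lesion with a smooth border and homogeneous
  interior texture;
* ``malignant`` — star-convex lesion with strong harmonic border perturbation
  and heterogeneous interior texture.

Lesions are darker than the surrounding skin, which is rendered as a light
intensity gradient plus sensor noise; optional dark curvilinear hair strokes
are overlaid as acquisition artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

LABELS = ("benign", "malignant")

# Defaults for the two classes: amplitude of the radial harmonic perturbation
# of the lesion border and the intra-lesion intensity standard deviation.
BENIGN_IRREGULARITY = 0.05
MALIGNANT_IRREGULARITY = 0.35
BENIGN_TEXTURE_SIGMA = 0.03
MALIGNANT_TEXTURE_SIGMA = 0.15


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic lesion generator.

    Parameters
    ----------
    image_size:
        Pixels per side of the square image (>= 32).
    n_per_class:
        Images generated per label (>= 1).
    border_irregularity:
        Sum of harmonic amplitudes of the radial border perturbation,
        dimensionless.  ``None`` selects the per-class default
        (benign 0.05, malignant 0.35).
    texture_sigma:
        Standard deviation of the intra-lesion intensity texture on the
        [0, 1] scale.  ``None`` selects the per-class default
        (benign 0.03, malignant 0.15).
    hair_strokes:
        ``(lo, hi)`` inclusive range of hair-stroke counts per image, or a
        single fixed count.
    noise_sigma:
        Additive Gaussian sensor-noise standard deviation.
    seed:
        Master seed; per-image streams are derived with a counter-based
        scheme so that insertion order never changes earlier images.
    """

    image_size: int = 128
    n_per_class: int = 10
    border_irregularity: float | None = None
    texture_sigma: float | None = None
    hair_strokes: int | tuple[int, int] = (0, 8)
    noise_sigma: float = 0.01
    seed: int = 0
    channels: int = 1  # 1 (gray) or 3 (per-channel skin tint)

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        for name in ("border_irregularity", "texture_sigma", "noise_sigma"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")


@dataclasses.dataclass
class ImageRecord:
    """One lesion image with its label and synthetic ground truth."""

    pixels: np.ndarray  # (H, W) or (H, W, 3) float in [0, 1]
    label: str
    true_mask: np.ndarray  # (H, W) bool
    id: str
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.true_mask.shape != self.pixels.shape[:2]:
            raise ValueError("true_mask must match the spatial shape of pixels")

    @property
    def gray(self) -> np.ndarray:
        """Luminance view of the pixels."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels @ np.array([0.299, 0.587, 0.114])


def _class_params(label: str, cfg: SyntheticConfig) -> tuple[float, float]:
    irr = cfg.border_irregularity
    tex = cfg.texture_sigma
    if irr is None:
        irr = BENIGN_IRREGULARITY if label == "benign" else MALIGNANT_IRREGULARITY
    if tex is None:
        tex = BENIGN_TEXTURE_SIGMA if label == "benign" else MALIGNANT_TEXTURE_SIGMA
    return irr, tex


def _star_convex_mask(size: int, irregularity: float, rng: np.random.Generator) -> np.ndarray:
    """Filled star-convex region r(theta) = r0 (1 + sum_k a_k sin(k theta + phi_k))."""
    r0 = size * rng.uniform(0.20, 0.28)
    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    harmonics = np.arange(2, 8)
    raw = rng.uniform(0.3, 1.0, size=harmonics.size)
    amps = raw / raw.sum() * irregularity  # sum |a_k| == irregularity
    phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)
    # slight base ellipticity so the benign lesion is a near-ellipse
    ecc = rng.uniform(0.85, 1.0)
    ang = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(ang), np.sin(ang)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    rr = np.hypot(u, v / ecc)
    theta = np.arctan2(v / ecc, u)
    pert = np.zeros_like(theta)
    for k, a, p in zip(harmonics, amps, phases):
        pert += a * np.sin(k * theta + p)
    return rr <= r0 * (1.0 + pert)


def generate_lesion_image(label: str, cfg: SyntheticConfig, seed: int) -> ImageRecord:
    """Generate one labelled lesion image; deterministic for a fixed seed.

    The lesion is a filled star-convex region, darker than the background,
    whose interior texture standard deviation is set by ``cfg.texture_sigma``
    (class default if unset).  ``true_mask`` marks the lesion.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    irregularity, texture_sigma = _class_params(label, cfg)
    size = cfg.image_size
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, seed)))

    mask = _star_convex_mask(size, irregularity, rng)

    # light skin-tone background with a gentle diagonal gradient
    yy, xx = np.mgrid[0:size, 0:size]
    g0, g1 = rng.uniform(0.78, 0.88), rng.uniform(0.70, 0.80)
    bg = g0 + (g1 - g0) * (yy + xx) / (2 * size - 2)

    lesion_level = rng.uniform(0.35, 0.45)
    img = np.where(mask, lesion_level, bg)

    if texture_sigma > 0:
        blotch = gaussian_filter(rng.standard_normal((size, size)), 2.0)
        sd = blotch.std()
        if sd > 0:
            blotch *= texture_sigma / sd
        img = np.where(mask, img + blotch, img)

    # soften the lesion edge slightly so the border is not aliased
    img = gaussian_filter(img, 0.6)

    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=(size, size))

    img = np.clip(img, 0.0, 1.0)

    if cfg.channels == 3:
        tint = np.array([1.0, rng.uniform(0.82, 0.92), rng.uniform(0.72, 0.85)])
        img = np.clip(img[..., None] * tint[None, None, :], 0.0, 1.0)

    rec = ImageRecord(
        pixels=img.astype(np.float64),
        label=label,
        true_mask=mask,
        id=f"{label}_{seed:05d}",
        meta={"irregularity": irregularity, "texture_sigma": texture_sigma},
    )

    n_strokes = cfg.hair_strokes
    if isinstance(n_strokes, tuple):
        n_strokes = int(rng.integers(n_strokes[0], n_strokes[1] + 1))
    if n_strokes:
        rec = add_hair_artifacts(rec, n_strokes, seed=int(rng.integers(0, 2**31 - 1)))
    return rec


def _bezier_points(p0, p1, p2, n: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    return pts[:, 0], pts[:, 1]


def add_hair_artifacts(img: ImageRecord, n_strokes: int, seed: int) -> ImageRecord:
    """Overlay dark curvilinear hair strokes (quadratic Bezier, width 1-3 px).

    ``true_mask`` is unchanged; stroke metadata (control points, widths) is
    recorded under ``meta['hair']``.  Stroke pixels are strictly darker than
    their pre-stroke values.
    """
    if n_strokes < 0:
        raise ValueError("n_strokes must be >= 0")
    if n_strokes == 0:
        return img
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x4A1)))
    size = img.pixels.shape[0]
    px = img.pixels.copy()
    gray = px.ndim == 2
    strokes = []
    dark = np.zeros(img.pixels.shape[:2])
    for _ in range(n_strokes):
        p0 = rng.uniform(0, size, 2)
        direction = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.4, 0.9) * size
        p2 = p0 + length * np.array([np.sin(direction), np.cos(direction)])
        mid = (p0 + p2) / 2 + rng.uniform(-0.15, 0.15, 2) * size
        width = int(rng.integers(1, 4))
        ys, xs = _bezier_points(p0, mid, p2, n=3 * size)
        stroke = np.zeros_like(dark)
        half = (width - 1) / 2.0
        for dy in range(-int(np.ceil(half)), int(np.ceil(half)) + 1):
            for dx in range(-int(np.ceil(half)), int(np.ceil(half)) + 1):
                if np.hypot(dy, dx) <= half + 0.5:
                    yi = np.round(ys + dy).astype(int)
                    xi = np.round(xs + dx).astype(int)
                    ok = (yi >= 0) & (yi < size) & (xi >= 0) & (xi < size)
                    stroke[yi[ok], xi[ok]] = 1.0
        depth = rng.uniform(0.35, 0.55)
        dark = np.maximum(dark, stroke * depth)
        strokes.append(
            {"p0": p0.tolist(), "p1": mid.tolist(), "p2": p2.tolist(), "width": width}
        )
    attenuation = 1.0 - dark
    floor = 0.02  # strokes stay strictly darker but never fully black
    if gray:
        px = np.maximum(px * attenuation, np.where(dark > 0, floor, px))
        px = np.where(dark > 0, np.minimum(px, img.pixels - 1e-4), px)
    else:
        px = px * attenuation[..., None]
        hit = dark > 0
        px[hit] = np.minimum(px[hit], img.pixels[hit] - 1e-4)
    px = np.clip(px, 0.0, 1.0)
    meta = dict(img.meta)
    meta["hair"] = strokes
    return ImageRecord(pixels=px, label=img.label, true_mask=img.true_mask, id=img.id, meta=meta)


def save_image(path: Path, pixels: np.ndarray) -> None:
    arr = np.clip(np.round(pixels * 255), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def load_image(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr / 255.0


def generate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a balanced synthetic dataset: PNGs, CSV manifest, JSON sidecar.

    Returns the manifest DataFrame with columns ``id, path, label``.
    Deterministic: the same config (including seed) yields identical
    manifests and identical file checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    rows = []
    counter = 0
    for label in LABELS:
        for _ in range(cfg.n_per_class):
            rec = generate_lesion_image(label, cfg, seed=counter)
            path = img_dir / f"{rec.id}.png"
            save_image(path, rec.pixels)
            save_image(img_dir / f"{rec.id}_mask.png", rec.true_mask.astype(float))
            rows.append({"id": rec.id, "path": str(path), "label": label})
            counter += 1
    manifest = pd.DataFrame(rows, columns=["id", "path", "label"])
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "generator.json").write_text(
        json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(cfg).items()},
            indent=2,
        )
    )
    return manifest


def records_for_manifest(cfg: SyntheticConfig) -> list[ImageRecord]:
    """In-memory equivalent of :func:`generate_dataset` (same seed scheme)."""
    recs = []
    counter = 0
    for label in LABELS:
        for _ in range(cfg.n_per_class):
            recs.append(generate_lesion_image(label, cfg, seed=counter))
            counter += 1
    return recs


def dataset_checksum(out_dir: str | Path) -> str:
    """SHA-256 over all PNG bytes and the manifest's ids and labels.

    Paths are excluded so checksums are location-independent.
    """
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.rglob("*.png")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    man = pd.read_csv(out / "manifest.csv")
    h.update(man[["id", "label"]].to_csv(index=False).encode())
    return h.hexdigest()
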