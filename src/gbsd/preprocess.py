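"""Hair removal, smoothing, and adaptive-threshold ROI extraction.

The lesion is localized with a per-pixel adaptive threshold: a pixel is
foreground when its intensity falls below the mean of its local window minus
an offset (lesions are darker than the surrounding skin).  Hair artifacts are
removed beforehand with a multi-orientation morphological black-hat transform
followed by median inpainting, and the image is smoothed with a Gaussian blur.

Coordinates are row-major and 0-based; bounding boxes are half-open
``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage
from skimage.transform import resize

log = logging.getLogger("gbsd.preprocess")

ROI_SIZE = 128

# Defaults recorded from calibration on the synthetic generator.
DEFAULT_WINDOW = 31
DEFAULT_OFFSET = 0.03
DEFAULT_HAIR_KERNEL = 15
DEFAULT_HAIR_ORIENTATIONS = 8
DEFAULT_HAIR_THRESHOLD = 0.08
DEFAULT_BLUR_SIGMA = 1.0


@dataclasses.dataclass
class ROIResult:
    """Pre-processed image, lesion mask, bounding box and resized ROI."""

    cleaned: np.ndarray  # filtered full-frame image
    mask: np.ndarray  # (H, W) bool lesion mask
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    roi: np.ndarray  # (ROI_SIZE, ROI_SIZE) cropped/resized image


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    return img


def _line_footprint(length: int, angle: float) -> np.ndarray:
    """Binary linear structuring element of the given length and angle."""
    half = (length - 1) / 2.0
    t = np.linspace(-half, half, 2 * length)
    ys = np.round(t * np.sin(angle)).astype(int)
    xs = np.round(t * np.cos(angle)).astype(int)
    r = int(np.ceil(half))
    fp = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
    fp[np.clip(ys + r, 0, 2 * r), np.clip(xs + r, 0, 2 * r)] = True
    return fp


def remove_hair(
    img: np.ndarray,
    kernel_len: int = DEFAULT_HAIR_KERNEL,
    n_orientations: int = DEFAULT_HAIR_ORIENTATIONS,
    threshold: float = DEFAULT_HAIR_THRESHOLD,
) -> np.ndarray:
    """Remove dark hair strokes by black-hat detection + median inpainting.

    A grayscale black-hat (closing minus image) is computed with linear
    structuring elements at ``n_orientations`` angles; the union of thresholded
    responses forms the hair mask, whose pixels are replaced by the median of
    nearby non-hair pixels.  The output intensity range is preserved.
    """
    if kernel_len < 3:
        raise ValueError("kernel_len must be >= 3")
    gray = _as_gray(img)
    votes = np.zeros(gray.shape, dtype=np.int64)
    for i in range(n_orientations):
        fp = _line_footprint(kernel_len, np.pi * i / n_orientations)
        closed = ndimage.grey_closing(gray, footprint=fp, mode="reflect")
        votes += (closed - gray) > threshold
    # a hair is thin in almost every orientation, so most linear closings
    # respond; the lesion boundary responds only tangentially and is vetoed
    hair = votes >= max(2, n_orientations // 2)
    if not hair.any():
        return gray.copy()
    # hairs are a few pixels wide: anything surviving a 5x5 erosion is a
    # wide dark region (pigment blotch), not a hair — subtract it
    wide = ndimage.binary_erosion(hair, structure=np.ones((5, 5)))
    wide = ndimage.binary_dilation(wide, structure=np.ones((3, 3)), iterations=3)
    hair &= ~wide
    if not hair.any():
        return gray.copy()
    # hairs are long curvilinear components; drop compact dark blobs
    # (pigment blotches) whose extent is below the kernel length
    labels, n = ndimage.label(hair, structure=np.ones((3, 3)))
    if n:
        objs = ndimage.find_objects(labels)
        keep = np.zeros(n + 1, dtype=bool)
        for idx, sl in enumerate(objs, start=1):
            span = max(sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
            if span >= kernel_len:
                keep[idx] = True
        hair = keep[labels]
    if not hair.any():
        return gray.copy()
    hair = ndimage.binary_dilation(hair, iterations=1)

    out = gray.copy()
    out[hair] = np.nan
    # median of non-hair pixels within a growing window until all filled
    win = 5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        while np.isnan(out).any() and win <= max(out.shape):
            sw = np.lib.stride_tricks.sliding_window_view(
                np.pad(out, win // 2, mode="reflect"), (win, win)
            )
            med = np.nanmedian(sw.reshape(out.shape[0], out.shape[1], -1), axis=-1)
            nan = np.isnan(out)
            out[nan] = med[nan]
            win += 4
    np.nan_to_num(out, copy=False, nan=float(np.nanmedian(gray)))
    return np.clip(out, gray.min(), gray.max())


def smooth(img: np.ndarray, sigma: float = DEFAULT_BLUR_SIGMA) -> np.ndarray:
    """Gaussian blur; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = _as_gray(img)
    if sigma == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma, mode="reflect")


def adaptive_threshold_mask(
    img: np.ndarray,
    window: int = DEFAULT_WINDOW,
    offset: float = DEFAULT_OFFSET,
    darker: bool = True,
) -> np.ndarray:
    """Per-pixel adaptive threshold against the local-window mean.

    A pixel is foreground when its intensity is below (``darker=True``) or
    above the mean of its ``window`` x ``window`` neighbourhood by more than
    ``offset``.  Reflective border padding.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    gray = _as_gray(img)
    local_mean = ndimage.uniform_filter(gray, size=window, mode="reflect")
    if darker:
        return gray < local_mean - offset
    return gray > local_mean + offset


def extract_roi(img: np.ndarray, mask: np.ndarray, margin: float = 0.10) -> ROIResult:
    """Keep the largest connected component, fill holes, crop and resize.

    The crop takes a ``margin`` fraction around the component's bounding box;
    the ROI is resized to ``ROI_SIZE`` x ``ROI_SIZE``.  An empty mask falls
    back to the full-frame ROI with a logged warning.
    """
    gray = _as_gray(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask must have the same shape as img")
    h, w = gray.shape
    if not mask.any():
        log.warning("empty lesion mask: falling back to full-image ROI")
        clean = np.zeros_like(mask)
        bbox = (0, 0, h, w)
        roi = resize(gray, (ROI_SIZE, ROI_SIZE), anti_aliasing=True)
        return ROIResult(cleaned=gray, mask=clean, bbox=bbox, roi=roi)

    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
    mask = ndimage.binary_fill_holes(mask)

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    mr = int(round(margin * (r1 - r0)))
    mc = int(round(margin * (c1 - c0)))
    bbox = (max(0, r0 - mr), max(0, c0 - mc), min(h, r1 + mr), min(w, c1 + mc))
    crop = gray[bbox[0] : bbox[2], bbox[1] : bbox[3]]
    roi = resize(crop, (ROI_SIZE, ROI_SIZE), anti_aliasing=True)
    return ROIResult(cleaned=gray, mask=mask, bbox=bbox, roi=roi)


def preprocess_image(
    img: np.ndarray,
    window: int = DEFAULT_WINDOW,
    offset: float = DEFAULT_OFFSET,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    hair_kernel: int = DEFAULT_HAIR_KERNEL,
) -> ROIResult:
    """Full pipeline: hair removal -> blur -> adaptive threshold -> ROI."""
    cleaned = remove_hair(img, kernel_len=hair_kernel)
    blurred = smooth(cleaned, blur_sigma)
    mask = adaptive_threshold_mask(blurred, window=window, offset=offset)
    # bridge small gaps in the boundary response so hole filling can close it
    mask = ndimage.binary_closing(mask, structure=np.ones((5, 5)), border_value=0)
    res = extract_roi(blurred, mask)
    return ROIResult(cleaned=cleaned, mask=res.mask, bbox=res.bbox, roi=res.roi)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
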