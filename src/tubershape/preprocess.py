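"""Image preprocessing: raw RGB capture -> clean centred binary mask.

The chain mirrors a fixed machine-vision setup: a single bright tuber on a
near-black board, photographed at 3072×2048 and worked on at 614×410.  Stages,
in order: region-interpolation resize to the reference extents, weighted-average
graying, Otsu binarisation, morphological open/close, median (majority) edge
smoothing, largest-component selection, and centroid centring.

All images are numpy arrays: RGB as ``(H, W, 3) uint8``, grayscale as
``(H, W) uint8``, masks as ``(H, W) bool``.  Pixel coordinates are
``(x right, y down)``, 0-based, with pixel centres at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components

from .errors import (
    DegenerateSizeError,
    EmptyMaskError,
    NoContrastError,
    ObjectTooLargeError,
    StageError,
)

#: Working extents as (width, height): all thresholds downstream assume them.
REFERENCE_EXTENTS: tuple[int, int] = (614, 410)

# ITU-R 601 luma weights; the conventional "weighted average" graying.
_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

_MIN_EXTENT = 8


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain."""

    scale_factor: float = 0.2
    reference_extents: tuple[int, int] = REFERENCE_EXTENTS  # (width, height)
    kernel_radius: int = 2      # disc radius of the morphological element
    median_window: int = 5      # odd window of the majority filter
    bright_object: bool = True  # object brighter than background


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < _MIN_EXTENT or img.shape[1] < _MIN_EXTENT:
        raise DegenerateSizeError(f"image extents {img.shape[:2]} below minimum {_MIN_EXTENT}")
    return img.astype(np.uint8, copy=False)


def resize_region(img: np.ndarray, factor: float) -> np.ndarray:
    """Downscale by area (box) interpolation: each output pixel is the mean
    of its source region.

    Output extents are ``round(H*factor) × round(W*factor)``, so a 3072×2048
    capture at factor 0.2 lands exactly on 614×410.
    """
    img = _as_rgb(img)
    if not 0 < factor <= 1:
        raise ValueError(f"scale factor must be in (0, 1], got {factor}")
    h, w = img.shape[:2]
    out_h = int(np.floor(h * factor + 0.5))
    out_w = int(np.floor(w * factor + 0.5))
    if out_h < _MIN_EXTENT or out_w < _MIN_EXTENT:
        raise DegenerateSizeError(f"resize to {out_w}×{out_h} is degenerate")
    return _resize_box(img, out_h, out_w)


def _resize_box(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    if (out_h, out_w) == img.shape[:2]:
        return img.copy()
    pil = Image.fromarray(img)
    out = pil.resize((out_w, out_h), resample=Image.Resampling.BOX)
    return np.asarray(out)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Weighted-average graying with 0.299/0.587/0.114 channel weights."""
    img = _as_rgb(img)
    gray = img.astype(np.float64) @ _GRAY_WEIGHTS
    return np.rint(gray).clip(0, 255).astype(np.uint8)


def otsu_binarize(gray: np.ndarray, bright_object: bool = True) -> tuple[np.ndarray, int]:
    """Threshold with Otsu's method (maximum between-class variance).

    Returns ``(mask, threshold)``.  With ``bright_object`` the foreground is
    the set of pixels strictly above the threshold (object on a black board);
    flip the flag for dark objects on bright backgrounds.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    if np.ptp(gray) == 0:
        raise NoContrastError("single-intensity image: Otsu threshold undefined")
    thr = threshold_otsu(gray)
    mask = gray > thr if bright_object else gray <= thr
    return mask, int(thr)


def morphological_clean(mask: np.ndarray, kernel_radius: int = 2) -> np.ndarray:
    """Opening followed by closing with a disc element.

    Removes isolated specks smaller than the element and fills interior holes
    smaller than the element.
    """
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    footprint = morphology.disk(kernel_radius)
    out = morphology.opening(mask, footprint)
    if not out.any():
        raise EmptyMaskError("mask emptied by morphological opening")
    return morphology.closing(out, footprint)


def median_smooth(mask: np.ndarray, window: int = 5) -> np.ndarray:
    """Majority (median) filter on the binary mask; smooths jagged edges.

    Windows are edge-replicated outside the canvas, so uniform masks are
    exact fixed points.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    mask = np.asarray(mask, dtype=bool)
    out = ndimage.median_filter(mask.astype(np.uint8), size=window, mode="nearest")
    return out.astype(bool)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("empty mask")
    labels, n = label_components(mask, connectivity=2, return_num=True)
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def center_translate(mask: np.ndarray) -> np.ndarray:
    """Translate the foreground (integer shift) so its centroid sits at the
    image centre.  Foreground pixel count is preserved exactly."""
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise EmptyMaskError("cannot centre an empty mask")
    h, w = mask.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy = int(np.round(cy - ys.mean()))
    dx = int(np.round(cx - xs.mean()))
    ny, nx = ys + dy, xs + dx
    if ny.min() < 0 or nx.min() < 0 or ny.max() >= h or nx.max() >= w:
        raise ObjectTooLargeError("centring would push the object off the canvas")
    out = np.zeros_like(mask)
    out[ny, nx] = True
    return out


def preprocess_pipeline(img: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: resize to reference extents -> gray -> Otsu -> morphological
    clean -> median smooth -> largest component -> centre.

    The working size is forced to ``config.reference_extents`` regardless of
    the input size, since the irregularity thresholds are only valid there.
    Stage failures are re-raised as :class:`StageError` with the stage name.
    """
    cfg = config or PreprocessConfig()
    ref_w, ref_h = cfg.reference_extents

    def run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise StageError(stage, exc) from exc

    img = run("input", _as_rgb, img)
    if img.shape[:2] != (ref_h, ref_w):
        img = run("resize", _resize_box, img, ref_h, ref_w)
    gray = run("gray", to_gray, img)
    mask, _ = run("binarize", otsu_binarize, gray, cfg.bright_object)
    mask = run("morphology", morphological_clean, mask, cfg.kernel_radius)
    mask = run("median", median_smooth, mask, cfg.median_window)
    mask = run("component", largest_component, mask)
    mask = run("center", center_translate, mask)
    return mask
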