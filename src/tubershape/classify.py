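"""Regular/irregular labelling by fixed feature thresholds.

The decision rules (valid at the 614×410 working extents):

* Hausdorff distance:  H <= 21 px  -> regular;  H > 21  -> irregular.
* IoU:                 IoU > 0.925 -> regular;  IoU <= 0.925 -> irregular.

The Hausdorff threshold is a pixel length and therefore scales with the
working resolution — it is only meaningful at the reference extents, which the
preprocessing pipeline enforces.  The IoU threshold is dimensionless and
resolution-independent.

For multi-view captures of one object the features are aggregated across
views (max H, min IoU) before thresholding, so that an irregularity visible
from any angle is not missed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .features import ShapeFeatures, compute_features
from .preprocess import REFERENCE_EXTENTS, PreprocessConfig, preprocess_pipeline


class Label(str, Enum):
    REGULAR = "regular"
    IRREGULAR = "irregular"


#: Marker used by the CLI when the pipeline fails on an image.
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class Thresholds:
    """Fixed decision thresholds, valid at ``reference_extents``."""

    hd_threshold: float = 21.0
    iou_threshold: float = 0.925
    reference_extents: tuple[int, int] = REFERENCE_EXTENTS  # (width, height)

    def __post_init__(self):
        if self.hd_threshold <= 0:
            raise ValueError("hd_threshold must be positive")
        if not 0 < self.iou_threshold < 1:
            raise ValueError("iou_threshold must be in (0, 1)")


def classify_hd(h: float, t: Thresholds | None = None) -> Label:
    """Irregular iff the Hausdorff distance strictly exceeds the threshold."""
    t = t or Thresholds()
    if h < 0:
        raise ValueError(f"Hausdorff distance cannot be negative, got {h}")
    return Label.IRREGULAR if h > t.hd_threshold else Label.REGULAR


def classify_iou(iou: float, t: Thresholds | None = None) -> Label:
    """Irregular iff the IoU is at or below the threshold."""
    t = t or Thresholds()
    if not 0 <= iou <= 1:
        raise ValueError(f"IoU must be in [0, 1], got {iou}")
    return Label.IRREGULAR if iou <= t.iou_threshold else Label.REGULAR


def aggregate_views(views: list[ShapeFeatures]) -> ShapeFeatures:
    """Combine per-view features of one object: max Hausdorff, min IoU.

    The perimeter and area ratios are carried from the view with the largest
    Hausdorff distance (the most irregular-looking pose).
    """
    if not views:
        raise ValueError("aggregate_views needs at least one view")
    worst = int(np.argmax([v.hausdorff for v in views]))
    return ShapeFeatures(
        perimeter_ratio=views[worst].perimeter_ratio,
        area_ratio=views[worst].area_ratio,
        hausdorff=max(v.hausdorff for v in views),
        iou=min(v.iou for v in views),
    )


def classify_features(feats: ShapeFeatures, t: Thresholds | None = None,
                      mode: str = "iou") -> Label:
    """Apply the thresholds to already-computed features.

    ``mode``: ``"hd"``, ``"iou"``, or ``"both"`` (OR-vote: irregular if either
    feature votes irregular — an extension beyond the two single-feature
    rules, conservative towards discarding defects).
    """
    t = t or Thresholds()
    if mode == "hd":
        return classify_hd(feats.hausdorff, t)
    if mode == "iou":
        return classify_iou(feats.iou, t)
    if mode == "both":
        votes = (classify_hd(feats.hausdorff, t), classify_iou(feats.iou, t))
        return Label.IRREGULAR if Label.IRREGULAR in votes else Label.REGULAR
    raise ValueError(f"unknown mode {mode!r}")


def classify_image(img: np.ndarray, t: Thresholds | None = None, mode: str = "iou",
                   config: PreprocessConfig | None = None) -> tuple[Label, ShapeFeatures]:
    """End-to-end: preprocess an RGB image, compute features, threshold.

    The preprocessing pipeline forces the working size to the reference
    extents, so the thresholds apply.  Pipeline failures propagate as
    :class:`~tubershape.errors.StageError`; the CLI reports such images as
    undetermined.
    """
    t = t or Thresholds()
    cfg = config or PreprocessConfig(reference_extents=t.reference_extents)
    mask = preprocess_pipeline(img, cfg)
    feats, _, _ = compute_features(mask)
    return classify_features(feats, t, mode), feats
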