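"""The four irregularity features of a contour against its fitted ellipse.

Given the object contour (point set Q, perimeter C_p, area A_p) and the
least-squares ellipse (boundary samples P, perimeter C_e, area A_e):

* perimeter ratio  ``C = C_p / C_e``
* area ratio       ``A = A_p / A_e``
* bidirectional Hausdorff distance
  ``H(P, Q) = max(h(P, Q), h(Q, P))`` with
  ``h(P, Q) = max_{p in P} min_{q in Q} ||p - q||_2``
* IoU of the filled contour region (truth) and the filled ellipse (prediction)

For a regular, ellipse-like object C and A sit near 1, H near 0 and IoU near
1; protrusions and lobes drive H up and IoU down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .contour import Contour, contour_to_mask, extract_contour, polygon_area, polygon_perimeter
from .ellipse import EllipseParams, ellipse_area, ellipse_perimeter, fit_ellipse_lsq, sample_ellipse
from .errors import EmptyMaskError, ExtentMismatchError

_CHUNK = 512  # rows of P per pairwise-distance block

#: Chain resampling step (px) for perimeter measurement.  The raw 8-connected
#: pixel chain overestimates the length of a smooth boundary by ~5% (staircase
#: digitisation bias); measuring the polygon through every 4th chain pixel
#: removes the bias to well under 1% without smoothing the geometry.
_PERIMETER_STEP = 4


@dataclass(frozen=True)
class ShapeFeatures:
    """One view's irregularity scores."""

    perimeter_ratio: float
    area_ratio: float
    hausdorff: float
    iou: float

    def to_dict(self) -> dict:
        return {"perimeter_ratio": self.perimeter_ratio, "area_ratio": self.area_ratio,
                "hausdorff": self.hausdorff, "iou": self.iou}


def perimeter_ratio(contour: Contour, e: EllipseParams) -> float:
    """C = contour perimeter / fitted-ellipse perimeter."""
    return polygon_perimeter(contour) / ellipse_perimeter(e)


def area_ratio(contour: Contour, e: EllipseParams) -> float:
    """A = contour area / fitted-ellipse area."""
    return polygon_area(contour) / ellipse_area(e)


def _check_set(pts: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{name} must be an (n, 2) array, got {pts.shape}")
    if len(pts) == 0:
        raise ValueError(f"{name} must be nonempty")
    return pts


def directed_hausdorff(p_set: np.ndarray, q_set: np.ndarray) -> float:
    """h(P, Q): the largest, over points of P, distance to the nearest point
    of Q.  Computed by exact pairwise L2 distances (blocked to bound memory),
    so it matches a brute-force double loop bit for bit."""
    P = _check_set(p_set, "P")
    Q = _check_set(q_set, "Q")
    worst = 0.0
    for i in range(0, len(P), _CHUNK):
        d = cdist(P[i:i + _CHUNK], Q).min(axis=1).max()
        worst = max(worst, float(d))
    return worst


def hausdorff(p_set: np.ndarray, q_set: np.ndarray) -> float:
    """Bidirectional Hausdorff distance: max of the two directed distances.

    Symmetric, nonnegative, zero iff the sets are equal; measures the maximum
    degree of mismatch between the two boundaries.
    """
    return max(directed_hausdorff(p_set, q_set), directed_hausdorff(q_set, p_set))


def mask_iou(m1: np.ndarray, m2: np.ndarray) -> float:
    """Intersection over union of two same-extent binary masks."""
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    if m1.shape != m2.shape:
        raise ExtentMismatchError(f"mask extents differ: {m1.shape} vs {m2.shape}")
    union = np.logical_or(m1, m2).sum()
    if union == 0:
        raise EmptyMaskError("both masks are empty; IoU undefined")
    inter = np.logical_and(m1, m2).sum()
    return float(inter) / float(union)


def compute_features(mask: np.ndarray, max_spacing: float = 1.0,
                     contour_method: str = "trace") -> tuple[ShapeFeatures, Contour, EllipseParams]:
    """Full feature extraction from a preprocessed binary mask.

    Extracts the contour, fits the ellipse to the contour points, samples the
    ellipse boundary at ``max_spacing`` and computes all four scores.
    Returns ``(features, contour, ellipse)``.
    """
    c = extract_contour(mask, method=contour_method)
    e = fit_ellipse_lsq(c.points)
    p_set = sample_ellipse(e, max_spacing)
    h = hausdorff(p_set, c.points)
    cmask = contour_to_mask(c, mask.shape)
    emask = _ellipse_mask_clipped(e, mask.shape)
    # Perimeter on the resampled chain (see _PERIMETER_STEP): a pixel-chain
    # polygon would inflate C_p by the staircase bias.
    c_meas = Contour(c.points[::_PERIMETER_STEP]) if c.n >= 3 * _PERIMETER_STEP else c
    feats = ShapeFeatures(
        perimeter_ratio=perimeter_ratio(c_meas, e),
        area_ratio=area_ratio(c, e),
        hausdorff=h,
        iou=mask_iou(cmask, emask),
    )
    return feats, c, e


def _ellipse_mask_clipped(e: EllipseParams, extents: tuple[int, int]) -> np.ndarray:
    # Rasterise directly from the implicit inequality; a fitted ellipse may
    # overhang the canvas slightly for objects near the border, in which case
    # the off-canvas part simply does not contribute pixels.
    import math

    h, w = extents
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - e.cx, yy - e.cy
    ct, st = math.cos(e.theta), math.sin(e.theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
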