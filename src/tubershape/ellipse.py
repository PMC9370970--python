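"""Direct least-squares ellipse fitting and ellipse geometry.

The fit minimises the algebraic distance of the conic
``A x^2 + B xy + C y^2 + D x + E y + F = 0`` to the points, subject to the
ellipse constraint ``4AC - B^2 = 1`` (Fitzgibbon's direct method, in the
numerically stabilised Halir–Flusser block form, with mean-centred
coordinates).  The constraint guarantees the minimiser is an ellipse, never a
parabola or hyperbola, which is what makes the method safe on noisy contours.

Also provided: conversion between conic and geometric parameters, parametric
boundary sampling, Ramanujan's perimeter approximation, and rasterisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import EllipseFitError, NotAnEllipseError


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse: centre ``(cx, cy)``, semi-axes ``a >= b > 0`` and
    major-axis angle ``theta`` canonicalised to ``[0, pi)``."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float

    def __post_init__(self):
        a, b, theta = self.a, self.b, self.theta
        if a < b:
            a, b = b, a
            theta += math.pi / 2
        if b <= 0:
            raise ValueError(f"semi-minor axis must be positive, got {b}")
        object.__setattr__(self, "a", float(a))
        object.__setattr__(self, "b", float(b))
        object.__setattr__(self, "theta", float(theta % math.pi))

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "a": self.a, "b": self.b,
                "theta_rad": self.theta}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseParams":
        return cls(d["cx"], d["cy"], d["a"], d["b"], d["theta_rad"])


def geometric_to_conic(e: EllipseParams) -> np.ndarray:
    """Expand centre/axes/angle into normalised conic coefficients (A..F)."""
    ct, st = math.cos(e.theta), math.sin(e.theta)
    a2, b2 = e.a ** 2, e.b ** 2
    A = ct * ct / a2 + st * st / b2
    B = 2 * ct * st * (1 / a2 - 1 / b2)
    C = st * st / a2 + ct * ct / b2
    D = -2 * A * e.cx - B * e.cy
    E = -B * e.cx - 2 * C * e.cy
    F = A * e.cx ** 2 + B * e.cx * e.cy + C * e.cy ** 2 - 1
    coef = np.array([A, B, C, D, E, F])
    return coef / np.linalg.norm(coef)


def conic_to_geometric(coef: np.ndarray) -> EllipseParams:
    """Closed-form conversion of conic coefficients to geometric parameters.

    Raises :class:`NotAnEllipseError` when the discriminant ``B^2 - 4AC`` is
    not negative.
    """
    A, B, C, D, E, F = np.asarray(coef, dtype=float)
    disc = B * B - 4 * A * C
    if not disc < 0:
        raise NotAnEllipseError(f"discriminant B^2-4AC = {disc:.3g} >= 0")
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    # Centred conic: u' M u = -Q(centre), M = [[A, B/2], [B/2, C]].
    M = np.array([[A, B / 2], [B / 2, C]])
    q0 = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    evals, evecs = np.linalg.eigh(M)
    rhs = -q0
    if rhs == 0:
        raise NotAnEllipseError("degenerate (point) conic")
    ratios = rhs / evals
    if np.any(ratios <= 0):
        raise NotAnEllipseError("conic is not a real ellipse")
    axes = np.sqrt(ratios)  # eigh sorts evals ascending -> axes descending
    a, b = axes[0], axes[1]
    vec_major = evecs[:, 0]  # smaller eigenvalue -> major axis direction
    theta = math.atan2(vec_major[1], vec_major[0])
    return EllipseParams(cx, cy, a, b, theta)


def fit_ellipse_lsq(points: np.ndarray) -> EllipseParams:
    """Fit an ellipse to ``(n, 2)`` points by direct constrained least squares.

    For points lying exactly on an ellipse the parameters are recovered to
    machine precision; for noisy points the algebraic-distance minimiser under
    ``4AC - B^2 = 1`` is returned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise EllipseFitError(f"points must be (n, 2), got {pts.shape}")
    if len(pts) < 5:
        raise EllipseFitError(f"need >= 5 points, got {len(pts)}")

    mean = pts.mean(axis=0)
    x, y = (pts - mean).T

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate point configuration (collinear?)") from exc
    M = S1 + S2 @ T
    # Apply inv(C1) for constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]].
    M = np.vstack([M[2] / 2, -M[1], M[0] / 2])
    evals, evecs = np.linalg.eig(M)
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.isreal(evals) & (np.real(cond) > 0)
    if not ok.any():
        raise EllipseFitError("no ellipse solution for these points")
    a1 = np.real(evecs[:, ok.argmax()])
    coef_centred = np.concatenate([a1, T @ a1])

    # Undo the mean shift: substitute x -> x - mx, y -> y - my.
    A, B, C, D, E, F = coef_centred
    mx, my = mean
    coef = np.array([
        A,
        B,
        C,
        D - 2 * A * mx - B * my,
        E - B * mx - 2 * C * my,
        F + A * mx * mx + B * mx * my + C * my * my - D * mx - E * my,
    ])
    try:
        return conic_to_geometric(coef / np.linalg.norm(coef))
    except NotAnEllipseError as exc:
        raise EllipseFitError(str(exc)) from exc


def algebraic_residual(points: np.ndarray, e: EllipseParams) -> float:
    """RMS algebraic distance of points to the ellipse's conic (diagnostic)."""
    coef = geometric_to_conic(e)
    x, y = np.asarray(points, dtype=float).T
    vals = (coef[0] * x * x + coef[1] * x * y + coef[2] * y * y
            + coef[3] * x + coef[4] * y + coef[5])
    return float(np.sqrt(np.mean(vals ** 2)))


def sample_ellipse(e: EllipseParams, max_spacing: float = 1.0) -> np.ndarray:
    """Parametric boundary samples with adjacent spacing <= ``max_spacing``.

    The parametric speed is bounded by ``a``, so ``N = ceil(2*pi*a /
    max_spacing)`` uniform parameter steps guarantee the spacing bound.
    """
    if max_spacing <= 0:
        raise ValueError("max_spacing must be positive")
    n = max(int(math.ceil(2 * math.pi * e.a / max_spacing)), 16)
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    ct, st = math.cos(e.theta), math.sin(e.theta)
    x = e.cx + e.a * np.cos(t) * ct - e.b * np.sin(t) * st
    y = e.cy + e.a * np.cos(t) * st + e.b * np.sin(t) * ct
    return np.column_stack([x, y])


def ellipse_perimeter(e: EllipseParams) -> float:
    """Ramanujan's second approximation to the ellipse circumference
    (relative error < 1e-4 up to aspect ratio 5)."""
    a, b = e.a, e.b
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def ellipse_area(e: EllipseParams) -> float:
    """Exact area ``pi * a * b``."""
    return math.pi * e.a * e.b


def ellipse_extents(e: EllipseParams) -> tuple[float, float]:
    """Axis-aligned half-extents (half-width, half-height) of the ellipse."""
    ct, st = math.cos(e.theta), math.sin(e.theta)
    half_w = math.sqrt((e.a * ct) ** 2 + (e.b * st) ** 2)
    half_h = math.sqrt((e.a * st) ** 2 + (e.b * ct) ** 2)
    return half_w, half_h


def ellipse_mask(e: EllipseParams, extents: tuple[int, int]) -> np.ndarray:
    """Rasterise the filled ellipse: pixels whose centres satisfy the implicit
    inequality <= 1 on an ``extents = (H, W)`` canvas."""
    h, w = extents
    half_w, half_h = ellipse_extents(e)
    if (e.cx - half_w < -0.5 or e.cx + half_w > w - 0.5
            or e.cy - half_h < -0.5 or e.cy + half_h > h - 0.5):
        raise ValueError("ellipse exceeds the canvas extents")
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - e.cx, yy - e.cy
    ct, st = math.cos(e.theta), math.sin(e.theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
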