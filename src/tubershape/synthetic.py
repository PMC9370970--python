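"""Synthetic tuber-like image generator with analytic ground truth.

Shapes are star-convex radial perturbations of a base ellipse:

    r(phi) = r_ellipse(phi) * (1 + amplitude * cos(k*phi + phase)) + jitter(phi)

where ``r_ellipse`` is the polar radius of the base ellipse about its centre,
``k`` is the lobe count and ``jitter`` is a smooth random high-order harmonic
perturbation (RMS ``boundary_jitter`` pixels) standing in for natural surface
roughness.  ``amplitude = 0`` yields a regular, ellipse-like object;
amplitudes of 0.15 and above produce visibly lobed, irregular objects.

Rendering emulates the capture setup the detector targets: a yellow-brown
object (gray level ~190) on a near-black board (gray level ~30) with Gaussian
pixel noise, strongly bimodal so Otsu segmentation is reliable.  Everything
is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import Label
from .errors import SpecError

#: Default canvas (H, W): the detector's reference working extents.
DEFAULT_EXTENTS: tuple[int, int] = (410, 614)

#: Documented sampling ranges for random datasets.
SEMI_MAJOR_RANGE = (80.0, 140.0)
ASPECT_RANGE = (0.55, 0.95)          # b/a
LOBE_COUNT_CHOICES = (3, 4, 5, 6)
IRREGULAR_AMPLITUDE_RANGE = (0.25, 0.45)
REGULAR_JITTER = 0.5
IRREGULAR_JITTER = 1.0
_CANVAS_MARGIN = 8.0
_CENTER_WOBBLE = 12.0

#: Generator class boundary: lobed shapes at or above this amplitude are
#: labelled irregular.
IRREGULAR_AMPLITUDE_MIN = 0.15

_JITTER_ORDERS = np.arange(8, 16)


@dataclass(frozen=True)
class Photometry:
    """Pixel statistics of the emulated capture."""

    object_color: tuple[int, int, int] = (220, 190, 130)   # luma ~192
    background_color: tuple[int, int, int] = (30, 30, 30)
    noise_sigma: float = 8.0


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic shape."""

    a: float
    b: float
    theta: float = 0.0
    center: tuple[float, float] = (307.0, 205.0)  # (cx, cy)
    lobe_count: int = 0
    lobe_amplitude: float = 0.0
    lobe_phase: float = 0.0
    boundary_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.b <= self.a:
            raise SpecError(f"need 0 < b <= a, got a={self.a}, b={self.b}")
        if self.lobe_count < 0:
            raise SpecError("lobe_count must be >= 0")
        if not 0 <= self.lobe_amplitude <= 0.5:
            raise SpecError(f"lobe_amplitude must be in [0, 0.5], got {self.lobe_amplitude}")
        if self.boundary_jitter < 0:
            raise SpecError("boundary_jitter must be >= 0")

    @property
    def truth_label(self) -> Label:
        irregular = self.lobe_count >= 1 and self.lobe_amplitude >= IRREGULAR_AMPLITUDE_MIN
        return Label.IRREGULAR if irregular else Label.REGULAR

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "theta": self.theta, "center": list(self.center),
                "lobe_count": self.lobe_count, "lobe_amplitude": self.lobe_amplitude,
                "lobe_phase": self.lobe_phase, "boundary_jitter": self.boundary_jitter,
                "seed": self.seed}


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray       # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool, the analytic interior
    truth_label: Label
    spec: ShapeSpec


def _jitter_coefficients(spec: ShapeSpec) -> np.ndarray:
    """Harmonic jitter coefficients, deterministic in the spec's seed."""
    if spec.boundary_jitter == 0:
        return np.zeros(2 * len(_JITTER_ORDERS))
    rng = np.random.default_rng(spec.seed)
    scale = spec.boundary_jitter / math.sqrt(len(_JITTER_ORDERS))
    return rng.normal(0.0, scale, size=2 * len(_JITTER_ORDERS))


def radial_profile(spec: ShapeSpec, phi: np.ndarray | float) -> np.ndarray:
    """Boundary radius r(phi) about the shape centre, in pixels."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    rel = phi - spec.theta
    r_e = spec.a * spec.b / np.sqrt((spec.b * np.cos(rel)) ** 2 + (spec.a * np.sin(rel)) ** 2)
    factor = np.ones_like(phi)
    if spec.lobe_count >= 1 and spec.lobe_amplitude > 0:
        factor += spec.lobe_amplitude * np.cos(spec.lobe_count * phi + spec.lobe_phase)
    r = r_e * factor
    coeffs = _jitter_coefficients(spec)
    if coeffs.any():
        c, s = np.split(coeffs, 2)
        r = r + (np.cos(np.outer(phi, _JITTER_ORDERS)) @ c
                 + np.sin(np.outer(phi, _JITTER_ORDERS)) @ s)
    if np.any(r <= 0):
        raise SpecError("radial profile is nonpositive somewhere; spec invalid")
    return r


def truth_mask(spec: ShapeSpec, extents: tuple[int, int] = DEFAULT_EXTENTS) -> np.ndarray:
    """Analytic interior of the shape rasterised at pixel centres."""
    h, w = extents
    cx, cy = spec.center
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    rho = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    return rho <= radial_profile(spec, phi.ravel()).reshape(phi.shape)


def max_radius(spec: ShapeSpec, n: int = 4096) -> float:
    phi = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return float(radial_profile(spec, phi).max())


def polar_area(spec: ShapeSpec, n: int = 8192) -> float:
    """Analytic shape area by the polar integral (1/2) * int r(phi)^2 dphi."""
    phi = np.linspace(0, 2 * math.pi, n, endpoint=False)
    r = radial_profile(spec, phi)
    return 0.5 * float(np.sum(r ** 2)) * (2 * math.pi / n)


def render_sample(spec: ShapeSpec, extents: tuple[int, int] = DEFAULT_EXTENTS,
                  photometry: Photometry | None = None) -> SyntheticSample:
    """Render the shape to an RGB image plus its analytic ground-truth mask."""
    phot = photometry or Photometry()
    h, w = extents
    cx, cy = spec.center
    rmax = max_radius(spec)
    if (cx - rmax < _CANVAS_MARGIN / 2 or cx + rmax > w - 1 - _CANVAS_MARGIN / 2
            or cy - rmax < _CANVAS_MARGIN / 2 or cy + rmax > h - 1 - _CANVAS_MARGIN / 2):
        raise SpecError("shape does not fit in the canvas with margin")
    mask = truth_mask(spec, extents)
    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(phot.background_color, dtype=float)
    img[mask] = np.asarray(phot.object_color, dtype=float)
    img += rng.normal(0.0, phot.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSample(image=img, truth_mask=mask, truth_label=spec.truth_label, spec=spec)


def _random_spec(rng: np.random.Generator, irregular: bool,
                 extents: tuple[int, int]) -> ShapeSpec:
    h, w = extents
    a = rng.uniform(*SEMI_MAJOR_RANGE)
    b = a * rng.uniform(*ASPECT_RANGE)
    theta = rng.uniform(0, math.pi)
    cx = (w - 1) / 2 + rng.uniform(-_CENTER_WOBBLE, _CENTER_WOBBLE)
    cy = (h - 1) / 2 + rng.uniform(-_CENTER_WOBBLE, _CENTER_WOBBLE)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    if irregular:
        # Cap the amplitude so the lobed shape still fits the canvas.
        half = min(h, w) / 2
        amp_cap = (half - _CANVAS_MARGIN - _CENTER_WOBBLE - 4 * IRREGULAR_JITTER) / a - 1
        lo, hi = IRREGULAR_AMPLITUDE_RANGE
        amp = rng.uniform(lo, min(hi, amp_cap))
        return ShapeSpec(a=a, b=b, theta=theta, center=(cx, cy),
                         lobe_count=int(rng.choice(LOBE_COUNT_CHOICES)),
                         lobe_amplitude=float(amp),
                         lobe_phase=rng.uniform(0, 2 * math.pi),
                         boundary_jitter=IRREGULAR_JITTER, seed=seed)
    return ShapeSpec(a=a, b=b, theta=theta, center=(cx, cy),
                     boundary_jitter=REGULAR_JITTER, seed=seed)


def render_dataset(n_regular: int, n_irregular: int, seed: int = 0,
                   extents: tuple[int, int] = DEFAULT_EXTENTS,
                   photometry: Photometry | None = None) -> list[SyntheticSample]:
    """Reproducible labelled dataset: ``n_regular`` unperturbed ellipses and
    ``n_irregular`` lobed shapes, parameters drawn from the documented ranges."""
    if n_regular < 0 or n_irregular < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    samples = [render_sample(_random_spec(rng, False, extents), extents, photometry)
               for _ in range(n_regular)]
    samples += [render_sample(_random_spec(rng, True, extents), extents, photometry)
                for _ in range(n_irregular)]
    return samples


def write_dataset(samples: list[SyntheticSample], out_dir) -> None:
    """Write PNGs plus a ``labels.csv`` (file, label, spec JSON)."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["file,label,spec"]
    for i, s in enumerate(samples):
        name = f"sample_{i:04d}.png"
        Image.fromarray(s.image).save(out / name)
        rows.append(f'{name},{s.truth_label.value},"{json.dumps(s.spec.to_dict()).replace(chr(34), chr(39))}"')
    (out / "labels.csv").write_text("\n".join(rows) + "\n")
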