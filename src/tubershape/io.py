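"""File I/O helpers: images, masks and run configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .classify import Thresholds
from .preprocess import PreprocessConfig


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)).save(path)


def load_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def load_config(path) -> tuple[Thresholds, PreprocessConfig, dict]:
    """Load thresholds + preprocessing parameters from TOML/YAML/JSON.

    Recognised keys (all optional): ``hd_threshold``, ``iou_threshold``,
    ``reference_extents`` ([width, height]), ``scale_factor``,
    ``kernel_radius``, ``median_window``, ``bright_object``, ``mode``.
    Returns ``(thresholds, preprocess_config, raw_dict)``.
    """
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text) or {}
    elif p.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(text)
    elif p.suffix == ".json":
        raw = json.loads(text)
    else:
        raise ValueError(f"unsupported config format: {p.suffix}")
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")

    ref = tuple(raw.get("reference_extents", Thresholds().reference_extents))
    thr = Thresholds(
        hd_threshold=float(raw.get("hd_threshold", Thresholds().hd_threshold)),
        iou_threshold=float(raw.get("iou_threshold", Thresholds().iou_threshold)),
        reference_extents=ref,
    )
    pre = PreprocessConfig(
        scale_factor=float(raw.get("scale_factor", PreprocessConfig().scale_factor)),
        reference_extents=ref,
        kernel_radius=int(raw.get("kernel_radius", PreprocessConfig().kernel_radius)),
        median_window=int(raw.get("median_window", PreprocessConfig().median_window)),
        bright_object=bool(raw.get("bright_object", True)),
    )
    return thr, pre, raw
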