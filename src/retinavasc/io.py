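"""Reading and writing images, masks, configs, and metric reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/JPEG/TIFF) as an HxWx3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG (0 = background, anything else = foreground)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_av_mask(path: str | Path) -> np.ndarray:
    """Read an artery/vein label mask coded {0: bg, 1: artery, 2: vein, 3: unknown}."""
    with Image.open(path) as im:
        labels = np.asarray(im.convert("L"))
    if labels.max() > 3:
        raise ValueError("A/V mask must be coded with labels 0..3")
    return labels.astype(np.uint8)


def write_av_mask(path: str | Path, labels: np.ndarray) -> None:
    write_image(path, np.asarray(labels, np.uint8))


def read_config(path: str | Path) -> dict:
    """Flat key-value config (YAML)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of keys to values")
    return data


def write_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2)
        fh.write("\n")
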