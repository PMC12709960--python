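"""Read/write for depth maps, crop masks, trimaps, overlays and manifests.

Value conventions (shared by every module):

* depth maps are 2-D float arrays with values in ``[0, 255]``;
* crop masks are 2-D ``uint8`` arrays over ``{0, 1}`` (1 = crop foreground),
  stored on disk as 8-bit PNG with foreground 255;
* trimaps are 2-D ``uint8`` arrays over ``{0, 1, IGNORE}``; the ignore
  sentinel is serialized as pixel value 128;
* pixel coordinates are (row, column), 0-based, origin top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError

#: In-memory ignore label of a trimap; serialized as 128 on disk.
IGNORE: int = 2

#: Trimap ignore pixel value on disk.
IGNORE_PIXEL: int = 128

#: Known acquisition scenarios; drives depth-normalization gating downstream.
SCENARIOS = ("in-field", "lab", "uav")

_MANIFEST_COLUMNS = ("id", "depth", "rgb", "mask", "scenario")


def _require_2d(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{what} must be single-channel 2-D; got {arr.ndim}-D input"
            + (f" with {arr.shape[-1]} channels" if arr.ndim == 3 else "")
        )
    return arr


def validate_depth(depth: np.ndarray) -> np.ndarray:
    """Validate a depth map: 2-D, finite, values in [0, 255], H, W >= 3."""
    depth = np.asarray(depth, dtype=float)
    _require_2d(depth, "depth map")
    if depth.shape[0] < 3 or depth.shape[1] < 3:
        raise DimensionError(f"depth map too small: {depth.shape}; need >= 3x3")
    if not np.all(np.isfinite(depth)):
        raise FormatError("depth map contains non-finite values")
    if depth.min() < 0 or depth.max() > 255:
        raise FormatError(
            f"depth values outside [0, 255]: range [{depth.min()}, {depth.max()}]"
        )
    return depth


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Validate a binary crop mask and return it as uint8 over {0, 1}."""
    mask = np.asarray(mask)
    _require_2d(mask, "mask")
    if not np.isin(mask, (0, 1)).all():
        raise FormatError("mask values must be in {0, 1}")
    return mask.astype(np.uint8)


def read_depth(path: str | Path) -> np.ndarray:
    """Read a depth map from an 8-bit grayscale image or a ``.npy`` array.

    8-bit images are read verbatim; floating-point arrays are min-max
    rescaled onto [0, 255] (relative monocular depth carries no global
    calibration). A constant float array maps to all zeros.
    """
    path = Path(path)
    raw = np.load(path) if path.suffix.lower() == ".npy" else iio.imread(path)
    raw = _require_2d(raw, f"depth input {path.name}")
    arr = raw.astype(float)
    # 8-bit reads are already on the target scale; floating or out-of-range
    # inputs carry no calibration and are min-max rescaled per image.
    if np.issubdtype(raw.dtype, np.floating) or arr.min() < 0 or arr.max() > 255:
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) * (255.0 / (hi - lo))
    return validate_depth(arr)


def write_depth(depth: np.ndarray, path: str | Path) -> Path:
    """Write a depth map as 8-bit grayscale PNG (values rounded)."""
    depth = validate_depth(depth)
    path = Path(path)
    iio.imwrite(path, np.floor(depth + 0.5).clip(0, 255).astype(np.uint8))
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as 8-bit PNG with foreground 255."""
    mask = validate_mask(mask)
    path = Path(path)
    iio.imwrite(path, (mask * 255).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG; any pixel outside {0, 255} is a format error."""
    arr = _require_2d(iio.imread(path), f"mask {Path(path).name}")
    bad = ~np.isin(arr, (0, 255))
    if bad.any():
        raise FormatError(
            f"mask {Path(path).name} contains pixel value(s) "
            f"{sorted(np.unique(arr[bad]).tolist())} outside {{0, 255}}"
        )
    return (arr == 255).astype(np.uint8)


def write_trimap(trimap: np.ndarray, path: str | Path) -> Path:
    """Write a trimap as 8-bit PNG: 0 -> 0, 1 -> 255, IGNORE -> 128."""
    trimap = np.asarray(trimap)
    _require_2d(trimap, "trimap")
    if not np.isin(trimap, (0, 1, IGNORE)).all():
        raise FormatError(f"trimap values must be in {{0, 1, {IGNORE}}}")
    out = np.zeros(trimap.shape, dtype=np.uint8)
    out[trimap == 1] = 255
    out[trimap == IGNORE] = IGNORE_PIXEL
    iio.imwrite(Path(path), out)
    return Path(path)


def read_trimap(path: str | Path) -> np.ndarray:
    """Read a trimap PNG; pixels must be in {0, 128, 255}."""
    arr = _require_2d(iio.imread(path), f"trimap {Path(path).name}")
    bad = ~np.isin(arr, (0, IGNORE_PIXEL, 255))
    if bad.any():
        raise FormatError(
            f"trimap {Path(path).name} contains pixel value(s) "
            f"{sorted(np.unique(arr[bad]).tolist())} outside {{0, 128, 255}}"
        )
    out = np.zeros(arr.shape, dtype=np.uint8)
    out[arr == 255] = 1
    out[arr == IGNORE_PIXEL] = IGNORE
    return out


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an RGB image as an HxWx3 uint8 array."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(f"expected RGB image, got shape {arr.shape}")
    return arr[..., :3].astype(np.uint8)


def write_rgb(rgb: np.ndarray, path: str | Path) -> Path:
    iio.imwrite(Path(path), np.asarray(rgb).clip(0, 255).astype(np.uint8))
    return Path(path)


def blend_overlay(
    rgb: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.5,
    highlight: Sequence[float] = (0, 255, 0),
) -> np.ndarray:
    """Blend a highlight color into the masked pixels of an RGB image.

    Supports visual screening of pseudo masks: on ``mask == 1`` pixels the
    output is ``(1 - alpha) * rgb + alpha * highlight``; background pixels
    pass through untouched.
    """
    rgb = np.asarray(rgb, dtype=float)
    mask = validate_mask(mask)
    if rgb.shape[:2] != mask.shape:
        raise DimensionError(f"rgb shape {rgb.shape[:2]} != mask shape {mask.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise FormatError(f"alpha must be in [0, 1], got {alpha}")
    out = rgb.copy()
    hl = np.asarray(highlight, dtype=float)
    out[mask == 1] = (1.0 - alpha) * rgb[mask == 1] + alpha * hl
    return out.clip(0, 255)


@dataclass
class ManifestRecord:
    """One dataset sample: a depth map plus optional RGB and ground truth."""

    id: str
    depth: str
    rgb: str | None = None
    mask: str | None = None
    scenario: str = "in-field"


@dataclass
class DatasetManifest:
    """An ordered collection of samples, loadable from CSV or JSON."""

    records: list[ManifestRecord] = field(default_factory=list)
    root: Path = Path(".")

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("manifest sample ids are not unique")
        for r in self.records:
            if r.scenario not in SCENARIOS:
                raise FormatError(
                    f"unknown scenario {r.scenario!r} for sample {r.id}; "
                    f"expected one of {SCENARIOS}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def resolve(self, rel: str | None) -> Path | None:
        return None if rel in (None, "") else self.root / rel

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "depth": r.depth,
                    "rgb": r.rgb or "",
                    "mask": r.mask or "",
                    "scenario": r.scenario,
                }
                for r in self.records
            ],
            columns=list(_MANIFEST_COLUMNS),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps([r.__dict__ for r in self.records], indent=1))
        else:
            self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path, check_files: bool = True) -> "DatasetManifest":
        path = Path(path)
        if path.suffix.lower() == ".json":
            rows = json.loads(path.read_text())
        else:
            df = pd.read_csv(path, dtype=str).fillna("")
            missing = set(("id", "depth")) - set(df.columns)
            if missing:
                raise FormatError(f"manifest missing column(s) {sorted(missing)}")
            rows = df.to_dict("records")
        records = [
            ManifestRecord(
                id=str(r["id"]),
                depth=str(r["depth"]),
                rgb=str(r.get("rgb") or "") or None,
                mask=str(r.get("mask") or "") or None,
                scenario=str(r.get("scenario") or "in-field"),
            )
            for r in rows
        ]
        manifest = cls(records=records, root=path.parent)
        if check_files:
            for r in manifest:
                for p in (r.depth, r.rgb, r.mask):
                    if p and not (manifest.root / p).exists():
                        raise FormatError(
                            f"manifest references missing file {p!r} (sample {r.id})"
                        )
        return manifest
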