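"""Image, label-mask and metric-report I/O.

Conventions used throughout the package:

* Images are ``uint8`` arrays of shape ``(H, W, 3)`` (RGB, 0-255).
* Instance label masks are non-negative integer arrays of shape ``(H, W)``
  where 0 is background and each positive value identifies one nucleus.
  Masks are *canonical* when their positive labels are exactly ``1..n``,
  numbered by first pixel occurrence in a row-major scan.
* Coordinates are ``(row, col)``, 0-based, origin top-left; windows are
  half-open ``[r0, r0+h) x [c0, c0+w)``.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
from PIL import Image
import tifffile

__all__ = [
    "MetricRow",
    "MetricReport",
    "canonicalize_mask",
    "validate_image",
    "validate_mask",
    "read_image",
    "read_label_mask",
    "write_image",
    "write_label_mask",
    "write_report",
]

MAX_INSTANCES = 65535  # 16-bit PNG label budget

METRIC_COLUMNS = ("precision", "recall", "f1", "adc", "aji")


@dataclasses.dataclass(frozen=True)
class MetricRow:
    """Per-image evaluation result (all values in [0, 1])."""

    image_id: str
    precision: float
    recall: float
    f1: float
    adc: float
    aji: float

    def values(self) -> tuple[float, ...]:
        return (self.precision, self.recall, self.f1, self.adc, self.aji)


@dataclasses.dataclass
class MetricReport:
    """A collection of per-image metric rows plus aggregate statistics."""

    rows: list[MetricRow] = dataclasses.field(default_factory=list)

    def append(self, row: MetricRow) -> None:
        self.rows.append(row)

    def means(self) -> tuple[float, ...]:
        arr = np.array([r.values() for r in self.rows], dtype=float)
        return tuple(arr.mean(axis=0))

    def stds(self) -> tuple[float, ...]:
        arr = np.array([r.values() for r in self.rows], dtype=float)
        return tuple(arr.std(axis=0))


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check an RGB image array and return it as uint8."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have positive height and width")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("image values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check a label mask array (2-D, non-negative integers)."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D label mask, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label mask must be integer-typed, got {arr.dtype}")
    if arr.size and arr.min() < 0:
        raise ValueError("label mask contains negative values")
    return arr


def canonicalize_mask(mask: np.ndarray) -> np.ndarray:
    """Relabel positive instances to 1..n by first occurrence in row-major scan.

    Idempotent; returns an ``int32`` array. Labels with no pixels disappear,
    so downstream code can index instances densely.
    """
    arr = validate_mask(mask)
    flat = arr.ravel()
    # first occurrence order of each distinct positive label
    labels, first_idx = np.unique(flat, return_index=True)
    keep = labels > 0
    labels, first_idx = labels[keep], first_idx[keep]
    order = np.argsort(first_idx, kind="stable")
    labels = labels[order]
    lut = np.zeros(int(arr.max()) + 1 if arr.size else 1, dtype=np.int32)
    lut[labels] = np.arange(1, len(labels) + 1, dtype=np.int32)
    return lut[arr]


def num_instances(mask: np.ndarray) -> int:
    """Number of distinct positive labels in a mask."""
    arr = validate_mask(mask)
    return int(np.count_nonzero(np.unique(arr)))


def _load_array(path: str | os.PathLike) -> np.ndarray:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".tif", ".tiff")):
        return tifffile.imread(path)
    with Image.open(path) as im:
        return np.asarray(im)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF as an (H, W, 3) uint8 RGB array.

    Grayscale input is replicated to 3 channels; an alpha channel is
    dropped. Bit depths above 8 per channel are rejected.
    """
    arr = _load_array(path)
    if arr.dtype != np.uint8:
        raise ValueError(
            f"unsupported bit depth for image {path!s}: dtype {arr.dtype} "
            "(only 8 bits per channel supported)"
        )
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        elif arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {path!s}")
    else:
        raise ValueError(f"unsupported image shape {arr.shape} in {path!s}")
    return np.ascontiguousarray(arr)


def read_label_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel 8/16-bit PNG/TIFF as a canonical label mask."""
    arr = _load_array(path)
    if arr.ndim != 2:
        raise ValueError(
            f"label mask {path!s} must be single-channel, got shape {arr.shape}"
        )
    if arr.dtype not in (np.uint8, np.uint16, np.int32, np.int64):
        if np.issubdtype(arr.dtype, np.signedinteger):
            arr = arr.astype(np.int64)
        else:
            raise ValueError(f"unsupported label mask dtype {arr.dtype} in {path!s}")
    if arr.size and int(arr.min()) < 0:
        raise ValueError(f"label mask {path!s} contains negative values")
    return canonicalize_mask(arr)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB image as 8-bit PNG/TIFF."""
    arr = validate_image(image)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="RGB").save(path)


def write_label_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a label mask as 16-bit single-channel PNG (or TIFF).

    The mask is canonicalized first so that ``read_label_mask`` round-trips
    to the identical array.
    """
    arr = canonicalize_mask(mask)
    n = int(arr.max())
    if n > MAX_INSTANCES:
        raise ValueError(
            f"mask has {n} instances; 16-bit output supports at most {MAX_INSTANCES}"
        )
    out = arr.astype(np.uint16)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, out)
    else:
        Image.fromarray(out).save(path)  # uint16 -> 16-bit grayscale PNG


def write_report(report: MetricReport, path: str | os.PathLike) -> None:
    """Write a metric report as CSV with trailing mean and std rows."""
    if not report.rows:
        raise ValueError("cannot write an empty metric report")
    import pandas as pd

    frame = pd.DataFrame(
        [(r.image_id,) + r.values() for r in report.rows],
        columns=("image_id",) + METRIC_COLUMNS,
    )
    agg = pd.DataFrame(
        [("mean",) + report.means(), ("std",) + report.stds()],
        columns=frame.columns,
    )
    pd.concat([frame, agg], ignore_index=True).to_csv(path, index=False)
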