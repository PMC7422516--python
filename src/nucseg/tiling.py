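"""Overlapping-tile cropping and instance-aware stitching.

Large images are split into overlapping square tiles for inference; the
overlap exists so that a nucleus cut by one tile boundary is seen whole by
a neighboring tile. Per-axis offsets for image extent D and tile size t are
{0, (D-t)//2, D-t}: for a 1000-pixel axis and 500-pixel tiles this gives
offsets {0, 250, 500}, i.e. the 3x3 = 9 overlapping windows of a standard
1000x1000 scan.

Stitching places per-tile instance predictions at absolute coordinates and
merges duplicate detections of the same nucleus: two instances from
different tiles are merged (pixel union, transitively via union-find) when
their IoU or smaller-over-intersection containment is high. For unmerged
conflicting claims on a pixel, the instance whose centroid lies farther
from its source-tile boundary wins — the tile that saw the nucleus more
centrally is trusted more.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import canonicalize_mask, validate_mask

__all__ = ["TileSpec", "StitchParams", "make_tiles", "crop", "stitch_instances"]


@dataclasses.dataclass(frozen=True)
class TileSpec:
    """One crop window: 0-based (row, col) origin, (h, w) size, tile index."""

    origin: tuple[int, int]
    size: tuple[int, int]
    index: int

    def window(self) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) half-open bounds."""
        r0, c0 = self.origin
        h, w = self.size
        return r0, r0 + h, c0, c0 + w


@dataclasses.dataclass(frozen=True)
class StitchParams:
    """Duplicate-merge thresholds for stitching."""

    merge_iou: float = 0.5
    containment: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.merge_iou <= 1 and 0 <= self.containment <= 1):
            raise ValueError("stitch thresholds must lie in [0, 1]")


def _axis_offsets(extent: int, tile: int) -> list[int]:
    return sorted({0, (extent - tile) // 2, extent - tile})


def make_tiles(height: int, width: int, tile: int) -> list[TileSpec]:
    """Overlapping square tile windows covering an image.

    Per axis the offsets are {0, (D-tile)//2, D-tile} (deduplicated,
    sorted); tiles are their Cartesian product in row-major order. A tile
    equal to the image extent yields the single full-image window.
    """
    if tile > height or tile > width:
        raise ValueError(
            f"tile size {tile} exceeds image extent {height}x{width}"
        )
    specs = []
    for r0 in _axis_offsets(height, tile):
        for c0 in _axis_offsets(width, tile):
            specs.append(TileSpec((r0, c0), (tile, tile), len(specs)))
    return specs


def crop(array: np.ndarray, spec: TileSpec) -> np.ndarray:
    """Half-open window copy; 2-D mask crops are re-canonicalized."""
    arr = np.asarray(array)
    r0, r1, c0, c1 = spec.window()
    if r0 < 0 or c0 < 0 or r1 > arr.shape[0] or c1 > arr.shape[1]:
        raise ValueError(
            f"tile window {spec.window()} outside array of shape {arr.shape[:2]}"
        )
    window = arr[r0:r1, c0:c1].copy()
    if arr.ndim == 2 and np.issubdtype(arr.dtype, np.integer):
        window = canonicalize_mask(window)
    return window


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclasses.dataclass
class _Placed:
    """One tile instance placed at absolute canvas coordinates."""

    flat: np.ndarray  # sorted flat pixel indices on the canvas
    tile_index: int
    label: int
    border_dist: float  # centroid distance to the source-tile boundary
    bbox: tuple[int, int, int, int]


def _place_instances(
    tile_masks: list[np.ndarray],
    specs: list[TileSpec],
    canvas: tuple[int, int],
) -> list[_Placed]:
    H, W = canvas
    placed: list[_Placed] = []
    for mask, spec in zip(tile_masks, specs):
        arr = validate_mask(mask)
        r0, r1, c0, c1 = spec.window()
        if arr.shape != (r1 - r0, c1 - c0):
            raise ValueError(
                f"tile mask shape {arr.shape} does not match spec size {spec.size}"
            )
        if r1 > H or c1 > W:
            raise ValueError(f"tile window {spec.window()} outside canvas {canvas}")
        for label in np.unique(arr):
            if label == 0:
                continue
            rows, cols = np.nonzero(arr == label)
            abs_rows, abs_cols = rows + r0, cols + c0
            cy, cx = float(abs_rows.mean()), float(abs_cols.mean())
            border = min(cy - r0, (r1 - 1) - cy, cx - c0, (c1 - 1) - cx)
            flat = np.sort(abs_rows.astype(np.int64) * W + abs_cols)
            bbox = (abs_rows.min(), abs_rows.max(), abs_cols.min(), abs_cols.max())
            placed.append(_Placed(flat, spec.index, int(label), border, bbox))
    return placed


def _bbox_overlap(a: _Placed, b: _Placed) -> bool:
    return not (
        a.bbox[1] < b.bbox[0]
        or b.bbox[1] < a.bbox[0]
        or a.bbox[3] < b.bbox[2]
        or b.bbox[3] < a.bbox[2]
    )


def stitch_instances(
    tile_masks: list[np.ndarray],
    specs: list[TileSpec],
    canvas: tuple[int, int],
    params: StitchParams = StitchParams(),
) -> np.ndarray:
    """Reassemble per-tile instance masks into one canonical canvas mask.

    Instances from different tiles are merged by pixel union when their
    IoU >= ``merge_iou`` or intersection/min-size >= ``containment``
    (transitively). Remaining pixel conflicts go to the instance whose
    centroid is farther from its source-tile boundary. Permutation-
    invariant in tile order.
    """
    if len(tile_masks) != len(specs):
        raise ValueError(
            f"{len(tile_masks)} tile masks but {len(specs)} tile specs"
        )
    H, W = canvas
    # deterministic processing order regardless of input tile order
    order = np.argsort([s.index for s in specs], kind="stable")
    tile_masks = [tile_masks[i] for i in order]
    specs = [specs[i] for i in order]

    placed = _place_instances(tile_masks, specs, canvas)
    n = len(placed)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = placed[i], placed[j]
            if a.tile_index == b.tile_index or not _bbox_overlap(a, b):
                continue
            inter = np.intersect1d(a.flat, b.flat, assume_unique=True).size
            if inter == 0:
                continue
            union = a.flat.size + b.flat.size - inter
            iou = inter / union
            contain = inter / min(a.flat.size, b.flat.size)
            if iou >= params.merge_iou or contain >= params.containment:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    # priority = max member border distance; paint ascending so the highest
    # priority group ends up owning contested pixels
    entries = []
    for root, members in groups.items():
        flat = np.unique(np.concatenate([placed[i].flat for i in members]))
        prio = max(placed[i].border_dist for i in members)
        entries.append((prio, -root, flat))
    entries.sort(key=lambda e: (e[0], e[1]))

    out = np.zeros(H * W, dtype=np.int32)
    for new_label, (_, _, flat) in enumerate(entries, start=1):
        out[flat] = new_label
    return canonicalize_mask(out.reshape(H, W))
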