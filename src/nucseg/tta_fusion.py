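"""Multiple-inference (test-time-augmentation) instance fusion.

The segmenter runs on all 7 geometric variants of an image; each prediction
is inverted back to the original frame. Every nucleus of the original-image
prediction is then compared against all nuclei of the 7 inverted
predictions, and those with IoU above a threshold (default 0.2) form its
matched set. Pixel-level majority voting over the matched set keeps a pixel
only when strictly more than 50% of the matched masks contain it; the kept
pixel sets become the fused instances.

Reference instances come only from the original (identity) prediction, so
fusion can refine or drop detections but never invent new ones. The vote
denominator is the size of the matched set, not a fixed 7: a nucleus missed
by some variants is not vetoed by masks that never saw it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import augment
from .io_formats import canonicalize_mask, validate_mask

__all__ = ["FusionParams", "iou", "fuse", "run_multiple_inference"]


@dataclasses.dataclass(frozen=True)
class FusionParams:
    """IoU matching threshold (strict >) and pixel vote threshold (strict >)."""

    iou_threshold: float = 0.2
    vote_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.iou_threshold <= 1 and 0 <= self.vote_threshold <= 1):
            raise ValueError("fusion thresholds must lie in [0, 1]")


def _as_indices(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return np.unique(arr.ravel())


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two pixel sets.

    Accepts boolean masks or flat index arrays; two empty sets have IoU 0.
    """
    ia, ib = _as_indices(a), _as_indices(b)
    if ia.size == 0 and ib.size == 0:
        return 0.0
    inter = np.intersect1d(ia, ib, assume_unique=True).size
    union = ia.size + ib.size - inter
    return inter / union


def _instances(mask: np.ndarray) -> dict[int, np.ndarray]:
    """Label -> sorted flat pixel indices."""
    arr = validate_mask(mask)
    flat = arr.ravel()
    out: dict[int, np.ndarray] = {}
    for label in np.unique(flat):
        if label == 0:
            continue
        out[int(label)] = np.flatnonzero(flat == label)
    return out


def fuse(
    predictions: list[tuple[str, np.ndarray]],
    params: FusionParams = FusionParams(),
) -> np.ndarray:
    """Fuse 7 per-variant instance predictions into one canonical mask.

    ``predictions`` pairs each transform name with the label mask predicted
    on that variant; masks are inverted to the original frame here. For
    each original-prediction instance, instances of any variant with
    IoU > ``iou_threshold`` are collected (the instance matches itself at
    IoU 1) and a pixel is kept iff it occurs in strictly more than
    ``vote_threshold`` * M of the M matched masks. Pixels claimed by two
    fused instances go to the one with the higher vote fraction (tie:
    smaller original label).
    """
    if len(predictions) != 7:
        raise ValueError(f"expected 7 predictions, got {len(predictions)}")
    names = [t for t, _ in predictions]
    if names.count("identity") != 1:
        raise ValueError("predictions must contain exactly one identity entry")

    inverted = [
        (t, augment.apply(validate_mask(m), augment.inverse(t)))
        for t, m in predictions
    ]
    shapes = {m.shape for _, m in inverted}
    if len(shapes) != 1:
        raise ValueError(f"masks disagree in shape after inversion: {shapes}")
    shape = shapes.pop()

    reference = next(m for t, m in inverted if t == "identity")
    ref_instances = _instances(reference)
    variant_instances = [_instances(m) for _, m in inverted]

    owner = np.zeros(shape[0] * shape[1], dtype=np.int32)
    owner_frac = np.zeros(shape[0] * shape[1], dtype=float)

    for ref_label in sorted(ref_instances):
        ref_pixels = ref_instances[ref_label]
        matched: list[np.ndarray] = []
        for inst_map in variant_instances:
            for pixels in inst_map.values():
                if iou(ref_pixels, pixels) > params.iou_threshold:
                    matched.append(pixels)
        M = len(matched)
        if M == 0:
            continue
        votes = np.bincount(
            np.concatenate(matched), minlength=owner.size
        ).astype(float)
        frac = votes / M
        keep = np.flatnonzero(frac > params.vote_threshold)
        if keep.size == 0:
            continue
        # claim pixels: strictly higher vote fraction beats an earlier
        # (smaller-label) owner; ties keep the earlier owner
        claim = keep[(owner[keep] == 0) | (frac[keep] > owner_frac[keep])]
        owner[claim] = ref_label
        owner_frac[claim] = frac[claim]

    return canonicalize_mask(owner.reshape(shape))


def run_multiple_inference(
    image: np.ndarray,
    segmenter,
    params: FusionParams = FusionParams(),
) -> np.ndarray:
    """Segment all 7 variants of a square image and fuse the predictions.

    ``segmenter`` is any backend with a ``segment(image) -> label mask``
    method; the whole procedure is deterministic when the backend is.
    """
    predictions = [
        (name, segmenter.segment(variant))
        for name, variant in augment.tta_variants(image)
    ]
    return fuse(predictions, params)
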