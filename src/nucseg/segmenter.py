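"""Pluggable instance-segmentation backends and the classical baseline.

The pipeline (normalization, tiling, TTA fusion, evaluation) is agnostic to
the detector behind ``SegmenterBackend.segment``. Two things live here:

* a deterministic classical baseline — nuclei-class GMM posterior (or
  inverted luminance), Otsu threshold, hole filling, distance transform,
  marker-controlled watershed — sufficient for desk-scale runs against the
  synthetic generator;
* the recorded adapter configuration for a Mask R-CNN backend (anchor
  geometry, candidate budget, optimizer settings), so an externally trained
  detector can be plugged in with the same settings. The network itself is
  not part of this package.
"""

from __future__ import annotations

import abc
import dataclasses

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from . import stain_gmm
from .io_formats import canonicalize_mask, validate_image, validate_mask

__all__ = [
    "SegmenterBackend",
    "BaselineSegmenter",
    "MaskRCNNConfig",
    "baseline_segment",
    "resolve_overlaps",
]


class SegmenterBackend(abc.ABC):
    """Instance segmenter contract: image in, validated label mask out."""

    name: str = "backend"
    deterministic: bool = True

    @abc.abstractmethod
    def _segment(self, image: np.ndarray) -> np.ndarray:
        """Backend-specific segmentation; may return any integer label map."""

    def segment(self, image: np.ndarray) -> np.ndarray:
        """Run the backend and enforce the label-mask invariants."""
        img = validate_image(image)
        mask = canonicalize_mask(validate_mask(self._segment(img)))
        if mask.shape != img.shape[:2]:
            raise ValueError(
                f"backend {self.name!r} returned shape {mask.shape} "
                f"for image {img.shape[:2]}"
            )
        return mask


@dataclasses.dataclass(frozen=True)
class MaskRCNNConfig:
    """Recorded adapter settings for an external Mask R-CNN detector.

    Anchor scales are box *areas* (8^2 .. 128^2), smaller than common
    detection defaults because nuclei are small objects.
    """

    anchor_ratios: tuple[str, ...] = ("1:1", "1:2", "2:1")
    anchor_scales: tuple[int, ...] = (8**2, 16**2, 32**2, 64**2, 128**2)
    top_candidates: int = 1000
    backbone: str = "resnet101-fpn"
    learning_rate: float = 0.001
    momentum: float = 0.9

    def to_dict(self) -> dict:
        return {
            "anchor_ratios": list(self.anchor_ratios),
            "anchor_scales": list(self.anchor_scales),
            "top_candidates": self.top_candidates,
            "backbone": self.backbone,
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MaskRCNNConfig":
        return cls(
            anchor_ratios=tuple(data["anchor_ratios"]),
            anchor_scales=tuple(data["anchor_scales"]),
            top_candidates=int(data["top_candidates"]),
            backbone=str(data["backbone"]),
            learning_rate=float(data["learning_rate"]),
            momentum=float(data["momentum"]),
        )


def _nuclei_likelihood_gmm(image: np.ndarray, seed: int) -> np.ndarray:
    """Nuclei-class posterior from the 3-class stain GMM.

    The nuclei component is identified as the one with the highest mean
    optical density (hematoxylin-stained nuclei are the darkest class).
    """
    model, posterior = stain_gmm.fit_gmm_em(
        image, K=3, codec=stain_gmm.OD_CODEC, seed=seed
    )
    nuclei_k = int(np.argmax(model.means.sum(axis=1)))
    return posterior[:, :, nuclei_k]


def _nuclei_likelihood_luminance(image: np.ndarray) -> np.ndarray:
    lum = image.astype(float) @ np.array([0.299, 0.587, 0.114])
    return 1.0 - lum / 255.0


def baseline_segment(
    image: np.ndarray,
    min_area: int = 30,
    seed: int = 0,
    likelihood: str = "gmm",
) -> np.ndarray:
    """Classical watershed instance segmentation of nuclei.

    Pipeline: nuclei-likelihood map (GMM posterior, or inverted luminance
    when ``likelihood='luminance'``), Otsu global threshold, hole filling,
    Euclidean distance transform, local-maxima markers separated by at
    least the estimated nucleus radius, marker-controlled watershed, and
    removal of instances below ``min_area`` pixels. Deterministic given
    ``seed``; an empty mask is a valid output.
    """
    img = validate_image(image)
    if likelihood == "gmm":
        try:
            lik = _nuclei_likelihood_gmm(img, seed)
        except ValueError:  # degenerate (flat) image
            lik = _nuclei_likelihood_luminance(img)
    elif likelihood == "luminance":
        lik = _nuclei_likelihood_luminance(img)
    else:
        raise ValueError(f"unknown likelihood source {likelihood!r}")

    if np.ptp(lik) < 1e-12:
        return np.zeros(img.shape[:2], dtype=np.int32)
    binary = lik > threshold_otsu(lik)
    if not binary.any():
        return np.zeros(img.shape[:2], dtype=np.int32)
    binary = ndimage.binary_fill_holes(binary)

    distance = ndimage.distance_transform_edt(binary)

    # expected nucleus radius from the connected components of the binary map
    comp, n_comp = ndimage.label(binary)
    if n_comp:
        areas = np.bincount(comp.ravel())[1:]
        radius = int(max(3, round(np.sqrt(np.median(areas) / np.pi))))
    else:
        radius = 3
    coords = peak_local_max(
        distance, min_distance=radius, labels=binary, exclude_border=False
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)

    labels = watershed(-distance, markers, mask=binary)

    if min_area > 0:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_area)
        labels[np.isin(labels, small[small > 0])] = 0
    return canonicalize_mask(labels)


@dataclasses.dataclass
class BaselineSegmenter(SegmenterBackend):
    """The classical watershed baseline as a pluggable backend."""

    min_area: int = 30
    seed: int = 0
    likelihood: str = "gmm"
    name: str = "baseline"
    deterministic: bool = True

    def _segment(self, image: np.ndarray) -> np.ndarray:
        return baseline_segment(
            image, min_area=self.min_area, seed=self.seed, likelihood=self.likelihood
        )


def resolve_overlaps(
    instances: list[tuple[np.ndarray, float]],
    shape: tuple[int, int],
) -> np.ndarray:
    """Flatten possibly-overlapping scored instance masks into a label map.

    ``instances`` pairs a pixel set (boolean mask of ``shape`` or flat index
    array) with a confidence score. Each contested pixel goes to the
    highest-scoring claimant; ties go to the larger instance, then to the
    smaller list index. Instances left without pixels are dropped.
    """
    H, W = shape
    claims = []
    for idx, (pixels, score) in enumerate(instances):
        arr = np.asarray(pixels)
        flat = np.flatnonzero(arr) if arr.dtype == bool else np.unique(arr.ravel())
        claims.append((float(score), flat.size, -idx, idx, flat))
    # paint in ascending priority so the strongest claim lands last
    claims.sort(key=lambda c: (c[0], c[1], c[2]))
    out = np.zeros(H * W, dtype=np.int32)
    for _, _, _, idx, flat in claims:
        out[flat] = idx + 1
    return canonicalize_mask(out.reshape(H, W))
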