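"""Seeded synthetic H&E-like image generator with known instance ground truth.

Emulates the three-class pixel structure of hematoxylin-and-eosin stained
tissue: elliptical nuclei (hematoxylin blue-purple), a blobby surrounding-
tissue region (eosin pink), and bright background. Stain variation between
slides is modeled as a global additive shift of all class color means, which
gives the color-normalization stage a controlled, correctable perturbation.

Nothing here attempts physical realism (no chromatin texture, no optics);
the generator exists so every pipeline stage can be exercised against exact
ground truth without external datasets.
"""

from __future__ import annotations

import csv
import dataclasses
import os

import numpy as np
from scipy import ndimage

from .io_formats import canonicalize_mask, write_image, write_label_mask

__all__ = ["SynthParams", "generate_image", "generate_dataset"]

# Default class colors: nuclei (blue-purple), tissue (pink), background
# (near-white). Chosen well inside [0,255] so clipping bias is negligible.
DEFAULT_CLASS_MEANS = ((105.0, 65.0, 160.0), (205.0, 140.0, 170.0), (238.0, 235.0, 238.0))
DEFAULT_CLASS_STDS = ((8.0, 8.0, 8.0), (8.0, 8.0, 8.0), (4.0, 4.0, 4.0))

NUCLEI, TISSUE, BACKGROUND = 0, 1, 2  # class indices


@dataclasses.dataclass
class SynthParams:
    """Parameters of one synthetic H&E-like image.

    ``class_color_means`` are RGB means for (nuclei, tissue, background);
    ``stain_shift`` is added to all three means, emulating an over- or
    under-stained slide; ``noise_std`` is extra per-pixel additive noise on
    top of the per-class color spread.
    """

    height: int = 256
    width: int = 256
    n_nuclei: int = 20
    radius_range: tuple[float, float] = (6.0, 12.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    class_color_means: tuple = DEFAULT_CLASS_MEANS
    class_color_stds: tuple = DEFAULT_CLASS_STDS
    stain_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_std: float = 3.0
    overlap_allowed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.radius_range[0] < 2:
            raise ValueError("minimum nucleus radius must be >= 2 pixels")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max) with min <= max")
        e0, e1 = self.eccentricity_range
        if not (0 <= e0 <= e1 < 1):
            raise ValueError("eccentricity_range must lie in [0, 1) with min <= max")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        for stds in self.class_color_stds:
            if any(s < 0 for s in stds):
                raise ValueError("class color stds must be non-negative")


def _ellipse_pixels(
    cy: float, cx: float, a: float, b: float, theta: float, h: int, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a filled rotated ellipse clipped to the frame."""
    r0 = max(int(np.floor(cy - a - 1)), 0)
    r1 = min(int(np.ceil(cy + a + 1)) + 1, h)
    c0 = max(int(np.floor(cx - a - 1)), 0)
    c1 = min(int(np.ceil(cx + a + 1)) + 1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - cy, cc - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _tissue_region(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Random blobby foreground region covering roughly half the frame."""
    field = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(field, sigma=min(h, w) / 10.0)
    return smooth > np.median(smooth)


def generate_image(params: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (RGB image, ground-truth label mask) pair.

    Each nucleus is a filled rotated ellipse; when ``overlap_allowed`` is
    false, centers are rejection-sampled until all ellipses are pairwise
    disjoint, within a budget of ``100 * n_nuclei`` placement attempts.
    Pixel colors are drawn per class from per-channel Gaussians centered at
    ``class mean + stain_shift``, plus ``noise_std`` additive noise, clipped
    to [0, 255]. Deterministic given ``params.seed``.
    """
    h, w = params.height, params.width
    rng = np.random.default_rng(params.seed)

    mask = np.zeros((h, w), dtype=np.int32)
    tissue = _tissue_region(rng, h, w)

    placed = 0
    budget = 100 * max(params.n_nuclei, 1)
    attempts = 0
    while placed < params.n_nuclei:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {params.n_nuclei} disjoint nuclei in "
                f"{budget} attempts (placed {placed})"
            )
        attempts += 1
        a = rng.uniform(*params.radius_range)  # semi-major axis
        ecc = rng.uniform(*params.eccentricity_range)
        b = a * np.sqrt(1.0 - ecc**2)  # semi-minor axis
        theta = rng.uniform(0.0, np.pi)
        cy = rng.uniform(a, h - a) if h > 2 * a else h / 2.0
        cx = rng.uniform(a, w - a) if w > 2 * a else w / 2.0
        rr, cc = _ellipse_pixels(cy, cx, a, b, theta, h, w)
        if rr.size == 0:
            continue
        if not params.overlap_allowed and np.any(mask[rr, cc] > 0):
            continue
        placed += 1
        mask[rr, cc] = placed

    # class index per pixel: nuclei override tissue, tissue overrides background
    cls = np.full((h, w), BACKGROUND, dtype=np.int8)
    cls[tissue] = TISSUE
    cls[mask > 0] = NUCLEI

    means = np.asarray(params.class_color_means, dtype=float) + np.asarray(
        params.stain_shift, dtype=float
    )
    stds = np.asarray(params.class_color_stds, dtype=float)
    image = means[cls] + rng.standard_normal((h, w, 3)) * stds[cls]
    if params.noise_std > 0:
        image += rng.standard_normal((h, w, 3)) * params.noise_std
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return image, canonicalize_mask(mask)


def generate_dataset(
    params: SynthParams, n_images: int, out_dir: str | os.PathLike
) -> list[dict]:
    """Write ``n_images`` image/mask pairs plus a CSV manifest.

    Image ``i`` uses seed ``params.seed + i``. Returns the manifest rows
    (dicts with image_path, mask_path, seed).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    manifest: list[dict] = []
    for i in range(n_images):
        p = dataclasses.replace(params, seed=params.seed + i)
        image, mask = generate_image(p)
        image_path = os.path.join(out_dir, f"image_{i:03d}.png")
        mask_path = os.path.join(out_dir, f"mask_{i:03d}.png")
        write_image(image, image_path)
        write_label_mask(mask, mask_path)
        manifest.append(
            {"image_path": image_path, "mask_path": mask_path, "seed": p.seed}
        )

    manifest_path = os.path.join(out_dir, "manifest.csv")
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image_path", "mask_path", "seed"])
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
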