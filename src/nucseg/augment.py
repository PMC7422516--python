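"""The 7-element geometric transform group used for augmentation and TTA.

Identity, three counter-clockwise rotations (90/180/270 degrees) and three
flips (horizontal, vertical, both). Every transform has an exact inverse in
the set and preserves pixel values exactly — no interpolation — so label
masks survive a round trip bit-for-bit. Size-changing augmentations are
deliberately excluded from this group.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TRANSFORMS", "INVERSE", "inverse", "apply", "tta_variants"]

# order matters: identity first, then rotations, then flips
TRANSFORMS: tuple[str, ...] = (
    "identity",
    "rot90",
    "rot180",
    "rot270",
    "hflip",
    "vflip",
    "hvflip",
)

INVERSE: dict[str, str] = {
    "identity": "identity",
    "rot90": "rot270",
    "rot180": "rot180",
    "rot270": "rot90",
    "hflip": "hflip",
    "vflip": "vflip",
    "hvflip": "hvflip",
}


def inverse(name: str) -> str:
    """Inverse transform name."""
    try:
        return INVERSE[name]
    except KeyError:
        raise ValueError(f"unknown transform {name!r}") from None


def apply(x: np.ndarray, name: str) -> np.ndarray:
    """Apply a named transform to an image (H,W,3) or mask (H,W).

    Rotations are counter-clockwise on the pixel grid; hflip mirrors
    columns, vflip mirrors rows. Quarter-turn rotations require square
    input so output shape equals input shape.
    """
    arr = np.asarray(x)
    if arr.ndim not in (2, 3):
        raise ValueError(f"expected 2-D mask or 3-D image, got shape {arr.shape}")
    if name in ("rot90", "rot270") and arr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"{name} requires square input, got {arr.shape[0]}x{arr.shape[1]}"
        )
    if name == "identity":
        return arr.copy()
    if name == "rot90":
        return np.ascontiguousarray(np.rot90(arr, 1))
    if name == "rot180":
        return np.ascontiguousarray(np.rot90(arr, 2))
    if name == "rot270":
        return np.ascontiguousarray(np.rot90(arr, 3))
    if name == "hflip":
        return np.ascontiguousarray(arr[:, ::-1])
    if name == "vflip":
        return np.ascontiguousarray(arr[::-1, :])
    if name == "hvflip":
        return np.ascontiguousarray(arr[::-1, ::-1])
    raise ValueError(f"unknown transform {name!r}")


def tta_variants(image: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """All 7 transform variants of a square image, identity first."""
    arr = np.asarray(image)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"test-time augmentation requires square input, got "
            f"{arr.shape[0]}x{arr.shape[1]}"
        )
    return [(name, apply(arr, name)) for name in TRANSFORMS]
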