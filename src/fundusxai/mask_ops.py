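"""Lesion/landmark mask loading, post-processing, and patch tiling.

Masks are binary fields on the image grid, one per lesion or landmark
type.  Anatomical landmarks (optic disc, macula) are unique per eye, so
their masks may be reduced to their largest connected component;
pathological lesion masks are never post-processed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.measure import label, regionprops
from skimage.transform import resize as _sk_resize

__all__ = [
    "LESION_TYPES",
    "LANDMARK_TYPES",
    "LesionMask",
    "MaskFormatError",
    "load_mask",
    "retain_single_component",
    "tile_patches",
    "save_mask",
]

#: Pathology types: microaneurysm, hard/soft exudate, hemorrhage (plus the
#: retinal/preretinal/vitreous split used by ground-truth lesion atlases),
#: fibrous proliferation, neovascularization.
LESION_TYPES = ("MA", "EX", "SE", "HE", "NV", "rHE", "pHE", "vHE", "FP")
#: Anatomical landmarks: optic disc and macula.
LANDMARK_TYPES = ("OD", "MC")
VALID_TYPES = LESION_TYPES + LANDMARK_TYPES


class MaskFormatError(ValueError):
    """Mask file unreadable or not single-channel."""


@dataclass
class LesionMask:
    """Binary mask M for one lesion/landmark type on the image grid."""

    values: np.ndarray  # uint8 {0,1}
    lesion_type: str
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.lesion_type not in VALID_TYPES:
            raise ValueError(
                f"unknown lesion type {self.lesion_type!r}; expected one of {VALID_TYPES}"
            )

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())


def load_mask(path, lesion_type: str, image_id: str = "") -> LesionMask:
    """Read a single-channel PNG; any pixel > 0 becomes 1."""
    try:
        img = Image.open(str(path))
    except Exception as exc:  # unreadable file
        raise MaskFormatError(f"cannot read mask file {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise MaskFormatError(
            f"mask {path} must be single-channel, got shape {arr.shape}"
        )
    return LesionMask((arr > 0).astype(np.uint8), lesion_type, image_id)


def conform_to_shape(mask: LesionMask, shape: tuple[int, int]) -> LesionMask:
    """Resize a mask to the paired image grid if shapes disagree.

    Bilinear resize then re-binarize at 0.5, with a warning — masks are
    expected to match their image.
    """
    if mask.values.shape == tuple(shape):
        return mask
    warnings.warn(
        f"mask {mask.image_id!r}/{mask.lesion_type} shape {mask.values.shape} "
        f"!= image shape {shape}; resizing",
        stacklevel=2,
    )
    resized = _sk_resize(mask.values.astype(float), shape, order=1, anti_aliasing=False)
    return LesionMask((resized >= 0.5).astype(np.uint8), mask.lesion_type, mask.image_id)


def retain_single_component(mask: LesionMask) -> LesionMask:
    """Keep only the largest 8-connected component of a landmark mask.

    Only valid for OD/MC: each eye has exactly one optic disc and one
    macula, so multiple detected blobs mean spurious detections.
    Lesion masks must not be cleaned this way (lesions are legitimately
    multiple) — calling this on one is a usage error.  Size ties break
    to the component whose lexicographically smallest (row, col) pixel
    comes first; an empty mask passes through with a warning.
    """
    if mask.lesion_type not in LANDMARK_TYPES:
        raise ValueError(
            f"retain_single_component applies only to landmarks {LANDMARK_TYPES}, "
            f"got lesion type {mask.lesion_type!r} (lesion masks are not post-processed)"
        )
    if mask.pixel_count == 0:
        warnings.warn(
            f"empty {mask.lesion_type} mask for image {mask.image_id!r}", stacklevel=2
        )
        return mask
    labeled = label(mask.values, connectivity=2)  # 8-connectivity
    best = None
    for region in regionprops(labeled):
        anchor = min(map(tuple, region.coords))
        key = (-region.area, anchor)
        if best is None or key < best[0]:
            best = (key, region.label)
    keep = (labeled == best[1]).astype(np.uint8)
    return LesionMask(keep, mask.lesion_type, mask.image_id)


def tile_patches(
    image: np.ndarray, mask: LesionMask, patch_size: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split an image–mask pair into non-overlapping square tiles.

    Tiles are returned row-major; stitching them back in that order
    reconstructs the originals bit-exactly.  A 1120x1120 pair at patch
    size 224 yields 25 tiles.
    """
    h, w = image.shape[:2]
    if h % patch_size or w % patch_size:
        raise ValueError(
            f"image dimensions {(h, w)} must be divisible by patch size {patch_size}"
        )
    if mask.values.shape[:2] != (h, w):
        raise ValueError(
            f"mask shape {mask.values.shape} does not match image shape {(h, w)}"
        )
    pairs = []
    for r in range(0, h, patch_size):
        for c in range(0, w, patch_size):
            pairs.append(
                (
                    image[r : r + patch_size, c : c + patch_size],
                    mask.values[r : r + patch_size, c : c + patch_size],
                )
            )
    return pairs


def save_mask(path, mask: LesionMask) -> None:
    Image.fromarray((mask.values * 255).astype(np.uint8), mode="L").save(str(path))
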