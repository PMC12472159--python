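"""Heatmap post-processing: resize, [0,1] normalization, percentile binarization.

The pipeline order is resize -> normalize -> threshold, so the [0,1]
range holds on the final image grid.  The binary activation map keeps a
pixel when its normalized value is >= the percentile threshold (ties
included), which guarantees the active fraction is at least
(100 - p)/100 and equals it when all pixel values are distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import tifffile
from PIL import Image
from scipy.ndimage import map_coordinates

from .attribution import RawAttribution

__all__ = [
    "Heatmap",
    "ThresholdSpec",
    "BinaryActivationMap",
    "DEFAULT_PERCENTILES",
    "resize_to_image",
    "normalize_heatmap",
    "percentile_threshold",
    "heatmap_from_raw",
    "save_heatmap",
    "load_heatmap",
    "save_activation_map",
    "load_activation_map",
]

#: Method-default top-percentile cutoffs: Grad-CAM maps are coarse, so a
#: wider top decile is kept; IG maps are pixel-sharp, so only the top 3%.
DEFAULT_PERCENTILES: Mapping[str, float] = {"gradcam": 90.0, "ig": 97.0}


@dataclass
class Heatmap:
    """Normalized attribution field H on the full image grid, values in [0,1]."""

    values: np.ndarray
    provenance: str  # 'gradcam' | 'ig'
    image_id: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class ThresholdSpec:
    percentile: float

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError(
                f"percentile must lie in (0, 100), got {self.percentile}"
            )

    @classmethod
    def for_method(cls, method: str) -> "ThresholdSpec":
        return cls(DEFAULT_PERCENTILES[method])


@dataclass
class BinaryActivationMap:
    """Top-percentile indicator field A derived from a heatmap."""

    values: np.ndarray  # uint8 {0,1}
    threshold_used: float
    degenerate_flag: bool = False

    @property
    def active_fraction(self) -> float:
        return float(self.values.mean())


def resize_to_image(raw, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinearly interpolate a 2-D field onto ``target_shape``.

    Corner-aligned bilinear interpolation; the identity when shapes
    already match.  Needed because Grad-CAM lives on the (coarser)
    conv-layer grid while masks live on the image grid.
    """
    field = raw.reduced() if isinstance(raw, RawAttribution) else np.asarray(raw, float)
    th, tw = int(target_shape[0]), int(target_shape[1])
    if th <= 0 or tw <= 0:
        raise ValueError(f"target shape must be positive, got {(th, tw)}")
    if field.shape == (th, tw):
        return field.astype(float)
    sh, sw = field.shape
    rows = np.linspace(0, sh - 1, th) if th > 1 else np.array([(sh - 1) / 2.0])
    cols = np.linspace(0, sw - 1, tw) if tw > 1 else np.array([(sw - 1) / 2.0])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(field.astype(float), [rr, cc], order=1, mode="nearest")


def normalize_heatmap(
    field: np.ndarray, provenance: str = "gradcam", image_id: str = ""
) -> Heatmap:
    """Min–max normalize to [0,1]; a constant field becomes all-zero.

    The constant (degenerate) case is flagged and warned about so
    downstream reports can exclude it.
    """
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ArithmeticError("heatmap field contains NaN or Inf")
    lo, hi = field.min(), field.max()
    if hi == lo:
        warnings.warn(
            f"degenerate (constant) heatmap for image {image_id!r}; "
            "normalized to all zeros",
            stacklevel=2,
        )
        return Heatmap(np.zeros_like(field), provenance, image_id, degenerate=True)
    return Heatmap((field - lo) / (hi - lo), provenance, image_id)


def percentile_threshold(h: Heatmap, spec: ThresholdSpec) -> BinaryActivationMap:
    """Binarize a heatmap at the given percentile of its own pixel values.

    The threshold T is the linear-interpolation percentile over all
    pixels; a pixel is active iff H >= T.  Because the statistic is a
    rank, any strictly increasing transform applied before
    normalization leaves the activation map unchanged.
    """
    t = float(np.percentile(h.values, spec.percentile))
    active = (h.values >= t).astype(np.uint8)
    return BinaryActivationMap(
        values=active, threshold_used=t, degenerate_flag=h.degenerate
    )


def heatmap_from_raw(
    raw: RawAttribution,
    target_shape: tuple[int, int],
    image_id: str = "",
) -> Heatmap:
    """Full pipeline on a raw attribution: reduce, resize, normalize."""
    return normalize_heatmap(
        resize_to_image(raw, target_shape), raw.method, image_id
    )


def save_heatmap(path, h: Heatmap) -> None:
    tifffile.imwrite(str(path), h.values.astype(np.float32))


def load_heatmap(path, provenance: str = "gradcam", image_id: str = "") -> Heatmap:
    values = tifffile.imread(str(path)).astype(np.float64)
    return Heatmap(values, provenance, image_id, degenerate=bool(values.max() == values.min() == 0))


def save_activation_map(path, a: BinaryActivationMap) -> None:
    Image.fromarray((a.values * 255).astype(np.uint8), mode="L").save(str(path))


def load_activation_map(path) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)))
    return (arr > 0).astype(np.uint8)
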