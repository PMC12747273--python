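"""Tissue segmentation and patch extraction.

A slide enters the engine as an RGB raster.  Tissue is located by a
coarse colour pipeline — HSV conversion, median blur of the saturation
channel, thresholding (Otsu by default), morphological closing — and the
tissue region is cut into fixed-size, non-overlapping patches on a grid
anchored at the image origin.  Spatial-transcriptomics spots get square
patches centred on the spot, sized so one patch covers roughly 64 µm of
tissue regardless of scan resolution.

Conventions used throughout the package: pixel coordinates are 0-based,
boxes are half-open ``[x, x+size) × [y, y+size)``, and y grows downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce

__all__ = [
    "PatchRef",
    "TissueMask",
    "segment_tissue",
    "extract_patches",
    "normalize_magnification",
    "st_patch_size",
    "extract_spot_patches",
]

#: supported magnification tags and their relative scale
_MAG_SCALE = {"80X": 80, "40X": 40, "20X": 20, "10X": 10}


@dataclass(frozen=True)
class PatchRef:
    """Location of one patch: slide, top-left pixel offset, size, magnification."""

    slide_id: str
    x: int
    y: int
    size_px: int
    magnification_tag: str = "20X"

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("patch offsets must be non-negative")
        if self.size_px < 1:
            raise ValueError("size_px must be >= 1")


@dataclass(frozen=True)
class TissueMask:
    """Binary tissue raster aligned to the slide at ``downsample`` factor."""

    mask: np.ndarray  # bool, H×W at the downsampled scale
    downsample: int = 1

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


def segment_tissue(
    image: np.ndarray,
    blur_kernel_px: int = 7,
    sat_threshold: float | None = None,
    closing_kernel_px: int = 5,
    seg_downsample: int = 1,
) -> TissueMask:
    """Locate tissue by saturation thresholding.

    Pipeline: RGB→HSV, median blur of the saturation channel, threshold
    (Otsu on the blurred channel when ``sat_threshold`` is None), then
    binary closing to fill small gaps and holes.  ``seg_downsample``
    block-averages the image first, for large slides.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("segment_tissue expects an RGB H×W×3 image")
    if image.size == 0:
        raise ValueError("empty image")
    if seg_downsample > 1:
        image = block_reduce(
            image.astype(np.float64), (seg_downsample, seg_downsample, 1), np.mean
        )
    sat = rgb2hsv(image)[..., 1]
    if blur_kernel_px > 1:
        sat = ndimage.median_filter(sat, size=blur_kernel_px)
    if sat_threshold is None:
        # a blank (zero-saturation) image has no Otsu split: empty mask
        if np.allclose(sat.max(), sat.min()):
            return TissueMask(np.zeros(sat.shape, dtype=bool), seg_downsample)
        sat_threshold = threshold_otsu(sat)
    mask = sat > sat_threshold
    if closing_kernel_px > 1 and mask.any():
        structure = np.ones((closing_kernel_px, closing_kernel_px), dtype=bool)
        mask = ndimage.binary_closing(mask, structure=structure)
    return TissueMask(mask, seg_downsample)


def extract_patches(
    image: np.ndarray,
    mask: TissueMask,
    size_px: int = 256,
    min_tissue_frac: float = 0.5,
    slide_id: str = "slide",
    magnification_tag: str = "20X",
) -> tuple[list[PatchRef], np.ndarray]:
    """Tile the slide into non-overlapping ``size_px`` squares.

    The grid is anchored at (0, 0); partial edge tiles are discarded.  A
    tile is kept iff the fraction of its area covered by the tissue mask
    is at least ``min_tissue_frac`` (a tile meeting the threshold exactly
    is kept).  Returns the kept refs and an array of pixel patches.
    """
    image = np.asarray(image)
    if size_px < 1:
        raise ValueError("size_px must be >= 1")
    h, w = image.shape[:2]
    refs: list[PatchRef] = []
    arrays: list[np.ndarray] = []
    ds = mask.downsample
    m = mask.mask
    for y in range(0, h - size_px + 1, size_px):
        for x in range(0, w - size_px + 1, size_px):
            my0, my1 = y // ds, math.ceil((y + size_px) / ds)
            mx0, mx1 = x // ds, math.ceil((x + size_px) / ds)
            window = m[my0:my1, mx0:mx1]
            frac = window.mean() if window.size else 0.0
            if frac >= min_tissue_frac:
                refs.append(PatchRef(slide_id, x, y, size_px, magnification_tag))
                arrays.append(image[y : y + size_px, x : x + size_px])
    stacked = (
        np.stack(arrays) if arrays else np.empty((0, size_px, size_px) + image.shape[2:])
    )
    return refs, stacked


def normalize_magnification(
    image: np.ndarray, source_tag: str, target_tag: str = "20X"
) -> np.ndarray:
    """Downsample ``image`` from ``source_tag`` to ``target_tag`` by area averaging.

    Only downsampling is allowed — resolution cannot be invented — and the
    identity pair returns the input unchanged.
    """
    for tag in (source_tag, target_tag):
        if tag not in _MAG_SCALE:
            raise ValueError(f"unknown magnification tag {tag!r}")
    if source_tag == target_tag:
        return np.asarray(image)
    factor = _MAG_SCALE[source_tag] / _MAG_SCALE[target_tag]
    if factor < 1:
        raise ValueError(
            f"cannot upsample {source_tag} to {target_tag}: information cannot be created"
        )
    if factor != int(factor):
        raise ValueError(f"non-integer downsample factor {factor}")
    factor = int(factor)
    image = np.asarray(image)
    block = (factor, factor) + (1,) * (image.ndim - 2)
    out = block_reduce(image.astype(np.float64), block, np.mean)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.round(out).astype(np.asarray(image).dtype)
    return out


def st_patch_size(mpp: float) -> int:
    """Patch edge (pixels) covering ~64 µm: ``2**ceil(log2(64 / mpp))``."""
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    return int(2 ** math.ceil(math.log2(64.0 / mpp)))


def extract_spot_patches(
    image: np.ndarray,
    spots: list[tuple[float, float]],
    mpp: float,
    slide_id: str = "slide",
) -> tuple[list[PatchRef], np.ndarray]:
    """Cut one ``st_patch_size(mpp)`` square centred on each detection spot.

    Spots whose square would leave the image are clamped to the boundary,
    preserving the spot↔patch bijection.  Order of spots is preserved.
    """
    image = np.asarray(image)
    size = st_patch_size(mpp)
    h, w = image.shape[:2]
    if size > w or size > h:
        raise ValueError(f"patch size {size} exceeds image {w}×{h}")
    refs: list[PatchRef] = []
    arrays: list[np.ndarray] = []
    for sx, sy in spots:
        x = int(round(sx)) - size // 2
        y = int(round(sy)) - size // 2
        x = min(max(x, 0), w - size)
        y = min(max(y, 0), h - size)
        refs.append(PatchRef(slide_id, x, y, size))
        arrays.append(image[y : y + size, x : x + size])
    stacked = (
        np.stack(arrays) if arrays else np.empty((0, size, size) + image.shape[2:])
    )
    return refs, stacked
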