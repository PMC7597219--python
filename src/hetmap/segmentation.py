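"""IHC positive-pixel classification by diagonal bisection of the red-blue
joint color histogram.

Brown peroxidase signal and purple hematoxylin counterstain are both
red-blue mixtures; in the joint (R, B) histogram the two populations fall
on either side of the R = B diagonal, so the per-pixel rule is simply
R > B -> positive, B > R -> counterstain, after background removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import disk, opening

from .core import BinaryMask, Section
from .masking import exhaustive_mask

BACKGROUND, COUNTERSTAIN, POSITIVE = 0, 1, 2


@dataclass
class JointHistogram:
    """256x256 counts indexed (red value, blue value)."""

    counts: np.ndarray
    n_pixels: int


def rb_joint_histogram(section: Section, roi: BinaryMask | None = None) -> JointHistogram:
    """Joint histogram of (R, B) values over the ROI (whole image if None)."""
    px = section.pixels
    if roi is None:
        r = px[:, :, 0].ravel()
        b = px[:, :, 2].ravel()
    else:
        r = px[:, :, 0][roi.values]
        b = px[:, :, 2][roi.values]
    counts = np.zeros((256, 256), dtype=np.int64)
    np.add.at(counts, (r.astype(int), b.astype(int)), 1)
    return JointHistogram(counts, int(r.size))


def classify_pixels(section: Section, background_threshold: int = 200,
                    tissue_mask: BinaryMask | None = None) -> np.ndarray:
    """Label every pixel background (0), counterstain (1) or positive (2).

    Background first: pixels whose minimum channel is at or above the
    threshold, or that fall outside the exhaustive tissue mask, are
    background.  Remaining pixels split along the histogram diagonal:
    R > B is positive (brown), otherwise counterstain (ties conservatively
    to counterstain).
    """
    px = section.pixels
    if px.size == 0:
        return np.zeros(px.shape[:2], dtype=np.uint8)
    if tissue_mask is None:
        tissue_mask = exhaustive_mask(section)
    bg = (px.min(axis=2) >= background_threshold) | ~tissue_mask.values
    labels = np.where(px[:, :, 0] > px[:, :, 2], POSITIVE, COUNTERSTAIN)
    labels = np.where(bg, BACKGROUND, labels)
    return labels.astype(np.uint8)


def classify_tiled(section: Section, tile: tuple[int, int] = (512, 512),
                   background_threshold: int = 200,
                   tissue_mask: BinaryMask | None = None) -> np.ndarray:
    """Tile-wise classification, bit-identical to the untiled result.

    The decision rule is pixelwise, so tiling is purely a memory strategy
    for large rasters; the tissue mask is computed once on the full raster
    to keep results independent of the tile grid.
    """
    rows, cols = section.shape
    if rows == 0 or cols == 0:
        return np.zeros((rows, cols), dtype=np.uint8)
    if tissue_mask is None:
        tissue_mask = exhaustive_mask(section)
    out = np.zeros((rows, cols), dtype=np.uint8)
    th, tw = tile
    for r0 in range(0, rows, th):
        for c0 in range(0, cols, tw):
            r1, c1 = min(r0 + th, rows), min(c0 + tw, cols)
            sub = Section(section.pixels[r0:r1, c0:c1],
                          pixel_size_um=section.pixel_size_um,
                          resolution_fraction=section.resolution_fraction,
                          stain=section.stain)
            sub_mask = BinaryMask(tissue_mask.values[r0:r1, c0:c1],
                                  tissue_mask.pixel_size_um)
            out[r0:r1, c0:c1] = classify_pixels(sub, background_threshold, sub_mask)
    return out


def positive_mask(section: Section, background_threshold: int = 200,
                  tissue_mask: BinaryMask | None = None,
                  opening_radius: int = 1) -> BinaryMask:
    """Binary mask of positive-antigen pixels, opened to drop speckle."""
    labels = classify_pixels(section, background_threshold, tissue_mask)
    pos = labels == POSITIVE
    if opening_radius > 0 and pos.any():
        pos = opening(pos, disk(opening_radius))
    return BinaryMask(pos, section.pixel_size_um)


def class_area_fractions(labels: np.ndarray) -> dict[str, float]:
    """Fraction of raster pixels in each class."""
    n = labels.size or 1
    return {"background": float(np.mean(labels == BACKGROUND)),
            "counterstain": float(np.mean(labels == COUNTERSTAIN)),
            "positive": float(np.mean(labels == POSITIVE))}
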