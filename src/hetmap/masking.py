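"""Tissue masks.

Two flavors are used at different stages: a *rough* mask (silhouette only —
holes filled, debris removed) drives the pre-alignment and global
registration of the overall biopsy shape, while an *exhaustive* mask keeps
every tear, rip and hole and feeds the registration confidence map.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk

from .core import BinaryMask, Section


def _foreground(section: Section) -> np.ndarray:
    """Otsu threshold on inverted luminance; True where tissue-like."""
    gray = rgb2gray(section.pixels)  # in [0, 1]
    inv = 1.0 - gray
    if inv.max() - inv.min() < 1e-3:
        return np.zeros(section.shape, dtype=bool)
    t = threshold_otsu(inv)
    return inv > t


def rough_mask(section: Section) -> BinaryMask:
    """Tissue silhouette: threshold, close, fill holes, drop small debris.

    The closing disk radius is 1% of the smaller image side (min 3 px);
    connected components smaller than 1% of the largest one are removed.
    """
    fg = _foreground(section)
    if not fg.any():
        warnings.warn("all-background image: rough mask is empty")
        return BinaryMask(fg, section.pixel_size_um)
    radius = max(3, int(round(0.01 * min(section.shape))))
    fg = closing(fg, disk(radius))
    fg = binary_fill_holes(fg)
    labels = label(fg)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts >= 0.01 * counts.max()
    fg = keep[labels]
    return BinaryMask(fg, section.pixel_size_um)


def exhaustive_mask(section: Section) -> BinaryMask:
    """Tissue mask preserving every rip/hole: bare thresholding, no filling,
    no component removal."""
    fg = _foreground(section)
    if not fg.any():
        warnings.warn("all-background image: exhaustive mask is empty")
    return BinaryMask(fg, section.pixel_size_um)
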