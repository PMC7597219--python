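"""Rigid pre-alignment of tissue masks.

The moving mask is first translated so the centers of mass of the two
silhouettes coincide, then rotated about its (translated) center of mass to
the angle, swept in fixed increments over the full circle, that maximizes
the normalized cross-correlation with the fixed mask.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import affine_transform, shift as nd_shift

from .core import AffineMap, BinaryMask, RigidPrealign


def center_of_mass(mask: BinaryMask) -> tuple[float, float]:
    """Arithmetic mean (x, y) of the True pixels."""
    if mask.area == 0:
        raise ValueError("empty mask has no center of mass")
    rows, cols = np.nonzero(mask.values)
    return float(cols.mean()), float(rows.mean())


def estimate_translation(fixed: BinaryMask, moving: BinaryMask) -> tuple[float, float]:
    """Vector from the moving center of mass to the fixed one."""
    fx, fy = center_of_mass(fixed)
    mx, my = center_of_mass(moving)
    return fx - mx, fy - my


def _rotate_mask(values: np.ndarray, degrees: float, center_xy: tuple[float, float]) -> np.ndarray:
    """Rotate a boolean raster forward by ``degrees`` about ``center_xy``
    using nearest-neighbor sampling."""
    backward = AffineMap.rotation(degrees, center_xy).inverse()
    # affine_transform works in (row, col); swap axes of the (x, y) map
    m = backward.matrix[::-1, ::-1]
    off = backward.offset[::-1]
    return affine_transform(values.astype(np.uint8), m, offset=off, order=0,
                            mode="constant", cval=0).astype(bool)


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mask product sum normalized by the geometric mean of mask areas."""
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / np.sqrt(na * nb))


def estimate_rotation(fixed: BinaryMask, moving_translated: BinaryMask,
                      step_deg: float = 10.0) -> float:
    """Best sweep rotation (degrees) of the translated moving mask.

    Sweeps {0, step, ..., 360-step} about the moving center of mass and
    returns the angle maximizing normalized cross-correlation with the
    fixed mask; ties break to the smallest angle.
    """
    if fixed.area == 0 or moving_translated.area == 0:
        raise ValueError("empty mask")
    if abs(360.0 / step_deg - round(360.0 / step_deg)) > 1e-9:
        raise ValueError("step must divide 360")
    center = center_of_mass(moving_translated)
    best_angle, best_score = 0.0, -np.inf
    for angle in np.arange(0.0, 360.0, step_deg):
        rot = _rotate_mask(moving_translated.values, angle, center)
        score = normalized_cross_correlation(fixed.values, rot)
        if score > best_score + 1e-12:
            best_angle, best_score = float(angle), score
    return best_angle


def prealign(fixed: BinaryMask, moving: BinaryMask, step_deg: float = 10.0) -> RigidPrealign:
    """Full pre-alignment: center-of-mass translation then rotation sweep."""
    dx, dy = estimate_translation(fixed, moving)
    shifted = nd_shift(moving.values.astype(np.uint8), (dy, dx), order=0,
                       mode="constant", cval=0).astype(bool)
    moved = BinaryMask(shifted, moving.pixel_size_um)
    angle = estimate_rotation(fixed, moved, step_deg=step_deg)
    center = center_of_mass(moved)
    return RigidPrealign(translation=(dx, dy), rotation_deg=angle,
                         rotation_center=center)
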