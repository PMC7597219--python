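"""Registration and segmentation evaluation.

Landmark-based: the relative target registration error (rTRE) — Euclidean
landmark distance normalized by the image diagonal — with its challenge
aggregates (average/median of per-pair medians, average of per-pair
maxima) and robustness (fraction of landmarks whose error improved).

Mask-based: the registration confidence map (pixelwise sum of registered
exhaustive tissue masks with an overlap-level breakdown), the Dice
coefficient, and the symmetric Hausdorff distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .core import BinaryMask, LandmarkSet


@dataclass
class LandmarkEval:
    per_landmark_rtre: np.ndarray
    image_pair_id: tuple = (0, 1)
    diagonal_px: float = 1.0

    def __post_init__(self) -> None:
        self.per_landmark_rtre = np.asarray(self.per_landmark_rtre, dtype=float)

    @property
    def median(self) -> float:
        return float(np.median(self.per_landmark_rtre))

    @property
    def max(self) -> float:
        return float(np.max(self.per_landmark_rtre))


def rtre(fixed: LandmarkSet, registered: LandmarkSet, diagonal_px: float,
         pair_id: tuple = (0, 1)) -> LandmarkEval:
    """Per-landmark Euclidean error divided by the image diagonal."""
    if diagonal_px <= 0:
        raise ValueError("diagonal must be positive")
    if len(fixed) != len(registered) or not np.array_equal(fixed.ids, registered.ids):
        raise ValueError("landmark ids do not match")
    d = np.linalg.norm(fixed.points - registered.points, axis=1)
    return LandmarkEval(d / diagonal_px, pair_id, diagonal_px)


def aggregate_rtre(evals: list[LandmarkEval]) -> tuple[float, float, float]:
    """(AMrTRE, MMrTRE, AMxrTRE): mean and median over image pairs of the
    per-pair median rTRE, and mean over pairs of the per-pair maximum."""
    if not evals:
        raise ValueError("no evaluations")
    medians = np.array([e.median for e in evals])
    maxima = np.array([e.max for e in evals])
    return float(medians.mean()), float(np.median(medians)), float(maxima.mean())


def robustness(initial: LandmarkEval, final: LandmarkEval) -> float:
    """Fraction of landmarks whose rTRE strictly improved vs the initial
    (unregistered) state."""
    if len(initial.per_landmark_rtre) != len(final.per_landmark_rtre):
        raise ValueError("landmark count mismatch")
    improved = final.per_landmark_rtre < initial.per_landmark_rtre
    return float(improved.mean())


@dataclass
class OverlapBreakdown:
    """Percentage of the union support at each overlap count 1..K."""

    per_level_percent: dict[int, float]
    n_masks: int


def confidence_map(masks: list[BinaryMask]) -> tuple[np.ndarray, OverlapBreakdown]:
    """Pixelwise sum of registered masks and its overlap breakdown.

    Percentages are normalized over pixels covered by at least one mask, so
    they sum to 100; level K (= number of masks) is complete overlap.
    """
    if len(masks) < 2:
        raise ValueError("need at least two masks")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("mask shapes differ")
    counts = np.zeros(shape, dtype=np.int32)
    for m in masks:
        counts += m.values
    support = counts >= 1
    total = int(support.sum())
    k = len(masks)
    pct = {}
    for level in range(1, k + 1):
        pct[level] = 100.0 * float((counts == level).sum()) / total if total else 0.0
    return counts, OverlapBreakdown(pct, k)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """2|A n B| / (|A| + |B|); two empty masks count as perfectly equal."""
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = a.area, b.area
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def directed_hausdorff(a: BinaryMask, b: BinaryMask, pixel_size_um: float = 1.0) -> float:
    """max over a in A of the distance to the nearest point of B, in um.

    Computed with a Euclidean distance transform of B's complement.
    """
    if a.area == 0 or b.area == 0:
        raise ValueError("empty mask")
    dist_to_b = distance_transform_edt(~b.values)
    return float(dist_to_b[a.values].max()) * pixel_size_um


def hausdorff(a: BinaryMask, b: BinaryMask, pixel_size_um: float = 1.0) -> float:
    """Symmetric Hausdorff distance max(h(A,B), h(B,A)) in um."""
    return max(directed_hausdorff(a, b, pixel_size_um),
               directed_hausdorff(b, a, pixel_size_um))
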