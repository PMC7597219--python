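"""Tumor heterogeneity map: per-stain positive masks stacked over the
fixed section, with combination colors for colocalized stains."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2gray

from .core import BinaryMask, Section

DEFAULT_COLORS = [
    (46, 160, 67),    # green
    (214, 39, 40),    # red
    (31, 119, 180),   # blue
    (255, 127, 14),   # orange
    (148, 103, 189),  # lilac
    (140, 86, 75),    # maroon
]


@dataclass
class HeterogeneityMap:
    overlay: np.ndarray  # (rows, cols, 4) uint8 RGBA
    legend: dict[tuple[str, ...], tuple[int, int, int]]
    per_stain_masks: dict[str, BinaryMask]
    tissue_area_px: int = 0
    _combo_labels: np.ndarray = field(default=None, repr=False)
    _combos: list = field(default_factory=list, repr=False)


def _blend(colors: list[tuple[int, int, int]]) -> tuple[int, int, int]:
    """Additive average in linear RGB (gamma 2.2)."""
    lin = np.mean([[(c / 255.0) ** 2.2 for c in col] for col in colors], axis=0)
    return tuple(int(round(255 * v ** (1 / 2.2))) for v in lin)


def build_map(fixed: Section, masks: list[tuple[str, BinaryMask]],
              palette: dict | None = None) -> HeterogeneityMap:
    """Overlay per-stain positive masks on a desaturated fixed section.

    Pixels positive for exactly one stain take that stain's color; pixels
    positive for several take the combination color (user palette entry if
    given, additive blend otherwise).  Alpha encodes positivity.
    """
    shape = fixed.shape
    for name, m in masks:
        if m.shape != shape:
            raise ValueError(f"mask for stain {name!r} does not match the fixed shape")
    user_palette = palette is not None and len(palette) > 0
    palette = dict(palette or {})
    names = [name for name, _ in masks]
    for k, name in enumerate(names):
        if name not in palette:
            if user_palette:
                warnings.warn(f"no palette entry for stain {name!r}; auto-assigned")
            palette[name] = DEFAULT_COLORS[k % len(DEFAULT_COLORS)]

    gray = (rgb2gray(fixed.pixels) * 255).astype(np.uint8)
    overlay = np.stack([gray, gray, gray, np.full(shape, 255, np.uint8)], axis=-1)

    stack = np.stack([m.values for _, m in masks], axis=0)
    code = np.zeros(shape, dtype=np.int32)
    for k in range(len(masks)):
        code |= stack[k].astype(np.int32) << k

    legend: dict[tuple[str, ...], tuple[int, int, int]] = {}
    for r in range(1, len(masks) + 1):
        for combo in itertools.combinations(range(len(masks)), r):
            bits = sum(1 << k for k in combo)
            sel = code == bits
            if not sel.any():
                continue
            combo_names = tuple(names[k] for k in combo)
            if combo_names in palette:
                color = tuple(palette[combo_names])
            elif len(combo_names) == 1:
                color = tuple(palette[combo_names[0]])
            else:
                color = _blend([palette[n] for n in combo_names])
            legend[combo_names] = color
            overlay[sel, 0] = color[0]
            overlay[sel, 1] = color[1]
            overlay[sel, 2] = color[2]

    from .masking import rough_mask
    tissue = rough_mask(fixed)
    return HeterogeneityMap(
        overlay=overlay,
        legend=legend,
        per_stain_masks={name: m for name, m in masks},
        tissue_area_px=tissue.area,
        _combo_labels=code,
        _combos=names,
    )


def stain_area_report(hmap: HeterogeneityMap) -> pd.DataFrame:
    """Pixel counts and tissue-area fractions per stain and combination."""
    rows = []
    tissue = max(hmap.tissue_area_px, 1)
    for name, m in hmap.per_stain_masks.items():
        rows.append({"label": name, "kind": "stain", "pixels": m.area,
                     "tissue_fraction": m.area / tissue})
    names = hmap._combos
    code = hmap._combo_labels
    for combo_names in hmap.legend:
        bits = sum(1 << names.index(n) for n in combo_names)
        count = int((code == bits).sum())
        rows.append({"label": "+".join(combo_names),
                     "kind": "combination" if len(combo_names) > 1 else "exclusive",
                     "pixels": count, "tissue_fraction": count / tissue})
    return pd.DataFrame(rows)
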