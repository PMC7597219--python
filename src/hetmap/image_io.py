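"""Raster and landmark I/O plus working-resolution downsampling.

Landmark CSVs follow the ANHIR dialect: a header line, then comma-separated
rows ``id,X,Y`` with X = column and Y = row in pixels.  Any header whose
second and third columns parse as numbers in the body is accepted.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .core import LandmarkSet, Section


class LandmarkFormatError(ValueError):
    pass


def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    """Read an ANHIR-style landmark CSV (columns id, X, Y)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        if df.shape[0] == 0:
            return LandmarkSet(np.empty((0, 2)), np.empty(0, dtype=int))
        raise LandmarkFormatError(f"{path}: expected at least 3 columns (id, X, Y)")
    ids_col, x_col, y_col = df.columns[:3]
    xs = pd.to_numeric(df[x_col], errors="coerce")
    ys = pd.to_numeric(df[y_col], errors="coerce")
    bad = np.flatnonzero(xs.isna() | ys.isna())
    if bad.size:
        raise LandmarkFormatError(f"{path}: non-numeric X/Y at row {bad[0]}")
    ids = pd.to_numeric(df[ids_col], errors="coerce")
    if ids.isna().any():
        ids = pd.Series(np.arange(len(df)))
    return LandmarkSet(np.stack([xs.to_numpy(float), ys.to_numpy(float)], axis=1),
                       ids.to_numpy(int))


def write_landmarks(path: str | os.PathLike, landmarks: LandmarkSet) -> None:
    df = pd.DataFrame({"id": landmarks.ids,
                       "X": landmarks.points[:, 0],
                       "Y": landmarks.points[:, 1]})
    df.to_csv(path, index=False)


def read_section(path: str | os.PathLike, *, pixel_size_um: float = 1.0,
                 resolution_fraction: float = 1.0, stain: str = "",
                 landmarks_path: str | os.PathLike | None = None) -> Section:
    """Read a PNG/TIFF raster into a Section, optionally with its landmarks."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    lm = read_landmarks(landmarks_path) if landmarks_path is not None else None
    stain = stain or Path(path).stem
    return Section(img.astype(np.uint8), pixel_size_um=pixel_size_um,
                   resolution_fraction=resolution_fraction, stain=stain, landmarks=lm)


def write_section(path: str | os.PathLike, section: Section) -> None:
    iio.imwrite(path, section.pixels)


def downsample(section: Section, fraction: float) -> Section:
    """Resize a section (and its landmarks / pixel size) to ``fraction`` of
    full resolution.

    A Gaussian anti-alias prefilter is applied before bilinear resizing.
    Landmarks are rescaled by the ratio of the actual integer raster shapes,
    so repeated downsampling stays consistent with a single one.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    if fraction > section.resolution_fraction:
        raise ValueError("cannot upsample beyond the stored resolution fraction")
    ratio = fraction / section.resolution_fraction
    if ratio == 1.0:
        return section.copy()
    rows, cols = section.shape
    new_rows = max(1, int(round(rows * ratio)))
    new_cols = max(1, int(round(cols * ratio)))
    sigma = max(0.0, (1.0 / ratio - 1.0) / 2.0)
    img = section.pixels.astype(float)
    if sigma > 0:
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    out = resize(img, (new_rows, new_cols), order=1, anti_aliasing=False,
                 preserve_range=True)
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    sx = new_cols / cols
    sy = new_rows / rows
    lm = section.landmarks.scaled(sx, sy) if section.landmarks is not None else None
    return Section(out,
                   pixel_size_um=section.pixel_size_um * (section.resolution_fraction / fraction),
                   resolution_fraction=fraction,
                   stain=section.stain,
                   landmarks=lm)
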