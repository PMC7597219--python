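"""Synthetic serial-section fixtures with exactly known ground truth.

Emulates what the registration pipeline sees in practice: a common tissue
silhouette with low-frequency internal texture, two-stain IHC coloring
(brown positive signal on a purple counterstain over a near-white
background), per-section rigid offsets, smooth B-spline warps, and
acquisition artifacts (rips, holes/tissue loss, folds).

Landmarks and truth masks are transported *analytically* through the known
forward transform (local warp, then rigid motion about the canvas center),
while the raster is resampled bilinearly through the numerically inverted
map — ground truth stays exact to machine precision while images remain
realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import AffineMap, BinaryMask, LandmarkSet, Section
from .local_reg import BSplineGrid, ffd_displacement_clipped as _safe_ffd

BACKGROUND_LEVEL = 245          # flat near-white slide background
PURPLE = np.array([110.0, 80.0, 160.0])   # counterstain, B - R = 50
BROWN = np.array([150.0, 95.0, 70.0])     # positive signal, R - B = 80
DEFAULT_STAINS = ("CD1a", "CD4", "CD8", "CD68")


@dataclass
class FixtureConfig:
    canvas_size: tuple[int, int] = (256, 256)  # (rows, cols)
    n_sections: int = 4
    stain_names: tuple[str, ...] = DEFAULT_STAINS
    rigid_range: tuple[float, float] = (20.0, 25.0)  # max |t| px, max |theta| deg
    warp_amplitude: float = 8.0   # max control-point displacement, px
    warp_spacing: float = 64.0    # control spacing, px
    artifact_rates: dict = field(default_factory=lambda: {
        "rip": 0.5, "hole": 0.5, "fold": 0.3})
    n_landmarks: int = 86
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise ValueError("need at least two sections")
        if self.n_landmarks < 4:
            raise ValueError("need at least four landmarks")
        if self.warp_spacing < 4:
            raise ValueError("warp spacing must be >= 4 px")
        if any(not (0 <= r <= 1) for r in self.artifact_rates.values()):
            raise ValueError("artifact rates must be in [0, 1]")
        if min(self.canvas_size) < 32:
            raise ValueError("canvas too small to hold a silhouette with margin")


@dataclass
class BaseTissue:
    """Template rendering plus its recorded ground truth."""

    section: Section
    silhouette: BinaryMask   # outer outline, lumina filled
    lumina: BinaryMask       # interior openings (glandular lumina / gaps)
    positive_mask: BinaryMask
    texture: np.ndarray  # intensity modulation in [0.6, 1], tissue only

    @property
    def tissue(self) -> BinaryMask:
        """Stained pixels: silhouette minus interior lumina."""
        return BinaryMask(self.silhouette.values & ~self.lumina.values)


@dataclass
class SectionTruth:
    rigid: tuple[float, float, float]  # (dx, dy, theta_deg)
    grid: BSplineGrid
    landmarks: LandmarkSet            # true positions in this section's frame
    landmarks_in_canvas: np.ndarray   # bool flags, outside-canvas landmarks kept
    silhouette: BinaryMask            # outer outline after deformation
    tissue: BinaryMask                # silhouette minus lumina and artifacts
    positive_mask: BinaryMask
    artifact_mask: BinaryMask         # erased (rip/hole) pixels


@dataclass
class SyntheticStack:
    sections: list[Section]
    ground_truth: list[SectionTruth]
    config: FixtureConfig

    @property
    def fixed(self) -> Section:
        return self.sections[0]


# ---------------------------------------------------------------------------
# base tissue

def _silhouette_radius(theta: np.ndarray, r0: float, rng: np.random.Generator):
    amp = rng.uniform(0.04, 0.12, size=4)
    phase = rng.uniform(0, 2 * np.pi, size=4)
    r = np.ones_like(theta)
    for k, (a, p) in enumerate(zip(amp, phase), start=2):
        r += a * np.cos(k * theta + p)
    return r0 * r


def _render_stain(silhouette: np.ndarray, texture: np.ndarray,
                  positive: np.ndarray, noise_sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    rows, cols = silhouette.shape
    img = np.full((rows, cols, 3), float(BACKGROUND_LEVEL))
    base = np.where(positive[:, :, None], BROWN, PURPLE)
    shaded = base * texture[:, :, None]
    img[silhouette] = shaded[silhouette]
    if noise_sigma > 0:
        noise = rng.normal(0, noise_sigma, img.shape)
        noise[~silhouette] = 0.0
        img = img + noise
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def make_base_tissue(config: FixtureConfig) -> BaseTissue:
    """Template section: smooth blob silhouette, textured purple
    counterstain, brown positive blobs, landmarks inside the tissue."""
    rng = np.random.default_rng(config.seed)
    rows, cols = config.canvas_size
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    r0 = 0.36 * min(rows, cols)

    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    silhouette = rad <= _silhouette_radius(theta, r0, rng)

    # two texture octaves: broad intensity variation plus medium-scale
    # structure (glands/stroma scale); no nuclei-level detail
    coarse = gaussian_filter(rng.normal(size=(rows, cols)), 12.0)
    fine = gaussian_filter(rng.normal(size=(rows, cols)), 4.0)
    texture = coarse / coarse.std() + 0.6 * fine / fine.std()
    texture = (texture - texture.min()) / (np.ptp(texture) + 1e-12)
    texture = 0.6 + 0.4 * texture

    lumina = _lumina(silhouette, rng)
    tissue = silhouette & ~lumina
    positive = _positive_blobs(silhouette, rng) & tissue
    pixels = _render_stain(tissue, texture, positive, config.noise_sigma, rng)
    landmarks = _sample_landmarks(silhouette, config.n_landmarks, rng,
                                  exclude=lumina)
    sec = Section(pixels, stain=config.stain_names[0], landmarks=landmarks)
    return BaseTissue(sec, BinaryMask(silhouette), BinaryMask(lumina),
                      BinaryMask(positive), texture)


def _lumina(silhouette: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Small interior openings (glandular lumina, vessels, alveolar gaps)
    that the exhaustive tissue mask preserves and the rough mask fills."""
    from scipy.ndimage import binary_erosion

    rows, cols = silhouette.shape
    interior = np.argwhere(binary_erosion(silhouette, iterations=8))
    lum = np.zeros_like(silhouette)
    if len(interior) == 0:
        return lum
    yy, xx = np.mgrid[0:rows, 0:cols]
    for _ in range(int(rng.integers(30, 45))):
        cy, cx = interior[rng.integers(len(interior))]
        ry, rx = rng.uniform(2.0, 6.0, size=2)
        lum |= (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2) <= 1.0
    return lum & silhouette


def _positive_blobs(silhouette: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    rows, cols = silhouette.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    interior = np.argwhere(silhouette)
    pos = np.zeros_like(silhouette)
    n_blobs = rng.integers(4, 8)
    for _ in range(n_blobs):
        cyb, cxb = interior[rng.integers(len(interior))]
        ry = rng.uniform(8, 22)
        rx = rng.uniform(8, 22)
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cxb) * ca + (yy - cyb) * sa
        v = -(xx - cxb) * sa + (yy - cyb) * ca
        pos |= (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    return pos & silhouette  # positive signal never leaves the tissue


def _sample_landmarks(silhouette: np.ndarray, n: int,
                      rng: np.random.Generator,
                      exclude: np.ndarray | None = None) -> LandmarkSet:
    from scipy.ndimage import binary_dilation, binary_erosion

    inner = binary_erosion(silhouette, iterations=4)
    if exclude is not None:  # keep landmarks on tissue, off the lumina
        inner &= ~binary_dilation(exclude, iterations=2)
    coords = np.argwhere(inner if inner.any() else silhouette)
    idx = rng.choice(len(coords), size=n, replace=len(coords) < n)
    pts = coords[idx][:, ::-1].astype(float)  # (row, col) -> (x, y)
    pts += rng.uniform(-0.5, 0.5, pts.shape)  # sub-pixel positions
    return LandmarkSet(pts, np.arange(n))


# ---------------------------------------------------------------------------
# known deformation

def forward_map(rigid: tuple[float, float, float], grid: BSplineGrid | None,
                canvas_size: tuple[int, int]):
    """Forward transform x -> R_theta(x + ffd(x) - c) + c + t, c = canvas
    center.  Applied analytically to landmarks."""
    dx, dy, theta = rigid
    rows, cols = canvas_size
    c = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    rot = AffineMap.rotation(theta, c)

    def f(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        if grid is not None:
            pts = pts + _safe_ffd(grid, pts)
        return rot.map_points(pts) + np.array([dx, dy])

    return f


def _inverse_map(rigid, grid, canvas_size, points: np.ndarray) -> np.ndarray:
    """Numerical inverse of the forward map (fixed-point on the local warp)."""
    dx, dy, theta = rigid
    rows, cols = canvas_size
    c = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    inv_rot = AffineMap.rotation(theta, c).inverse()
    q = inv_rot.map_points(np.asarray(points, float).reshape(-1, 2)
                           - np.array([dx, dy]))
    if grid is None:
        return q
    y = q.copy()
    for _ in range(25):
        y = q - _safe_ffd(grid, y)
    return y


def deform_section(section: Section, rigid: tuple[float, float, float],
                   grid: BSplineGrid | None, artifacts: dict | None,
                   seed: int, truth_masks: dict[str, BinaryMask] | None = None
                   ) -> tuple[Section, dict]:
    """Apply a known rigid + B-spline deformation and optional artifacts.

    Returns the warped section plus a record holding the analytically
    transported landmarks (with outside-canvas flags), any transported
    truth masks, and the erased-artifact mask.  Artifacts (rips/holes are
    erased to background, folds darken a band) are applied *after* warping
    and recorded so overlap metrics can tell artifact loss from
    registration failure.
    """
    if abs(rigid[2]) > 180:
        raise ValueError("|rotation| must be <= 180 degrees")
    rows, cols = section.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    targets = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    src = _inverse_map(rigid, grid, (rows, cols), targets)
    coords = np.stack([src[:, 1], src[:, 0]])

    out = np.empty_like(section.pixels)
    for ch in range(3):
        s = map_coordinates(section.pixels[:, :, ch].astype(float), coords,
                            order=1, mode="constant", cval=BACKGROUND_LEVEL)
        out[:, :, ch] = np.clip(np.round(s), 0, 255).reshape(rows, cols)

    moved_masks = {}
    for name, m in (truth_masks or {}).items():
        w = map_coordinates(m.values.astype(float), coords, order=1,
                            mode="constant", cval=0.0).reshape(rows, cols)
        moved_masks[name] = BinaryMask(w > 0.5, m.pixel_size_um)

    f = forward_map(rigid, grid, (rows, cols))
    record: dict = {"rigid": rigid, "grid": grid, "masks": moved_masks}
    if section.landmarks is not None:
        pts = f(section.landmarks.points)
        in_canvas = ((pts[:, 0] >= 0) & (pts[:, 0] < cols)
                     & (pts[:, 1] >= 0) & (pts[:, 1] < rows))
        record["landmarks"] = LandmarkSet(pts, section.landmarks.ids.copy())
        record["landmarks_in_canvas"] = in_canvas

    rng = np.random.default_rng(seed)
    erased = np.zeros((rows, cols), dtype=bool)
    tissue = moved_masks.get("silhouette")
    tissue_v = tissue.values if tissue is not None else np.ones((rows, cols), bool)
    rates = artifacts or {}
    if rng.random() < rates.get("rip", 0.0):
        erased |= _rip(tissue_v, rng)
    if rng.random() < rates.get("hole", 0.0):
        erased |= _hole(tissue_v, rng)
    if rng.random() < rates.get("fold", 0.0):
        band = _rip(tissue_v, rng, width=(4.0, 8.0))
        out[band] = np.clip(out[band].astype(float) * 0.7, 0, 255).astype(np.uint8)
        record["fold_mask"] = band
    out[erased] = BACKGROUND_LEVEL
    record["artifact_mask"] = BinaryMask(erased)

    lm = record.get("landmarks")
    new_sec = Section(out, pixel_size_um=section.pixel_size_um,
                      resolution_fraction=section.resolution_fraction,
                      stain=section.stain, landmarks=lm)
    return new_sec, record


def _rip(tissue: np.ndarray, rng: np.random.Generator,
         width: tuple[float, float] = (1.5, 3.0)) -> np.ndarray:
    """Thin strip through the tissue along a random chord."""
    rows, cols = tissue.shape
    pts = np.argwhere(tissue)
    if len(pts) == 0:
        return np.zeros_like(tissue)
    cy, cx = pts[rng.integers(len(pts))]
    ang = rng.uniform(0, np.pi)
    w = rng.uniform(*width)
    yy, xx = np.mgrid[0:rows, 0:cols]
    # distance from the line through (cx, cy) with direction ang
    d = np.abs(-(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang))
    along = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
    half_len = rng.uniform(0.2, 0.45) * min(rows, cols)
    return (d <= w) & (np.abs(along) <= half_len) & tissue


def _hole(tissue: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    rows, cols = tissue.shape
    pts = np.argwhere(tissue)
    if len(pts) == 0:
        return np.zeros_like(tissue)
    cy, cx = pts[rng.integers(len(pts))]
    ry, rx = rng.uniform(4, 10, size=2)
    yy, xx = np.mgrid[0:rows, 0:cols]
    return ((((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2) <= 1.0) & tissue


# ---------------------------------------------------------------------------
# full stack

def make_stack(config: FixtureConfig) -> SyntheticStack:
    """Serial-section stack: the first section is the fixed template; every
    other section is an independently deformed copy with its own stain
    rendering and its own ground truth record."""
    rng = np.random.default_rng(config.seed)
    base = make_base_tissue(config)
    rows, cols = config.canvas_size
    max_t, max_deg = config.rigid_range

    sections: list[Section] = []
    truths: list[SectionTruth] = []
    for k in range(config.n_sections):
        stain = config.stain_names[k % len(config.stain_names)]
        sec_rng = np.random.default_rng([config.seed, k])
        tissue = base.tissue.values
        positive = _positive_blobs(base.silhouette.values, sec_rng) & tissue
        pixels = _render_stain(tissue, base.texture, positive,
                               config.noise_sigma, sec_rng)
        sec = Section(pixels, stain=stain,
                      landmarks=LandmarkSet(base.section.landmarks.points.copy(),
                                            base.section.landmarks.ids.copy()))
        if k == 0:
            rigid = (0.0, 0.0, 0.0)
            grid = None
        else:
            rigid = (float(sec_rng.uniform(-max_t, max_t)),
                     float(sec_rng.uniform(-max_t, max_t)),
                     float(sec_rng.uniform(-max_deg, max_deg)))
            grid = BSplineGrid.for_shape((rows, cols),
                                         (config.warp_spacing, config.warp_spacing))
            grid.phi = sec_rng.uniform(-config.warp_amplitude,
                                       config.warp_amplitude, grid.phi.shape)
        truth_masks = {"silhouette": base.silhouette,
                       "tissue": BinaryMask(tissue),
                       "positive": BinaryMask(positive)}
        artifacts = config.artifact_rates if k > 0 else None
        warped, rec = deform_section(sec, rigid, grid, artifacts,
                                     seed=int(sec_rng.integers(2 ** 31)),
                                     truth_masks=truth_masks)
        erased = rec["artifact_mask"].values
        truths.append(SectionTruth(
            rigid=rigid,
            grid=grid if grid is not None else BSplineGrid.for_shape(
                (rows, cols), (config.warp_spacing, config.warp_spacing)),
            landmarks=rec["landmarks"],
            landmarks_in_canvas=rec["landmarks_in_canvas"],
            silhouette=rec["masks"]["silhouette"],
            tissue=BinaryMask(rec["masks"]["tissue"].values & ~erased),
            positive_mask=BinaryMask(rec["masks"]["positive"].values & ~erased),
            artifact_mask=rec["artifact_mask"],
        ))
        sections.append(warped)
    return SyntheticStack(sections, truths, config)


def write_stack(stack: SyntheticStack, out_dir: str | Path) -> None:
    """Persist a stack as PNG + landmark CSV + JSON ground-truth sidecar."""
    import json

    from .image_io import write_landmarks, write_section

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = []
    for k, (sec, truth) in enumerate(zip(stack.sections, stack.ground_truth)):
        stem = f"section_{k:02d}_{sec.stain}"
        write_section(out / f"{stem}.png", sec)
        write_landmarks(out / f"{stem}_landmarks.csv", sec.landmarks)
        sidecar.append({
            "index": k,
            "stain": sec.stain,
            "rigid": list(truth.rigid),
            "grid": {"phi": truth.grid.phi.tolist(),
                     "spacing": list(truth.grid.spacing),
                     "origin": list(truth.grid.origin)},
            "landmarks_in_canvas": truth.landmarks_in_canvas.astype(int).tolist(),
        })
    (out / "ground_truth.json").write_text(json.dumps(
        {"config": {"canvas_size": list(stack.config.canvas_size),
                    "n_sections": stack.config.n_sections,
                    "seed": stack.config.seed},
         "sections": sidecar}, indent=2))
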