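"""End-to-end orchestration: masks -> pre-alignment -> affine + demons on
masks -> B-spline FFD on RGB -> stain classification -> heterogeneity map,
with per-stage landmark and overlap evaluation.

All mask-stage transforms are composed analytically; the moving RGB raster
is resampled exactly twice (once to feed the FFD, once to render the final
composition).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import BinaryMask, ComposedTransform, DisplacementField, Section
from .global_reg import (AffineOptConfig, DemonsConfig, register_affine,
                         register_demons, warp)
from .heterogeneity import HeterogeneityMap, build_map, stain_area_report
from .local_reg import FFDConfig, ffd_displacement, register_ffd
from .masking import exhaustive_mask, rough_mask
from .metrics import (LandmarkEval, OverlapBreakdown, confidence_map, rtre,
                      robustness)
from .prealign import prealign
from .segmentation import positive_mask

STAGES = ("initial", "align", "global", "local")


@dataclass
class PipelineConfig:
    fixed_index: int = 0
    affine: AffineOptConfig = field(default_factory=AffineOptConfig)
    demons: DemonsConfig = field(default_factory=DemonsConfig)
    ffd: FFDConfig = field(default_factory=FFDConfig)
    background_threshold: int = 200
    prealign_step_deg: float = 10.0
    palette: dict | None = None
    seed: int = 0


@dataclass
class SectionResult:
    stain: str
    transforms: dict[str, ComposedTransform]
    evals: dict[str, LandmarkEval]
    registered_rgb: np.ndarray | None = None
    positive: BinaryMask | None = None
    error: str | None = None

    @property
    def robustness(self) -> float | None:
        if "initial" in self.evals and "local" in self.evals:
            return robustness(self.evals["initial"], self.evals["local"])
        return None


@dataclass
class PipelineResult:
    fixed: Section
    sections: list[SectionResult]
    overlap: dict[str, OverlapBreakdown]
    heterogeneity: HeterogeneityMap | None
    median_rtre: dict[str, float]

    def stage_medians(self) -> dict[str, float]:
        return self.median_rtre


def _affine_stage(aff):
    return lambda pts: aff.map_points(pts)


def _field_stage(fld: DisplacementField):
    return lambda pts: fld.map_points(pts)


def _ffd_stage(grid):
    from .local_reg import ffd_displacement_clipped

    return lambda pts: pts + ffd_displacement_clipped(grid, pts)


def register_pair(fixed: Section, moving: Section, cfg: PipelineConfig
                  ) -> dict[str, ComposedTransform]:
    """Register one moving section to the fixed one; returns the composed
    backward transform (fixed frame -> moving frame) after each stage."""
    fixed_rough = rough_mask(fixed)
    moving_rough = rough_mask(moving)

    # T_Align on rough masks
    rigid = prealign(fixed_rough, moving_rough, step_deg=cfg.prealign_step_deg)
    t_align = ComposedTransform([_affine_stage(rigid.backward())])

    # T_Affine on rough masks
    m1 = warp(moving_rough, t_align.dense_field(fixed.shape))
    aff = register_affine(fixed_rough, m1, cfg.affine)
    t_affine = t_align.prepended(_affine_stage(aff.transform))

    # T_Demons on rough masks
    m2 = warp(moving_rough, t_affine.dense_field(fixed.shape))
    dem = register_demons(fixed_rough, m2, cfg.demons)
    t_global = t_affine.prepended(_field_stage(dem))

    # T_Local (FFD) on globally registered RGB
    moving_global_rgb = warp(moving.pixels, t_global.dense_field(fixed.shape),
                             fill=255.0)
    grid, _cost = register_ffd(fixed, moving_global_rgb, cfg.ffd,
                               roi=fixed_rough)
    t_local = t_global.prepended(_ffd_stage(grid))

    return {"initial": ComposedTransform([]), "align": t_align,
            "global": t_global, "local": t_local}


def run_pipeline(cfg: PipelineConfig, sections: list[Section]) -> PipelineResult:
    """Register every moving section onto the fixed one, classify positive
    pixels, and assemble the heterogeneity map and evaluation metrics.

    A failure in one section is recorded and the pipeline continues with
    the remaining ones.
    """
    if len(sections) < 2:
        raise ValueError("need at least two sections")
    fixed = sections[cfg.fixed_index]
    movings = [s for k, s in enumerate(sections) if k != cfg.fixed_index]

    fixed_exh = exhaustive_mask(fixed)
    results: list[SectionResult] = []
    stage_masks: dict[str, list[BinaryMask]] = {"initial": [fixed_exh],
                                                "global": [fixed_exh],
                                                "local": [fixed_exh]}
    stain_masks: list[tuple[str, BinaryMask]] = []

    for moving in movings:
        try:
            transforms = register_pair(fixed, moving, cfg)
        except Exception as exc:  # keep going with the other sections
            results.append(SectionResult(moving.stain, {}, {}, error=str(exc)))
            continue

        evals: dict[str, LandmarkEval] = {}
        if fixed.landmarks is not None and moving.landmarks is not None \
                and len(fixed.landmarks) == len(moving.landmarks):
            for stage in STAGES:
                mapped = transforms[stage].map_points(fixed.landmarks.points)
                from .core import LandmarkSet
                pred = LandmarkSet(mapped, fixed.landmarks.ids.copy())
                evals[stage] = rtre(moving.landmarks, pred, fixed.diagonal_px)

        final_rgb = warp(moving.pixels, transforms["local"].dense_field(fixed.shape),
                         fill=255.0)
        global_rgb = warp(moving.pixels, transforms["global"].dense_field(fixed.shape),
                          fill=255.0)
        reg_section = Section(final_rgb.astype(np.uint8), stain=moving.stain,
                              pixel_size_um=moving.pixel_size_um)
        stage_masks["initial"].append(exhaustive_mask(moving))
        stage_masks["global"].append(
            exhaustive_mask(Section(global_rgb.astype(np.uint8))))
        stage_masks["local"].append(exhaustive_mask(reg_section))

        pos = positive_mask(reg_section, cfg.background_threshold)
        stain_masks.append((moving.stain, pos))
        results.append(SectionResult(moving.stain, transforms, evals,
                                     registered_rgb=final_rgb.astype(np.uint8),
                                     positive=pos))

    overlap = {}
    for stage, masks in stage_masks.items():
        if len(masks) >= 2:
            _, overlap[stage] = confidence_map(masks)

    het = build_map(fixed, stain_masks, cfg.palette) if stain_masks else None

    median_rtre = {}
    for stage in STAGES:
        vals = [r.evals[stage].median for r in results if stage in r.evals]
        if vals:
            median_rtre[stage] = float(np.median(vals))

    return PipelineResult(fixed, results, overlap, het, median_rtre)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict:
    """Persist registered sections, masks, map, metrics and a hash manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"artifacts": {}}

    def save_image(name: str, arr: np.ndarray) -> None:
        path = out / name
        iio.imwrite(path, arr)
        manifest["artifacts"][name] = hashlib.sha256(path.read_bytes()).hexdigest()

    for k, r in enumerate(result.sections):
        if r.registered_rgb is not None:
            save_image(f"registered_{k:02d}_{r.stain}.png", r.registered_rgb)
        if r.positive is not None:
            save_image(f"positive_{k:02d}_{r.stain}.png",
                       (r.positive.values * 255).astype(np.uint8))
    if result.heterogeneity is not None:
        save_image("heterogeneity_map.png", result.heterogeneity.overlay)
        report = stain_area_report(result.heterogeneity)
        report.to_csv(out / "stain_areas.csv", index=False)
        manifest["artifacts"]["stain_areas.csv"] = hashlib.sha256(
            (out / "stain_areas.csv").read_bytes()).hexdigest()

    metrics = {"median_rtre": result.median_rtre,
               "overlap": {stage: ob.per_level_percent
                           for stage, ob in result.overlap.items()},
               "robustness": [r.robustness for r in result.sections],
               "errors": [r.error for r in result.sections]}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    manifest["artifacts"]["metrics.json"] = hashlib.sha256(
        (out / "metrics.json").read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
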