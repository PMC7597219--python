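# hetmap

Automatic registration of serial, differently-stained histology sections and
construction of **tumor spatial heterogeneity maps**.

When a biopsy is sectioned and each cut is stained with a different
immunohistochemical (IHC) marker (e.g. CD1a, CD4, CD8, CD68), the sections
land on separate slides with arbitrary offsets, rotations and local
deformations from sample preparation — rips, folds, missing tissue. To see
*where* the different antigens sit relative to each other, the sections must
first be brought into one coordinate frame, then the brown positive signal
must be separated from the purple hematoxylin counterstain, and finally the
per-stain positive masks can be stacked over a chosen template section.

`hetmap` implements that full pipeline for working-resolution renditions of
whole-slide images, plus a synthetic serial-section generator with exactly
known ground truth so every stage is testable without any data download.

## Method

The composed transform is `T = T_Align + T_Global + T_Local`:

1. **Pre-alignment** (`T_Align`): on rough binary tissue masks — translation
   from the difference of centers of mass, then a rotation sweep in
   10° increments over the full circle maximizing normalized
   cross-correlation.
2. **Global model** (`T_Global = T_Affine + T_Demons`): still on masks — a
   6-parameter affine fit by regular-step gradient descent on mean squared
   error over a 3-level Gaussian pyramid, followed by diffeomorphic demons
   (force `v = (Im−If)∇If / (|∇If|² + (Im−If)²)`, update exponentiated by
   scaling-and-squaring, field Gaussian-smoothed every iteration).
3. **Local model** (`T_Local`): cubic B-spline free-form deformation of the
   globally registered RGB sections — control lattice with [50, 50] px
   spacing, cost `C(ϕ) = C_sim + λ·C_smooth` with the log intensity
   difference `C_sim = mean log|I_M − I_F|` and thin-plate bending energy,
   λ = 0.01, quasi-Newton optimization with analytic gradients.
4. **Stain classification**: the red–blue joint color histogram of an IHC
   section splits along its diagonal — tissue pixels with `R > B` are
   positive (brown, DAB), `B ≥ R` counterstain (purple); near-white pixels
   are background. Tile-wise processing is bit-identical to whole-image.
5. **Evaluation**: relative target registration error
   `rTRE = ‖x_f − x_m‖ / d` with its challenge aggregates (AMrTRE, MMrTRE,
   AMxrTRE), robustness (fraction of improved landmarks), the registration
   confidence map (pixelwise sum of exhaustive tissue masks with an
   overlap-level breakdown), Dice, and Hausdorff distance.

## Worked example

```python
import hetmap
from hetmap.pipeline import PipelineConfig, run_pipeline

# 4 synthetic serial sections, 256x256, with known deformations + landmarks
stack = hetmap.make_stack(hetmap.FixtureConfig(seed=1))
for sec, truth in zip(stack.sections, stack.ground_truth):
    sec.landmarks = truth.landmarks

result = run_pipeline(PipelineConfig(), stack.sections)
print({s: round(m, 6) for s, m in result.median_rtre.items()})
print({s: round(ob.per_level_percent[ob.n_masks], 2)
       for s, ob in result.overlap.items()})
```

prints (seed 1):

```
{'initial': 0.037459, 'align': 0.007079, 'global': 0.005913, 'local': 0.000791}
{'initial': 48.61, 'global': 87.88, 'local': 94.88}
```

The first line is the median landmark error as a fraction of the image
diagonal after each stage — every stage shrinks it, and the local stage
ends ~50× below the unregistered error. The second line is the
complete-overlap share of the registration confidence map: before
registration only 48.6% of the covered area is shared by all four
sections; outline-level (global) registration raises it to 87.9% and the
B-spline stage, which also aligns interior structure (lumina, gaps), to
94.9%.

The command line mirrors the library:

```sh
hetmap simulate --out stack/ --seed 1          # synthetic fixture stack
hetmap register sections.yaml --out run/       # full pipeline + manifest
hetmap segment section.png --out labels.png    # 3-class stain classification
hetmap evaluate sections.yaml                  # overlap breakdown
```

## Layout

| module | role |
| --- | --- |
| `hetmap.synthetic` | serial-section fixtures with exact ground truth |
| `hetmap.image_io` | PNG/TIFF rasters, landmark CSVs, downsampling |
| `hetmap.masking` | rough (silhouette) and exhaustive tissue masks |
| `hetmap.prealign` | center-of-mass translation + rotation sweep |
| `hetmap.global_reg` | masked affine + diffeomorphic demons, warping |
| `hetmap.local_reg` | B-spline FFD with log-difference cost |
| `hetmap.segmentation` | red–blue diagonal stain classifier |
| `hetmap.metrics` | rTRE family, robustness, confidence map, Dice, Hausdorff |
| `hetmap.heterogeneity` | stacked per-stain overlay + area report |
| `hetmap.pipeline`, `hetmap.cli` | orchestration and `hetmap` CLI |

See `docs/methods.md` for the modeling details, parameter defaults and
known limitations.
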