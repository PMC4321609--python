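# spindleasym

Quantification of **spindle size asymmetry (SSA)** in metaphase cells from
confocal microscopy, for developmental and stem-cell biologists studying
asymmetric cell division (e.g. apical progenitors of the developing cerebral
cortex, where the daughter inheriting the larger half-spindle adopts a
different fate).

## The two measures and why they agree

A metaphase spindle has two poles. Labelling the larger one *left*, SSA is the
normalized percent difference

```
Δ_V = (V_L − V_R)/(V_L + V_R) × 100        (3D: voxel volumes of the segmented poles)
Δ   = (A_L − A_R)/(A_L + A_R) × 100        (2D: pole areas on a maximum-intensity projection)
```

with a cell called *symmetric* when the difference is ≤ 10 % and *asymmetric*
above. The 3D route is accurate but laborious; the 2D route is fast. This
package implements both, plus the geometric argument for why the cheap 2D
measure carries the same information:

model each pole as a solid of revolution with shape function
*f* : [0, 1] → ℝ₊ (*f*(0) = 1, *f*(1) = 0), diameter *d* and width *w*. By
Pappus' centroid theorem, V = 2π A(D) r̄ with A(D) = (dw/2)∫f and
r̄ = (d²w / 8A(D))∫f². When both poles share *f*, the centroid ratio
r̄_L/r̄_R collapses to the diameter ratio δ = d_L/d_R — **independently of the
shape** — so

```
Δ_V = (δ A_L − A_R)/(δ A_L + A_R) × 100,
```

and Δ_V is pinched between the affine envelope
`min(δ, 1/δ)·Δ + ε(δ) ≤ Δ_V ≤ max(δ, 1/δ)·Δ + ε(δ)`, ε(δ) = (δ−1)/(δ+1)×100.
Measured diameter ratios sit near δ ≈ 1.09 ± 0.12, so Δ_V is quasi-linear in Δ
with slope ≈ 1, and the two measures discriminate symmetric from asymmetric
cells equally well. At δ = 1 they are *identical* for every shape function.

The statistical layer models SSA magnitudes per developmental stage with
folded normal distributions, compares stages by permutation tests (10,000
label shuffles, add-one p-value), and validates the 2D/3D relationship by OLS
regression with 95 % pointwise and Working–Hotelling simultaneous confidence
bands.

Because no imaging data are deposited with the original study, the package
ships a ground-truthed synthetic renderer: solids-of-revolution spindles
rasterized at confocal sampling (0.045 μm laterally, 0.3 μm axially),
Gaussian PSF, noise, pericentrin puncta and a DNA plate — so every pipeline
claim is testable end to end.

## Worked example

```python
import numpy as np
from spindleasym.synthetic import RenderConfig, default_model, render_stack
from spindleasym.volume3d import PipelineConfig, measure_3d
from spindleasym.area2d import measure_2d_auto

model = default_model(delta_2d=20.0)          # true Δ = Δ_V = 20 (δ = 1)
stack, truth = render_stack(RenderConfig(model=model, seed=4, snr=10.0))

m3 = measure_3d(stack, PipelineConfig())
m2 = measure_2d_auto(stack)
print(f"true Δ_V = {truth.delta_v:.1f}")
print(f"3D pipeline: Δ_V = {m3.delta_3d:.2f} ({m3.symmetry_class})")
print(f"2D pipeline: Δ  = {m2.delta_2d:.2f}, tilt α = {m2.angle_deg:.1f}°")
```

prints

```
true Δ_V = 20.0
3D pipeline: Δ_V = 20.91 (asymmetric)
2D pipeline: Δ  = 20.92, tilt α = 0.0°
```

i.e. both pipelines recover the built-in 20 % asymmetry from a noisy rendered
stack within about one percentage point, and the cell is correctly classified
as asymmetric (Δ_V > 10).

The same workflow is available from the shell:

```sh
spindleasym simulate --seed 9 --out pop --mode render --n-stacks 3
spindleasym measure3d pop/stack_*.tif --out m3.csv
spindleasym measure2d pop/stack_*.tif --out m2.csv
spindleasym compare --csv-2d m2.csv --csv-3d m3.csv --out cmp
spindleasym theory-check --seed 1 --out bounds.csv
spindleasym fit-folded pop/population.csv --by-stage
spindleasym permtest pop/population.csv --group-a E10.5 --group-b E14.5 --seed 2
```

## Layout

- `spindleasym.ssa_core` — Δ definitions, left/right convention, symmetry classes, CSV records
- `spindleasym.theory` — shape functions, Pappus volumes, voxel-counting oracle, affine bounds
- `spindleasym.volume3d` — 3D pipeline: ROI crop, per-section thresholding, cleaning, pole selection, voxel volumes
- `spindleasym.area2d` — projections, polygon ROI areas, centrosome QC, spindle tilt angle
- `spindleasym.ssa_stats` — folded-normal MLE, permutation tests, regression bands
- `spindleasym.synthetic` — ground-truthed stack renderer and population generator
- `spindleasym.cli` — `spindleasym` command-line entry point

See `docs/methods.md` for modelling assumptions, parameter choices and known
limitations.
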