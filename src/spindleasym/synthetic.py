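"""Ground-truthed synthetic confocal stacks and SSA populations.

The renderer emulates a fixed metaphase cell imaged on a point-scanning
confocal: the two spindle poles are solids of revolution sharing an axis
and meeting at the equatorial (metaphase-plate) plane, rasterized onto
an anisotropic voxel grid (default 0.045 um laterally, 0.3 um axially),
blurred with an anisotropic Gaussian approximation of the point-spread
function, and corrupted with Gaussian read-out noise at a configurable
signal-to-noise ratio.  Pericentrin puncta sit at the pole apexes and a
DNA blob marks the metaphase plate; a configurable intensity dip at the
plate reproduces the tubulin-sparse gap visible between the half
spindles of real cells.  Ground truth (volumes, areas, percent
differences, the diameter ratio and the tilt angle) is computed
analytically from the generating model, never from the raster.

The population generator samples per-stage SSA magnitudes from folded
normal distributions — the developmental series peaks mid-neurogenesis —
plus diameter ratios and tilt angles, and inverts each sampled 2D
difference into a concrete spheroid-pole model, yielding matched
(Delta, Delta_V) tables or rendered stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from spindleasym.ssa_core import classify_symmetry
from spindleasym.theory import (
    ShapeFunction,
    SolidOfRevolutionPole,
    SpindleModel,
    pappus_volume,
)
from spindleasym.volume3d import VoxelStack

__all__ = [
    "RenderConfig",
    "GroundTruth",
    "PopulationConfig",
    "render_stack",
    "generate_population",
    "default_model",
]

#: Paper-scale acquisition: (dz, dy, dx) in micrometres.
DEFAULT_VOXEL_SIZE = (0.3, 0.045, 0.045)


def default_model(
    delta_2d: float = 20.0, diameter_ratio: float = 1.0, d_right: float = 3.0,
    w_right: float = 2.2, shape: ShapeFunction | None = None,
) -> SpindleModel:
    """Spheroid-pole model realizing a target 2D difference at a given delta.

    The cross-sectional area of a pole scales as d * w, so a 2D percent
    difference ``delta_2d`` fixes the area ratio
    (100 + delta)/(100 - delta) and, at diameter ratio delta, the width
    ratio w_L/w_R in closed form.
    """
    if not (0.0 <= delta_2d < 100.0):
        raise ValueError("delta_2d must lie in [0, 100)")
    shape = shape or ShapeFunction.spheroid()
    area_ratio = (100.0 + delta_2d) / (100.0 - delta_2d)
    d_left = diameter_ratio * d_right
    w_left = w_right * area_ratio / diameter_ratio
    return SpindleModel(
        left=SolidOfRevolutionPole(shape, d_left, w_left),
        right=SolidOfRevolutionPole(shape, d_right, w_right),
    )


@dataclass
class GroundTruth:
    """Analytic truth for a rendered cell; satisfies the percent-difference
    definitions exactly by construction."""

    v_left: float
    v_right: float
    a_left: float
    a_right: float
    delta_2d: float
    delta_v: float
    diameter_ratio: float
    angle_deg: float
    pole_labels: np.ndarray | None = None


@dataclass
class RenderConfig:
    """Rendering parameters.

    ``psf_sigma`` is the Gaussian PSF standard deviation (z, y, x) in um
    (axial elongation sigma_z > sigma_xy, as for a confocal); ``snr`` is
    foreground intensity over noise standard deviation; ``plate_dip`` is
    the fractional tubulin-intensity drop at the metaphase plate;
    ``tilt_alpha`` rotates the spindle axis out of the imaging plane.
    A seed is mandatory: rendering is deterministic given the config.
    """

    model: SpindleModel
    seed: int
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    psf_sigma: tuple[float, float, float] = (0.25, 0.08, 0.08)
    tilt_alpha: float = 0.0
    snr: float = 10.0
    noiseless: bool = False
    intensities: dict = field(
        default_factory=lambda: {"tubulin": 200.0, "pericentrin": 220.0, "dna": 150.0, "background": 10.0}
    )
    centrosome_size_ratio: float = 1.0
    plate_dip: float = 0.85
    plate_sigma: float = 0.12
    margin: float = 1.2
    shape_zyx: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt_alpha <= 90.0):
            raise ValueError("tilt_alpha must lie in [0, 90] degrees")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")


def _required_extent(config: RenderConfig) -> tuple[float, float, float]:
    model = config.model
    alpha = math.radians(config.tilt_alpha)
    span = model.left.width + model.right.width
    radial = max(model.left.diameter, model.right.diameter)
    # axis lies in the x-z plane; radial extent spreads into all axes
    ext_x = span * math.cos(alpha) + radial
    ext_z = span * math.sin(alpha) + radial
    ext_y = radial
    return (ext_z + 2 * config.margin, ext_y + 2 * config.margin, ext_x + 2 * config.margin)


def render_stack(config: RenderConfig) -> tuple[VoxelStack, GroundTruth]:
    """Rasterize a spindle model into a 3-channel stack plus ground truth.

    The pole interiors are evaluated exactly on voxel centers (labels 1 =
    left, 2 = right kept in the ground truth), then blurred and noised to
    produce the tubulin channel; pericentrin puncta are placed at the two
    pole apexes with the configured size ratio; the DNA channel is a
    flattened blob at the metaphase plate.
    """
    model = config.model
    dz, dy, dx = config.voxel_size
    ext_z, ext_y, ext_x = _required_extent(config)
    if config.shape_zyx is not None:
        nz, ny, nx = config.shape_zyx
        if nz * dz < ext_z - 2 * config.margin or ny * dy < ext_y - 2 * config.margin or nx * dx < ext_x - 2 * config.margin:
            raise ValueError("spindle exceeds the requested field of view")
    else:
        nz = int(np.ceil(ext_z / dz))
        ny = int(np.ceil(ext_y / dy))
        nx = int(np.ceil(ext_x / dx))

    # physical voxel-center coordinates relative to the cell center; the
    # half-voxel offset along z and x keeps voxel centers off the exact
    # equatorial plane, which would otherwise be assigned asymmetrically
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz + dz / 2.0
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx + dx / 2.0
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")

    alpha = math.radians(config.tilt_alpha)
    u = np.array([math.sin(alpha), 0.0, math.cos(alpha)])  # (z, y, x) axis direction
    t = zz * u[0] + yy * u[1] + xx * u[2]
    r2 = (zz - t * u[0]) ** 2 + (yy - t * u[1]) ** 2 + (xx - t * u[2]) ** 2

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    left, right = model.left, model.right
    sel = (t <= 0) & (t >= -left.width)
    s = np.clip(-t / left.width, 0.0, 1.0)
    radius = 0.5 * left.diameter * left.shape(s)
    labels[sel & (r2 <= radius**2)] = 1
    sel = (t > 0) & (t <= right.width)
    s = np.clip(t / right.width, 0.0, 1.0)
    radius = 0.5 * right.diameter * right.shape(s)
    labels[sel & (r2 <= radius**2)] = 2

    levels = config.intensities
    bg = levels["background"]
    tubulin = np.full(labels.shape, bg, dtype=float)
    inside = labels > 0
    dip = 1.0 - config.plate_dip * np.exp(-((t / config.plate_sigma) ** 2))
    tubulin[inside] = bg + (levels["tubulin"] - bg) * dip[inside]

    # pericentrin puncta at the two apexes, amplitude ratio = size ratio
    apex_left = -left.width * u
    apex_right = right.width * u
    sig = 0.15
    d2_l = (zz - apex_left[0]) ** 2 + (yy - apex_left[1]) ** 2 + (xx - apex_left[2]) ** 2
    d2_r = (zz - apex_right[0]) ** 2 + (yy - apex_right[1]) ** 2 + (xx - apex_right[2]) ** 2
    amp = levels["pericentrin"]
    pericentrin = bg + amp * config.centrosome_size_ratio * np.exp(-d2_l / (2 * sig**2))
    pericentrin += amp * np.exp(-d2_r / (2 * sig**2))

    # DNA: condensed chromosomes as a flattened disc at the plate
    plate_r = 0.45 * max(left.diameter, right.diameter)
    dna = np.full(labels.shape, bg, dtype=float)
    dna[(np.abs(t) <= 0.35) & (r2 <= plate_r**2)] = levels["dna"]

    sigma_vox = tuple(s / v for s, v in zip(config.psf_sigma, config.voxel_size))
    channels = []
    rng = np.random.default_rng(config.seed)
    for raw in (tubulin, pericentrin, dna):
        img = gaussian_filter(raw, sigma=sigma_vox) if any(s > 0 for s in sigma_vox) else raw
        if not config.noiseless:
            noise_sd = levels["tubulin"] / config.snr
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        channels.append(np.clip(img, 0.0, None))

    stack = VoxelStack(
        np.stack(channels),
        voxel_size=config.voxel_size,
        channel_names=("tubulin", "pericentrin", "dna"),
    )

    v_l = pappus_volume(left).volume
    v_r = pappus_volume(right).volume
    a_l = left.cross_section_area()
    a_r = right.cross_section_area()
    truth = GroundTruth(
        v_left=v_l,
        v_right=v_r,
        a_left=a_l,
        a_right=a_r,
        delta_2d=(a_l - a_r) / (a_l + a_r) * 100.0,
        delta_v=(v_l - v_r) / (v_l + v_r) * 100.0,
        diameter_ratio=model.diameter_ratio,
        angle_deg=config.tilt_alpha,
        pole_labels=labels,
    )
    return stack, truth


@dataclass
class PopulationConfig:
    """Population-level sampling parameters.

    ``stages`` maps stage name -> (mu, sigma, n) of the folded-normal SSA
    distribution, defaulting to a five-stage developmental series whose
    location rises to a mid-series peak and then falls, totalling 322
    cells.  Diameter ratios are near one (mean 1.09, sd 0.12) and tilt
    angles are half-normal with an 8-degree scale.
    """

    seed: int
    stages: dict[str, tuple[float, float, int]] = field(
        default_factory=lambda: {
            "E10.5": (4.0, 4.0, 64),
            "E11.5": (7.0, 5.0, 64),
            "E13.0": (10.0, 6.0, 66),
            "E14.5": (14.0, 7.0, 64),
            "E16.5": (8.0, 5.0, 64),
        }
    )
    diameter_ratio_mean: float = 1.09
    diameter_ratio_sd: float = 0.12
    alpha_scale_deg: float = 8.0
    mode: str = "theory"
    render: RenderConfig | None = None

    def __post_init__(self) -> None:
        for name, (mu, sigma, n) in self.stages.items():
            if sigma <= 0:
                raise ValueError(f"stage {name}: sigma must be positive")
            if n < 0:
                raise ValueError(f"stage {name}: n must be non-negative")


def generate_population(
    config: PopulationConfig,
) -> tuple[pd.DataFrame, list[GroundTruth], list[VoxelStack] | None]:
    """Sample a ground-truthed SSA population.

    Each cell draws a 2D difference from its stage's folded normal, a
    diameter ratio, and a tilt angle, then builds the spheroid-pole
    model realizing them; the matching 3D difference comes from the
    Pappus volumes.  ``mode="theory"`` returns the measurement table and
    analytic truths only; ``mode="render"`` additionally rasterizes each
    cell (ground-truth labels kept, table unchanged) and is intended for
    small n.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    truths: list[GroundTruth] = []
    stacks: list[VoxelStack] | None = [] if config.mode == "render" else None
    shape = ShapeFunction.spheroid()
    for stage, (mu, sigma, n) in config.stages.items():
        if n == 0:
            import warnings

            warnings.warn(f"stage {stage!r} has n=0 and is omitted", stacklevel=2)
            continue
        deltas = np.abs(rng.normal(mu, sigma, size=n))
        deltas = np.clip(deltas, 0.0, 90.0)
        ratios = np.clip(
            rng.normal(config.diameter_ratio_mean, config.diameter_ratio_sd, size=n),
            0.6,
            1.8,
        )
        alphas = np.clip(np.abs(rng.normal(0.0, config.alpha_scale_deg, size=n)), 0.0, 90.0)
        for i in range(n):
            model = default_model(
                delta_2d=float(deltas[i]), diameter_ratio=float(ratios[i]), shape=shape
            ).canonicalized()
            v_l = pappus_volume(model.left).volume
            v_r = pappus_volume(model.right).volume
            a_l = model.left.cross_section_area()
            a_r = model.right.cross_section_area()
            d2 = (a_l - a_r) / (a_l + a_r) * 100.0
            dv = abs(v_l - v_r) / (v_l + v_r) * 100.0
            truth = GroundTruth(
                v_left=v_l,
                v_right=v_r,
                a_left=a_l,
                a_right=a_r,
                delta_2d=d2,
                delta_v=dv,
                diameter_ratio=model.diameter_ratio,
                angle_deg=float(alphas[i]),
            )
            if config.mode == "render":
                render_cfg = replace(
                    config.render or RenderConfig(model=model, seed=0),
                    model=model,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    tilt_alpha=float(alphas[i]),
                )
                stack, truth_r = render_stack(render_cfg)
                truth.pole_labels = truth_r.pole_labels
                stacks.append(stack)
            truths.append(truth)
            rows.append(
                {
                    "cell_id": f"{stage}_{i:03d}",
                    "stage": stage,
                    "delta_2d": d2,
                    "delta_3d": dv,
                    "diameter_ratio": model.diameter_ratio,
                    "angle_deg": float(alphas[i]),
                    "symmetry_class": classify_symmetry(d2),
                }
            )
    return pd.DataFrame(rows), truths, stacks
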