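"""2D spindle-pole area quantification on maximum-intensity projections.

The 2D route to spindle size asymmetry avoids voxel-by-voxel
segmentation: the tubulin channel is collapsed to a maximum-intensity
projection, the two pole domains are delimited by polygon ROIs (drawn
manually, or produced automatically by splitting the projected spindle
mask perpendicular to the centrosome axis), and the percent area
difference Delta = (A_L - A_R)/(A_L + A_R) * 100 is reported.

Two quality controls accompany the measurement, both based on the
pericentrin channel: the two centrosomes must be of equal size
(otherwise part of a pole may lie outside the acquired volume), and the
spindle tilt angle alpha relative to the imaging plane is recorded from
the in-plane (X) and axial (Y) centrosome separations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import pearsonr
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu

from spindleasym.ssa_core import (
    InvalidMeasurementError,
    PoleAreas,
    SpindleMeasurement,
    classify_symmetry,
    delta_2d,
)
from spindleasym.volume3d import VoxelStack

logger = logging.getLogger(__name__)

__all__ = [
    "QCError",
    "Projection2D",
    "PolygonROI",
    "CentrosomePair",
    "SpindleAngle",
    "max_projection",
    "polygon_area",
    "detect_centrosomes",
    "centrosome_equal",
    "spindle_angle",
    "measure_2d",
    "measure_2d_auto",
    "angle_vs_ssa",
    "rois_from_csv",
    "rois_to_csv",
]


class QCError(RuntimeError):
    """A quality-control criterion failed (e.g. unequal centrosomes)."""


@dataclass
class Projection2D:
    """Maximum-intensity projection with physical pixel size (dy, dx) um."""

    pixels: np.ndarray
    pixel_size: tuple[float, float]


@dataclass
class PolygonROI:
    """Simple polygon in (x, y) pixel coordinates delimiting one pole area."""

    vertices: list[tuple[float, float]]
    label: str = "area_1"

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"ROI {self.label!r} is not a simple polygon")

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class CentrosomePair:
    """The two pericentrin puncta: centroids in physical um and size estimates.

    Sizes are integrated intensities above the detection threshold, the
    robust metric for near diffraction-limited puncta.
    """

    centroids_um: tuple[tuple[float, float, float], tuple[float, float, float]]
    sizes: tuple[float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("centrosome sizes must be positive")

    @property
    def size_ratio(self) -> float:
        big, small = max(self.sizes), min(self.sizes)
        return big / small


@dataclass
class SpindleAngle:
    """Spindle tilt from centrosome separations: alpha = atan2(Y, X) degrees."""

    x_dist: float
    y_dist: float

    @property
    def alpha_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.y_dist, self.x_dist)))


def max_projection(stack: VoxelStack, channel: str | int = "tubulin") -> Projection2D:
    """Pixel-wise maximum over z of the given channel."""
    data = stack.channel(channel)
    dz, dy, dx = stack.voxel_size
    return Projection2D(pixels=data.max(axis=0), pixel_size=(dy, dx))


def polygon_area(roi: PolygonROI, pixel_size: tuple[float, float]) -> float:
    """Polygon area in um^2 (shoelace x pixel area); orientation-independent."""
    dy, dx = pixel_size
    return roi.as_shapely().area * dy * dx


def detect_centrosomes(
    stack: VoxelStack,
    pericentrin_channel: str | int = "pericentrin",
    min_voxels: int = 2,
) -> CentrosomePair:
    """Locate the two pericentrin puncta in 3D.

    The channel is thresholded at half the peak prominence above the
    median background (robust for sparse near-diffraction-limited puncta,
    where a bimodality-based threshold collapses), components smaller
    than ``min_voxels`` are discarded, and the two components with the
    largest integrated intensity are kept.  A third comparably bright
    component, or fewer than two puncta, is a QC failure: the cell
    cannot be scored.
    """
    data = np.asarray(stack.channel(pericentrin_channel), dtype=float)
    if data.max() <= data.min():
        raise QCError("pericentrin channel is blank")
    # light smoothing suppresses shot/read noise without displacing the
    # (already PSF-blurred) puncta
    data = ndimage.gaussian_filter(data, sigma=1.0)
    background = float(np.median(data))
    mask = data > background + 0.5 * (data.max() - background)
    comp, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        raise QCError("no pericentrin puncta detected")
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
    intensities = ndimage.sum_labels(data, comp, index=range(1, n + 1))
    keep = [i for i in range(n) if sizes[i] >= min_voxels]
    if len(keep) < 2:
        raise QCError(f"expected 2 centrosome puncta, found {len(keep)}")
    keep.sort(key=lambda i: -intensities[i])
    if len(keep) > 2 and intensities[keep[2]] >= 0.5 * intensities[keep[1]]:
        raise QCError("more than two comparably bright puncta: ambiguous centrosomes")
    labels = [keep[0] + 1, keep[1] + 1]
    centroids = ndimage.center_of_mass(data, comp, labels)
    scale = np.asarray(stack.voxel_size)
    centroids_um = tuple(tuple(np.asarray(c) * scale) for c in centroids)
    return CentrosomePair(
        centroids_um=centroids_um,
        sizes=(float(intensities[keep[0]]), float(intensities[keep[1]])),
    )


def centrosome_equal(pair: CentrosomePair, tol: float = 0.2) -> bool:
    """True when the large/small size ratio is at most 1 + tol (inclusive)."""
    return pair.size_ratio <= 1.0 + tol + 1e-12


def spindle_angle(pair: CentrosomePair) -> SpindleAngle:
    """Tilt of the pole-pole axis from the imaging plane.

    X is the in-plane (y, x) Euclidean separation of the centrosomes, Y
    the axial |dz| separation, both in micrometres; alpha in [0, 90] deg.
    """
    (z1, y1, x1), (z2, y2, x2) = pair.centroids_um
    x_dist = float(np.hypot(y1 - y2, x1 - x2))
    y_dist = float(abs(z1 - z2))
    return SpindleAngle(x_dist=x_dist, y_dist=y_dist)


def measure_2d(
    stack: VoxelStack,
    roi_1: PolygonROI,
    roi_2: PolygonROI,
    channel: str | int = "tubulin",
    centrosome_tol: float = 0.2,
    skip_qc: bool = False,
    symmetry_threshold: float = 10.0,
    cell_id: str = "cell",
    stage: str = "",
) -> SpindleMeasurement:
    """2D measurement from two non-overlapping pole ROIs.

    Runs centrosome QC (override with ``skip_qc``), computes the two
    polygon areas on the projection's pixel grid, orders them so the
    larger is "left", and reports Delta with the symmetry class and the
    spindle angle alpha when centrosomes are available.
    """
    p1, p2 = roi_1.as_shapely(), roi_2.as_shapely()
    inter = p1.intersection(p2).area
    if inter > 1e-9 * max(p1.area, p2.area, 1.0):
        raise InvalidMeasurementError("pole ROIs overlap; they must partition the spindle")

    angle = None
    provenance: dict = {"mode": "manual_roi"}
    try:
        pair = detect_centrosomes(stack)
        angle = spindle_angle(pair).alpha_deg
        provenance["centrosome_size_ratio"] = pair.size_ratio
        if not centrosome_equal(pair, centrosome_tol):
            raise QCError(
                f"centrosome size ratio {pair.size_ratio:.2f} exceeds 1 + {centrosome_tol}"
            )
    except QCError as exc:
        if not skip_qc:
            logger.info("cell %s skipped: %s", cell_id, exc)
            raise
        provenance["qc_overridden"] = str(exc)

    proj = max_projection(stack, channel)
    areas = PoleAreas(polygon_area(roi_1, proj.pixel_size), polygon_area(roi_2, proj.pixel_size))
    d = delta_2d(areas)
    return SpindleMeasurement(
        cell_id=cell_id,
        stage=stage,
        delta_2d=d,
        angle_deg=angle,
        symmetry_class=classify_symmetry(d, symmetry_threshold),
        provenance=provenance,
    )


def measure_2d_auto(
    stack: VoxelStack,
    channel: str | int = "tubulin",
    centrosome_tol: float = 0.2,
    skip_qc: bool = False,
    symmetry_threshold: float = 10.0,
    cell_id: str = "cell",
    stage: str = "",
) -> SpindleMeasurement:
    """Human-free 2D measurement.

    The projection is thresholded (Otsu), the largest component kept,
    and the spindle mask split along the line perpendicular to the
    projected centrosome axis through the metaphase plate — located at
    the projected DNA-intensity centroid when a DNA channel is present,
    else at the mask centroid; the two half areas stand in for manually
    drawn ROIs.  Provenance records ``mode="auto"``.
    """
    pair = detect_centrosomes(stack)
    if not centrosome_equal(pair, centrosome_tol) and not skip_qc:
        raise QCError(f"centrosome size ratio {pair.size_ratio:.2f} fails QC")
    angle = spindle_angle(pair).alpha_deg

    proj = max_projection(stack, channel)
    img = proj.pixels.astype(float)
    mask = img > threshold_otsu(img)
    comp, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        raise InvalidMeasurementError("no spindle signal in projection")
    # keep every substantial component: the two pole domains are often
    # separated by the tubulin-sparse gap at the metaphase plate
    sizes = np.bincount(comp.ravel())[1:]
    keep = np.flatnonzero(sizes >= max(25, 0.05 * sizes.max())) + 1
    mask = np.isin(comp, keep)

    dy, dx = proj.pixel_size
    (_, yl1, xl1), (_, yl2, xl2) = pair.centroids_um
    axis = np.array([yl1 - yl2, xl1 - xl2])
    if np.linalg.norm(axis) == 0:
        raise InvalidMeasurementError("projected centrosome axis is degenerate")
    axis /= np.linalg.norm(axis)
    coords = np.argwhere(mask).astype(float) * np.array([dy, dx])
    anchor = coords.mean(axis=0)
    if "dna" in stack.channel_names:
        dna = max_projection(stack, "dna").pixels.astype(float)
        weights = np.clip(dna - np.median(dna), 0.0, None)
        if weights.sum() > 0:
            cy, cx = ndimage.center_of_mass(weights)
            anchor = np.array([cy * dy, cx * dx])
    side = (coords - anchor) @ axis
    a1 = float(np.count_nonzero(side >= 0)) * dy * dx
    a2 = float(np.count_nonzero(side < 0)) * dy * dx
    if a1 <= 0 or a2 <= 0:
        raise InvalidMeasurementError("auto split produced an empty pole area")

    areas = PoleAreas(a1, a2)
    d = delta_2d(areas)
    return SpindleMeasurement(
        cell_id=cell_id,
        stage=stage,
        delta_2d=d,
        angle_deg=angle,
        symmetry_class=classify_symmetry(d, symmetry_threshold),
        provenance={"mode": "auto", "centrosome_size_ratio": pair.size_ratio},
    )


def angle_vs_ssa(measurements: Sequence[SpindleMeasurement]) -> dict:
    """Pearson correlation between spindle tilt alpha and SSA magnitude Delta.

    Independence of the two (small |r|, non-significant p) supports that
    tilted spindles do not inflate projected-area asymmetry.  Returns a
    summary dict; ``computable`` is False when alpha (or Delta) is
    constant and the correlation undefined.
    """
    pairs = [
        (m.angle_deg, m.delta_2d)
        for m in measurements
        if m.angle_deg is not None and m.delta_2d is not None
    ]
    if len(pairs) < 3:
        return {"computable": False, "reason": "fewer than 3 cells with angle and delta"}
    alpha = np.array([p[0] for p in pairs])
    delta = np.array([p[1] for p in pairs])
    if np.ptp(alpha) == 0 or np.ptp(delta) == 0:
        return {
            "computable": False,
            "reason": "constant variable",
            "alpha_sd": float(alpha.std(ddof=1)),
            "n": len(pairs),
        }
    r, p = pearsonr(alpha, delta)
    return {
        "computable": True,
        "r": float(r),
        "p_value": float(p),
        "alpha_sd": float(alpha.std(ddof=1)),
        "n": len(pairs),
    }


# -- ROI CSV dialect: columns label, vertex_index, x, y -----------------

def rois_to_csv(rois: Iterable[PolygonROI], path: str | Path) -> None:
    rows = []
    for roi in rois:
        for i, (x, y) in enumerate(roi.vertices):
            rows.append({"label": roi.label, "vertex_index": i, "x": x, "y": y})
    pd.DataFrame(rows, columns=["label", "vertex_index", "x", "y"]).to_csv(path, index=False)


def rois_from_csv(path: str | Path) -> list[PolygonROI]:
    frame = pd.read_csv(path)
    out = []
    for label, group in frame.groupby("label", sort=True):
        group = group.sort_values("vertex_index")
        out.append(PolygonROI(list(zip(group["x"], group["y"])), label=str(label)))
    return out
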