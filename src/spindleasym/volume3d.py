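"""3D spindle-pole volume quantification from confocal z-stacks.

Re-implements the classic interactive ImageJ workflow as a scriptable
pipeline: crop a rectangular ROI around the spindle, threshold the
tubulin channel section by section, clean small spurious components,
assign foreground voxels to the two spindle poles (seeded wand-style
region growing, with a plane-split fallback when the poles touch), and
convert voxel counts to physical volumes using the anisotropic voxel
dimensions.  The end product per cell is the 3D spindle-pole difference
Delta_V = (V_L - V_R)/(V_L + V_R) * 100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from spindleasym.ssa_core import (
    InvalidMeasurementError,
    PoleVolumes,
    SpindleMeasurement,
    classify_symmetry,
    delta_v,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelStack",
    "PipelineConfig",
    "crop_roi",
    "threshold_stack",
    "clean_mask",
    "select_pole",
    "pole_volumes",
    "measure_3d",
]

#: Default channel order used by the synthetic renderer and the CLI.
DEFAULT_CHANNELS = ("tubulin", "pericentrin", "dna")


@dataclass
class VoxelStack:
    """Multi-channel 3D intensity grid with physical voxel dimensions.

    ``intensities`` is indexed (channel, z, y, x); ``voxel_size`` is
    (dz, dy, dx) in micrometres.  Confocal voxels are anisotropic: the
    axial step (0.2-0.6 um) exceeds the lateral pixel size (~0.045 um).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim == 3:
            self.intensities = self.intensities[None]
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be (channel, z, y, x) or (z, y, x)")
        if len(self.channel_names) != self.intensities.shape[0]:
            self.channel_names = tuple(
                f"ch{i}" for i in range(self.intensities.shape[0])
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name: str | int) -> np.ndarray:
        if isinstance(name, int):
            return self.intensities[name]
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.intensities[idx]

    # -- TIFF I/O -----------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(
            path,
            np.moveaxis(self.intensities, 0, 1),  # -> (z, channel, y, x)
            photometric="minisblack",
            planarconfig="separate",
            metadata={
                "axes": "ZCYX",
                "voxel_size_um": list(self.voxel_size),
                "channels": list(self.channel_names),
            },
        )

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        voxel_size: tuple[float, float, float] | None = None,
        channel_names: Sequence[str] | None = None,
    ) -> "VoxelStack":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        if data.ndim == 4:  # stored ZCYX
            data = np.moveaxis(data, 1, 0)
        if voxel_size is None:
            voxel_size = tuple(meta.get("voxel_size_um", (0.3, 0.045, 0.045)))
        if channel_names is None:
            channel_names = tuple(meta.get("channels", DEFAULT_CHANNELS))
        return cls(data, tuple(voxel_size), tuple(channel_names))


def crop_roi(stack: VoxelStack, rect: tuple[int, int, int, int]) -> VoxelStack:
    """Crop every z-slice to the rectangle (y0, x0, height, width).

    The ROI isolates the spindle from surrounding signal before
    thresholding; voxel dimensions are preserved.
    """
    y0, x0, h, w = rect
    nz, ny, nx = stack.shape_zyx
    if h <= 0 or w <= 0:
        raise ValueError("ROI rectangle must have positive height and width")
    if y0 < 0 or x0 < 0 or y0 + h > ny or x0 + w > nx:
        raise ValueError(f"ROI {rect} exceeds image bounds (ny={ny}, nx={nx})")
    return replace(
        stack, intensities=stack.intensities[:, :, y0 : y0 + h, x0 : x0 + w]
    )


def threshold_stack(
    stack: VoxelStack,
    method: str = "otsu",
    level: float | None = None,
    channel: str | int = "tubulin",
) -> np.ndarray:
    """Binarize the tubulin channel.

    ``otsu`` thresholds every optical section independently, which copes
    with section-to-section attenuation, but floors each section's level
    at the whole-stack Otsu threshold: sections containing no spindle
    signal (noise only, or a sliver of one pole) would otherwise adapt
    their threshold far below the signal level and flood the mask.
    ``fixed`` applies one global ``level``.  A blank (constant) section
    yields an empty mask slice with a logged warning rather than an
    error.
    """
    data = stack.channel(channel)
    mask = np.zeros(data.shape, dtype=bool)
    if method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
        mask = data > level
    elif method == "otsu":
        if data.max() == data.min():
            warnings.warn("thresholding produced an empty mask", stacklevel=2)
            return mask
        global_level = threshold_otsu(data)
        for z in range(data.shape[0]):
            plane = data[z]
            if plane.max() == plane.min():
                logger.warning("slice %d is blank; leaving it empty", z)
                continue
            mask[z] = plane > max(threshold_otsu(plane), global_level)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    if not mask.any():
        warnings.warn("thresholding produced an empty mask", stacklevel=2)
    return mask


def clean_mask(mask: np.ndarray, min_voxels: int = 5) -> np.ndarray:
    """Drop 26-connected components smaller than ``min_voxels`` voxels."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if min_voxels == 1 or not mask.any():
        return mask.copy()
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labeled.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    return np.isin(labeled, keep)


# slice-wise wand emulation: 8-connectivity within each optical section,
# plus face adjacency between consecutive sections
_WAND_STRUCTURE = np.zeros((3, 3, 3), dtype=bool)
_WAND_STRUCTURE[1] = True
_WAND_STRUCTURE[0, 1, 1] = _WAND_STRUCTURE[2, 1, 1] = True


def _plane_split(
    mask: np.ndarray,
    axis_direction: np.ndarray,
    voxel_size: tuple[float, float, float],
    point_um: np.ndarray | None = None,
) -> np.ndarray:
    """Split foreground by the plane normal to ``axis_direction``.

    The plane passes through ``point_um`` (physical coordinates) when
    given — ideally the metaphase plate, e.g. the DNA-channel centroid —
    and through the mask centroid otherwise.  For asymmetric spindles
    the centroid lies inside the larger pole, so a physically anchored
    split point is strongly preferred.  Coordinates are physical
    (micrometres) so anisotropic voxels do not skew the plane.  Returns
    labels 0/1/2.
    """
    coords = np.argwhere(mask).astype(float) * np.asarray(voxel_size)
    centroid = coords.mean(axis=0) if point_um is None else np.asarray(point_um, float)
    direction = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("axis direction must be non-zero")
    side = (coords - centroid) @ (direction / norm)
    labels = np.zeros(mask.shape, dtype=np.uint8)
    idx = np.argwhere(mask)
    labels[tuple(idx[side >= 0].T)] = 1
    labels[tuple(idx[side < 0].T)] = 2
    return labels


def select_pole(
    mask: np.ndarray,
    seed: tuple[int, int, int],
    connectivity: str = "wand",
    split_axis: np.ndarray | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    split_point: np.ndarray | None = None,
    force_split: bool = False,
) -> np.ndarray:
    """Assign foreground voxels to pole 1 (seeded side) and pole 2 (the rest).

    The seeded region is grown with slice-wise 8-connectivity unioned
    across neighbouring sections (``"wand"``, emulating per-section wand
    clicks) or full 26-connectivity (``"full"``).  If the grown region
    swallows the whole foreground — touching poles with no intensity gap
    at the metaphase plate — and ``split_axis`` (the centrosome-to-
    centrosome direction, (dz, dy, dx)) is provided, the mask is instead
    split by the plane through its centroid perpendicular to that axis.

    Returns a label volume: 0 background, 1 seeded pole, 2 other pole.
    """
    seed = tuple(int(c) for c in seed)
    if not mask[seed]:
        raise ValueError(f"seed {seed} does not lie on a foreground voxel")
    structure = _WAND_STRUCTURE if connectivity == "wand" else np.ones((3, 3, 3), bool)
    comp, _ = ndimage.label(mask, structure=structure)
    pole1 = comp == comp[seed]
    pole2 = mask & ~pole1
    if force_split or not pole2.any():
        if split_axis is None:
            raise InvalidMeasurementError(
                "seeded region covers the whole spindle and no split axis was given"
            )
        labels = _plane_split(mask, split_axis, voxel_size, point_um=split_point)
        if labels[seed] == 2:  # keep the seeded side as pole 1
            labels[labels > 0] = 3 - labels[labels > 0]
        return labels
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[pole1] = 1
    labels[pole2] = 2
    return labels


def pole_volumes(
    labels: np.ndarray, voxel_size: tuple[float, float, float]
) -> tuple[PoleVolumes, dict]:
    """Physical pole volumes (um^3) from a label volume, canonically ordered.

    Also returns raw voxel counts keyed by original label, since counts
    are what the voxel grid actually measures.
    """
    n1 = int(np.count_nonzero(labels == 1))
    n2 = int(np.count_nonzero(labels == 2))
    if n1 == 0 or n2 == 0:
        raise InvalidMeasurementError("both spindle poles must be non-empty")
    dz, dy, dx = voxel_size
    vol = dz * dy * dx
    return PoleVolumes(n1 * vol, n2 * vol), {"pole_1_voxels": n1, "pole_2_voxels": n2}


@dataclass
class PipelineConfig:
    """End-to-end 3D measurement configuration.

    ``seed`` is a (z, y, x) voxel on one pole; when omitted, the pipeline
    auto-splits the mask by the plane perpendicular to the centrosome
    axis detected from the pericentrin channel.
    """

    roi: tuple[int, int, int, int] | None = None
    threshold: str = "otsu"
    threshold_level: float | None = None
    min_voxels: int = 5
    seed: tuple[int, int, int] | None = None
    connectivity: str = "wand"
    tubulin_channel: str | int = "tubulin"
    pericentrin_channel: str | int = "pericentrin"
    dna_channel: str | int | None = "dna"
    symmetry_threshold: float = 10.0
    cell_id: str = "cell"
    stage: str = ""


def measure_3d(stack: VoxelStack, config: PipelineConfig | None = None) -> SpindleMeasurement:
    """Full 3D pipeline: crop, threshold, clean, split into poles, Delta_V.

    Stage provenance (threshold method/levels, seed or split axis,
    min_voxels, voxel counts) is recorded on the returned measurement.
    """
    config = config or PipelineConfig()
    provenance: dict = {"stages": []}
    try:
        if config.roi is not None:
            stack = crop_roi(stack, config.roi)
            provenance["roi"] = list(config.roi)
        provenance["stages"].append("crop")

        mask = threshold_stack(
            stack, config.threshold, config.threshold_level, config.tubulin_channel
        )
        provenance["threshold"] = config.threshold
        provenance["stages"].append("threshold")

        mask = clean_mask(mask, config.min_voxels)
        provenance["min_voxels"] = config.min_voxels
        provenance["stages"].append("clean")

        plane_split_needed = _needs_plane_split(mask, config)
        split_axis = None
        split_point = None
        if config.seed is None or plane_split_needed:
            split_axis = _centrosome_axis(stack, config)
            if split_axis is None:
                split_axis = _principal_axis(mask, stack.voxel_size)
            split_point = _plate_point(stack, config)
        seed = config.seed if config.seed is not None else _auto_seed(mask, config)
        labels = select_pole(
            mask,
            seed,
            connectivity=config.connectivity,
            split_axis=split_axis,
            voxel_size=stack.voxel_size,
            split_point=split_point,
            force_split=config.seed is None and plane_split_needed,
        )
        provenance["seed"] = list(seed)
        provenance["split_axis_used"] = bool(plane_split_needed and config.seed is None)
        provenance["stages"].append("select")

        volumes, counts = pole_volumes(labels, stack.voxel_size)
        provenance.update(counts)
        provenance["stages"].append("volumes")
    except Exception as exc:
        stage = provenance["stages"][-1] if provenance["stages"] else "start"
        raise type(exc)(f"[after stage {stage!r}] {exc}") from exc

    dv = delta_v(volumes)
    return SpindleMeasurement(
        cell_id=config.cell_id,
        stage=config.stage,
        delta_3d=dv,
        symmetry_class=classify_symmetry(dv, config.symmetry_threshold),
        provenance=provenance,
    )


def _needs_plane_split(mask: np.ndarray, config: PipelineConfig) -> bool:
    """Plane split is needed when no genuine second pole component exists.

    Stray crumbs shed from a noisy surface can make the component count
    exceed one without the poles actually being separated, so the second
    component must also be a substantial fraction of the first.
    """
    comp, n = ndimage.label(
        mask,
        structure=_WAND_STRUCTURE if config.connectivity == "wand" else np.ones((3, 3, 3), bool),
    )
    if n < 2:
        return True
    sizes = np.sort(np.bincount(comp.ravel())[1:])[::-1]
    return sizes[1] < 0.1 * sizes[0]


def _auto_seed(mask: np.ndarray, config: PipelineConfig) -> tuple[int, int, int]:
    """A voxel inside the largest connected component."""
    comp, n = ndimage.label(
        mask,
        structure=_WAND_STRUCTURE if config.connectivity == "wand" else np.ones((3, 3, 3), bool),
    )
    largest = np.argmax(np.bincount(comp.ravel())[1:]) + 1
    idx = np.argwhere(comp == largest)
    return tuple(idx[len(idx) // 2])


def _centrosome_axis(stack: VoxelStack, config: PipelineConfig) -> np.ndarray | None:
    """Centrosome-to-centrosome direction in physical (dz, dy, dx) coordinates."""
    try:
        from spindleasym.area2d import detect_centrosomes

        pair = detect_centrosomes(stack, config.pericentrin_channel)
    except Exception:
        logger.warning("centrosome detection failed; falling back to mask principal axis")
        return None
    c1, c2 = (np.asarray(c) for c in pair.centroids_um)
    return c1 - c2


def _plate_point(stack: VoxelStack, config: PipelineConfig) -> np.ndarray | None:
    """Metaphase-plate anchor for the split plane: the DNA intensity centroid.

    The condensed chromosomes sit exactly between the two half-spindles,
    so their background-subtracted centroid marks where the poles meet.
    Returns None (fall back to the mask centroid) without a DNA channel.
    """
    if config.dna_channel is None:
        return None
    try:
        dna = np.asarray(stack.channel(config.dna_channel), dtype=float)
    except KeyError:
        return None
    weights = np.clip(dna - np.median(dna), 0.0, None)
    total = weights.sum()
    if total <= 0:
        return None
    centroid_vox = np.array(ndimage.center_of_mass(weights))
    return centroid_vox * np.asarray(stack.voxel_size)


def _principal_axis(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Longest principal axis of the foreground, in physical coordinates."""
    coords = np.argwhere(mask).astype(float) * np.asarray(voxel_size)
    if coords.shape[0] < 2:
        raise InvalidMeasurementError("mask too small to orient a split plane")
    coords -= coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    return vt[0]
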