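"""Canonical SSA statistics.

The spindle size asymmetry (SSA) of a metaphase cell is quantified as the
normalized percent difference between its two spindle poles, measured
either from pole volumes (3D) or from projected pole areas (2D):

    delta = (L - R) / (L + R) * 100,

where by convention the *left* pole is the larger of the two.  A cell is
called symmetric when the difference does not exceed a threshold
(default 10 percent) and asymmetric otherwise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "InvalidMeasurementError",
    "PoleVolumes",
    "PoleAreas",
    "SpindleMeasurement",
    "canonical_order",
    "delta_v",
    "delta_2d",
    "classify_symmetry",
    "measurements_to_csv",
    "measurements_from_csv",
]

#: Default symmetric/asymmetric cut-off, in percent.
SYMMETRY_THRESHOLD = 10.0

_CSV_COLUMNS = [
    "cell_id",
    "stage",
    "delta_2d",
    "delta_3d",
    "diameter_ratio",
    "angle_deg",
    "symmetry_class",
]


class InvalidMeasurementError(ValueError):
    """A pole measurement violates its physical constraints."""


def canonical_order(pole_a: float, pole_b: float) -> tuple[float, float]:
    """Order two pole sizes so the larger one comes first.

    The larger pole is labelled "left" by convention; on an exact tie the
    input order is preserved (the label assignment is arbitrary and the
    downstream asymmetry is 0 either way).

    Parameters
    ----------
    pole_a, pole_b
        Strictly positive pole sizes (both volumes or both areas, in the
        same units).

    Returns
    -------
    (left, right) with ``left >= right``.
    """
    a, b = float(pole_a), float(pole_b)
    if not (a > 0 and b > 0) or not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidMeasurementError(
            f"pole sizes must be finite and strictly positive, got ({pole_a}, {pole_b})"
        )
    return (a, b) if a >= b else (b, a)


@dataclass(frozen=True)
class PoleVolumes:
    """Volumes of the two spindle poles, canonically ordered.

    Units are the caller's (cubic micrometres or voxel counts) but must be
    identical for both poles.
    """

    v_left: float
    v_right: float

    def __post_init__(self) -> None:
        left, right = canonical_order(self.v_left, self.v_right)
        object.__setattr__(self, "v_left", left)
        object.__setattr__(self, "v_right", right)


@dataclass(frozen=True)
class PoleAreas:
    """Projected areas of the two spindle poles (square micrometres)."""

    a_left: float
    a_right: float

    def __post_init__(self) -> None:
        left, right = canonical_order(self.a_left, self.a_right)
        object.__setattr__(self, "a_left", left)
        object.__setattr__(self, "a_right", right)


def _percent_difference(left: float, right: float) -> float:
    total = left + right
    if total <= 0:
        raise InvalidMeasurementError("pole sizes must sum to a positive value")
    return (left - right) / total * 100.0


def delta_v(v: PoleVolumes) -> float:
    """3D spindle-pole difference (V_L - V_R)/(V_L + V_R) x 100, in [0, 100)."""
    return _percent_difference(v.v_left, v.v_right)


def delta_2d(a: PoleAreas) -> float:
    """2D spindle-pole difference (A_L - A_R)/(A_L + A_R) x 100, in [0, 100)."""
    return _percent_difference(a.a_left, a.a_right)


def classify_symmetry(delta: float, threshold: float = SYMMETRY_THRESHOLD) -> str:
    """Classify a spindle as ``"symmetric"`` (delta <= threshold) or ``"asymmetric"``.

    ``delta`` is a folded (non-negative) percent difference in [0, 100].
    """
    if not (0.0 <= delta <= 100.0):
        raise InvalidMeasurementError(f"delta must lie in [0, 100], got {delta}")
    return "symmetric" if delta <= threshold else "asymmetric"


@dataclass
class SpindleMeasurement:
    """Per-cell SSA record.

    ``delta_2d`` and ``delta_3d`` are folded percent differences;
    ``diameter_ratio`` is the left/right pole diameter ratio (theory-derived
    when measured on images); ``angle_deg`` is the spindle tilt relative to
    the imaging plane in degrees, in [0, 90].  Optional fields are ``None``
    when not measured.
    """

    cell_id: str
    stage: str = ""
    delta_2d: float | None = None
    delta_3d: float | None = None
    diameter_ratio: float | None = None
    angle_deg: float | None = None
    symmetry_class: str | None = None
    provenance: dict = dataclasses.field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("delta_2d", 0.0, 100.0),
            ("delta_3d", 0.0, 100.0),
            ("angle_deg", 0.0, 90.0),
        ):
            value = getattr(self, name)
            if value is not None and not (lo <= value <= hi):
                raise InvalidMeasurementError(
                    f"{name} must lie in [{lo}, {hi}], got {value}"
                )
        if self.diameter_ratio is not None and not self.diameter_ratio > 0:
            raise InvalidMeasurementError("diameter_ratio must be positive")


def measurements_to_csv(
    measurements: Iterable[SpindleMeasurement], path: str | Path
) -> None:
    """Write measurements as CSV with a fixed header; missing optionals empty."""
    rows = []
    for m in measurements:
        rows.append({col: getattr(m, col) for col in _CSV_COLUMNS})
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    frame.to_csv(path, index=False)


def measurements_from_csv(path: str | Path) -> list[SpindleMeasurement]:
    """Read measurements written by :func:`measurements_to_csv`."""
    frame = pd.read_csv(path, dtype={"cell_id": str, "stage": str})
    out: list[SpindleMeasurement] = []
    for record in frame.to_dict(orient="records"):
        kwargs = {}
        for col in _CSV_COLUMNS:
            value = record.get(col)
            if isinstance(value, float) and math.isnan(value):
                value = None
            if col in ("cell_id", "stage") and value is None:
                value = ""
            kwargs[col] = value
        out.append(SpindleMeasurement(**kwargs))
    return out


def measurements_to_frame(
    measurements: Sequence[SpindleMeasurement],
) -> pd.DataFrame:
    """Tabulate measurements as a DataFrame with the CSV column layout."""
    return pd.DataFrame(
        [{col: getattr(m, col) for col in _CSV_COLUMNS} for m in measurements],
        columns=_CSV_COLUMNS,
    )
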