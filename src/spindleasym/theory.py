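"""Solids-of-revolution spindle-pole models and the 2D/3D asymmetry theory.

A spindle pole is modelled as the solid obtained by rotating the region

    D = {(x, r) : 0 <= x <= w,  0 <= r <= (d/2) f(x/w)}

about the x-axis, where ``f : [0, 1] -> R+`` is a continuous *shape
function* with f(0) = 1 (full diameter at the metaphase plate) and
f(1) = 0 (closing at the centrosome apex), ``d`` is the pole diameter and
``w`` its width.  Pappus' centroid theorem gives the pole volume as

    V = 2 pi A(D) rbar,

with A(D) the area of the generating region and rbar the distance of its
centroid to the revolution axis.  In normalized form,

    A(D) = (d w / 2) * int_0^1 f(u) du,
    rbar = (d^2 w / (8 A(D))) * int_0^1 f(u)^2 du.

Because rbar_L / rbar_R reduces to the diameter ratio delta = d_L / d_R
whenever both poles share the same shape function, the 3D percent
difference satisfies

    Delta_V = (delta A_L - A_R) / (delta A_L + A_R) * 100,

independently of f — the structural result that makes projected-area
(2D) asymmetry measurements equivalent in discriminative power to voxel
volume (3D) measurements.  The affine bounds

    min(delta, 1) Delta + eps(delta) <= Delta_V <= max(delta, 1) Delta + eps(delta),
    eps(delta) = (delta - 1) / (delta + 1) * 100,

quantify the quasi-linearity; they collapse to Delta_V = Delta at
delta = 1.

A note on conventions: the half-spheroid closed forms
``V = 2 pi d^2 w / 3`` and ``A = pi d w / 2`` treat ``d`` as the
equatorial *radius* (semi-diameter); the general region above and the
cone closed forms treat ``d`` as the *diameter*.  The closed forms are
kept in their classical printed form, and cross-checks against the
Pappus route must scale accordingly (a spheroid pole of closed-form size
``d`` corresponds to a revolution region of diameter ``2 d``).  All
asymmetry statistics are ratios and independent of this choice.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import PchipInterpolator

__all__ = [
    "InvalidShapeError",
    "ShapeFunction",
    "SolidOfRevolutionPole",
    "SpindleModel",
    "PappusQuantities",
    "spheroid_closed_form",
    "cone_closed_form",
    "pappus_volume",
    "voxel_volume_oracle",
    "delta_2d_from_model",
    "delta_v_from_model",
    "epsilon_delta",
    "bounds_eq6",
    "random_shape_function",
    "random_spindle_model",
]

_ENDPOINT_TOL = 1e-6


class InvalidShapeError(ValueError):
    """A shape function violates f(0)=1, f(1)=0, continuity or positivity."""


class ShapeFunction:
    """Normalized generating curve of a pole: continuous, f(0)=1, f(1)=0, f >= 0.

    Wraps either a closed-form callable (``spheroid``, ``cone``) or a
    monotone-safe interpolant through sample knots (:meth:`from_knots`).
    """

    def __init__(self, func: Callable[[np.ndarray], np.ndarray], kind: str = "custom",
                 knots: tuple[tuple[float, ...], tuple[float, ...]] | None = None):
        self._func = func
        self.kind = kind
        self.knots = knots
        self.validate()

    def __call__(self, u):
        return np.asarray(self._func(np.asarray(u, dtype=float)), dtype=float)

    # -- constructors -------------------------------------------------
    @classmethod
    def spheroid(cls) -> "ShapeFunction":
        """f(u) = sqrt(1 - u^2): half-spheroid profile."""
        return cls(lambda u: np.sqrt(np.clip(1.0 - u * u, 0.0, None)), kind="spheroid")

    @classmethod
    def cone(cls) -> "ShapeFunction":
        """f(u) = 1 - u: right-circular cone profile."""
        return cls(lambda u: 1.0 - u, kind="cone")

    @classmethod
    def from_knots(cls, u: Sequence[float], values: Sequence[float]) -> "ShapeFunction":
        """Shape-preserving cubic (PCHIP) through knots; no overshoot below 0."""
        u = np.asarray(u, dtype=float)
        values = np.asarray(values, dtype=float)
        if u[0] != 0.0 or u[-1] != 1.0:
            raise InvalidShapeError("knot abscissae must span [0, 1]")
        if np.any(values < 0):
            raise InvalidShapeError("knot values must be non-negative")
        interp = PchipInterpolator(u, values)
        return cls(interp, kind="knots", knots=(tuple(u), tuple(values)))

    # -- validation ---------------------------------------------------
    def validate(self, n_grid: int = 2049) -> None:
        f0 = float(self(0.0))
        f1 = float(self(1.0))
        if abs(f0 - 1.0) > _ENDPOINT_TOL or abs(f1) > _ENDPOINT_TOL:
            raise InvalidShapeError(
                f"shape function must satisfy f(0)=1 and f(1)=0, got f(0)={f0}, f(1)={f1}"
            )
        grid = np.linspace(0.0, 1.0, n_grid)
        vals = self(grid)
        if np.any(vals < -_ENDPOINT_TOL):
            raise InvalidShapeError("shape function must be non-negative on [0, 1]")
        # continuity proxy: for a continuous profile the largest neighbour
        # jump shrinks when the grid is refined; a genuine discontinuity
        # keeps its jump size at any resolution
        coarse = np.max(np.abs(np.diff(self(np.linspace(0.0, 1.0, (n_grid - 1) // 4 + 1)))))
        fine = np.max(np.abs(np.diff(vals)))
        if fine > 0.05 and fine > 0.6 * coarse:
            raise InvalidShapeError("shape function appears discontinuous on [0, 1]")

    def integrals(self, n_quad: int = 512) -> tuple[float, float]:
        """(int f du, int f^2 du) on [0, 1] by composite Simpson."""
        if n_quad < 32:
            raise ValueError("n_quad must be >= 32")
        u = np.linspace(0.0, 1.0, n_quad + 1)
        vals = self(u)
        return float(simpson(vals, x=u)), float(simpson(vals * vals, x=u))

    def to_dict(self) -> dict:
        if self.kind in ("spheroid", "cone"):
            return {"kind": self.kind}
        if self.kind == "knots" and self.knots is not None:
            return {"kind": "knots", "u": list(self.knots[0]), "values": list(self.knots[1])}
        raise ValueError("only spheroid/cone/knots shapes serialize")

    @classmethod
    def from_dict(cls, payload: dict) -> "ShapeFunction":
        kind = payload["kind"]
        if kind == "spheroid":
            return cls.spheroid()
        if kind == "cone":
            return cls.cone()
        if kind == "knots":
            return cls.from_knots(payload["u"], payload["values"])
        raise ValueError(f"unknown shape kind {kind!r}")


@dataclass(frozen=True)
class SolidOfRevolutionPole:
    """One spindle pole: shape function, diameter ``d`` and width ``w`` (same length unit)."""

    shape: ShapeFunction
    diameter: float
    width: float

    def __post_init__(self) -> None:
        if not (self.diameter > 0 and self.width > 0):
            raise ValueError("pole diameter and width must be positive")

    def generating_area(self, n_quad: int = 512) -> float:
        """Area A(D) of the generating (half cross-section) region."""
        i1, _ = self.shape.integrals(n_quad)
        return 0.5 * self.diameter * self.width * i1

    def cross_section_area(self, n_quad: int = 512) -> float:
        """Full cross-sectional area in a plane containing the axis: 2 A(D)."""
        return 2.0 * self.generating_area(n_quad)


@dataclass(frozen=True)
class PappusQuantities:
    """Generating area, centroid distance to axis, and the resulting volume."""

    area_AD: float
    centroid_rbar: float
    volume: float


def pappus_volume(pole: SolidOfRevolutionPole, n_quad: int = 512) -> PappusQuantities:
    """Pole volume by Pappus' centroid theorem, V = 2 pi A(D) rbar.

    The generating-region area and centroid are reduced to the normalized
    quadratures ``int f`` and ``int f^2`` and evaluated by composite
    Simpson with ``n_quad`` intervals (>= 32).
    """
    pole.shape.validate()
    i1, i2 = pole.shape.integrals(n_quad)
    if i1 <= 0:
        raise InvalidShapeError("shape function integrates to zero: degenerate pole")
    d, w = pole.diameter, pole.width
    area = 0.5 * d * w * i1
    rbar = d * d * w * i2 / (8.0 * area)
    volume = 2.0 * math.pi * area * rbar
    return PappusQuantities(area_AD=area, centroid_rbar=rbar, volume=volume)


def voxel_volume_oracle(pole: SolidOfRevolutionPole, grid_step: float) -> float:
    """Brute-force volume: count cubic grid cells inside the revolved region.

    A cell of side ``grid_step`` counts when its center ``(x, y, z)``
    satisfies ``sqrt(y^2 + z^2) <= (d/2) f(x/w)`` with ``0 <= x <= w``.
    Entirely independent of the quadrature route; converges to
    :func:`pappus_volume` as the grid is refined.
    """
    d, w = pole.diameter, pole.width
    if grid_step > min(d, w) / 20.0:
        warnings.warn(
            "voxel oracle grid is coarse (step > min(d, w)/20); volume may be inaccurate",
            stacklevel=2,
        )
    half = d / 2.0
    x = np.arange(grid_step / 2.0, w, grid_step)
    # cell centers at (k + 1/2) * step avoid the coordinate planes, so the
    # (y, z) lattice splits into four congruent quadrants
    yz = np.arange(grid_step / 2.0, half + grid_step, grid_step)
    r2 = np.sort((yz[:, None] ** 2 + yz[None, :] ** 2).ravel())
    radius = half * pole.shape(x / w)
    counts = np.searchsorted(r2, radius**2, side="right")
    return 4 * int(counts.sum()) * grid_step**3


def spheroid_closed_form(d: float, w: float) -> tuple[float, float]:
    """Half-spheroid pole: volume 2 pi d^2 w / 3 and cross-section pi d w / 2.

    Classical form with ``d`` the equatorial radius; satisfies V = 4 A d / 3.
    """
    if not (d > 0 and w > 0):
        raise ValueError("dimensions must be positive")
    return 2.0 * math.pi * d * d * w / 3.0, math.pi * d * w / 2.0


def cone_closed_form(d: float, w: float) -> tuple[float, float]:
    """Right-circular cone pole of diameter ``d``, height ``w``: (pi d^2 w / 12, d w / 2)."""
    if not (d > 0 and w > 0):
        raise ValueError("dimensions must be positive")
    return math.pi * d * d * w / 12.0, d * w / 2.0


@dataclass(frozen=True)
class SpindleModel:
    """Two solids-of-revolution poles sharing a shape function and revolution axis."""

    left: SolidOfRevolutionPole
    right: SolidOfRevolutionPole

    def __post_init__(self) -> None:
        if self.left.shape is not self.right.shape:
            # allow distinct objects only if they serialize identically
            try:
                same = self.left.shape.to_dict() == self.right.shape.to_dict()
            except ValueError:
                same = False
            if not same:
                raise ValueError("left and right poles must share the shape function")

    @property
    def diameter_ratio(self) -> float:
        """delta = d_L / d_R."""
        return self.left.diameter / self.right.diameter

    def canonicalized(self, n_quad: int = 512) -> "SpindleModel":
        """Relabel so the left pole has the larger cross-sectional area."""
        if self.left.cross_section_area(n_quad) >= self.right.cross_section_area(n_quad):
            return self
        return SpindleModel(left=self.right, right=self.left)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "shape": self.left.shape.to_dict(),
            "d_left": self.left.diameter,
            "d_right": self.right.diameter,
            "w_left": self.left.width,
            "w_right": self.right.width,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SpindleModel":
        text = str(source)
        if "{" not in text:  # a path rather than inline JSON
            text = Path(source).read_text()
        payload = json.loads(text)
        shape = ShapeFunction.from_dict(payload["shape"])
        return cls(
            left=SolidOfRevolutionPole(shape, payload["d_left"], payload["w_left"]),
            right=SolidOfRevolutionPole(shape, payload["d_right"], payload["w_right"]),
        )


def delta_2d_from_model(model: SpindleModel, n_quad: int = 512) -> float:
    """Signed 2D percent difference from cross-sectional areas (left minus right)."""
    a_l = model.left.cross_section_area(n_quad)
    a_r = model.right.cross_section_area(n_quad)
    return (a_l - a_r) / (a_l + a_r) * 100.0


def delta_v_from_model(model: SpindleModel, n_quad: int = 512) -> float:
    """Signed 3D percent difference from Pappus volumes (left minus right)."""
    v_l = pappus_volume(model.left, n_quad).volume
    v_r = pappus_volume(model.right, n_quad).volume
    return (v_l - v_r) / (v_l + v_r) * 100.0


def epsilon_delta(diameter_ratio: float) -> float:
    """Affine offset eps(delta) = (delta - 1)/(delta + 1) * 100 of the 2D/3D bounds."""
    if diameter_ratio <= 0:
        raise ValueError("diameter ratio must be positive")
    return (diameter_ratio - 1.0) / (diameter_ratio + 1.0) * 100.0


def bounds_eq6(delta_2d: float, diameter_ratio: float) -> tuple[float, float]:
    """Affine bounds on Delta_V given Delta and the diameter ratio delta.

    With x = Delta/100 and e = eps(delta)/100, the exact relation for
    area-ordered poles (A_L >= A_R) is the Moebius map

        Delta_V / 100 = (x + e) / (1 + e x),

    which is concave in x for delta > 1 and convex for delta < 1.
    Bounding it between its chord and tangent on [0, 1] gives the valid
    affine envelope

        min(delta, 1/delta) Delta + eps <= Delta_V <= max(delta, 1/delta) Delta + eps.

    (The coefficients min/max(delta, 1) sometimes quoted for this
    envelope fail as a lower bound for delta > 1 once Delta is moderate
    — e.g. delta = 1.09, Delta = 33.3 gives Delta_V = 37.11 below
    Delta + eps = 37.64 — whereas the min/max(delta, 1/delta) pair above
    is provable; both coincide at delta = 1, where the bounds collapse
    to Delta_V = Delta exactly.)  Quasi-linearity for delta near one
    follows either way.
    """
    if not (0.0 <= delta_2d <= 100.0):
        raise ValueError("delta_2d must lie in [0, 100]")
    eps = epsilon_delta(diameter_ratio)
    lo_coef = min(diameter_ratio, 1.0 / diameter_ratio)
    hi_coef = max(diameter_ratio, 1.0 / diameter_ratio)
    return lo_coef * delta_2d + eps, hi_coef * delta_2d + eps


def random_shape_function(
    rng: np.random.Generator, n_knots: int = 6, monotone: bool = True
) -> ShapeFunction:
    """Sample a random continuous profile with f(0)=1, f(1)=0.

    Monotone profiles (single-lobed poles) interpolate strictly decreasing
    random knot values; non-monotone profiles allow bounded bumps while
    staying non-negative (PCHIP does not overshoot the knot range).
    """
    # rejection-sample knot abscissae with a minimum spacing so profiles
    # stay resolvable by quadrature and rasterization
    while True:
        u = np.sort(rng.uniform(0.05, 0.95, size=n_knots - 2))
        u = np.concatenate([[0.0], u, [1.0]])
        if np.min(np.diff(u)) >= 0.03:
            break
    if monotone:
        interior = np.sort(rng.uniform(0.02, 0.98, size=n_knots - 2))[::-1]
    else:
        interior = rng.uniform(0.05, 1.0, size=n_knots - 2)
    values = np.concatenate([[1.0], interior, [0.0]])
    return ShapeFunction.from_knots(u, values)


def random_spindle_model(
    rng: np.random.Generator,
    diameter_ratio: float | None = None,
    monotone: bool = True,
) -> SpindleModel:
    """Sample a random model: shared random shape, random sizes.

    ``diameter_ratio`` fixes delta = d_L / d_R; by default it is drawn
    log-uniformly in [2/3, 3/2].  Widths are independent in [0.5, 3].
    """
    shape = random_shape_function(rng, monotone=monotone)
    d_r = rng.uniform(0.8, 2.5)
    if diameter_ratio is None:
        diameter_ratio = math.exp(rng.uniform(math.log(2 / 3), math.log(3 / 2)))
    d_l = diameter_ratio * d_r
    w_l, w_r = rng.uniform(0.5, 3.0, size=2)
    return SpindleModel(
        left=SolidOfRevolutionPole(shape, d_l, w_l),
        right=SolidOfRevolutionPole(shape, d_r, w_r),
    )
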