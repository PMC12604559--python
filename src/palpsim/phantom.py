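"""Tissue phantoms with a single stiff inclusion, and workspace discretization.

A phantom is a planar two-material body: a hard inclusion (3D-printed PLA,
~5 GPa) embedded in a soft matrix (Ecoflex 00-10, ~7 kPa).  Three inclusion
geometries are provided — circle, rectangle and horseshoe (annular sector) —
with analytic areas matching the benchmark samples of 12.57, 7.79 and
7.88 mm^2 respectively.  The workspace is discretized into square lattices
(coarse 5x5 and fine 50x50 by default); lattice points sit at
``x_i = x0 + i*dx`` with ``dx = (x_max - x_min)/N``, i.e. at cell corners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Shape(str, Enum):
    CIRCLE = "circle"
    RECTANGLE = "rectangle"
    HORSESHOE = "horseshoe"


# Default workspace: 10 mm x 10 mm centred on the inclusion.  Gives a
# 0.2 mm fine-grid pitch at N = 50 and comfortably contains all fixtures.
DEFAULT_EXTENT = (0.0, 10.0, 0.0, 10.0)
DEFAULT_CENTER = (5.0, 5.0)

# Material stiffness: PLA inclusion vs Ecoflex 00-10 matrix.
STIFF_HARD_PA = 5.0e9
STIFF_SOFT_PA = 7.0e3

# Fixture geometry (mm), chosen so analytic areas match the printed
# benchmark areas: pi*2^2 = 12.566, 3.6*2.164 = 7.790, and the horseshoe
# span is solved exactly from span*(R^2 - r^2)/2 = 7.88.
CIRCLE_RADIUS = 2.0
RECT_W, RECT_H = 3.6, 2.164
HS_R_OUT, HS_R_IN = 2.2, 1.2
HS_SPAN = 2.0 * 7.88 / (HS_R_OUT**2 - HS_R_IN**2)  # rad of material arc


class GeometryError(ValueError):
    """Inclusion/workspace geometry is inconsistent."""


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a two-material phantom.

    Coordinates are continuous millimetres with the origin at the workspace
    lower-left corner.  ``inclusion_center`` is the geometric centre of the
    inclusion primitive (for the horseshoe: the annulus centre, which is not
    the material centroid).
    """

    shape: Shape
    inclusion_area: float  # mm^2, analytic
    inclusion_center: tuple[float, float] = DEFAULT_CENTER
    workspace_extent: tuple[float, float, float, float] = DEFAULT_EXTENT
    stiffness_hard: float = STIFF_HARD_PA  # Pa
    stiffness_soft: float = STIFF_SOFT_PA  # Pa
    inclusion_thickness: float = 0.5  # mm, metadata only

    def __post_init__(self) -> None:
        if self.inclusion_area <= 0:
            raise GeometryError("inclusion_area must be positive")
        if not (self.stiffness_hard > self.stiffness_soft > 0):
            raise GeometryError("require stiffness_hard > stiffness_soft > 0")
        x0, x1, y0, y1 = self.workspace_extent
        if not (x1 > x0 and y1 > y0):
            raise GeometryError("degenerate workspace extent")


@dataclass(frozen=True)
class GridSpec:
    """Square N x N lattice over a rectangular extent.

    Point (i, j) maps to (x0 + i*dx, y0 + j*dy); flat index = i*N + j.
    Spacing is dx = (x_max - x_min)/N exactly, so the lattice covers
    [x0, x0 + (N-1)*dx] — points sit at cell corners, not centres.
    """

    x0: float
    y0: float
    N: int
    dx: float
    dy: float
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @property
    def n_points(self) -> int:
        return self.N * self.N

    def points(self) -> np.ndarray:
        """All lattice points as an (N^2, 2) array in flat-index order."""
        i = np.arange(self.N)
        xs = self.x0 + i * self.dx
        ys = self.y0 + i * self.dy
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def key(self) -> tuple:
        return (self.x0, self.y0, self.N, self.dx, self.dy)


def make_grid(extent: tuple[float, float, float, float], N: int) -> GridSpec:
    """Discretize ``extent = (x_min, x_max, y_min, y_max)`` into an N x N lattice."""
    x_min, x_max, y_min, y_max = extent
    if not (x_max > x_min and y_max > y_min):
        raise GeometryError("invalid extent: zero or negative width/height")
    if N < 2:
        raise ValueError("grid resolution N must be >= 2")
    dx = (x_max - x_min) / N
    dy = (y_max - y_min) / N
    return GridSpec(x0=x_min, y0=y_min, N=N, dx=dx, dy=dy,
                    x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max)


class StiffnessMap:
    """Continuous-coordinate phantom queried for membership and stiffness.

    ``membership(x, y)`` returns 1 inside the hard inclusion (boundary
    inclusive) and 0 in the soft matrix; it is deterministic and vectorized.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self._check_inside_workspace()

    # -- geometry -----------------------------------------------------------

    def membership(self, x, y):
        cx, cy = self.spec.inclusion_center
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.spec.shape == Shape.CIRCLE:
            r = np.sqrt(self.spec.inclusion_area / np.pi)
            inside = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        elif self.spec.shape == Shape.RECTANGLE:
            w, h = self._rect_sides()
            inside = (np.abs(x - cx) <= w / 2) & (np.abs(y - cy) <= h / 2)
        else:  # horseshoe: annular sector, opening toward +x
            rho = np.hypot(x - cx, y - cy)
            phi = np.arctan2(y - cy, x - cx)
            # material occupies |wrap(phi - pi)| <= span/2
            dphi = np.abs((phi - np.pi + np.pi) % (2 * np.pi) - np.pi)
            inside = (rho >= HS_R_IN) & (rho <= HS_R_OUT) & (dphi <= HS_SPAN / 2)
        return inside.astype(int)

    def _rect_sides(self) -> tuple[float, float]:
        # preserve the fixture aspect ratio while honouring the requested area
        scale = np.sqrt(self.spec.inclusion_area / (RECT_W * RECT_H))
        return RECT_W * scale, RECT_H * scale

    def stiffness(self, x, y):
        """Stiffness in Pa at continuous coordinates (vectorized)."""
        m = self.membership(x, y)
        return np.where(m == 1, self.spec.stiffness_hard, self.spec.stiffness_soft)

    @property
    def true_centroid(self) -> tuple[float, float]:
        """Centroid of the hard-material region.

        For the horseshoe this is the area centroid of the annular sector,
        which lies inside the notch (outside the material itself).
        """
        cx, cy = self.spec.inclusion_center
        if self.spec.shape != Shape.HORSESHOE:
            return (cx, cy)
        half = HS_SPAN / 2
        rr = (HS_R_OUT**3 - HS_R_IN**3) / (HS_R_OUT**2 - HS_R_IN**2)
        rho = (2.0 / 3.0) * rr * np.sin(half) / half
        # material is centred on polar angle pi (opening toward +x)
        return (cx - rho, cy)

    @property
    def analytic_area(self) -> float:
        return self.spec.inclusion_area

    def contains(self, x: float, y: float) -> bool:
        x0, x1, y0, y1 = self.spec.workspace_extent
        return x0 <= x <= x1 and y0 <= y <= y1

    def _check_inside_workspace(self) -> None:
        x0, x1, y0, y1 = self.spec.workspace_extent
        cx, cy = self.spec.inclusion_center
        if self.spec.shape == Shape.CIRCLE:
            r = np.sqrt(self.spec.inclusion_area / np.pi)
            ok = (cx - r >= x0 and cx + r <= x1 and cy - r >= y0 and cy + r <= y1)
        elif self.spec.shape == Shape.RECTANGLE:
            w, h = self._rect_sides()
            ok = (cx - w / 2 >= x0 and cx + w / 2 <= x1
                  and cy - h / 2 >= y0 and cy + h / 2 <= y1)
        else:
            ok = (cx - HS_R_OUT >= x0 and cx + HS_R_OUT <= x1
                  and cy - HS_R_OUT >= y0 and cy + HS_R_OUT <= y1)
        if not ok:
            raise GeometryError("inclusion exceeds workspace extent")

    # -- sampling -----------------------------------------------------------

    def sample(self, grid: GridSpec) -> np.ndarray:
        """Stiffness (Pa) sampled on a grid, flat-index order."""
        pts = grid.points()
        return self.stiffness(pts[:, 0], pts[:, 1])

    def membership_grid(self, grid: GridSpec) -> np.ndarray:
        pts = grid.points()
        return self.membership(pts[:, 0], pts[:, 1])


def make_phantom(spec: PhantomSpec) -> StiffnessMap:
    """Build a :class:`StiffnessMap` from a validated spec."""
    return StiffnessMap(spec)


def standard_phantom(shape: Shape | str) -> StiffnessMap:
    """The three benchmark fixtures with printed inclusion areas."""
    shape = Shape(shape)
    if shape == Shape.CIRCLE:
        area = np.pi * CIRCLE_RADIUS**2  # 12.566 ~ printed 12.57
    elif shape == Shape.RECTANGLE:
        area = RECT_W * RECT_H  # 7.790 ~ printed 7.79
    else:
        area = HS_SPAN * (HS_R_OUT**2 - HS_R_IN**2) / 2.0  # exactly 7.88
    return make_phantom(PhantomSpec(shape=shape, inclusion_area=area))


def normalize_map(values: np.ndarray) -> np.ndarray:
    """Normalize grid-sampled stiffness: subtract the mean, divide by the
    maximal peak-to-peak variation.

    A constant field (zero peak-to-peak) is returned as all zeros with a
    warning — there is nothing to scale.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty field")
    centered = values - values.mean()
    ptp = np.ptp(values)
    if ptp == 0:
        warnings.warn("constant stiffness field: normalized to all zeros",
                      stacklevel=2)
        return np.zeros_like(values)
    return centered / ptp
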