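"""Contact mechanics and the virtual tactile sensor.

The probe tip is spherical, so small-deflection contact follows Hertz
theory, ``F = M * d**1.5`` with a composite parameter ``M`` built from the
paired radii and elastic constants.  The deployed sensor carries a 400-um
PDMS membrane whose force/deflection response was calibrated piecewise: a
Hertz branch up to d = 1.85e-4 m and a double-Gaussian exponential branch
beyond it (coefficients used as printed by the calibration fit).

The virtual sensor converts local phantom stiffness into a residual film
thickness: pressing on the hard inclusion compresses the film to ~100 um,
on the soft matrix to ~300 um, out of the 400-um rest thickness.  A reading
is classed hard (y = 1) when the residual thickness is at or below the
calibrated threshold d_t = 150 um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import StiffnessMap

FILM_THICKNESS_UM = 400.0
DEFAULT_DT_UM = 150.0  # calibrated residual-thickness threshold

# Residual film thickness of the sensor fixture (um): hard inclusions
# compress the film well below d_t, the soft matrix well above it.
THICK_HARD_UM = 100.0
THICK_SOFT_UM = 300.0

# Calibrated 400-um-film force law (SI units, d in metres).
HERTZ_M = 11_751.422
BREAKPOINT_M = 1.85e-4
_G1_A, _G1_C, _G1_W = 0.3622, 4.361e-4, 4.186e-5
_G2_A, _G2_C, _G2_W = 0.3113, 4.651e-4, 1.814e-4


class OutOfBoundsError(ValueError):
    """Probed point lies outside the workspace."""


@dataclass(frozen=True)
class ContactParams:
    """Hertzian pairing of the probe (1), PDMS membrane (2) and tube (3)."""

    r1: float  # m
    r2: float  # m
    nu1: float
    nu2: float
    nu3: float
    E1: float  # Pa
    E2: float
    E3: float

    def __post_init__(self) -> None:
        for E in (self.E1, self.E2, self.E3):
            if E <= 0:
                raise ValueError("Young's moduli must be positive")
        for nu in (self.nu1, self.nu2, self.nu3):
            if not (0 <= nu < 0.5):
                raise ValueError("Poisson ratios must lie in [0, 0.5)")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("radii must be positive")

    @property
    def h(self) -> tuple[float, float, float]:
        """Compliance terms h_i = (1 - nu_i^2) / E_i, in 1/Pa."""
        return ((1 - self.nu1**2) / self.E1,
                (1 - self.nu2**2) / self.E2,
                (1 - self.nu3**2) / self.E3)

    @property
    def Re(self) -> float:
        """Equivalent radius r1*r2/(r1+r2), in m."""
        return self.r1 * self.r2 / (self.r1 + self.r2)


def composite_modulus(params: ContactParams) -> float:
    """Composite Hertz parameter M = (4/3) * [h1+h2+h3]^-1 * sqrt(Re)."""
    h1, h2, h3 = params.h
    return (4.0 / 3.0) / (h1 + h2 + h3) * np.sqrt(params.Re)


def hertz_force(d, M: float):
    """Hertz contact force F = M * d**(3/2) for deflection d (m)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("deflection must be non-negative")
    if M <= 0:
        raise ValueError("composite parameter M must be positive")
    out = M * d**1.5
    return float(out) if out.ndim == 0 else out


def calibrated_force(d):
    """Calibrated 400-um-film contact force (N) for deflection d (m).

    Piecewise, exactly as fitted: the Hertz branch below the 1.85e-4-m
    breakpoint and a two-term Gaussian-exponential branch above it.  The
    exponential branch is a fit to loading data and turns over beyond its
    Gaussian centres (~4.6e-4 m), outside the calibrated loading range.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("deflection must be non-negative")
    hertz = HERTZ_M * d**1.5
    expo = (_G1_A * np.exp(-(((d - _G1_C) / _G1_W) ** 2))
            + _G2_A * np.exp(-(((d - _G2_C) / _G2_W) ** 2)))
    out = np.where(d <= BREAKPOINT_M, hertz, expo)
    return float(out) if out.ndim == 0 else out


def monotonicity_violations(lo: float = 0.0, hi: float = 5.0e-4,
                            step: float = 1.0e-6) -> np.ndarray:
    """Deflections (m) where the calibrated force law locally decreases.

    Scans ``[lo, hi]`` at ``step`` resolution and returns the left endpoint
    of every decreasing interval.  Used to flag the turnover of the fitted
    exponential branch past its Gaussian centres.
    """
    d = np.arange(lo, hi + step / 2, step)
    f = calibrated_force(d)
    bad = np.diff(f) < 0
    return d[:-1][bad]


@dataclass(frozen=True)
class DeflectionReading:
    """One palpation sample: where, how compressed, and the hardness class."""

    location: tuple[float, float]  # mm
    film_thickness: float  # um, residual under preload
    deflection: float  # um, 400 - residual
    estimated_force: float  # N, via the calibrated force law
    hardness_class: int  # {0, 1}


def classify(film_thickness_um: float, d_t: float = DEFAULT_DT_UM) -> int:
    """Binary hardness: 1 iff residual thickness <= d_t (more compressed
    means harder).  The tie at exactly d_t classifies as hard."""
    return int(film_thickness_um <= d_t)


def sense(stiff_map: StiffnessMap, point: tuple[float, float],
          noise_sd: float = 0.0, rng: np.random.Generator | int | None = None,
          d_t: float = DEFAULT_DT_UM) -> DeflectionReading:
    """Simulate one palpation reading at ``point`` (mm).

    The residual film thickness is the fixture value for the local material
    (100 um hard / 300 um soft) plus optional Gaussian noise (sd in um),
    truncated to [0, 400] um.  Deterministic for a fixed rng/seed.
    """
    x, y = point
    if not stiff_map.contains(x, y):
        raise OutOfBoundsError(f"point {point} outside workspace")
    member = int(stiff_map.membership(x, y))
    thickness = THICK_HARD_UM if member == 1 else THICK_SOFT_UM
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        thickness = float(np.clip(thickness + gen.normal(0.0, noise_sd),
                                  0.0, FILM_THICKNESS_UM))
    deflection = FILM_THICKNESS_UM - thickness
    force = calibrated_force(deflection * 1e-6)
    return DeflectionReading(location=(float(x), float(y)),
                             film_thickness=thickness,
                             deflection=deflection,
                             estimated_force=force,
                             hardness_class=classify(thickness, d_t))
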