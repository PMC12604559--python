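"""Sliding-scan boundary segmentation of the inclusion.

The sensor slides outward from the estimated centroid along a fan of
equally spaced rays, acquiring a single reading per position.  Crossing a
material boundary produces a spike in the signal derivative: negative on a
soft-to-hard entry (the film suddenly compresses) and positive on a
hard-to-soft exit.  The simulator models each transition as a logistic
ramp of ~3-sample width centred on the exact geometric crossing, so the
derivative pulse peaks at the boundary; detection then thresholds the
per-sample signal change and localizes each pulse to sub-sample accuracy
by parabolic interpolation of the derivative peak.

Boundary points are gathered per ray (first exit for rays starting inside
the material; entry/exit pairs for rays starting outside, as happens from
the horseshoe's notch), ordered by angle, and interpolated into a closed
contour — a raw polygon or a periodic cubic spline in polar form — whose
shoelace area yields the area error and the precision 1 - |dA| / A_true.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon

from .contact import THICK_HARD_UM, THICK_SOFT_UM
from .phantom import StiffnessMap

DEFAULT_STEP_MM = 0.02
# Per-step signal-change threshold (um). The hard/soft plateau contrast is
# 200 um spread over a ~3-step ramp, giving peak per-step changes of ~50 um;
# a flat noiseless baseline has zero step-to-step variation.
DEFAULT_DELTA_I = 10.0
RAMP_WIDTH_FACTOR = 0.75  # logistic scale, in units of the ray step


@dataclass
class RaySignal:
    origin: tuple[float, float]  # mm
    angle: float  # rad
    step: float  # mm
    s: np.ndarray  # arc positions from 0, strictly increasing
    intensity: np.ndarray  # dimensionless reading per position

    def positions(self) -> np.ndarray:
        u = np.array([np.cos(self.angle), np.sin(self.angle)])
        return np.asarray(self.origin) + self.s[:, None] * u


@dataclass(frozen=True)
class PulseEvent:
    position: tuple[float, float]  # mm
    s: float  # arc length along the ray, mm
    polarity: int  # -1 entry (soft->hard), +1 exit (hard->soft)


@dataclass
class BoundaryPointSet:
    centroid: tuple[float, float]
    angles: np.ndarray
    outer_points: list[tuple[float, np.ndarray]]  # (angle, point)
    inner_points: list[tuple[float, np.ndarray]]
    events: list[list[PulseEvent]]  # per ray


@dataclass
class ShapeEstimate:
    contour: np.ndarray  # outer closed contour vertices
    inner_contour: np.ndarray | None
    area: float  # mm^2 (outer - inner when both exist)
    area_error: float  # mm^2, estimated - true
    precision: float  # 1 - |area_error| / true_area
    mode: str
    fell_back: bool = False


def _arc_to_boundary(stiff_map: StiffnessMap, origin, angle: float) -> float:
    """Arc length from origin to the workspace boundary along ``angle``."""
    x0, x1, y0, y1 = stiff_map.spec.workspace_extent
    ox, oy = origin
    u = (np.cos(angle), np.sin(angle))
    t = np.inf
    for o, d, lo, hi in ((ox, u[0], x0, x1), (oy, u[1], y0, y1)):
        if abs(d) > 1e-12:
            for bound in (lo, hi):
                tt = (bound - o) / d
                if tt > 0:
                    t = min(t, tt)
    return t


def _bisect_crossing(stiff_map: StiffnessMap, origin, angle: float,
                     s_lo: float, s_hi: float, tol: float = 1e-7) -> float:
    """Locate the membership transition in (s_lo, s_hi] by bisection."""
    ox, oy = origin
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    m_lo = int(stiff_map.membership(ox + s_lo * cos_a, oy + s_lo * sin_a))
    while s_hi - s_lo > tol:
        mid = 0.5 * (s_lo + s_hi)
        m = int(stiff_map.membership(ox + mid * cos_a, oy + mid * sin_a))
        if m == m_lo:
            s_lo = mid
        else:
            s_hi = mid
    return 0.5 * (s_lo + s_hi)


def simulate_ray(stiff_map: StiffnessMap, origin: tuple[float, float],
                 angle: float, step: float = DEFAULT_STEP_MM,
                 noise_sd: float = 0.0,
                 rng: np.random.Generator | int | None = None) -> RaySignal:
    """Simulate the sliding-scan signal along one outward ray.

    The baseline is the residual film thickness of the local material;
    each boundary crossing contributes a logistic ramp centred on the exact
    crossing arc, whose derivative is the polarity pulse used downstream.
    """
    ox, oy = origin
    if not stiff_map.contains(ox, oy):
        raise ValueError(f"ray origin {origin} outside workspace")
    if step <= 0:
        raise ValueError("step must be positive")
    s_max = _arc_to_boundary(stiff_map, origin, angle)
    s = np.arange(0.0, s_max + step / 2, step)
    s = s[s <= s_max]
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    member = stiff_map.membership(ox + s * cos_a, oy + s * sin_a)

    def level(m):  # residual thickness per material
        return THICK_HARD_UM if m else THICK_SOFT_UM

    intensity = np.full_like(s, level(member[0]), dtype=float)
    w = RAMP_WIDTH_FACTOR * step
    changes = np.nonzero(np.diff(member) != 0)[0]
    for k in changes:
        s_c = _bisect_crossing(stiff_map, origin, angle, s[k], s[k + 1])
        delta = level(member[k + 1]) - level(member[k])
        intensity += delta / (1.0 + np.exp(-(s - s_c) / w))
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        intensity = intensity + gen.normal(0.0, noise_sd, size=len(s))
    return RaySignal(origin=(float(ox), float(oy)), angle=float(angle),
                     step=float(step), s=s, intensity=intensity)


def detect_events(signal: RaySignal,
                  delta_i_threshold: float = DEFAULT_DELTA_I) -> list[PulseEvent]:
    """Detect boundary pulses from per-sample signal changes.

    Consecutive samples whose change magnitude exceeds the threshold are
    grouped into same-sign runs; each run yields one event at the parabola
    vertex of its derivative peak (sub-sample localization).  All crossings
    are reported, so non-convex shapes produce multiple events per ray.
    """
    if len(signal.s) < 3:
        raise ValueError("signal must have at least 3 samples")
    d = np.diff(signal.intensity)
    mid = 0.5 * (signal.s[:-1] + signal.s[1:])
    hot = np.abs(d) > delta_i_threshold
    events: list[PulseEvent] = []
    u = np.array([np.cos(signal.angle), np.sin(signal.angle)])
    k = 0
    while k < len(d):
        if not hot[k]:
            k += 1
            continue
        sign = np.sign(d[k])
        j = k
        while j + 1 < len(d) and hot[j + 1] and np.sign(d[j + 1]) == sign:
            j += 1
        run = np.arange(k, j + 1)
        peak = run[np.argmax(np.abs(d[run]))]
        s_ev = mid[peak]
        if 0 < peak < len(d) - 1:
            y0, y1, y2 = np.abs(d[peak - 1: peak + 2])
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                offset = 0.5 * (y0 - y2) / denom
                s_ev = mid[peak] + np.clip(offset, -1.0, 1.0) * signal.step
        pos = np.asarray(signal.origin) + s_ev * u
        events.append(PulseEvent(position=(float(pos[0]), float(pos[1])),
                                 s=float(s_ev), polarity=int(sign)))
        k = j + 1
    return events


def segment(stiff_map: StiffnessMap, centroid: tuple[float, float],
            n_rays: int = 16, step: float = DEFAULT_STEP_MM,
            delta_i_threshold: float = DEFAULT_DELTA_I,
            phase: float = 0.0, noise_sd: float = 0.0,
            rng: np.random.Generator | int | None = None,
            diametric: bool = False) -> BoundaryPointSet:
    """Cast ``n_rays`` equally spaced rays from the centroid and collect
    boundary points.

    Rays starting inside the material keep their first exit event; rays
    starting outside it (e.g. from the horseshoe notch) keep the first
    entry/exit pair, feeding the inner and outer contours respectively.
    With ``diametric=True`` each direction is scanned as a full chord of
    the workspace through the centroid instead of an outward half-ray.
    """
    cx, cy = centroid
    if not stiff_map.contains(cx, cy):
        raise ValueError("centroid outside workspace")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    outer, inner, per_ray = [], [], []

    def _rel_angle(pos) -> float:
        return float(np.mod(np.arctan2(pos[1] - cy, pos[0] - cx), 2 * np.pi))

    if diametric:
        # n_rays//2 full chords through the centroid; entry and exit of each
        # chord are both outer-boundary points.
        n_lines = max(n_rays // 2, 1)
        angles = phase + np.pi * np.arange(n_lines) / n_lines
        for theta in angles:
            back = _arc_to_boundary(stiff_map, centroid, theta + np.pi)
            origin = (cx + (back - 1e-9) * np.cos(theta + np.pi),
                      cy + (back - 1e-9) * np.sin(theta + np.pi))
            sig = simulate_ray(stiff_map, origin, theta, step=step,
                               noise_sd=noise_sd, rng=gen)
            events = detect_events(sig, delta_i_threshold)
            per_ray.append(events)
            if not events:
                warnings.warn(f"chord at {theta:.3f} rad detected no boundary",
                              stacklevel=2)
                continue
            entries = [e for e in events if e.polarity < 0]
            exits = [e for e in events if e.polarity > 0]
            if entries:
                p = np.asarray(entries[0].position)
                outer.append((_rel_angle(p), p))
            if exits:
                p = np.asarray(exits[-1].position)
                outer.append((_rel_angle(p), p))
    else:
        angles = phase + 2.0 * np.pi * np.arange(n_rays) / n_rays
        for theta in angles:
            sig = simulate_ray(stiff_map, centroid, theta, step=step,
                               noise_sd=noise_sd, rng=gen)
            events = detect_events(sig, delta_i_threshold)
            per_ray.append(events)
            if not events:
                warnings.warn(f"ray at {theta:.3f} rad detected no boundary",
                              stacklevel=2)
                continue
            origin_inside = bool(stiff_map.membership(cx, cy))
            if origin_inside:
                exits = [e for e in events if e.polarity > 0]
                if exits:
                    outer.append((theta, np.asarray(exits[0].position)))
            else:
                entries = [e for e in events if e.polarity < 0]
                if entries:
                    entry = entries[0]
                    inner.append((theta, np.asarray(entry.position)))
                    exits = [e for e in events
                             if e.polarity > 0 and e.s > entry.s]
                    if exits:
                        outer.append((theta, np.asarray(exits[0].position)))
    return BoundaryPointSet(centroid=(float(cx), float(cy)), angles=angles,
                            outer_points=outer, inner_points=inner,
                            events=per_ray)


def _closed_contour(points: np.ndarray, origin, mode: str) -> tuple[np.ndarray, bool]:
    """Angle-order ``points`` around ``origin`` and close them.

    Returns (vertices, fell_back).  Spline mode fits a periodic cubic
    spline to r(theta) and densifies to 720 vertices; an invalid
    (self-intersecting) spline contour falls back to the raw polygon.
    """
    rel = points - np.asarray(origin)
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    r = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(theta, kind="stable")
    theta, r = theta[order], r[order]
    poly = points[order]
    if mode == "polygon":
        return poly, False
    if mode != "spline":
        raise ValueError(f"unknown reconstruction mode {mode!r}")
    # merge duplicate angles (diametric scans can revisit a direction)
    keep = np.concatenate([[True], np.diff(theta) > 1e-9])
    theta, r = theta[keep], r[keep]
    if len(theta) < 3:
        return poly, True
    th_ext = np.append(theta, theta[0] + 2 * np.pi)
    r_ext = np.append(r, r[0])
    spline = CubicSpline(th_ext, r_ext, bc_type="periodic")
    th_dense = np.linspace(th_ext[0], th_ext[-1], 721)[:-1]
    r_dense = spline(th_dense)
    verts = np.asarray(origin) + np.column_stack(
        [r_dense * np.cos(th_dense), r_dense * np.sin(th_dense)])
    if not Polygon(verts).is_valid:
        warnings.warn("self-intersecting spline contour: falling back to polygon",
                      stacklevel=2)
        return poly, True
    return verts, False


def reconstruct(points: BoundaryPointSet, mode: str = "spline",
                true_area: float | None = None) -> ShapeEstimate:
    """Interpolate boundary points into a closed contour and score its area.

    The estimated material area is the outer-contour area minus the
    inner-contour area when an inner boundary was detected (horseshoe);
    simple shapes use the outer contour alone.
    """
    outer = np.array([p for _, p in points.outer_points])
    if len(outer) < 3:
        raise ValueError("need at least 3 boundary points to reconstruct")
    contour, fb_outer = _closed_contour(outer, points.centroid, mode)
    area = Polygon(contour).area
    inner_contour = None
    fb = fb_outer
    if len(points.inner_points) >= 3:
        inner = np.array([p for _, p in points.inner_points])
        inner_contour, fb_inner = _closed_contour(inner, points.centroid, mode)
        area -= Polygon(inner_contour).area
        fb = fb or fb_inner
    if true_area is None:
        err, prec = float("nan"), float("nan")
    else:
        err = area - true_area
        prec = 1.0 - abs(err) / true_area
    return ShapeEstimate(contour=contour, inner_contour=inner_contour,
                         area=float(area), area_error=float(err),
                         precision=float(prec), mode=mode, fell_back=fb)


def segmentation_benchmark(stiff_maps: dict[str, StiffnessMap],
                           n_rays_list=(4, 8, 12, 16), mode: str = "spline",
                           step: float = DEFAULT_STEP_MM,
                           centroids: dict[str, tuple[float, float]] | None = None,
                           phase: float = 0.0) -> pd.DataFrame:
    """Estimated area, error and precision per (shape, ray count).

    Uses true material centroids unless ``centroids`` supplies estimates
    (e.g. from the active search stage).
    """
    rows = []
    for shape, stiff_map in stiff_maps.items():
        cen = (centroids or {}).get(shape, stiff_map.true_centroid)
        for n_rays in n_rays_list:
            bps = segment(stiff_map, cen, n_rays=n_rays, step=step, phase=phase)
            est = reconstruct(bps, mode=mode, true_area=stiff_map.analytic_area)
            rows.append({"shape": shape, "n_rays": n_rays, "mode": mode,
                         "centroid_x": cen[0], "centroid_y": cen[1],
                         "true_area": stiff_map.analytic_area,
                         "estimated_area": est.area,
                         "area_error": est.area_error,
                         "precision": est.precision})
    return pd.DataFrame(rows)
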