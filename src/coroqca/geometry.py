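"""Vessel geometry: arc length, lumen-area profiles, and the interpolated reference line.

The measured quantity of 3D quantitative coronary angiography (QCA) used here is
the lumen cross-sectional area A(s) as a function of centerline arc length s
(mm, measured from the proximal end).  Lesions are defined against a *reference*
profile R(s): the lumen the vessel would have if it were healthy, obtained by a
robust fit to the non-diseased portions of the vessel.

Conventions
-----------
* lengths in mm, areas in mm²; s increases proximal → distal;
* the reference is fitted as a straight line in the *equivalent diameter*
  domain d(s) = 2·sqrt(A/π) — the standard QCA convention — with iterative
  trimming of below-line (diseased) samples, then mapped back to area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateVesselError,
    InvalidGeometryError,
    ParameterError,
)

__all__ = [
    "Centerline",
    "AreaProfile",
    "ReferenceProfile",
    "CrossSection",
    "ReferenceFitConfig",
    "arc_length",
    "polygon_area",
    "resample_profile",
    "fit_reference_profile",
]

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D vessel centerline with cumulative arc length.

    Attributes
    ----------
    points : (n, 3) array, mm
    s : (n,) cumulative arc length, mm; s[0] = 0, strictly increasing.
    """

    points: np.ndarray
    s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise InvalidGeometryError("centerline needs >= 2 points of shape (n, 3)")
        object.__setattr__(self, "points", pts)
        s = self.s if self.s is not None else arc_length(pts)
        s = np.asarray(s, dtype=float)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if abs(s[0]) > _EPS or np.any(np.abs(np.diff(s) - seg) > _EPS):
            raise InvalidGeometryError("arc length inconsistent with point spacing")
        object.__setattr__(self, "s", s)


@dataclass(frozen=True)
class AreaProfile:
    """Lumen cross-sectional area A(s) of one vessel.

    ``s`` strictly increasing starting at 0 (mm); ``A`` strictly positive (mm²).
    """

    s: np.ndarray
    A: np.ndarray
    vessel_id: str = ""

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if s.ndim != 1 or A.ndim != 1 or len(s) != len(A) or len(s) < 4:
            raise InvalidGeometryError(
                "area profile needs matching 1-D s and A with >= 4 samples",
                vessel_id=self.vessel_id or None,
            )
        if abs(s[0]) > _EPS:
            raise InvalidGeometryError("arc length must start at 0", self.vessel_id or None)
        if np.any(np.diff(s) <= 0):
            raise InvalidGeometryError("arc length must be strictly increasing", self.vessel_id or None)
        if np.any(A <= 0) or not np.all(np.isfinite(A)):
            raise InvalidGeometryError("areas must be finite and > 0", self.vessel_id or None)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "A", A)

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference ("healthy") area R(s) on the same grid as its AreaProfile.

    ``retained`` marks the samples judged healthy by the trimmed fit;
    ``n_iterations`` counts trimming iterations actually performed.
    """

    s: np.ndarray
    R: np.ndarray
    retained: np.ndarray | None = None
    n_iterations: int = 0

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        R = np.asarray(self.R, dtype=float)
        if len(s) != len(R):
            raise InvalidGeometryError("reference grid length mismatch")
        if np.any(R <= 0):
            raise InvalidGeometryError("reference areas must be > 0")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "R", R)


@dataclass(frozen=True)
class CrossSection:
    """Planar lumen contour polygon at arc-length position ``s_position``."""

    vertices: np.ndarray
    s_position: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidGeometryError("cross-section polygon needs >= 3 planar vertices")
        object.__setattr__(self, "vertices", v)
        if v.shape[0] <= 64 and _self_intersects(v):
            raise InvalidGeometryError("cross-section polygon is self-intersecting")


def _self_intersects(v: np.ndarray) -> bool:
    """Pairwise segment-intersection check for small polygons."""
    n = len(v)
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def _ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent segments share a vertex
            p1, p2 = segs[i]
            p3, p4 = segs[j]
            d1, d2 = _ccw(p3, p4, p1), _ccw(p3, p4, p2)
            d3, d4 = _ccw(p1, p2, p3), _ccw(p1, p2, p4)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return True
    return False


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def arc_length(points) -> np.ndarray:
    """Cumulative arc length of an ordered 3D polyline.

    Returns ``s`` with ``s[0] = 0`` and ``s[-1]`` equal to the polyline length.
    Raises :class:`InvalidGeometryError` on fewer than 2 points or duplicated
    consecutive points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidGeometryError("arc_length needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= _EPS):
        raise InvalidGeometryError("duplicated consecutive centerline points")
    return np.concatenate([[0.0], np.cumsum(seg)])


def polygon_area(section: CrossSection) -> float:
    """Area (mm²) of a lumen contour polygon; orientation-independent (shoelace)."""
    v = section.vertices
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed))


def resample_profile(profile: AreaProfile, step: float) -> AreaProfile:
    """Resample an area profile onto a uniform grid of spacing ``step`` mm.

    The last interval may be shorter so that both endpoints are preserved
    exactly.  Values come from monotone-preserving piecewise-cubic (PCHIP)
    interpolation, which reproduces linear segments exactly and does not
    overshoot local extrema.  A profile already on the requested uniform grid
    is returned unchanged.
    """
    if not np.isfinite(step) or step <= 0:
        raise ParameterError(f"resampling step must be > 0, got {step}")
    s0, s1 = float(profile.s[0]), float(profile.s[-1])
    if step >= s1 - s0:
        raise ParameterError("resampling step must be smaller than the profile length")
    d = np.diff(profile.s)
    if np.allclose(d, step, rtol=0, atol=1e-12):
        return profile
    grid = np.arange(s0, s1, step)
    if s1 - grid[-1] > 1e-12:
        grid = np.concatenate([grid, [s1]])
    else:
        grid[-1] = s1
    from scipy.interpolate import PchipInterpolator

    A = PchipInterpolator(profile.s, profile.A)(grid)
    A[0], A[-1] = profile.A[0], profile.A[-1]
    return AreaProfile(s=grid, A=A, vessel_id=profile.vessel_id)


@dataclass(frozen=True)
class ReferenceFitConfig:
    """Settings for the trimmed reference-line fit.

    trim_threshold
        samples with residual below ``-trim_threshold * sigma`` (sigma from the
        MAD of the retained residuals) are treated as diseased and excluded.
    min_healthy_fraction
        abort with :class:`DegenerateVesselError` when fewer samples remain.
    """

    max_iterations: int = 20
    trim_threshold: float = 3.0
    min_healthy_fraction: float = 0.25
    min_samples: int = 20
    init_end_fraction: float = 0.2  # fraction of vessel length at each end used to seed the fit


def fit_reference_profile(
    profile: AreaProfile, config: ReferenceFitConfig | None = None
) -> ReferenceProfile:
    """Fit the interpolated reference ("healthy") lumen line of one vessel.

    Fits equivalent diameter d(s) = 2·sqrt(A/π) with a straight line in s by
    iteratively trimmed least squares.  The fit is seeded from the proximal
    and distal end segments of the vessel (the healthy portions a reference
    line interpolates across the lesion), then refined: discard samples whose
    residual falls below −trim_threshold·sigma (sigma is a MAD-based scale
    taken from the positive residual side, since diseased samples lie *below*
    the healthy line), refit least-squares on the retained set, and repeat
    until the retained set is stable (at most ``max_iterations`` passes,
    re-entry allowed).  The fitted line is mapped back to area, R = π(d/2)².

    Raises
    ------
    DegenerateVesselError
        if fewer than ``min_healthy_fraction`` of samples remain, or the fitted
        line implies a non-positive lumen anywhere on the vessel.
    """
    cfg = config or ReferenceFitConfig()
    s, A = profile.s, profile.A
    if len(s) < cfg.min_samples:
        raise InvalidGeometryError(
            f"reference fit needs >= {cfg.min_samples} samples, got {len(s)}",
            profile.vessel_id or None,
        )
    d = 2.0 * np.sqrt(A / np.pi)
    # Seed from the vessel ends: the reference interpolates across the lesion
    # from the flanking (presumed healthy) segments.  Starting from an
    # all-samples fit instead would be dominated by a long lesion and the
    # trimming could fail to bootstrap.
    span = s[-1] - s[0]
    ends = (s <= s[0] + cfg.init_end_fraction * span) | (
        s >= s[-1] - cfg.init_end_fraction * span
    )
    coef = np.polyfit(s[ends], d[ends], 1)
    retained = np.ones(len(s), dtype=bool)
    n_iter = 0
    min_retained = max(2, int(np.ceil(cfg.min_healthy_fraction * len(s))))
    for _ in range(cfg.max_iterations):
        resid = d - np.polyval(coef, s)
        # Scale from the POSITIVE residual side only: diseased samples lie
        # below the line, so the upper side is healthy-dominated and the
        # estimate is not shrunk by the lower-side censoring the trimming
        # itself introduces.  The threshold (default 3 sigma) clears the
        # healthy measurement noise; a tighter threshold would let each refit
        # drift upward and cascade trimming into the healthy cloud.
        pos = resid[resid > _EPS]
        sigma = 1.4826 * float(np.median(pos)) if len(pos) >= 5 else 0.0
        if sigma <= _EPS:
            new = resid >= -_EPS
        else:
            new = resid >= -cfg.trim_threshold * sigma
        if new.sum() < min_retained:
            raise DegenerateVesselError(
                f"reference fit retained only {int(new.sum())}/{len(s)} samples "
                f"(< {cfg.min_healthy_fraction:.0%}); vessel looks diffusely diseased",
                profile.vessel_id or None,
            )
        coef = np.polyfit(s[new], d[new], 1)
        if np.array_equal(new, retained):
            break
        retained = new
        n_iter += 1
    d_fit = np.polyval(coef, s)
    if np.any(d_fit <= 0):
        raise DegenerateVesselError(
            "fitted reference diameter non-positive on the vessel",
            profile.vessel_id or None,
        )
    R = np.pi * (d_fit / 2.0) ** 2
    return ReferenceProfile(s=s, R=R, retained=retained, n_iterations=n_iter)
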