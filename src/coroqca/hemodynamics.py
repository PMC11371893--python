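"""Functional lesion descriptors from a vessel pressure-ratio (vFFR) profile.

vFFR is the angiography-derived computational estimate of fractional flow
reserve: the ratio of local to aortic pressure along the vessel, 1.0 at the
proximal end and decreasing with cumulative pressure loss.  This module never
computes pressure physics — profiles are inputs (measured, or produced by the
synthetic surrogate in :mod:`coroqca.cohort`).  It reads two scalars off a
profile:

* distal vFFR: the value at the distal end of the vessel;
* ΔvFFR: the translesional gradient, v(s_prox) − v(s_dist) at the detected
  lesion edges (linear interpolation between samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidGeometryError
from .lesion import LesionSegment

__all__ = ["VFFRProfile", "TranslesionalMetrics", "delta_vffr", "distal_vffr"]

_TOL = 1e-9


@dataclass(frozen=True)
class VFFRProfile:
    """Pressure-ratio samples v(s) along one vessel.

    All values in (0, 1]; the proximal value must be within 0.02 of 1.0
    (profiles are normalised to the aortic pressure at the vessel inlet).
    """

    s: np.ndarray
    v: np.ndarray
    vessel_id: str = ""

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        v = np.asarray(self.v, dtype=float)
        vid = self.vessel_id or None
        if s.ndim != 1 or len(s) != len(v) or len(s) < 2:
            raise InvalidGeometryError("vFFR profile needs matching s and v, >= 2 samples", vid)
        if np.any(np.diff(s) <= 0):
            raise InvalidGeometryError("vFFR arc length must be strictly increasing", vid)
        if np.any(v <= 0) or np.any(v > 1 + _TOL):
            raise InvalidGeometryError("vFFR values must lie in (0, 1]", vid)
        if abs(v[0] - 1.0) > 0.02:
            raise InvalidGeometryError(
                f"proximal vFFR {v[0]:.3f} not within 0.02 of 1.0 (profile not normalised?)", vid
            )
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "v", np.minimum(v, 1.0))


@dataclass(frozen=True)
class TranslesionalMetrics:
    """Distal vFFR and translesional gradient of one vessel."""

    vffr_distal: float
    delta_vffr: float


def delta_vffr(profile: VFFRProfile, segment: LesionSegment) -> float:
    """Translesional vFFR gradient: v(s_prox) − v(s_dist) at the lesion edges.

    Values are read by linear interpolation.  For a physiological
    (nonincreasing) profile the result is ≥ 0; a noisy profile may yield a
    negative gradient, which is returned as-is with a warning.
    """
    lo, hi = profile.s[0] - _TOL, profile.s[-1] + _TOL
    if not (lo <= segment.s_prox <= hi and lo <= segment.s_dist <= hi):
        raise AlignmentError(
            f"lesion edges [{segment.s_prox:.2f}, {segment.s_dist:.2f}] mm outside "
            f"the vFFR profile range [{profile.s[0]:.2f}, {profile.s[-1]:.2f}] mm",
            profile.vessel_id or None,
        )
    v_prox = float(np.interp(segment.s_prox, profile.s, profile.v))
    v_dist = float(np.interp(segment.s_dist, profile.s, profile.v))
    dv = v_prox - v_dist
    if dv < -_TOL:
        warnings.warn(
            f"negative translesional gradient ({dv:.4g}) — non-monotone vFFR profile"
            + (f" for vessel {profile.vessel_id}" if profile.vessel_id else ""),
            stacklevel=2,
        )
    return dv


def distal_vffr(profile: VFFRProfile) -> float:
    """vFFR at the distal segment of the vessel (last sample of the profile)."""
    return float(profile.v[-1])
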