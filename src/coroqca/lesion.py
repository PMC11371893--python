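"""Lesion detection on measured-vs-reference area profiles and its scalar metrics.

A lesion is the segment containing the minimum lumen area (MLA), delimited
proximally and distally by the two *edges* where the measured area function
crosses the interpolated reference line.  From the segment:

* MLR  = MLA / PROXA (minimum lumen ratio; low = sharp proximal narrowing)
* LSL  = s_dist − s_prox (lesion segment length, mm)
* PLSL = s_mla − s_prox (proximal lesion segment length, mm)
* LLR  = PLSL / LSL
* %AS  = (1 − MLA / R(s_mla)) · 100 (percent area stenosis vs the reference)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InvalidSegmentError, OstialLesionError
from .geometry import (
    AreaProfile,
    ReferenceFitConfig,
    ReferenceProfile,
    fit_reference_profile,
    resample_profile,
)

__all__ = [
    "LesionSegment",
    "LesionMetrics",
    "QuantifyConfig",
    "detect_lesion",
    "detect_all_lesions",
    "compute_metrics",
    "quantify_vessel",
]

_CROSS_TOL = 1e-9  # |A - R| below this counts as a crossing (grazing contact)


@dataclass(frozen=True)
class LesionSegment:
    """Detected lesion: edge/MLA locations (mm) and the areas there (mm²)."""

    s_prox: float
    s_mla: float
    s_dist: float
    PROXA: float
    MLA: float
    DISTA: float

    def __post_init__(self):
        if not (self.s_prox < self.s_mla < self.s_dist):
            raise InvalidSegmentError(
                f"edge ordering violated: {self.s_prox}, {self.s_mla}, {self.s_dist}"
            )
        if min(self.PROXA, self.MLA, self.DISTA) <= 0:
            raise InvalidSegmentError("lesion areas must be > 0")
        if self.MLA > self.PROXA + _CROSS_TOL or self.MLA > self.DISTA + _CROSS_TOL:
            raise InvalidSegmentError("MLA must not exceed the edge areas")


@dataclass(frozen=True)
class LesionMetrics:
    """Scalar anatomical descriptors of one lesion."""

    MLR: float
    LSL: float
    PLSL: float
    LLR: float
    percent_area_stenosis: float | None = None
    segment: LesionSegment = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not (0 < self.MLR <= 1):
            raise InvalidSegmentError(f"MLR out of (0, 1]: {self.MLR}")
        if not (0 < self.PLSL < self.LSL):
            raise InvalidSegmentError("need 0 < PLSL < LSL")
        if not (0 < self.LLR < 1):
            raise InvalidSegmentError("LLR out of (0, 1)")
        if self.percent_area_stenosis is not None and not (
            0 <= self.percent_area_stenosis < 100
        ):
            raise InvalidSegmentError("percent area stenosis out of [0, 100)")


def _interp(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    return float(np.interp(x, xs, ys))


def _crossing(
    s: np.ndarray, diff: np.ndarray, i_out: int, i_in: int
) -> float:
    """Arc length where diff = A − R crosses zero between grid samples.

    ``i_out`` is the sample at/above the reference, ``i_in`` the first below.
    A sample within the crossing tolerance of zero *is* the crossing.
    """
    if abs(diff[i_out]) < _CROSS_TOL:
        return float(s[i_out])
    t = diff[i_out] / (diff[i_out] - diff[i_in])
    return float(s[i_out] + t * (s[i_in] - s[i_out]))


def _segment_from_run(
    profile: AreaProfile, reference: ReferenceProfile, lo: int, hi: int, i_mla: int
) -> LesionSegment:
    """Build a LesionSegment from a below-reference run [lo, hi] (inclusive)."""
    s, A, R = profile.s, profile.A, reference.R
    diff = A - R
    vid = profile.vessel_id or None
    if lo == 0:
        raise OstialLesionError(
            "lesion reaches the proximal end of the vessel; no proximal "
            "reference crossing (ostial/truncated lesion excluded)", vid,
        )
    if hi == len(s) - 1:
        raise OstialLesionError(
            "lesion reaches the distal end of the vessel; no distal "
            "reference crossing (truncated lesion excluded)", vid,
        )
    s_prox = _crossing(s, diff, lo - 1, lo)
    s_dist = _crossing(s, diff, hi + 1, hi)
    return LesionSegment(
        s_prox=s_prox,
        s_mla=float(s[i_mla]),
        s_dist=s_dist,
        PROXA=_interp(s_prox, s, A),
        MLA=float(A[i_mla]),
        DISTA=_interp(s_dist, s, A),
    )


def _below_runs(diff: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive samples with diff < −tol, as (lo, hi) inclusive."""
    below = diff < -_CROSS_TOL
    if not below.any():
        return []
    idx = np.flatnonzero(below)
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_lesion(
    profile: AreaProfile, reference: ReferenceProfile
) -> LesionSegment | None:
    """Detect the lesion containing the global minimum lumen area.

    Returns ``None`` when the measured area never falls below the reference
    (no lesion).  The MLA is the global minimum of A over all below-reference
    samples (ties broken toward the most proximal sample); the edges are the
    linearly interpolated crossings of A and R nearest the MLA on each side.

    Raises
    ------
    OstialLesionError
        when the MLA's below-reference run touches an end of the vessel, i.e.
        a crossing is missing on that side.
    AlignmentError
        when profile and reference are not on the same grid.
    """
    if len(profile.s) != len(reference.s) or np.any(
        np.abs(profile.s - reference.s) > _CROSS_TOL
    ):
        raise AlignmentError(
            "profile and reference must share one arc-length grid",
            profile.vessel_id or None,
        )
    diff = profile.A - reference.R
    runs = _below_runs(diff)
    if not runs:
        return None
    below_idx = np.concatenate([np.arange(lo, hi + 1) for lo, hi in runs])
    i_mla = int(below_idx[np.argmin(profile.A[below_idx])])  # argmin: first = most proximal
    lo, hi = next((lo, hi) for lo, hi in runs if lo <= i_mla <= hi)
    return _segment_from_run(profile, reference, lo, hi, i_mla)


def detect_all_lesions(
    profile: AreaProfile, reference: ReferenceProfile
) -> list[LesionSegment]:
    """Every below-reference run as a lesion segment (exploratory mode).

    Runs touching a vessel end are skipped (they have no crossing on one side)
    rather than raising, since this mode enumerates candidates.
    """
    diff = profile.A - reference.R
    out: list[LesionSegment] = []
    for lo, hi in _below_runs(diff):
        if lo == 0 or hi == len(profile.s) - 1:
            continue
        seg_idx = np.arange(lo, hi + 1)
        i_mla = int(seg_idx[np.argmin(profile.A[seg_idx])])
        out.append(_segment_from_run(profile, reference, lo, hi, i_mla))
    return out


def compute_metrics(
    segment: LesionSegment, reference: ReferenceProfile
) -> LesionMetrics:
    """Scalar metrics of a detected lesion.

    MLR = MLA/PROXA, LSL = s_dist − s_prox, PLSL = s_mla − s_prox,
    LLR = PLSL/LSL, %AS = (1 − MLA/R(s_mla))·100 with R evaluated at the MLA
    section (the reference, not PROXA: a PROXA-based stenosis would equal
    1 − MLR and carry no extra information).
    """
    if segment.PROXA <= 0:
        raise InvalidSegmentError("PROXA must be > 0")
    LSL = segment.s_dist - segment.s_prox
    if LSL <= 0:
        raise InvalidSegmentError("LSL must be > 0")
    PLSL = segment.s_mla - segment.s_prox
    R_mla = _interp(segment.s_mla, reference.s, reference.R)
    pct = (1.0 - segment.MLA / R_mla) * 100.0
    return LesionMetrics(
        MLR=min(segment.MLA / segment.PROXA, 1.0),
        LSL=LSL,
        PLSL=PLSL,
        LLR=PLSL / LSL,
        percent_area_stenosis=float(np.clip(pct, 0.0, np.nextafter(100.0, 0.0))),
        segment=segment,
    )


@dataclass(frozen=True)
class QuantifyConfig:
    """End-to-end quantification settings: resampling + reference fit."""

    step: float = 0.1  # mm; sub-voxel for angiographic reconstructions
    reference: ReferenceFitConfig = field(default_factory=ReferenceFitConfig)


def quantify_vessel(
    profile: AreaProfile, config: QuantifyConfig | None = None
) -> LesionMetrics | None:
    """Resample → fit reference → detect lesion → metrics, for one vessel.

    Deterministic given profile and config; returns ``None`` for a lesion-free
    vessel.  Geometry/detection errors propagate with the vessel id attached.
    """
    cfg = config or QuantifyConfig()
    resampled = resample_profile(profile, cfg.step)
    reference = fit_reference_profile(resampled, cfg.reference)
    segment = detect_lesion(resampled, reference)
    if segment is None:
        return None
    return compute_metrics(segment, reference)
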