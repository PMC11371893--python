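"""File formats and run configuration.

Interchange dialects (all UTF-8, lengths mm, areas mm², proximal→distal row
order):

* vessel geometry JSON — either per-point areas::

      {"vessel_id": "V1", "points": [[x, y, z], ...], "areas": [a1, ...]}

  or contour polygons::

      {"vessel_id": "V1", "sections": [{"s": 0.0, "vertices": [[x, y], ...]}, ...]}

* area-profile CSV — columns ``vessel_id, s_mm, area_mm2`` (multiple vessels
  per file allowed);
* vFFR CSV — columns ``vessel_id, s_mm, vffr``, joined to geometry on
  ``vessel_id``;
* cohort CSV — one row per vessel with labels, follow-up and metric columns;
* analysis report — JSON; configuration echo — YAML.

Floating-point output is printed at 6 significant digits for stable diffs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, SchemaError
from .geometry import AreaProfile, CrossSection, arc_length, polygon_area
from .hemodynamics import VFFRProfile

__all__ = [
    "RunConfig",
    "read_vessel_inputs",
    "read_geometry_json",
    "read_geometry_csv",
    "read_vffr_csv",
    "write_geometry_json",
    "write_vffr_csv",
    "write_lesion_table",
    "write_cohort",
    "format_float",
]

SIG_DIGITS = 6


def format_float(x: float) -> float:
    """Round to 6 significant digits (stable textual output)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{SIG_DIGITS}g}")


@dataclass(frozen=True)
class RunConfig:
    """Validated run parameters; echoed verbatim into every output directory."""

    input_paths: tuple = ()
    output_dir: str = "."
    step: float = 0.1
    bonferroni_m: int = 9
    thresholds: dict = field(default_factory=dict)
    stratify_mi_type: bool = True
    all_lesions: bool = False
    seed: int = 42
    log_level: str = "INFO"

    def __post_init__(self):
        if self.step <= 0:
            raise SchemaError(f"resampling step must be > 0, got {self.step}")

    def echo(self, directory: Path) -> None:
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "input_paths": list(self.input_paths),
            "output_dir": str(self.output_dir),
            "step": self.step,
            "bonferroni_m": self.bonferroni_m,
            "thresholds": dict(self.thresholds),
            "stratify_mi_type": self.stratify_mi_type,
            "all_lesions": self.all_lesions,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        (directory / "run_config.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_geometry_json(path: str | Path) -> AreaProfile:
    """One vessel from a geometry JSON file (points+areas or contour sections)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    vessel_id = payload.get("vessel_id", path.stem)
    if "points" in payload and "areas" in payload:
        points = np.asarray(payload["points"], dtype=float)
        areas = np.asarray(payload["areas"], dtype=float)
        if len(points) != len(areas):
            raise SchemaError(
                f"{path}: points ({len(points)}) and areas ({len(areas)}) length mismatch"
            )
        s = arc_length(points)
    elif "sections" in payload:
        secs = payload["sections"]
        s = np.asarray([sec["s"] for sec in secs], dtype=float)
        areas = np.asarray(
            [polygon_area(CrossSection(np.asarray(sec["vertices"], float), sec["s"])) for sec in secs]
        )
    else:
        raise SchemaError(
            f"{path}: expected keys ('points', 'areas') or 'sections' in geometry JSON"
        )
    s = s - s[0]
    return AreaProfile(s=s, A=areas, vessel_id=str(vessel_id))


def _require_columns(df: pd.DataFrame, cols: tuple, path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_geometry_csv(path: str | Path) -> list[AreaProfile]:
    """Area profiles from a CSV with columns vessel_id, s_mm, area_mm2."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("vessel_id", "s_mm", "area_mm2"), path)
    profiles = []
    for vid, sub in df.groupby("vessel_id", sort=False):
        s = sub["s_mm"].to_numpy(float)
        bad = np.flatnonzero(np.diff(s) <= 0)
        if len(bad):
            row = sub.index[bad[0] + 1]
            raise SchemaError(
                f"{path}: non-monotone s_mm for vessel {vid} at row {row} (column s_mm)"
            )
        profiles.append(
            AreaProfile(s=s - s[0], A=sub["area_mm2"].to_numpy(float), vessel_id=str(vid))
        )
    return profiles


def read_vffr_csv(path: str | Path) -> list[VFFRProfile]:
    """vFFR profiles from a CSV with columns vessel_id, s_mm, vffr."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("vessel_id", "s_mm", "vffr"), path)
    out = []
    for vid, sub in df.groupby("vessel_id", sort=False):
        s = sub["s_mm"].to_numpy(float)
        if np.any(np.diff(s) <= 0):
            row = sub.index[int(np.flatnonzero(np.diff(s) <= 0)[0]) + 1]
            raise SchemaError(
                f"{path}: non-monotone s_mm for vessel {vid} at row {row} (column s_mm)"
            )
        out.append(VFFRProfile(s=s, v=sub["vffr"].to_numpy(float), vessel_id=str(vid)))
    return out


def read_vessel_inputs(
    geometry_paths: list[str | Path], vffr_paths: list[str | Path] | None = None
) -> list[tuple[AreaProfile, VFFRProfile | None]]:
    """Load and join geometry (JSON/CSV) and optional vFFR profiles by vessel id.

    Raises :class:`SchemaError` on malformed files and :class:`AlignmentError`
    when a vFFR profile has no matching geometry.
    """
    profiles: dict[str, AreaProfile] = {}
    for p in geometry_paths:
        p = Path(p)
        if not p.exists():
            raise SchemaError(f"input file not found: {p}")
        loaded = [read_geometry_json(p)] if p.suffix.lower() == ".json" else read_geometry_csv(p)
        for prof in loaded:
            if prof.vessel_id in profiles:
                raise SchemaError(f"{p}: duplicate vessel_id {prof.vessel_id!r}")
            profiles[prof.vessel_id] = prof
    vffr: dict[str, VFFRProfile] = {}
    for p in vffr_paths or []:
        p = Path(p)
        if not p.exists():
            raise SchemaError(f"input file not found: {p}")
        for prof in read_vffr_csv(p):
            if prof.vessel_id not in profiles:
                raise AlignmentError(
                    f"{p}: vFFR profile for vessel {prof.vessel_id!r} has no matching geometry"
                )
            vffr[prof.vessel_id] = prof
    return [(prof, vffr.get(vid)) for vid, prof in profiles.items()]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_geometry_json(profile: AreaProfile, path: str | Path) -> None:
    """Vessel geometry as JSON (synthetic straight-centerline export)."""
    payload = {
        "vessel_id": profile.vessel_id,
        "points": [[format_float(s), 0.0, 0.0] for s in profile.s],
        "areas": [format_float(a) for a in profile.A],
    }
    Path(path).write_text(json.dumps(payload))


def write_vffr_csv(profile: VFFRProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "vessel_id": profile.vessel_id,
            "s_mm": [format_float(x) for x in profile.s],
            "vffr": [format_float(x) for x in profile.v],
        }
    )
    df.to_csv(path, index=False)


_LESION_COLUMNS = {
    "s_prox": "s_prox_mm",
    "s_mla": "s_mla_mm",
    "s_dist": "s_dist_mm",
    "PROXA": "PROXA_mm2",
    "MLA": "MLA_mm2",
    "DISTA": "DISTA_mm2",
}


def write_lesion_table(rows: list[dict], path: str | Path) -> None:
    """Lesion quantification CSV (one row per vessel with a detected lesion)."""
    columns = [
        "vessel_id",
        "s_prox_mm",
        "s_mla_mm",
        "s_dist_mm",
        "PROXA_mm2",
        "MLA_mm2",
        "DISTA_mm2",
        "MLR",
        "LSL_mm",
        "PLSL_mm",
        "LLR",
        "pct_area_stenosis",
    ]
    df = pd.DataFrame(rows, columns=columns)
    for c in columns[1:]:
        df[c] = df[c].map(lambda x: format_float(x) if pd.notna(x) else x)
    df.to_csv(path, index=False)


def lesion_row(vessel_id: str, metrics) -> dict:
    """Flatten LesionMetrics (+segment) into a lesion-table row."""
    seg = metrics.segment
    return {
        "vessel_id": vessel_id,
        "s_prox_mm": seg.s_prox,
        "s_mla_mm": seg.s_mla,
        "s_dist_mm": seg.s_dist,
        "PROXA_mm2": seg.PROXA,
        "MLA_mm2": seg.MLA,
        "DISTA_mm2": seg.DISTA,
        "MLR": metrics.MLR,
        "LSL_mm": metrics.LSL,
        "PLSL_mm": metrics.PLSL,
        "LLR": metrics.LLR,
        "pct_area_stenosis": metrics.percent_area_stenosis,
    }


def write_cohort(result, outdir: str | Path, write_profiles: bool = True) -> Path:
    """Write a generated cohort: cohort.csv, per-vessel files, config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = result.table.copy()
    for c in table.columns:
        if table[c].dtype.kind == "f":
            table[c] = table[c].map(format_float)
    table.to_csv(outdir / "cohort.csv", index=False)
    cfg = result.config
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(
            {
                "n_patients": cfg.n_patients,
                "n_fcl": cfg.n_fcl,
                "n_ncl": cfg.n_ncl,
                "nstemi_fraction": cfg.nstemi_fraction,
                "seed": cfg.seed,
                "step": cfg.step,
                "taper_slope": cfg.taper_slope,
                "event_time_quantiles": list(cfg.event_time_quantiles),
                "event_time_bounds": list(cfg.event_time_bounds),
                "quantiles": {
                    g: {m: list(t) for m, t in mm.items()} for g, mm in cfg.quantiles.items()
                },
                "spearman_targets": [[list(p), r] for p, r in cfg.spearman_targets],
            },
            sort_keys=True,
        )
    )
    if write_profiles and result.area_profiles:
        gdir = outdir / "geometry"
        vdir = outdir / "vffr"
        gdir.mkdir(exist_ok=True)
        vdir.mkdir(exist_ok=True)
        for vid, prof in result.area_profiles.items():
            write_geometry_json(prof, gdir / f"{vid}.json")
        for vid, prof in result.vffr_profiles.items():
            write_vffr_csv(prof, vdir / f"{vid}.csv")
    return outdir
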