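"""File readers/writers for the analysis pipeline.

One strict CSV dialect throughout: comma-separated, UTF-8, header row
required, '.' decimal.  Units are encoded in the column names (``time_s``,
``pressure_kPa``, ``height_mm``, ``force_N``) and validated, never
guessed.  Malformed input raises :class:`ParseError` naming the column or
row (1-based, counting the header as row 1).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bulge import BulgeTrace, MechanicalSummary, SpecimenMeta
from .uniaxial import DotFrame, UniaxialTrace

__all__ = [
    "ParseError",
    "read_bulge_trace_csv",
    "read_creep_csv",
    "read_marker_frames_csv",
    "read_specimen_meta_csv",
    "write_summary_table",
    "write_manifest",
]

BULGE_COLUMNS = ["time_s", "pressure_kPa", "height_mm"]
CREEP_COLUMNS = ["time_s", "pressure_kPa"]  # plus 'strain' or 'height_mm'
MARKER_COLUMNS = ["frame_id", "time_s",
                  "x1", "y1", "x2", "y2", "x3", "y3", "x4", "y4"]
META_COLUMNS = ["specimen_id", "thickness_mm", "state", "failure_location",
                "orifice_mm"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending column or row."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is row 1
            raise ParseError(f"{path}: non-numeric value in column '{c}' "
                             f"at row {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise ParseError(f"{path}: missing value in column '{c}' at row {row}")
        df[c] = coerced
    return df


def _check_time(t: np.ndarray, path: Path) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise ParseError(f"{path}: time not strictly increasing at row "
                         f"{int(bad[0]) + 3}")  # +2 header/1-base, +1 second sample


def read_bulge_trace_csv(path: str | Path) -> BulgeTrace:
    """Read one specimen's bulge record (time_s, pressure_kPa, height_mm)."""
    path = Path(path)
    df = _numeric(_read_csv(path, BULGE_COLUMNS), BULGE_COLUMNS, path)
    t = df["time_s"].to_numpy()
    _check_time(t, path)
    return BulgeTrace(time=t, pressure_p=df["pressure_kPa"].to_numpy(),
                      height_h=df["height_mm"].to_numpy())


def read_creep_csv(path: str | Path,
                   orifice_D: Optional[float] = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a creep record; returns (time, pressure, strain).

    Accepts a ``strain`` column directly or a ``height_mm`` column, which
    is converted through the cap geometry (requires ``orifice_D``).
    """
    path = Path(path)
    df = _read_csv(path, CREEP_COLUMNS)
    if "strain" in df.columns:
        cols = CREEP_COLUMNS + ["strain"]
        df = _numeric(df, cols, path)
        strain = df["strain"].to_numpy()
    elif "height_mm" in df.columns:
        cols = CREEP_COLUMNS + ["height_mm"]
        df = _numeric(df, cols, path)
        if orifice_D is None:
            raise ParseError(f"{path}: height_mm given but no orifice diameter "
                             "to convert to strain")
        R = orifice_D / 2.0
        strain = df["height_mm"].to_numpy() ** 2 / R ** 2
    else:
        raise ParseError(f"{path}: missing required column(s) "
                         "['strain' or 'height_mm']")
    t = df["time_s"].to_numpy()
    _check_time(t, path)
    return t, df["pressure_kPa"].to_numpy(), strain


def read_marker_frames_csv(path: str | Path,
                           gauge_length_l0: float = 18.0) -> UniaxialTrace:
    """Read a marker-frame record with force (uniaxial context).

    Columns: frame_id, time_s, force_N (or pressure_kPa), x1..y4 in mm.
    """
    path = Path(path)
    df = _read_csv(path, MARKER_COLUMNS)
    load_col = "force_N" if "force_N" in df.columns else "pressure_kPa"
    if load_col not in df.columns:
        raise ParseError(f"{path}: missing required column(s) "
                         "['force_N' or 'pressure_kPa']")
    cols = [c for c in MARKER_COLUMNS if c != "frame_id"] + [load_col]
    df = _numeric(df, cols, path)
    t = df["time_s"].to_numpy()
    _check_time(t, path)
    frames = []
    for _, row in df.iterrows():
        xy = np.array([[row["x1"], row["y1"]], [row["x2"], row["y2"]],
                       [row["x3"], row["y3"]], [row["x4"], row["y4"]]])
        frames.append(DotFrame(timestamp=float(row["time_s"]), marker_xy=xy,
                               pressure_or_force=float(row[load_col])))
    return UniaxialTrace(time=t, force_F=df[load_col].to_numpy(),
                         frames=tuple(frames), gauge_length_l0=gauge_length_l0)


def read_specimen_meta_csv(path: str | Path) -> dict[str, SpecimenMeta]:
    """Read specimen metadata keyed by specimen_id."""
    path = Path(path)
    df = _read_csv(path, META_COLUMNS)
    df = _numeric(df, ["thickness_mm", "orifice_mm"], path)
    out: dict[str, SpecimenMeta] = {}
    for _, row in df.iterrows():
        sid = str(row["specimen_id"])
        out[sid] = SpecimenMeta(
            specimen_id=sid,
            load_bearing_thickness_t=float(row["thickness_mm"]),
            in_vivo_strain_state=str(row["state"]),
            failure_location=str(row["failure_location"]),
            orifice_diameter_D=float(row["orifice_mm"]))
    return out


def summaries_to_frame(summaries: list[MechanicalSummary]) -> pd.DataFrame:
    rows = [{
        "specimen_id": s.specimen_id,
        "E_MPa": s.E,
        "p_fracture_kPa": s.p_fracture,
        "eps_fracture": s.eps_fracture,
        "r2": s.pressure_strain_r2,
        "excluded": s.excluded,
        "reason": s.reason,
    } for s in summaries]
    return pd.DataFrame(rows)


def write_summary_table(summaries: list[MechanicalSummary],
                        path: str | Path) -> None:
    """Write per-specimen summaries as CSV (or JSON if the suffix is .json)."""
    path = Path(path)
    df = summaries_to_frame(summaries)
    if path.suffix == ".json":
        path.write_text(df.to_json(orient="records", indent=2))
    else:
        df.to_csv(path, index=False)


def write_manifest(path: str | Path, config: object, seed: int,
                   extra: Optional[dict] = None) -> None:
    """Write a run manifest (config + seed + package version) as JSON."""
    from . import __version__
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        cfg = dataclasses.asdict(config)
    else:
        cfg = dict(config) if config is not None else {}
    manifest = {"config": cfg, "seed": seed, "elastometry_version": __version__}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
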