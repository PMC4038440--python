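"""Biaxial bulge-test analysis: strain and modulus time courses, fracture.

A bulge (biaxial tensile) test pressurises a skin segment clamped over a
circular orifice and records pressure ``p(t)`` (kPa) and centre bulge
height ``h(t)`` (mm).  The apparent modulus of elasticity, averaged over
the whole segment, is

    E = p·R²·(R² + h²) / (2·h³·t)

with ``R`` the orifice radius and ``t`` the thickness of the load-bearing
skin layer (0.1 mm by convention — flesh adhering below it carries almost
no load).  ``E`` is computed in kPa and reported in MPa.

The per-specimen reduction follows the observed behaviour of such tests:
``E(t)`` shows a start-up transient, then a plateau up to fracture, and the
pressure–strain relation is close to linear.  The summary modulus is the
median of pointwise ``E(t)`` over the plateau (samples with strain at or
above ``plateau_strain_min``); fracture is the last sample before the first
instantaneous pressure drop.  Specimens that failed at the orifice edge are
flagged excluded (mounting artifact).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .geometry import CapGeometry, biaxial_strain_from_height

__all__ = [
    "SpecimenMeta",
    "BulgeTrace",
    "MechanicalSummary",
    "apparent_modulus",
    "detect_fracture",
    "analyze_bulge_trace",
    "filter_edge_failures",
    "BulgeTest",
    "BulgeTestResults",
]

#: Default thickness (mm) of the load-bearing skin layer (epidermis +
#: hypodermis); fixed regardless of how much flesh adheres to the segment.
DEFAULT_THICKNESS_MM = 0.1

#: Default orifice diameter (mm) of the clamping washer.
DEFAULT_ORIFICE_MM = 12.0


@dataclass(frozen=True)
class SpecimenMeta:
    """Per-specimen metadata needed to analyse a bulge trace."""

    specimen_id: str
    load_bearing_thickness_t: float = DEFAULT_THICKNESS_MM
    segment_thickness: Optional[float] = None
    in_vivo_strain_state: str = "maintained"  # or "released"
    failure_location: str = "none"  # "center", "edge" or "none"
    orifice_diameter_D: float = DEFAULT_ORIFICE_MM

    def __post_init__(self) -> None:
        if not self.load_bearing_thickness_t > 0:
            raise ValueError("load-bearing thickness must be > 0")
        if not self.orifice_diameter_D > 0:
            raise ValueError("orifice diameter must be > 0")
        if self.failure_location not in ("center", "edge", "none"):
            raise ValueError(f"unknown failure location {self.failure_location!r}")
        if self.in_vivo_strain_state not in ("maintained", "released"):
            raise ValueError(f"unknown strain state {self.in_vivo_strain_state!r}")


@dataclass(frozen=True)
class BulgeTrace:
    """One specimen's sampled (time, pressure, height) record."""

    time: np.ndarray       # s, strictly increasing
    pressure_p: np.ndarray  # kPa, >= 0
    height_h: np.ndarray    # mm, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.pressure_p, dtype=float)
        h = np.asarray(self.height_h, dtype=float)
        if not (len(t) == len(p) == len(h)):
            raise ValueError("time, pressure and height must have equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("pressure must be >= 0")
        if np.any(h < 0):
            raise ValueError("height must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pressure_p", p)
        object.__setattr__(self, "height_h", h)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class MechanicalSummary:
    """Per-specimen mechanical summary of a bulge test."""

    specimen_id: str
    E: Optional[float]                 # MPa, plateau median
    p_fracture: Optional[float]        # kPa
    eps_fracture: Optional[float]      # mm² mm⁻²
    pressure_strain_r2: Optional[float]
    fracture_index: Optional[int]
    excluded: bool = False
    reason: str = ""


def apparent_modulus(p: float, geom: CapGeometry, t: float) -> float:
    """Apparent modulus of elasticity (MPa) of a pressurised cap.

    ``E = p·R²·(R²+h²)/(2·h³·t)`` with ``p`` in kPa and lengths in mm gives
    kPa; the returned value is divided by 1000 (MPa).  This is an *apparent*
    modulus averaged over the whole bulging segment — the strain field is
    not uniform but concentrates towards the centre.

    Undefined at ``h = 0`` (returns NaN).
    """
    if t <= 0:
        raise ValueError(f"thickness must be > 0, got {t}")
    if p < 0:
        raise ValueError(f"pressure must be >= 0, got {p}")
    R, h = geom.orifice_radius_R, geom.height_h
    if h == 0:
        return float("nan")
    e_kpa = p * R * R * (R * R + h * h) / (2.0 * h ** 3 * t)
    return e_kpa / 1000.0


def _modulus_series(p: np.ndarray, h: np.ndarray, R: float, t: float) -> np.ndarray:
    """Vectorised pointwise apparent modulus (MPa); NaN where h == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        e = p * R * R * (R * R + h * h) / (2.0 * h ** 3 * t) / 1000.0
    return np.where(h > 0, e, np.nan)


def detect_fracture(trace: BulgeTrace, drop_fraction: float = 0.2,
                    min_pressure: float = 5.0) -> Optional[int]:
    """Index of the last sample before the first instantaneous pressure drop.

    A drop is a decrease between consecutive samples exceeding
    ``drop_fraction`` of the current pressure.  Drops are only considered
    once the pressure has reached ``min_pressure`` (kPa): near zero pressure
    the relative criterion is dominated by sensor noise, and every physical
    fracture pressure lies far above this floor.

    Returns ``None`` if no such drop occurs.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples to detect fracture")
    p = trace.pressure_p
    drops = (p[:-1] - p[1:]) > drop_fraction * p[:-1]
    eligible = p[:-1] >= min_pressure
    idx = np.nonzero(drops & eligible)[0]
    return int(idx[0]) if len(idx) else None


def analyze_bulge_trace(trace: BulgeTrace, meta: SpecimenMeta,
                        plateau_strain_min: float = 0.02,
                        drop_fraction: float = 0.2,
                        min_pressure: float = 5.0) -> "BulgeTestResults":
    """Full per-specimen reduction of a bulge trace.

    Convenience wrapper around :class:`BulgeTest`.
    """
    return BulgeTest(trace, meta, plateau_strain_min=plateau_strain_min,
                     drop_fraction=drop_fraction,
                     min_pressure=min_pressure).fit()


def filter_edge_failures(summaries: list[MechanicalSummary]
                         ) -> tuple[list[MechanicalSummary], int]:
    """Drop excluded (edge-failure) summaries; returns (kept, n_excluded)."""
    kept = [s for s in summaries if not s.excluded]
    return kept, len(summaries) - len(kept)


class BulgeTest:
    """Model object for one biaxial bulge test.

    Parameters
    ----------
    trace
        The sampled (time, pressure, height) record.
    meta
        Specimen metadata (orifice, load-bearing thickness, failure location).
    plateau_strain_min
        Strain gate for the modulus plateau; pointwise ``E`` below it is
        treated as start-up transient and excluded from the summary.
    drop_fraction, min_pressure
        Fracture-detection thresholds (see :func:`detect_fracture`).
    """

    def __init__(self, trace: BulgeTrace, meta: SpecimenMeta,
                 plateau_strain_min: float = 0.02,
                 drop_fraction: float = 0.2,
                 min_pressure: float = 5.0) -> None:
        self.trace = trace
        self.meta = meta
        self.plateau_strain_min = plateau_strain_min
        self.drop_fraction = drop_fraction
        self.min_pressure = min_pressure

    @classmethod
    def from_dataframe(cls, df, meta: SpecimenMeta, **opts) -> "BulgeTest":
        """Build from a DataFrame with columns time_s, pressure_kPa, height_mm."""
        trace = BulgeTrace(time=df["time_s"].to_numpy(),
                           pressure_p=df["pressure_kPa"].to_numpy(),
                           height_h=df["height_mm"].to_numpy())
        return cls(trace, meta, **opts)

    def fit(self) -> "BulgeTestResults":
        trace, meta = self.trace, self.meta
        R = meta.orifice_diameter_D / 2.0
        t = meta.load_bearing_thickness_t

        strain = trace.height_h ** 2 / R ** 2
        modulus = _modulus_series(trace.pressure_p, trace.height_h, R, t)

        frac_idx = detect_fracture(trace, self.drop_fraction, self.min_pressure)
        end = len(trace) if frac_idx is None else frac_idx + 1

        pre_strain = strain[:end]
        pre_p = trace.pressure_p[:end]
        pre_E = modulus[:end]

        plateau = (pre_strain >= self.plateau_strain_min) & np.isfinite(pre_E)
        if np.any(plateau):
            e_summary: Optional[float] = float(np.median(pre_E[plateau]))
            reason = ""
        else:
            e_summary = None
            reason = "no plateau"

        if frac_idx is not None:
            p_f = float(trace.pressure_p[frac_idx])
            eps_f = float(strain[frac_idx])
        else:
            p_f = eps_f = None

        r2: Optional[float] = None
        if end >= 3 and np.ptp(pre_strain) > 0:
            lr = stats.linregress(pre_strain, pre_p)
            r2 = float(lr.rvalue ** 2)

        excluded = meta.failure_location == "edge"
        summary = MechanicalSummary(
            specimen_id=meta.specimen_id, E=e_summary, p_fracture=p_f,
            eps_fracture=eps_f, pressure_strain_r2=r2, fracture_index=frac_idx,
            excluded=excluded, reason="edge failure" if excluded else reason)
        return BulgeTestResults(model=self, strain=strain, modulus=modulus,
                                fracture_index=frac_idx, mechanical=summary)


@dataclass
class BulgeTestResults:
    """Results of :meth:`BulgeTest.fit`.

    Carries the pointwise strain and modulus time courses (post-fracture
    samples included in the arrays but excluded from every fit) and the
    per-specimen :class:`MechanicalSummary`.
    """

    model: BulgeTest
    strain: np.ndarray
    modulus: np.ndarray
    fracture_index: Optional[int]
    mechanical: MechanicalSummary

    # convenience accessors mirroring the summary fields
    @property
    def E(self) -> Optional[float]:
        return self.mechanical.E

    @property
    def p_fracture(self) -> Optional[float]:
        return self.mechanical.p_fracture

    @property
    def eps_fracture(self) -> Optional[float]:
        return self.mechanical.eps_fracture

    @property
    def pressure_strain_r2(self) -> Optional[float]:
        return self.mechanical.pressure_strain_r2

    def summary(self) -> str:
        m = self.mechanical
        fmt = lambda v, u="": "n/a" if v is None else f"{v:.4g}{u}"
        lines = [
            f"Bulge test summary — specimen {m.specimen_id}",
            f"  apparent modulus E : {fmt(m.E, ' MPa')} (plateau median)",
            f"  fracture pressure  : {fmt(m.p_fracture, ' kPa')}",
            f"  fracture strain    : {fmt(m.eps_fracture)}",
            f"  pressure-strain r2 : {fmt(m.pressure_strain_r2)}",
            f"  excluded           : {m.excluded}"
            + (f" ({m.reason})" if m.reason else ""),
        ]
        return "\n".join(lines)
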