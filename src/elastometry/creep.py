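"""Creep-relaxation analysis: phase segmentation and strain partitioning.

A creep-relaxation test loads a bulge specimen to a constant hold pressure,
holds it (the specimen creeps), then unloads to zero and observes recovery.
Pressure — the controlled variable — defines the phase boundaries.

The total strain at the end of the holding phase is partitioned as

    total(end of hold) = elastic + viscoelastic + plastic

with the operational definitions: *elastic* = instantaneous strain at the
end of loading; *plastic* = residual strain at the end of the recovery
window (irreversible); *viscoelastic* = the remainder.  The partition
identity holds exactly by construction on every input.

Hold-phase creep of viscoelastic tissue is close to linear in log time;
``log_time_creep_fit`` quantifies this with an OLS fit of strain against
``ln(time since hold start + t₀)``, where the small positive offset ``t₀``
regularises the first sample (configurable, default: first sample
interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "CreepPhases",
    "CreepResult",
    "LogCreepFit",
    "segment_phases",
    "partition_strains",
    "log_time_creep_fit",
    "CreepTest",
    "CreepTestResults",
]


@dataclass(frozen=True)
class CreepPhases:
    """Half-open index ranges [start, stop) of the three protocol phases.

    Contiguous, ordered and non-overlapping; together they cover the trace.
    """

    loading: tuple[int, int]
    holding: tuple[int, int]
    unloading_and_recovery: tuple[int, int]

    def __post_init__(self) -> None:
        l, h, u = self.loading, self.holding, self.unloading_and_recovery
        if not (l[0] == 0 and l[1] == h[0] and h[1] == u[0] and l[0] < l[1]
                and h[0] < h[1] and u[0] <= u[1]):
            raise ValueError(f"phases must be contiguous and ordered: {l}, {h}, {u}")


@dataclass
class CreepResult:
    """Elastic/viscoelastic/plastic partition plus the log-time creep fit."""

    elastic_strain: float
    viscoelastic_strain: float
    plastic_strain: float
    creep_slope_m: float      # strain per ln(s)
    creep_intercept: float
    creep_r2: float

    @property
    def total_end_of_hold(self) -> float:
        return self.elastic_strain + self.viscoelastic_strain + self.plastic_strain


@dataclass
class LogCreepFit:
    slope_m: float
    intercept: float
    r2: float
    degenerate: bool = False


def segment_phases(pressure: np.ndarray, time: np.ndarray,
                   hold_level: float, tol: float = 0.5,
                   min_below: int = 3) -> CreepPhases:
    """Segment a load–hold–unload pressure record into its three phases.

    *Loading* runs from the start to the first sample within ``tol`` of
    ``hold_level``; *holding* continues while pressure stays above
    ``hold_level − tol``; everything after the drop is *unloading and
    recovery*.  The drop must persist for ``min_below`` consecutive samples
    (an isolated sensor-noise dip does not end the hold).  Raises if the
    hold level is never reached.
    """
    p = np.asarray(pressure, dtype=float)
    t = np.asarray(time, dtype=float)
    if len(p) != len(t):
        raise ValueError("pressure and time must have equal length")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    at_hold = np.abs(p - hold_level) <= tol
    if not np.any(at_hold):
        raise ValueError(
            f"hold level {hold_level} kPa never reached (max {p.max():.3g} kPa)")
    i_hold = int(np.argmax(at_hold))
    if i_hold == 0:
        raise ValueError("record must start below the hold level")
    below = p[i_hold:] < hold_level - tol
    # unload = start of the first run of >= min_below consecutive
    # below-threshold samples (a shorter run at the record tail also counts)
    i_unload = len(p)
    j, n_b = 0, len(below)
    while j < n_b:
        if below[j]:
            k = j
            while k < n_b and below[k]:
                k += 1
            if (k - j) >= min_below or k == n_b:
                i_unload = i_hold + j
                break
            j = k
        else:
            j += 1
    if i_unload == i_hold:
        raise ValueError("holding phase is empty")
    return CreepPhases(loading=(0, i_hold), holding=(i_hold, i_unload),
                       unloading_and_recovery=(i_unload, len(p)))


def partition_strains(strain: np.ndarray, phases: CreepPhases,
                      time: Optional[np.ndarray] = None,
                      recovery_window_end: Optional[float] = None) -> CreepResult:
    """Partition total strain into elastic, viscoelastic and plastic parts.

    * elastic  = strain at the last loading sample
    * plastic  = strain at ``recovery_window_end`` (seconds; default: the
      last sample of the record)
    * viscoelastic = strain(end of hold) − elastic − plastic

    The identity elastic + viscoelastic + plastic = strain(end of hold)
    holds exactly.  The log-time creep fit fields are filled by
    :class:`CreepTest`; here they are zeroed.
    """
    eps = np.asarray(strain, dtype=float)
    u0, u1 = phases.unloading_and_recovery
    if len(eps) != u1:
        raise ValueError("strain must be aligned with the phase ranges")

    if recovery_window_end is None:
        i_rec = len(eps) - 1
    else:
        if time is None:
            raise ValueError("time array required when recovery_window_end is given")
        t = np.asarray(time, dtype=float)
        inside = np.nonzero(t <= recovery_window_end)[0]
        if not len(inside) or inside[-1] < u0:
            raise ValueError("recovery window ends before the unloading phase")
        i_rec = int(inside[-1])

    elastic = float(eps[phases.loading[1] - 1])
    total_hold = float(eps[phases.holding[1] - 1])
    plastic = float(eps[i_rec])
    viscoelastic = total_hold - elastic - plastic
    return CreepResult(elastic_strain=elastic, viscoelastic_strain=viscoelastic,
                       plastic_strain=plastic, creep_slope_m=0.0,
                       creep_intercept=0.0, creep_r2=0.0)


def log_time_creep_fit(strain_hold: np.ndarray, time_hold: np.ndarray,
                       t0_fit: Optional[float] = None) -> LogCreepFit:
    """OLS fit of hold-phase strain against ``ln(time since hold start + t₀)``.

    ``time_hold`` is rebased to the first hold sample.  ``t0_fit`` defaults
    to the first sample interval, avoiding ``ln(0)``.  A constant strain is
    degenerate: slope 0, r² reported 0 with a flag.
    """
    eps = np.asarray(strain_hold, dtype=float)
    t = np.asarray(time_hold, dtype=float)
    if len(eps) != len(t):
        raise ValueError("strain and time must have equal length")
    if len(eps) < 5:
        raise ValueError("need at least 5 hold samples")
    T = t - t[0]
    if t0_fit is None:
        t0_fit = float(T[1] - T[0])
    if t0_fit <= 0 or np.any(T + t0_fit <= 0):
        raise ValueError("rebased times plus offset must be positive")
    x = np.log(T + t0_fit)
    if np.ptp(eps) == 0:
        return LogCreepFit(slope_m=0.0, intercept=float(eps[0]), r2=0.0,
                           degenerate=True)
    lr = stats.linregress(x, eps)
    return LogCreepFit(slope_m=float(lr.slope), intercept=float(lr.intercept),
                       r2=float(lr.rvalue ** 2))


class CreepTest:
    """Model object for one creep-relaxation record.

    Parameters
    ----------
    time, pressure, strain
        Aligned arrays: seconds, kPa, dimensionless area strain.
    hold_level
        Target hold pressure (kPa).
    tol
        Pressure tolerance (kPa) for phase segmentation.
    """

    def __init__(self, time: np.ndarray, pressure: np.ndarray,
                 strain: np.ndarray, hold_level: float = 10.0,
                 tol: float = 0.5) -> None:
        self.time = np.asarray(time, dtype=float)
        self.pressure = np.asarray(pressure, dtype=float)
        self.strain = np.asarray(strain, dtype=float)
        self.hold_level = hold_level
        self.tol = tol

    @classmethod
    def from_dataframe(cls, df, hold_level: float = 10.0, tol: float = 0.5,
                       orifice_D: Optional[float] = None) -> "CreepTest":
        """Build from a DataFrame with time_s, pressure_kPa and either a
        ``strain`` column or a ``height_mm`` column (converted via the cap
        geometry using ``orifice_D``)."""
        if "strain" in df.columns:
            strain = df["strain"].to_numpy()
        elif "height_mm" in df.columns:
            if orifice_D is None:
                raise ValueError("orifice_D required to convert height to strain")
            R = orifice_D / 2.0
            strain = df["height_mm"].to_numpy() ** 2 / R ** 2
        else:
            raise ValueError("need a 'strain' or 'height_mm' column")
        return cls(df["time_s"].to_numpy(), df["pressure_kPa"].to_numpy(),
                   strain, hold_level=hold_level, tol=tol)

    def fit(self, recovery_window_end: Optional[float] = None,
            t0_fit: Optional[float] = None) -> "CreepTestResults":
        phases = segment_phases(self.pressure, self.time, self.hold_level,
                                self.tol)
        part = partition_strains(self.strain, phases, time=self.time,
                                 recovery_window_end=recovery_window_end)
        h0, h1 = phases.holding
        logfit = log_time_creep_fit(self.strain[h0:h1], self.time[h0:h1],
                                    t0_fit=t0_fit)
        result = CreepResult(
            elastic_strain=part.elastic_strain,
            viscoelastic_strain=part.viscoelastic_strain,
            plastic_strain=part.plastic_strain,
            creep_slope_m=logfit.slope_m,
            creep_intercept=logfit.intercept,
            creep_r2=logfit.r2)
        return CreepTestResults(model=self, phases=phases, result=result,
                                log_fit=logfit)


@dataclass
class CreepTestResults:
    """Results of :meth:`CreepTest.fit`."""

    model: CreepTest
    phases: CreepPhases
    result: CreepResult
    log_fit: LogCreepFit

    def summary(self) -> str:
        r = self.result
        ph = self.phases
        return "\n".join([
            "Creep-relaxation test summary",
            f"  phases (samples)    : loading {ph.loading}, holding {ph.holding},"
            f" unloading {ph.unloading_and_recovery}",
            f"  elastic strain      : {r.elastic_strain:.5f}",
            f"  viscoelastic strain : {r.viscoelastic_strain:.5f}",
            f"  plastic strain      : {r.plastic_strain:.5f}",
            f"  creep slope m       : {r.creep_slope_m:.5g} strain/ln(s)"
            f" (r2={r.creep_r2:.4f})",
        ])
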