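"""Seeded generator of virtual skin specimens for every test mode.

Every generator is reproducible from ``(config, seed)`` and carries known
ground truth so the analysis pipeline can be verified by parameter
recovery.

Constitutive model
------------------
Pressure is the controlled variable (real instruments ramp it nearly
linearly).  Define the *generalised strain*

    ψ(h) = 2·h³·t / (R²·(R² + h²))

so that the apparent-modulus formula reads ``p = E·ψ(h)``: a purely
elastic specimen of modulus ``E`` follows ``ψ(t) = p(t)/E`` exactly, and
the analysis pipeline's pointwise modulus recovers ``E`` to machine
precision.  Viscoelasticity enters through a logarithmic creep compliance

    J(u) = (1/E_inst)·(1 + θ·ln(1 + u/t₀)),

applied as a hereditary (Boltzmann) integral ψ(t) = ∫ J(t−s)·ṗ(s) ds,
discretised by the trapezoid rule; ``h(t)`` is recovered from ψ by
bisection on the strictly monotone ψ(h).  The user-facing creep parameter
``creep_m`` is the hold-phase *area-strain* per ln(second) at the 10 kPa
reference hold; θ = creep_m / ε_el(p_ref) converts it to the relative
compliance growth used in ψ-space.

Fracture occurs when the noiseless area strain ``h²/R²`` reaches the
specimen's drawn fracture strain (normal across specimens, truncated at
0.01); a Bernoulli draw marks edge failures (mounting artifacts).  Traces
keep six post-fracture samples with collapsed pressure, as real records
do.

The creep-relaxation generator applies the same logarithmic kernel and
Boltzmann superposition directly in area-strain space, so the hold phase
is log-linear in time by construction and recovery after unloading decays
as ``φ(T_hold+τ) − φ(τ) → 0``; see docs/methods.md for why the strain-space
formulation is used there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .bulge import BulgeTrace, SpecimenMeta
from .geometry import CapGeometry, height_from_strain, sphere_radius, FLAT
from .uniaxial import DotFrame, UniaxialTrace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CreepTrace",
    "available_presets",
    "simulate_bulge_cohort",
    "simulate_uniaxial_test",
    "simulate_creep_test",
    "generate_dot_frames_on_cap",
    "simulate_relaxation",
]

#: Reference hold pressure (kPa) at which creep_m is the strain-per-ln(s)
#: slope; the compliance scales creep by p/p_ref.
P_REF_KPA = 10.0

#: Fracture-strain draws are truncated below this value.
EPS_FRACTURE_FLOOR = 0.01

#: Number of post-fracture samples appended to a bulge trace.
N_POST_FRACTURE = 6


@dataclass(frozen=True)
class SimulationConfig:
    """Constitutive, fracture, protocol and noise parameters of a virtual
    specimen cohort.  Units: MPa (modulus), kPa (pressure), mm (length),
    s (time); strains dimensionless."""

    E_inst: float = 23.2
    E_cv: float = 0.0
    creep_m: float = 0.0
    creep_t0: float = 1.0
    plastic_fraction: float = 0.0
    eps_fracture_mean: float = 0.20
    eps_fracture_cv: float = 0.0
    edge_failure_prob: float = 0.2
    nu: float = 0.74
    in_vivo_release_strain: float = 0.155
    center_amplification_g: float = 2.16
    pressure_ramp_rate: float = 0.25
    sampling_dt: float = 1.0
    noise_sd_height: float = 0.0
    noise_sd_pressure: float = 0.0
    noise_sd_marker: float = 0.0
    orifice_D: float = 12.0
    thickness_t: float = 0.1
    uniaxial_strain_rate: float = 0.00278
    uniaxial_stiffness: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ["E_inst", "creep_t0", "eps_fracture_mean",
                    "pressure_ramp_rate", "sampling_dt", "orifice_D",
                    "thickness_t", "uniaxial_strain_rate", "uniaxial_stiffness"]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        nonneg = ["E_cv", "creep_m", "plastic_fraction", "eps_fracture_cv",
                  "nu", "in_vivo_release_strain", "noise_sd_height",
                  "noise_sd_pressure", "noise_sd_marker"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.edge_failure_prob <= 1:
            raise ValueError("edge_failure_prob must be in [0, 1]")
        if self.center_amplification_g <= 0:
            raise ValueError("center_amplification_g must be > 0")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SimulationConfig":
        """Load a named preset from the bundled presets file."""
        presets = _load_presets()
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
        params = dict(presets[name])
        params.pop("n", None)  # cohort size is a call argument, not a field
        params.update(overrides)
        valid = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in params.items() if k in valid})

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def _load_presets() -> dict:
    text = resources.files("elastometry").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(k for k in _load_presets() if k != "defaults")


def preset_cohort_size(name: str) -> Optional[int]:
    """Cohort size recorded with a preset, if any."""
    return _load_presets().get(name, {}).get("n")


@dataclass
class GroundTruth:
    """Drawn per-specimen parameters plus the generating config."""

    E: np.ndarray               # MPa
    eps_fracture: np.ndarray
    edge_failure: np.ndarray    # bool
    config: SimulationConfig


@dataclass(frozen=True)
class CreepTrace:
    """Simulated creep-relaxation record (time s, pressure kPa, strain)."""

    time: np.ndarray
    pressure: np.ndarray
    strain: np.ndarray


# ---------------------------------------------------------------------------
# ψ(h) and its inverse
# ---------------------------------------------------------------------------

def _psi_of_h(h: np.ndarray, R: float, t: float) -> np.ndarray:
    """Generalised strain ψ(h) = 2h³t/(R²(R²+h²)); p = E·ψ for elastic caps."""
    h = np.asarray(h, dtype=float)
    return 2.0 * h ** 3 * t / (R * R * (R * R + h * h))

def _h_of_psi(psi: np.ndarray, R: float, t: float) -> np.ndarray:
    """Invert ψ(h) by vectorised bisection (ψ is strictly increasing)."""
    psi = np.asarray(psi, dtype=float)
    lo = np.zeros_like(psi)
    hi = np.full_like(psi, 3.0 * R)
    while np.any(_psi_of_h(hi, R, t) < psi):
        hi = np.where(_psi_of_h(hi, R, t) < psi, 2.0 * hi, hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        too_low = _psi_of_h(mid, R, t) < psi
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def _compliance(u: np.ndarray, E_kpa: float, theta: float,
                t0: float) -> np.ndarray:
    """ψ-space creep compliance J(u) = (1/E)·(1 + θ·ln(1 + u/t₀)) (1/kPa).

    ``θ`` is the relative compliance growth per ln(second); it is derived
    from ``creep_m`` so that the creep-to-elastic ratio matches the
    strain-space kernel at the 10 kPa reference hold (see
    :func:`simulate_bulge_cohort`).
    """
    u = np.asarray(u, dtype=float)
    return (1.0 / E_kpa) * (1.0 + theta * np.log1p(u / t0))


def _hereditary_psi(time: np.ndarray, pressure: np.ndarray, E_kpa: float,
                    theta: float, t0: float) -> np.ndarray:
    """ψ(tᵢ) = ∫₀^tᵢ J(tᵢ−s)·ṗ(s) ds, trapezoid rule on the sample grid."""
    n = len(time)
    dp = np.gradient(pressure, time)
    psi = np.empty(n)
    psi[0] = 0.0
    for i in range(1, n):
        u = time[i] - time[: i + 1]
        integrand = _compliance(u, E_kpa, theta, t0) * dp[: i + 1]
        psi[i] = np.trapezoid(integrand, time[: i + 1])
    return psi


# ---------------------------------------------------------------------------
# Bulge cohort
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, cv: float,
                      size: int, floor: float) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    draws = rng.normal(mean, cv * mean, size)
    while np.any(draws < floor):
        bad = draws < floor
        draws[bad] = rng.normal(mean, cv * mean, int(bad.sum()))
    return draws


def simulate_bulge_cohort(config: SimulationConfig, n: int,
                          rng: Optional[np.random.Generator] = None
                          ) -> tuple[list[tuple[BulgeTrace, SpecimenMeta]],
                                     GroundTruth]:
    """Simulate a cohort of bulge tests with known ground truth.

    Each specimen: linear pressure ramp, viscoelastic (or purely elastic)
    height response, fracture at its drawn fracture strain, six
    post-fracture samples with collapsed pressure/height, Gaussian
    measurement noise on pressure and height.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R = config.orifice_D / 2.0
    t_thick = config.thickness_t

    E_draws = _truncated_normal(rng, config.E_inst, config.E_cv, n, floor=0.5)
    eps_draws = _truncated_normal(rng, config.eps_fracture_mean,
                                  config.eps_fracture_cv, n,
                                  floor=EPS_FRACTURE_FLOOR)
    edge = rng.random(n) < config.edge_failure_prob

    specimens: list[tuple[BulgeTrace, SpecimenMeta]] = []
    for i in range(n):
        E_kpa = E_draws[i] * 1000.0
        psi_frac = float(_psi_of_h(height_from_strain(R, eps_draws[i]),
                                   R, t_thick))
        # elastic estimate of time-to-fracture, generous margin for creep
        t_frac_est = psi_frac * E_kpa / config.pressure_ramp_rate
        t_max = 1.3 * t_frac_est + 10.0 * config.sampling_dt
        time = np.arange(0.0, t_max, config.sampling_dt)
        pressure = config.pressure_ramp_rate * time
        if config.creep_m == 0:
            psi = pressure / E_kpa
        else:
            # relative compliance growth θ chosen so that the creep-to-
            # elastic ratio at the 10 kPa reference hold matches the
            # strain-space kernel: φ(T)/ε_el = creep_m·ln(…)/ε_el(p_ref)
            h_ref = float(_h_of_psi(np.array([P_REF_KPA / E_kpa]), R, t_thick)[0])
            eps_ref = h_ref * h_ref / (R * R)
            theta = config.creep_m / eps_ref
            psi = _hereditary_psi(time, pressure, E_kpa, theta,
                                  config.creep_t0)
            if np.any(np.diff(psi) < 0):
                raise ValueError("config produces non-monotone generalised strain")
        h = _h_of_psi(psi, R, t_thick)
        strain = h * h / (R * R)

        over = np.nonzero(strain >= eps_draws[i])[0]
        if not len(over):
            raise ValueError("ramp too short to reach fracture strain")
        i_frac = int(over[0])

        # keep the ramp up to fracture, then six post-fracture samples with
        # instantaneously collapsed pressure and height
        keep = i_frac + 1
        decay = 0.35 * 0.9 ** np.arange(N_POST_FRACTURE)
        time_full = np.arange(0.0, (keep + N_POST_FRACTURE) * config.sampling_dt,
                              config.sampling_dt)[: keep + N_POST_FRACTURE]
        p_full = np.concatenate([pressure[:keep], pressure[i_frac] * decay])
        h_full = np.concatenate([h[:keep], h[i_frac] * 0.5 * 0.95 ** np.arange(N_POST_FRACTURE)])

        if config.noise_sd_pressure > 0:
            p_full = np.clip(p_full + rng.normal(0, config.noise_sd_pressure,
                                                 len(p_full)), 0, None)
        if config.noise_sd_height > 0:
            h_full = np.clip(h_full + rng.normal(0, config.noise_sd_height,
                                                 len(h_full)), 0, None)

        meta = SpecimenMeta(
            specimen_id=f"sim-{i:03d}",
            load_bearing_thickness_t=t_thick,
            failure_location="edge" if edge[i] else "center",
            orifice_diameter_D=config.orifice_D)
        specimens.append((BulgeTrace(time_full, p_full, h_full), meta))

    truth = GroundTruth(E=E_draws, eps_fracture=eps_draws,
                        edge_failure=edge, config=config)
    return specimens, truth


# ---------------------------------------------------------------------------
# Uniaxial test
# ---------------------------------------------------------------------------

_SQUARE = np.array([[-1.5, -1.5], [1.5, -1.5], [1.5, 1.5], [-1.5, 1.5]])


def simulate_uniaxial_test(config: SimulationConfig, duration: float = 300.0,
                           frame_interval: float = 15.0,
                           rng: Optional[np.random.Generator] = None
                           ) -> UniaxialTrace:
    """Simulate a uniaxial tensile test with marker photography.

    Linear axial strain ramp at ``uniaxial_strain_rate``; transverse strain
    ``−ν·ε_axial``; force proportional to axial strain; a 3 × 3 mm marker
    square deformed accordingly and photographed every ``frame_interval``
    seconds, with optional Gaussian marker noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, duration, frame_interval)
    eps_a = config.uniaxial_strain_rate * times
    eps_t = -config.nu * eps_a
    force = config.uniaxial_stiffness * eps_a

    frames = []
    for i, ti in enumerate(times):
        xy = _SQUARE * np.array([1.0 + eps_t[i], 1.0 + eps_a[i]])
        if config.noise_sd_marker > 0:
            xy = xy + rng.normal(0, config.noise_sd_marker, xy.shape)
        frames.append(DotFrame(timestamp=float(ti), marker_xy=xy,
                               pressure_or_force=float(force[i])))
    return UniaxialTrace(time=times, force_F=force, frames=tuple(frames))


# ---------------------------------------------------------------------------
# Creep-relaxation test
# ---------------------------------------------------------------------------

def simulate_creep_test(config: SimulationConfig, hold_pressure: float = 10.0,
                        hold_duration: float = 600.0,
                        load_duration: float = 20.0,
                        recovery_duration: float = 3600.0,
                        rng: Optional[np.random.Generator] = None
                        ) -> CreepTrace:
    """Simulate a load–hold–unload creep-relaxation record.

    Loading ramps the pressure linearly to ``hold_pressure`` producing
    instantaneous elastic area strain (through the cap geometry at
    ``E_inst``).  During the hold the viscoelastic strain grows as
    ``m_eff·ln(1 + T/t₀)`` with ``m_eff = creep_m·(p_hold/10 kPa)`` — the
    log-kernel creep function φ.  Unloading removes the elastic strain
    instantly; the viscoelastic part recovers by Boltzmann superposition,
    ``φ(T_hold + τ) − φ(τ)``, decaying to the plastic residual
    ``plastic_fraction × elastic strain`` accrued during the hold.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.sampling_dt
    R = config.orifice_D / 2.0
    E_kpa = config.E_inst * 1000.0

    # elastic area strain at the hold pressure, through the cap geometry
    def elastic_strain(p: np.ndarray) -> np.ndarray:
        psi = np.asarray(p, dtype=float) / E_kpa
        h = _h_of_psi(psi, R, config.thickness_t)
        return h * h / (R * R)

    m_eff = config.creep_m * hold_pressure / P_REF_KPA
    t0 = config.creep_t0

    def phi(T: np.ndarray) -> np.ndarray:
        return m_eff * np.log1p(np.maximum(T, 0.0) / t0)

    t_load = np.arange(0.0, load_duration, dt)
    t_hold = np.arange(load_duration, load_duration + hold_duration, dt)
    t_unld = np.arange(load_duration + hold_duration,
                       load_duration + hold_duration + recovery_duration, dt)

    p_load = hold_pressure * t_load / load_duration
    p_hold = np.full_like(t_hold, hold_pressure)
    p_unld = np.zeros_like(t_unld)

    eps_el_hold = float(elastic_strain(np.array([hold_pressure]))[0])
    plastic_end = config.plastic_fraction * eps_el_hold

    eps_load = elastic_strain(p_load)
    T_hold = t_hold - load_duration
    eps_hold = (eps_el_hold + phi(T_hold)
                + plastic_end * T_hold / hold_duration)
    tau = t_unld - (load_duration + hold_duration)
    eps_unld = phi(hold_duration + tau) - phi(tau) + plastic_end

    time = np.concatenate([t_load, t_hold, t_unld])
    pressure = np.concatenate([p_load, p_hold, p_unld])
    strain = np.concatenate([eps_load, eps_hold, eps_unld])
    if config.noise_sd_pressure > 0:
        pressure = np.clip(pressure + rng.normal(0, config.noise_sd_pressure,
                                                 len(pressure)), 0, None)
    if config.noise_sd_height > 0:
        # express height noise as equivalent strain noise at the hold height
        h_hold = height_from_strain(R, max(eps_el_hold, 1e-9))
        sd_eps = 2.0 * h_hold * config.noise_sd_height / (R * R)
        strain = strain + rng.normal(0, sd_eps, len(strain))
    return CreepTrace(time=time, pressure=pressure, strain=strain)


# ---------------------------------------------------------------------------
# Dot frames on the bulging cap
# ---------------------------------------------------------------------------

def generate_dot_frames_on_cap(config: SimulationConfig,
                               pressures: Sequence[float],
                               rng: Optional[np.random.Generator] = None
                               ) -> tuple[list[DotFrame], list[CapGeometry]]:
    """Simulate centre dot-pattern photographs at a series of pressures.

    For each pressure the mean area strain follows the elastic bulge model;
    the centre pattern strain is ``center_amplification_g`` times the mean,
    applied isotropically.  The photographed chord in each direction is the
    inverse arc-length correction of the stretched arc, so the analysis
    round-trips exactly.  A zero-pressure flat reference frame is prepended
    when absent.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = np.asarray(pressures, dtype=float)
    if len(p) == 0:
        raise ValueError("need at least one pressure step")
    if p[0] != 0.0:
        p = np.concatenate([[0.0], p])
    R = config.orifice_D / 2.0
    E_kpa = config.E_inst * 1000.0

    frames: list[DotFrame] = []
    geoms: list[CapGeometry] = []
    side0 = 3.0  # mm, nominal marker square
    for i, pi in enumerate(p):
        psi = pi / E_kpa
        h = 0.0 if pi == 0 else float(
            _h_of_psi(np.array([psi]), R, config.thickness_t)[0])
        geom = CapGeometry(orifice_radius_R=R, height_h=h)
        eps_mean = h * h / (R * R)
        eps_center = config.center_amplification_g * eps_mean
        lam = math.sqrt(1.0 + eps_center)  # linear stretch per direction
        b = side0 * lam                    # arc length between dots
        c = sphere_radius(config.orifice_D, h)
        if c == FLAT:
            k = b
        else:
            if b > math.pi * c:
                raise ValueError("amplified strain drives the arc beyond a "
                                 "semicircle; reduce pressure or amplification")
            k = 2.0 * c * math.sin(b / (2.0 * c))
        xy = _SQUARE * (k / side0)
        if config.noise_sd_marker > 0:
            xy = xy + rng.normal(0, config.noise_sd_marker, xy.shape)
        frames.append(DotFrame(timestamp=float(i), marker_xy=xy,
                               pressure_or_force=float(pi)))
        geoms.append(geom)
    return frames, geoms


# ---------------------------------------------------------------------------
# In-vivo strain relaxation
# ---------------------------------------------------------------------------

def simulate_relaxation(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[DotFrame, DotFrame]:
    """Marker frames before and after excision of a strained segment.

    The after-frame is the before-frame shrunk isotropically so that the
    area-based release strain equals ``in_vivo_release_strain`` exactly in
    the noise-free case.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s = config.in_vivo_release_strain
    before = _SQUARE.copy()
    after = _SQUARE / math.sqrt(1.0 + s)
    if config.noise_sd_marker > 0:
        before = before + rng.normal(0, config.noise_sd_marker, before.shape)
        after = after + rng.normal(0, config.noise_sd_marker, after.shape)
    return (DotFrame(timestamp=0.0, marker_xy=before),
            DotFrame(timestamp=1.0, marker_xy=after))
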