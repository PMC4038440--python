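"""Uniaxial tensile and marker (dot-pattern) strain analysis.

Uniaxial tests stretch a dumbbell-shaped skin strip at constant rate while
a square pattern of four surface markers (nominally 3 × 3 mm) is
photographed.  Axial and transverse strains follow from the marker
distances (``ε = Δl/l₀``); Poisson's ratio is the negative ratio of the
transverse and axial strain-vs-force slopes,

    ν = −slope(ε_transverse vs F) / slope(ε_axial vs F),

which is the standard definition and the one that reproduces the magnitude
relations of real skin (|ε_t| < |ε_a| with ν < 1).

The same dot pattern applied to the centre of a bulging cap yields local
in-plane strains once the photographed chords are corrected to arcs along
the curved surface (``geometry.arc_length``); two orthogonal strains
combine into a biaxial (area) strain via

    ε_biaxial = (1 + ε₁)(1 + ε₂) − 1.

Finally, comparing marker-quadrilateral areas before and after excising a
segment measures the in-vivo strain released on excision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .geometry import CapGeometry, arc_length, sphere_radius, FLAT

__all__ = [
    "DotFrame",
    "UniaxialTrace",
    "PoissonResult",
    "AnisotropyResult",
    "marker_strains",
    "poisson_ratio",
    "biaxial_from_orthogonal",
    "corrected_bulge_strains",
    "area_release_strain",
    "shoelace_area",
    "UniaxialTest",
    "UniaxialResults",
]


def shoelace_area(xy: np.ndarray) -> float:
    """Area of a polygon from ordered vertices (shoelace formula), mm²."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _is_convex(xy: np.ndarray) -> bool:
    n = len(xy)
    signs = []
    for i in range(n):
        a, b, c = xy[i], xy[(i + 1) % n], xy[(i + 2) % n]
        cross = (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0])
        signs.append(cross)
    signs = np.array(signs)
    return bool(np.all(signs > 0) or np.all(signs < 0))


@dataclass(frozen=True)
class DotFrame:
    """One photographed frame of the four-dot marker pattern.

    ``marker_xy`` holds the four corner coordinates (mm) in consistent
    cyclic order: (x−,y−), (x+,y−), (x+,y+), (x−,y+) for an undeformed
    square.  The y axis is the axial (or longitudinal) direction, x the
    transverse (latitudinal) one.  ``pressure_or_force`` is kPa in bulge
    context, N in uniaxial context.
    """

    timestamp: float
    marker_xy: np.ndarray  # (4, 2) mm
    pressure_or_force: float = 0.0

    def __post_init__(self) -> None:
        xy = np.asarray(self.marker_xy, dtype=float)
        if xy.shape != (4, 2):
            raise ValueError("marker_xy must be a (4, 2) array")
        if len(np.unique(xy, axis=0)) != 4:
            raise ValueError("the four markers must be distinct points")
        if not _is_convex(xy):
            raise ValueError("markers must form a convex quadrilateral")
        object.__setattr__(self, "marker_xy", xy)

    def axial_distance(self) -> float:
        """Distance between midpoints of the bottom and top edges (mm)."""
        xy = self.marker_xy
        bottom = 0.5 * (xy[0] + xy[1])
        top = 0.5 * (xy[3] + xy[2])
        return float(np.hypot(*(top - bottom)))

    def transverse_distance(self) -> float:
        """Distance between midpoints of the left and right edges (mm)."""
        xy = self.marker_xy
        left = 0.5 * (xy[0] + xy[3])
        right = 0.5 * (xy[1] + xy[2])
        return float(np.hypot(*(right - left)))

    def area(self) -> float:
        return shoelace_area(self.marker_xy)


@dataclass(frozen=True)
class UniaxialTrace:
    """Force + marker-frame record of a uniaxial tensile test."""

    time: np.ndarray
    force_F: np.ndarray           # N
    frames: tuple[DotFrame, ...]
    gauge_length_l0: float = 18.0  # clamping distance, mm

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force_F, dtype=float)
        if not (len(t) == len(f) == len(self.frames)):
            raise ValueError("time, force and frames must have equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("force must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force_F", f)
        object.__setattr__(self, "frames", tuple(self.frames))

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class PoissonResult:
    """Poisson's ratio from strain-vs-force slopes."""

    slope_axial: float       # strain per N
    slope_transverse: float  # strain per N
    nu: Optional[float]
    r2_axial: float
    r2_transverse: float
    flagged: str = ""


@dataclass
class AnisotropyResult:
    """In-plane strains of one dot frame on the bulging cap."""

    timestamp: float
    eps_longitudinal: float
    eps_latitudinal: float
    eps_biaxial_calculated: float
    isotropy_gap: float


def marker_strains(trace: UniaxialTrace) -> np.ndarray:
    """Per-frame (ε_axial, ε_transverse) from marker distances.

    The first frame defines the reference lengths ``l₀`` in both
    directions; strains are ``Δl/l₀``.  Returns an (n, 2) array.
    """
    l0_a = trace.frames[0].axial_distance()
    l0_t = trace.frames[0].transverse_distance()
    if l0_a == 0 or l0_t == 0:
        raise ValueError("reference marker distances must be nonzero")
    out = np.empty((len(trace), 2))
    for i, fr in enumerate(trace.frames):
        out[i, 0] = fr.axial_distance() / l0_a - 1.0
        out[i, 1] = fr.transverse_distance() / l0_t - 1.0
    return out


def poisson_ratio(trace: UniaxialTrace) -> PoissonResult:
    """Poisson's ratio ν = −slope_transverse/slope_axial from OLS fits.

    Both strains are regressed on force; requires at least 3 frames with
    nonzero force.  A zero axial slope leaves ν undefined (flagged).
    """
    strains = marker_strains(trace)
    F = trace.force_F
    if np.count_nonzero(F) < 3:
        raise ValueError("need at least 3 frames with nonzero force")
    la = stats.linregress(F, strains[:, 0])
    lt = stats.linregress(F, strains[:, 1])
    r2a = float(la.rvalue ** 2)
    # a perfectly constant transverse strain has zero slope and undefined r
    r2t = 0.0 if np.ptp(strains[:, 1]) == 0 else float(lt.rvalue ** 2)
    if la.slope == 0:
        return PoissonResult(0.0, float(lt.slope), None, r2a, r2t,
                             flagged="zero axial slope")
    return PoissonResult(float(la.slope), float(lt.slope),
                         -float(lt.slope) / float(la.slope), r2a, r2t)


def biaxial_from_orthogonal(eps_1: float, eps_2: float) -> float:
    """Biaxial (area) strain of two orthogonal linear strains.

    ``(1 + ε₁)(1 + ε₂) − 1`` — the area strain of a rectangle stretched by
    ε₁ and ε₂; symmetric in its arguments.
    """
    if eps_1 <= -1 or eps_2 <= -1:
        raise ValueError("strains must be > -1")
    return (1.0 + eps_1) * (1.0 + eps_2) - 1.0


def corrected_bulge_strains(frames: Sequence[DotFrame],
                            geoms: Sequence[CapGeometry]
                            ) -> list[AnisotropyResult]:
    """Curvature-corrected in-plane strains of dot frames on a bulging cap.

    The first frame must be the flat reference (h ≈ 0, zero pressure); its
    marker distances are the reference lengths ``b₀``.  For every later
    frame the photographed chord ``k`` in each direction is converted to an
    arc ``b`` on the sphere of the frame's cap geometry, and the strain is
    ``b/b₀ − 1``.  Longitudinal = axial (y), latitudinal = transverse (x).
    """
    if len(frames) != len(geoms):
        raise ValueError("need one CapGeometry per frame")
    if len(frames) < 2:
        raise ValueError("need a reference frame plus at least one loaded frame")
    ref, ref_geom = frames[0], geoms[0]
    if ref_geom.height_h > 1e-9:
        raise ValueError("first frame must be the flat (h=0) reference")
    b0_long = ref.axial_distance()
    b0_lat = ref.transverse_distance()

    results: list[AnisotropyResult] = []
    for fr, geom in zip(frames[1:], geoms[1:]):
        c = sphere_radius(geom.orifice_diameter_D, geom.height_h)
        b_long = arc_length(fr.axial_distance(), c).arc_b
        b_lat = arc_length(fr.transverse_distance(), c).arc_b
        e_long = b_long / b0_long - 1.0
        e_lat = b_lat / b0_lat - 1.0
        e_biax = biaxial_from_orthogonal(e_long, e_lat)
        denom = max(e_long, e_lat)
        gap = abs(e_long - e_lat) / denom if denom > 0 else 0.0
        results.append(AnisotropyResult(fr.timestamp, e_long, e_lat, e_biax, gap))
    return results


def area_release_strain(dots_before: DotFrame, dots_after: DotFrame) -> float:
    """In-vivo strain released on excision, from marker-quadrilateral areas.

    ``A_before/A_after − 1``: the area strain of the relaxed state needed
    to restore the attached state.  Positive when the segment shrinks.
    """
    a_before = dots_before.area()
    a_after = dots_after.area()
    if a_after == 0:
        raise ValueError("after-excision marker area is zero")
    return a_before / a_after - 1.0


class UniaxialTest:
    """Model object for one uniaxial tensile test with marker tracking."""

    def __init__(self, trace: UniaxialTrace) -> None:
        self.trace = trace

    def fit(self) -> "UniaxialResults":
        strains = marker_strains(self.trace)
        poisson = poisson_ratio(self.trace)
        return UniaxialResults(model=self, strains=strains, poisson=poisson)


@dataclass
class UniaxialResults:
    """Results of :meth:`UniaxialTest.fit`: per-frame strains + Poisson fit."""

    model: UniaxialTest
    strains: np.ndarray  # (n, 2): axial, transverse
    poisson: PoissonResult

    @property
    def nu(self) -> Optional[float]:
        return self.poisson.nu

    def summary(self) -> str:
        p = self.poisson
        nu = "undefined" if p.nu is None else f"{p.nu:.4f}"
        return "\n".join([
            "Uniaxial tensile test summary",
            f"  frames              : {len(self.strains)}",
            f"  axial slope         : {p.slope_axial:.4g} strain/N (r2={p.r2_axial:.4f})",
            f"  transverse slope    : {p.slope_transverse:.4g} strain/N (r2={p.r2_transverse:.4f})",
            f"  Poisson's ratio nu  : {nu}"
            + (f" [{p.flagged}]" if p.flagged else ""),
        ])
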