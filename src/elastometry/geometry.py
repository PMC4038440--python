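"""Spherical-cap geometry for bulge (biaxial) tensile tests.

A skin segment clamped over a circular orifice of radius ``R`` (diameter
``D = 2R``) and pressurised from below bulges outward.  Its shape is
modelled as a cap of a sphere; the cap is fully described by ``R`` and the
bulge height ``h`` measured at the centre of the orifice.

Closed forms used throughout the package (all lengths in mm):

* cap surface area          ``A = (R² + h²)·π``
* biaxial (area) strain     ``ε = ΔA/A₀ = h²/R²``
* radius of the sphere      ``c = (4h² + D²)/(8h)``
* chord-to-arc correction   ``b = 2c·arcsin(k/2c)``

where ``k`` is a chord between two surface markers (as photographed) and
``b`` the true distance along the curved surface.  The flat state ``h = 0``
has no finite sphere radius and is represented by the :data:`FLAT` sentinel
rather than an infinity, which keeps the ``b → k`` limit explicit.

The module also fits candidate meridional contour models (spherical cap,
paraboloid, axis-centred ellipse cap) to digitised ``(x, z)`` point sets
and ranks them by deviance (sum of squared residual distances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FLAT",
    "CapGeometry",
    "ArcCorrectedDistance",
    "ContourModelFit",
    "cap_area",
    "biaxial_strain_from_height",
    "height_from_strain",
    "sphere_radius",
    "arc_length",
    "fit_contour_models",
]

#: Sentinel for the flat (h = 0) state in which the osculating sphere is
#: undefined (its radius diverges).  Accepted by :func:`arc_length`.
FLAT = "flat"


@dataclass(frozen=True)
class CapGeometry:
    """Orifice radius and bulge height of a spherical-cap specimen.

    Caps beyond a full sphere of diameter ``D`` (``h > D``) are rejected as
    physically meaningless for a clamped membrane.
    """

    orifice_radius_R: float
    height_h: float

    def __post_init__(self) -> None:
        if not self.orifice_radius_R > 0:
            raise ValueError(f"orifice radius must be > 0, got {self.orifice_radius_R}")
        if self.height_h < 0:
            raise ValueError(f"bulge height must be >= 0, got {self.height_h}")
        if self.height_h > self.orifice_diameter_D:
            raise ValueError(
                f"bulge height {self.height_h} exceeds orifice diameter "
                f"{self.orifice_diameter_D}"
            )

    @property
    def orifice_diameter_D(self) -> float:
        return 2.0 * self.orifice_radius_R


@dataclass(frozen=True)
class ArcCorrectedDistance:
    """A chord ``k`` on the bulged surface with its arc-corrected length ``b``.

    ``sphere_radius_c`` is the radius of the sphere the cap belongs to, or
    :data:`FLAT` when the surface is flat (in which case ``b = k``).
    """

    chord_k: float
    sphere_radius_c: float | str
    arc_b: float


def cap_area(geom: CapGeometry) -> float:
    """Surface area (mm²) of the spherical cap, ``A = (R² + h²)·π``.

    At ``h = 0`` this reduces to the flat disc area ``πR²``; it is also
    algebraically identical to Archimedes' ``2πch`` with ``c`` from
    :func:`sphere_radius`.
    """
    R, h = geom.orifice_radius_R, geom.height_h
    return (R * R + h * h) * math.pi


def biaxial_strain_from_height(geom: CapGeometry) -> float:
    """Biaxial (area) strain ``ε = ΔA/A₀ = h²/R²`` of the bulged cap.

    Dimensionless (mm² mm⁻²); zero at ``h = 0`` and strictly increasing
    in ``h``.
    """
    R, h = geom.orifice_radius_R, geom.height_h
    return (h * h) / (R * R)


def height_from_strain(R: float, eps: float) -> float:
    """Bulge height (mm) that produces area strain ``eps``: ``h = R·√ε``.

    Inverse of :func:`biaxial_strain_from_height`; used by the simulator.
    """
    if R <= 0:
        raise ValueError(f"orifice radius must be > 0, got {R}")
    if eps < 0:
        raise ValueError(f"strain must be >= 0, got {eps}")
    return R * math.sqrt(eps)


def sphere_radius(D: float, h: float) -> float | str:
    """Radius ``c = (4h² + D²)/(8h)`` of the sphere the cap belongs to.

    Returns :data:`FLAT` for ``h = 0`` (the radius diverges; there is no
    finite sphere).  For a hemisphere (``h = D/2``) returns ``D/2``.
    """
    if D <= 0:
        raise ValueError(f"orifice diameter must be > 0, got {D}")
    if h < 0:
        raise ValueError(f"bulge height must be >= 0, got {h}")
    if h == 0:
        return FLAT
    return (4.0 * h * h + D * D) / (8.0 * h)


def arc_length(k: float, c: float | str) -> ArcCorrectedDistance:
    """Arc length ``b = 2c·arcsin(k/2c)`` subtended by a chord ``k``.

    ``c`` may be :data:`FLAT`, in which case ``b = k`` (the flat limit).
    A chord longer than the sphere diameter (``k > 2c``) is a domain error;
    ``k = 2c`` gives the semicircle ``b = πc``.
    """
    if k < 0:
        raise ValueError(f"chord must be >= 0, got {k}")
    if c == FLAT:
        return ArcCorrectedDistance(chord_k=k, sphere_radius_c=FLAT, arc_b=k)
    c = float(c)
    if c <= 0:
        raise ValueError(f"sphere radius must be > 0, got {c}")
    if k > 2.0 * c:
        raise ValueError(f"chord {k} exceeds sphere diameter {2 * c}")
    b = 2.0 * c * math.asin(k / (2.0 * c))
    return ArcCorrectedDistance(chord_k=k, sphere_radius_c=c, arc_b=b)


# ---------------------------------------------------------------------------
# Contour model fitting
# ---------------------------------------------------------------------------

#: Parameter counts used for tie-breaking in the deviance ranking.
_N_PARAMS = {"spheroid": 2, "paraboloid": 2, "ellipsoid": 3}

#: Deviances within this absolute band, or within _TIE_REL of the minimum,
#: are considered tied and broken by fewer parameters.  The relative band
#: reflects that the candidate models are (partially) nested: an extra
#: parameter always shaves a little residual off noisy data, so differences
#: within a few percent carry no evidence about the generating shape.
_TIE_TOL = 1e-10
_TIE_REL = 0.05


@dataclass
class ContourModelFit:
    """One candidate contour model fitted to digitised meridional points.

    ``deviance`` is the sum of squared residual distances (mm²): orthogonal
    distances for the spheroid and ellipsoid, vertical distances for the
    paraboloid.  Exactly one model in a ranking carries ``best=True``.
    """

    model_name: str
    parameters: np.ndarray
    deviance: float
    n_points: int
    success: bool = True
    message: str = ""
    best: bool = field(default=False, compare=False)


def _fit_spheroid(x: np.ndarray, z: np.ndarray) -> ContourModelFit:
    """Circle of revolution with centre on the bulge axis: params (z0, r)."""
    # Kasa-style linear initialisation with the centre constrained to x = 0:
    # x² + z² = 2·z0·z + (r² − z0²)
    A = np.column_stack([2.0 * z, np.ones_like(z)])
    rhs = x * x + z * z
    (z0, d), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    r2 = d + z0 * z0
    if r2 <= 0:
        return ContourModelFit("spheroid", np.array([z0, 0.0]), math.inf,
                               len(x), success=False, message="degenerate circle fit")
    r0 = math.sqrt(r2)

    def resid(p: np.ndarray) -> np.ndarray:
        return np.hypot(x, z - p[0]) - p[1]

    sol = least_squares(resid, x0=np.array([z0, r0]), method="lm")
    dev = float(np.sum(sol.fun ** 2))
    return ContourModelFit("spheroid", sol.x, dev, len(x), success=sol.success)


def _fit_paraboloid(x: np.ndarray, z: np.ndarray) -> ContourModelFit:
    """Paraboloid section ``z = z0 − a·x²``: params (z0, a), vertical residuals."""
    A = np.column_stack([np.ones_like(x), -(x * x)])
    try:
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    except np.linalg.LinAlgError:
        return ContourModelFit("paraboloid", np.zeros(2), math.inf, len(x),
                               success=False, message="singular design matrix")
    resid = z - A @ coef
    return ContourModelFit("paraboloid", coef, float(np.sum(resid ** 2)), len(x))


def _ellipse_point_distances(x: np.ndarray, z: np.ndarray,
                             z0: float, a: float, bz: float) -> np.ndarray:
    """Orthogonal distances from points to the ellipse x²/a² + (z−z0)²/bz² = 1.

    Per-point minimisation over the ellipse parameter angle: coarse grid
    followed by golden-section refinement.  Adequate for digitised contours
    (tens to hundreds of points).
    """
    theta = np.linspace(0.0, 2.0 * math.pi, 256, endpoint=False)
    ex = a * np.cos(theta)  # (256,)
    ez = z0 + bz * np.sin(theta)
    d2 = (x[:, None] - ex[None, :]) ** 2 + (z[:, None] - ez[None, :]) ** 2
    i_best = np.argmin(d2, axis=1)
    lo = theta[i_best] - (theta[1] - theta[0])
    hi = theta[i_best] + (theta[1] - theta[0])
    # vectorised golden-section refinement
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    for _ in range(40):
        m1 = hi - invphi * (hi - lo)
        m2 = lo + invphi * (hi - lo)

        def d2_at(t: np.ndarray) -> np.ndarray:
            return (x - a * np.cos(t)) ** 2 + (z - z0 - bz * np.sin(t)) ** 2

        take_lo = d2_at(m1) < d2_at(m2)
        hi = np.where(take_lo, m2, hi)
        lo = np.where(take_lo, lo, m1)
    t = 0.5 * (lo + hi)
    return np.sqrt((x - a * np.cos(t)) ** 2 + (z - z0 - bz * np.sin(t)) ** 2)


def _fit_ellipsoid(x: np.ndarray, z: np.ndarray,
                   init: np.ndarray | None) -> ContourModelFit:
    """Axis-aligned, axis-centred ellipse cap: params (z0, a, bz).

    The centre is constrained to the bulge axis (x = 0); whether the source
    fits did so is unknown, so this is a documented assumption.
    """
    if init is None:
        span = max(np.ptp(x), 1.0)
        init = np.array([float(np.mean(z)), span, span])

    def resid(p: np.ndarray) -> np.ndarray:
        z0, a, bz = p
        if a <= 0 or bz <= 0:
            return np.full_like(x, 1e6)
        return _ellipse_point_distances(x, z, z0, a, bz)

    try:
        sol = least_squares(resid, x0=init, method="lm", max_nfev=200)
    except Exception as exc:  # pragma: no cover - defensive
        return ContourModelFit("ellipsoid", init, math.inf, len(x),
                               success=False, message=str(exc))
    dev = float(np.sum(sol.fun ** 2))
    ok = sol.success and np.isfinite(dev)
    return ContourModelFit("ellipsoid", sol.x, dev if ok else math.inf,
                           len(x), success=ok,
                           message="" if ok else "ellipse fit failed")


def fit_contour_models(points: np.ndarray) -> list[ContourModelFit]:
    """Fit spheroid, paraboloid and ellipsoid models to a meridional contour.

    Parameters
    ----------
    points
        ``(n, 2)`` array of ``(x, z)`` coordinates in mm, the bulge axis at
        ``x = 0`` and at least 5 points spanning the orifice.

    Returns
    -------
    list of :class:`ContourModelFit`, best (minimum deviance) first.
    Deviances tied within 1e-10 are ranked by fewer parameters.  Degenerate
    inputs yield per-model failure flags (infinite deviance), never a crash.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, z) coordinates")
    if len(pts) < 5:
        raise ValueError(f"need at least 5 contour points, got {len(pts)}")
    x, z = pts[:, 0], pts[:, 1]

    sph = _fit_spheroid(x, z)
    par = _fit_paraboloid(x, z)
    ell_init = (np.array([sph.parameters[0], sph.parameters[1], sph.parameters[1]])
                if sph.success else None)
    ell = _fit_ellipsoid(x, z, ell_init)

    fits = [sph, par, ell]
    fits.sort(key=lambda f: (f.deviance, _N_PARAMS[f.model_name]))
    # tie-break pass: among fits within _TIE_TOL of the minimum, fewest params
    finite = [f for f in fits if math.isfinite(f.deviance)]
    if finite:
        dmin = finite[0].deviance
        band = max(_TIE_TOL, _TIE_REL * dmin)
        tied = [f for f in finite if f.deviance - dmin <= band]
        winner = min(tied, key=lambda f: _N_PARAMS[f.model_name])
        fits.remove(winner)
        fits.insert(0, winner)
        winner.best = True
    return fits
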