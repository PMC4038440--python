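# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not show
about real fruit skin.

## Geometry model

The bulging skin segment is treated as a spherical cap over a circular
orifice of radius `R` (diameter `D = 2R`). All geometric quantities are
closed forms in `R` and the centre height `h`: area `A = (R² + h²)π`,
biaxial (area) strain `ε = h²/R²`, sphere radius `c = (4h² + D²)/(8h)`,
and the chord→arc correction `b = 2c·arcsin(k/2c)`. Units are mm, mm²,
kPa, with moduli reported in MPa. The flat state `h = 0` is represented
by an explicit `FLAT` sentinel rather than an infinite sphere radius,
which avoids overflow and makes the `b → k` flat limit a testable code
path.

The cap assumption itself is checked by `fit_contour_models`, which fits
a circle-of-revolution ("spheroid", 2 parameters: axial centre offset and
radius), a paraboloid section `z = z₀ − a·x²` (2 parameters, vertical
residuals) and an axis-aligned, axis-centred ellipse cap (3 parameters)
to digitised meridional contours, ranking them by deviance (sum of
squared orthogonal residual distances; vertical for the paraboloid, the
standard choice for a graph-form model). Because the ellipse nests the
circle, raw deviance on noisy data always favours the ellipse by a margin
comparable to one residual degree of freedom; the ranking therefore
treats deviances within 5 % of the minimum (or 1e-10 absolute) as tied
and prefers the model with fewer parameters. Ellipse point distances are
computed by per-point golden-section minimisation over the parameter
angle — slow-but-robust, and adequate for digitised contours of tens to
hundreds of points. The centre of the ellipse is constrained to the bulge
axis; whether reference fits imposed that constraint is unknown, so it is
a documented assumption.

## Bulge-test reduction

The apparent modulus formula `E = p·R²·(R²+h²)/(2h³t)` is implemented
verbatim, including the factor 2 in the denominator (a thin-shell σ/ε
derivation would put a 4 there; the printed form is the community
convention for this instrument and is not "corrected"). `t` defaults to
0.1 mm — the load-bearing epidermis-plus-hypodermis layer — regardless of
how much flesh adheres to the segment, because the flesh carries almost
no load.

One modulus per specimen is reported as the **median of pointwise E(t)
over the plateau**, where the plateau is every pre-fracture sample with
`ε ≥ plateau_strain_min` (default 0.02). The early-transient gate removes
the start-up artifact real records show before the modulus settles; the
median is robust to isolated spikes. Both the gate and the fracture
thresholds are configuration knobs, since their exact values are
conventions rather than physics.

Fracture is the last sample before the first pressure decrease exceeding
`drop_fraction` (default 0.2) of the current pressure between consecutive
samples, considered only once pressure has reached `min_pressure`
(default 5 kPa). The floor exists because the relative-drop criterion is
ill-posed near zero pressure where sensor noise dominates; every
plausible fracture pressure for these tissues is an order of magnitude
above it. Post-fracture samples are retained in the trace but excluded
from every fit. Specimens recorded as failing at the orifice edge are
flagged `excluded` (mounting artifact) and dropped by
`filter_edge_failures`; exclusions are labelled, never silent.

A note on linearity: a constant-modulus cap follows
`p = E·ψ(h)` with `ψ = 2h³t/(R²(R²+h²))`, which in terms of area strain
is `p ∝ ε^{3/2}/(1+ε)`. A pressure–strain line fitted to such a record
has r² ≈ 0.99 over the strain range to fracture — close to, but not
exactly, linear. The reported `pressure_strain_r2` quantifies this per
specimen.

## Uniaxial and marker analysis

Marker strains use the Euclidean distances between opposite-edge
midpoints of the four-dot quadrilateral (robust to slight trapezoid
distortion); areas use the shoelace formula on the convexity-checked
vertices. Poisson's ratio is `ν = −slope_t/slope_a` from OLS fits of the
transverse and axial strains against force — the standard definition,
and the one consistent with `|ε_t| < |ε_a|` for ν < 1. Dot-pattern
strains on the bulging cap are corrected chord→arc per frame using that
frame's own height (rather than a single end-point height), and two
orthogonal strains combine multiplicatively into the biaxial strain.
In-vivo strain released on excision is `A_before/A_after − 1`: the strain
of the relaxed state needed to restore the attached state.

## Creep-relaxation analysis

Pressure, the controlled variable, defines the phase boundaries: loading
until the first sample within `tol` of the hold level, holding until the
first **persistent** drop below `hold_level − tol` (default 3 consecutive
samples, so an isolated noise dip cannot end a 10-minute hold), then
unloading and recovery. The partition is operational: elastic =
instantaneous strain at the end of loading; plastic = residual at the
end of the recovery window (default: last sample — irrecoverable within
the observation, exactly as a real experiment defines it); viscoelastic =
remainder. The identity elastic + viscoelastic + plastic = end-of-hold
strain holds exactly on every input by construction.

The log-time fit regresses hold strain on `ln(T + t₀)` with `T` rebased
to the hold start and `t₀` defaulting to the first sample interval — an
unavoidable regularisation of `ln(0)`, configurable. A constant hold
strain is degenerate and reported as slope 0, r² 0, with a flag.

## Synthetic specimen generator

The generator's job is to emulate what the instrument records, with known
ground truth:

- **Bulge cohorts.** `p(t)` is a linear ramp (default 0.25 kPa/s,
  reaching typical fracture pressures in ~3–4 minutes at 1 Hz sampling).
  The constitutive model is defined on the generalised strain
  `ψ(h) = 2h³t/(R²(R²+h²))`, so that `p = E·ψ` makes the analysis
  pipeline's pointwise modulus recover the generator's `E` to machine
  precision in the elastic limit — the inverse-formula round trip that
  anchors the whole verification strategy. Viscoelasticity enters through
  the creep compliance `J(u) = (1/E)(1 + θ·ln(1 + u/t₀))` in a Boltzmann
  hereditary integral discretised by the trapezoid rule; `h` is recovered
  from ψ by bisection (80 iterations, ~1e-12 mm accuracy) on the strictly
  monotone ψ(h). Per-specimen `E` and fracture strain are normal draws
  (fracture strain truncated at 0.01); edge failures are independent
  Bernoulli events; Gaussian measurement noise is added to pressure and
  height. Six post-fracture samples with collapsed pressure/height are
  appended, as real records show.
- **Creep records** use the same logarithmic kernel, but applied directly
  in area-strain space: hold strain is `ε_el + m_eff·ln(1 + T/t₀)` with
  `m_eff = creep_m·(p_hold/10 kPa)`, and recovery follows the kernel's own
  superposition `φ(T_hold + τ) − φ(τ)`, decaying to the plastic residual.
  The reason for the strain-space formulation here is geometric: because
  `ε ≈ ψ^{2/3}` locally, pushing the hereditary integral through the cap
  geometry would bend the hold-phase log-line and make the fitted slope
  systematically unequal to the generating one; defining the kernel on the
  observable keeps the generator's `creep_m` exactly recoverable. The two
  formulations are tied together by calibrating the ψ-space θ so that the
  creep-to-elastic ratio matches the strain-space kernel at the 10 kPa
  reference hold. **Units of `creep_m`:** hold-phase area strain per
  ln(second) at a 10 kPa hold; at other hold pressures the slope scales
  linearly with pressure.
- **Uniaxial records**: linear axial strain ramp at 0.00278 s⁻¹ (3 mm/min
  on an 18 mm gauge), `ε_t = −ν·ε_a`, force proportional to axial strain
  (10 N per unit strain, matching a 10 N load cell at fracture strains),
  marker frames every 15 s.
- **Dot frames on the cap**: centre-pattern strain =
  `center_amplification_g` × the height-derived mean strain (default
  2.16), applied isotropically; the photographed chord is the exact
  inverse of the arc correction so the analysis round-trips. The
  amplification factor is a simulator parameter describing the observed
  centre-vs-mean strain gradient, not a quantity derived from membrane
  mechanics.
- **Relaxation frames**: the after-excision frame is the before-frame
  shrunk isotropically so the area-based release strain equals
  `in_vivo_release_strain` (default 0.155) exactly in the noise-free case.

Presets in `presets.yaml` encode published cohort summaries (season
cohorts, the maintained/released in-vivo-strain contrast, other fruit
species) as generator parameters. For the maintained/released presets the
per-specimen `E` and fracture strain are drawn from the printed
means/CVs; the fracture pressure is *emergent* through the modulus
formula and comes out nearly equal between the two arms (≈44 vs ≈46 kPa),
which is exactly the observed contrast pattern (stiffness and fracture
strain differ, fracture pressure does not). Those preset cohorts are
generated without edge failures, reading the published replicate counts
as post-exclusion sizes.

What the generator does **not** emulate: the strain-field gradient across
the cap (only its centre amplification summary), piston/oil mechanics
(pressure is ramped directly), temperature and water relations, drift or
autocorrelated sensor noise, and any nonlinear (strain-hardening)
elasticity. Passing recovery tests therefore demonstrates that the
analysis correctly inverts the stated model under realistic noise — not
that real skin obeys that model.

## Problem sizes and tolerances

Cohort tests use n = 84 specimens (season-cohort size), 10 per arm for
the maintained/released contrast, 500 for the edge-exclusion binomial
check, and 1000 null simulations for the type-I-error calibration of the
two-group comparison (accepted band 0.03–0.07 at α = 0.05). Geometry
closed forms are checked against independent numerical oracles
(surface-of-revolution quadrature to 1e-9 relative, polyline arc length
to 1e-6, strain/height round trip to 1e-12). Statistical recovery
tolerances follow the sampling variability of the corresponding design
(e.g. cohort mean fracture strain within ±0.01 of the generating mean).

## Known limitations

- The apparent modulus is formula-defined and instrument-specific; it is
  not a material constant, and its printed factor-2 convention is kept.
- Contour model selection is parsimony-with-tie-band, not a formal
  information criterion; with very noisy contours the 5 % band is a
  heuristic.
- The operational plastic strain depends on the recovery window: with a
  log-kernel, viscoelastic recovery is slow, so a short window inflates
  the apparent plastic residual (the default 3600 s window keeps it below
  1e-3 for the default creep settings).
- Welch's t-test is used for all two-group comparisons (the
  pooled-variance variant is never assumed); multi-group comparisons use
  one-way ANOVA with Tukey HSD and a greedy compact-letter display.
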