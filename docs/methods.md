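# Methods

## Scope and intended use

`equivsquare` supports manual (second-check) output estimates for shaped
electron fields at the *nominal* depth of maximum dose — the d_max of the
10 × 10 cm field for the given energy — with field sizes defined in a single
SSD plane (95 cm by the Elekta convention; the library never converts
between SSD planes, applies inverse-square or air-gap corrections, or
computes depth-dose curves). It is a desk-calculation tool, not a dose
engine: no Monte Carlo, no heterogeneities, no oblique incidence.

## The pencil-beam model

Fermi–Eyges small-angle multiple-scattering theory gives a Gaussian lateral
kernel at depth z whose second moment is set by

    A2(z) = (1/4) ∫₀^z (z − z′)² T(z′) dz′   [cm²],

with T(z) the linear scattering power (rad²/cm). Integrating the kernel
over the aperture opening, and dividing out the prefactor (mass stopping
power × incident fluence) that cancels in every ratio used here, yields the
normalized dose in [0, 1]:

| aperture            | normalized central-axis dose        |
|---------------------|-------------------------------------|
| square, side X      | erf²(X / 4√A2)                      |
| rectangle L × W     | erf(L / 4√A2) · erf(W / 4√A2)       |
| circle, radius R    | 1 − exp(−R² / 4A2)                  |
| star-convex, R(θ)   | (1/2π) ∫₀^{2π} 1 − e^{−R(θ)²/4A2} dθ |

Assumptions inherited from the model: uniform incident fluence across the
opening, small-angle scattering only (no large-angle or bremsstrahlung
tails), a single effective A2 at the evaluation depth, and evaluation at
points strictly inside the aperture (the polar decomposition is invalid
outside; the library raises rather than guessing an extension there).

### The A2 parameter

A2 is energy- and depth-dependent and is rarely known precisely from
commissioning data, so it is always an explicit input — either a direct
value in cm² or a sampled T(z) curve integrated as above. Illustrative
values spanning clinical electron beams at d_max: roughly 0.05 cm²
(~15 MeV) to 1.0 cm² (~6 MeV). Everything that matters clinically (the
1.83 rule, the square-root rule, table interpolation) is deliberately
A2-free; A2 only enters the exact equivalence solver, the synthetic
fixtures and the profile/chamber calculations.

## Circle ↔ square equivalence

Equating the circle and square closed forms gives the exact relation

    R² = −4 A2 · ln[1 − erf²(X / 4√A2)].

Its asymptotics bound the ratio X/R for every A2: X → 2R as A2 → 0 (the
circumscribed square) and X → √π·R as A2 → ∞ (the equal-area square). The
clinical rule X = 1.83 R sits roughly midway between 1.7725 and 2 and is
hard-coded as the published constant rather than re-derived (its derivation
averaged equivalences over commissioned Monte Carlo output tables that are
not distributable); the exact solver is provided alongside so users can see
the A2-dependence the constant averages away. Note the bound's lower limit
is √π ≈ 1.7725, the analytic equal-area limit — some renderings print it as
"π", which cannot be a lower bound of a quantity that never exceeds 2.

Numerics: 1 − erf²(w) underflows in double precision near w ≈ 6 while the
equivalence must be evaluated at w of several hundred (small A2). The
implementation uses the exact identity
ln(1 − erf²w) = −w² + ln erfcx(w) + ln(1 + erf w), stable for all w > 0.
The inverse problem (square for a given circle) is solved by Brent's method
on the bracket [√π·R, 2R], which the limits guarantee contains the root;
tolerance 1e−13 in X.

### Accuracy of the 1.83 rule inside this model

The rule's relative dose error depends only on R/√A2. Over A2 ∈ [0.05, 1.0]
cm² and R ∈ [1.1, 5.5] cm the worst case is 4.9% (at the smallest R/√A2 ≈
1.1); the error falls below 1% for R ≳ 2.6·√A2 and is negligible for large
fields. These are properties of the pencil-beam surrogate, not measured
clinical accuracy: published Monte Carlo validation of the rule (which this
package does not and cannot reproduce without a commissioned planning
system) found agreement within 1% across energies and applicators. The
surrogate's worst cases sit exactly where its own small-field warnings fire.

## Output estimation workflow

Tables are piecewise-linear interpolated in side length, exact at the
knots, with **no extrapolation** — a request outside the commissioned range
raises, as reading past the edge of a paper table should. The interpolation
scheme is a package choice (clinical practice reads commissioning tables
by hand and does not prescribe one). Equivalent squares are carried at full
precision internally and rounded half-up to 0.1 cm for reporting;
estimated/measured ratios are reported to 3 decimals, matching clinical
charting practice.

"Best-fit circle" for an irregular cutout is defined here as the
**equal-area circle centered at the area centroid**: deterministic,
idempotent, and consistent with the large-A2 limit of the equivalence. (In
clinical practice such circles are often drawn by eye; any documented
convention beats an undocumented one.) Star-convexity of polygon cutouts is
validated on a 720-ray fan — each ray from the reference point must cross
the boundary exactly once.

Validity warnings (never errors) use the field's equivalent circular radius
R:

* `NO_LATERAL_EQUILIBRIUM` when R ≤ 0.88·√E_p,0 cm (E_p,0 the most probable
  surface energy in MeV) — the standard lateral scatter-equilibrium radius.
  The criterion is sometimes printed without the square root; the square-
  root form is the dimensionally standard one and is what is implemented.
* `PDD_SHIFT_GT_2PCT` when R ≤ 1.8 cm for 6–15 MeV beams — the depth-dose
  curve shifts toward the surface and the dose at the nominal d_max can be
  more than ~2% below the true maximum. At 6 MeV the shift stays under 2%
  down to R = 1.2 cm, so the warning is suppressed for 6 MeV when R > 1.2.

When the warned-about conditions apply, a depth-dose correction from
nominal d_max to the prescription depth may be needed; the package warns
and estimates anyway, it does not correct.

One charted clinical case (R = 2.0 cm, estimated 0.846, measured 0.836)
prints a ratio of 0.988 although 0.846/0.836 = 1.012; the other cases are
consistent with estimated/measured. The package always computes
estimated/measured and does not reproduce that inverted entry.

## Chamber volume-averaging correction

A plane-parallel chamber of collecting radius R_c reads the area average of
an axisymmetric profile f(r) (normalized to f(0) = 1), so the central-axis
dose is the reading times

    CF = [ (2/R_c²) ∫₀^{R_c} r f(r) dr ]⁻¹ .

Profiles arrive as sampled data; f is linearly interpolated and the moment
integral evaluated in closed form per segment, so the only approximation is
the interpolation itself (flat profile → CF = 1 exactly; linear profile
f = 1 − b·r → CF = 1/(1 − 2bR_c/3) to machine precision). The correction is
purely radial: no chamber depth extent, no perturbation or fluence
corrections.

## Numerical choices

* **Polar quadrature** (arbitrary apertures): adaptive quadrature with
  relative tolerance 1e−10 per smooth piece. Polygon boundaries kink R(θ)
  at vertex directions, so the circle [0, 2π) is split at the vertex angles
  seen from the evaluation point and each wedge integrated separately;
  agreement with the circle/square closed forms is better than 1e−8 in
  practice (tested at 1e−6).
* **A2 from T(z)**: linear interpolation of T makes the integrand piecewise
  cubic; 2-point Gauss–Legendre per segment integrates it exactly. Depths
  beyond the curve raise rather than extrapolate.
* **Degenerate inputs**: zero-area polygons, non-simple polygons,
  non-star-convex polygons (about the requested point), non-positive sizes,
  evaluation points outside the aperture, and table/profile requests out of
  range all raise typed exceptions (`GeometryError`, `RangeError`,
  `TableFormatError`) rather than returning garbage.
* **Rounding for reports**: decimal half-up (ties away from zero), because
  clinical charts round 11.895 to 11.9; Python's default banker's rounding
  would chart some ties differently.

## Synthetic fixtures: what they do and do not show

`synth_output_table` builds a square-cutout table as
se(X) = D_sq(X; A2) / D_sq(10; A2) on sides 2.0–10.0 cm in 0.5 cm steps
(the span over which square cutouts are commissioned), normalized to the
10 cm reference per the output-factor convention, with optional
multiplicative lognormal noise (default 0; ~0.003 fractional SD emulates
good measurement repeatability). `synth_circle_polygon` samples a circle at
n equally spaced angles with optional Gaussian radial jitter, emulating a
hand-cut aperture. All randomness flows through explicit integer seeds and
identical seeds give byte-identical CSV output.

These fixtures are internally consistent with the engine by construction.
Tests passing on them therefore demonstrate that the *workflow* (geometry →
equivalence → interpolation → report) is correct and that the rules are
exact or near-exact inside the pencil-beam model; they do not demonstrate
agreement with measured linac data, which depends on beam-model features
(energy spectra, applicator scatter, bremsstrahlung) the surrogate lacks.

## Known limitations

* Single-plane geometry: no SSD projection, no island/multi-hole apertures,
  no DICOM-RT block parsing.
* The polar dose form is restricted to interior points of star-convex
  apertures; near-edge and exterior behaviour of the pencil-beam model is
  not represented.
* The 1.83 rule's clinical accuracy claims rest on external Monte Carlo /
  measurement evidence; this package can only verify its behaviour inside
  the Fermi–Eyges surrogate (see accuracy section above).
* The chamber correction ignores the chamber's depth extent and assumes an
  axisymmetric profile.
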