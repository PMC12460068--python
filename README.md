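# equivsquare

Manual second checks of electron-beam monitor units need the output factor
(dose per MU at the nominal d_max, relative to the 10 × 10 cm reference
field) of the clinical cutout — but clinics only commission output tables
for *square* cutouts. Many real cutouts are circular or nearly so.
`equivsquare` is a small library + CLI for medical physicists that turns an
aperture description into an output estimate:

* **circles** — the equivalent-square rule **X = 1.83 R**, then table
  interpolation;
* **rectangles** — the square-root rule
  `Se(L×W) = sqrt(Se(L×L) · Se(W×W))`;
* **irregular (star-convex) cutouts** — reduce to the equal-area circle,
  then the circle rule;
* small-field validity warnings (loss of lateral scatter equilibrium,
  depth-dose shift at the nominal d_max) attached to every estimate;
* the plane-parallel-chamber volume-averaging correction
  `CF⁻¹ = (2/R_c²) ∫₀^{R_c} r f(r) dr` for measuring peaked small-field
  profiles.

## The model

Under Fermi–Eyges small-angle scattering theory the lateral spread at depth
z is Gaussian with a single parameter
`A₂(z) = ¼ ∫₀^z (z−z′)² T(z′) dz′` (cm², with T the linear scattering
power). Relative to a broad field, a centered square of side X delivers
`erf²(X / 4√A₂)` on the axis, and a circle of radius R delivers
`1 − exp(−R² / 4A₂)`. Equating the two gives the exact equivalence

```
R² = −4 A₂ · ln[1 − erf²(X / 4√A₂)]
```

whose ratio X/R is pinned between **√π** (equal-area square, large A₂) and
**2** (circumscribed square, small A₂) for *any* beam — the constant 1.83
sits midway and removes the need to know A₂ at all. The package provides
both the practical rule and the exact A₂-dependent solver (with a
numerically stable log-tail evaluation good to arbitrarily small A₂), plus
the generic polar-quadrature dose
`(1/2π) ∮ [1 − exp(−R(θ)²/4A₂)] dθ` for arbitrary star-convex apertures.

Because commissioning tables are clinic property, a fixtures module
generates synthetic output tables and near-circular polygon cutouts from
the same model, so the whole workflow is testable without external data.

## Worked example

Generate a synthetic 9 MeV commissioning table (A₂ = 0.2 cm², sides
2–10 cm) and check a circular 1.5 cm-radius cutout against a measured
output of 0.940:

```
$ equivsquare synth-table --a2 0.2 --out table.csv
$ equivsquare estimate --table table.csv --shape circle --radius 1.5 --measured 0.940
method: circle_rule
equivalent square: 2.7450 cm (reported 2.7 cm)
estimated output Se = 0.9349
measured Se = 0.9400; estimated/measured = 0.995
warning: NO_LATERAL_EQUILIBRIUM
warning: PDD_SHIFT_GT_2PCT
```

The circle was mapped to a 1.83 × 1.5 = 2.745 cm equivalent square and the
table interpolated there: the estimate agrees with the measurement to 0.5%.
Both warnings fire because R = 1.5 cm is below the lateral-equilibrium
radius 0.88·√9 ≈ 2.6 cm and below the 1.8 cm radius under which the
depth-dose at the nominal d_max can sag by more than ~2% — i.e. the
estimate is arithmetically fine but a depth-dose correction or a
measurement is advisable.

The exact equivalence shows what the 1.83 rule averages away:

```
$ equivsquare equivsq --radius 2.0 --a2 0.2
circle radius R = 2 cm
rule equivalent square X = 1.83 R = 3.6600 cm (reported 3.7 cm)
exact equivalent square (A2 = 0.2 cm^2): 3.7079 cm (X/R = 1.8540)
```

and the chamber correction for a measured small-field profile:

```
$ equivsquare cf --profile prof.csv --chamber-radius 0.25
CF = 1.01478  (CF - 1 = 1.478%)
```

i.e. a 5 mm-diameter plane-parallel chamber under-reads this profile by
about 1.5%, and the central-axis dose is the chamber reading times CF.

Every subcommand (`equivsq`, `estimate`, `sqrt-rule`, `cf`, `curves`,
`synth-table`, `synth-polygon`) accepts `--json` for machine-readable
output; the same functionality is available as a library (`import
equivsquare`).

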