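"""Synthetic inputs generated from the Fermi-Eyges engine.

Commissioned output-factor tables and hand-drawn cutout contours are clinic
property; this module fabricates physically plausible stand-ins from the
pencil-beam model itself so the whole estimation workflow can be exercised
and tested without external data.

A synthetic table normalizes the square-field dose to a reference side
(10 cm, matching the 10 x 10 output-factor convention), optionally perturbed
by multiplicative lognormal noise to emulate measurement scatter; a
fractional standard deviation of ~0.003 is typical of well-run cutout
commissioning. Synthetic 'circular' cutouts are polygons sampled on a circle
with optional Gaussian radial jitter, emulating a hand-cut aperture. All
randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aperture import Aperture
from .engine import dose_square
from .output import OutputFactorTable

__all__ = ["SyntheticTableSpec", "synth_output_table", "synth_circle_polygon"]


def _default_sides() -> tuple[float, ...]:
    return tuple(np.arange(2.0, 10.0 + 1e-9, 0.5))


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Recipe for a synthetic square-cutout output-factor table.

    Sides default to 2.0-10.0 cm in 0.5 cm steps, the span over which square
    cutouts are commissioned in practice; ``a2_cm2`` sets the lateral spread
    (0.05-1.0 cm^2 is realistic for 6-15 MeV at d_max).
    """

    a2_cm2: float
    sides: tuple[float, ...] = field(default_factory=_default_sides)
    reference_side: float = 10.0
    energy_label: float = 9.0
    applicator_label: str = "10x10"
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not self.a2_cm2 > 0:
            raise ValueError("a2_cm2 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (min(self.sides) <= self.reference_side <= max(self.sides)):
            raise ValueError("reference_side must lie within the sides range")


def synth_output_table(spec: SyntheticTableSpec) -> OutputFactorTable:
    """Build an OutputFactorTable with se(X) = D_sq(X; A2) / D_sq(ref; A2).

    With ``noise_sd`` > 0, each entry is multiplied by an independent
    lognormal factor of that fractional standard deviation, reproducibly
    under ``spec.seed``; noiseless tables satisfy se(reference_side) = 1
    exactly.
    """
    ref = dose_square(spec.reference_side, spec.a2_cm2)
    sides = tuple(sorted(float(s) for s in spec.sides))
    ses = np.array([dose_square(s, spec.a2_cm2) / ref for s in sides])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = math.sqrt(math.log1p(spec.noise_sd**2))
        ses = ses * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(ses))
    return OutputFactorTable(
        energy=float(spec.energy_label),
        applicator=spec.applicator_label,
        entries=tuple(zip(sides, (float(v) for v in ses))),
        reference_note=(
            f"synthetic Fermi-Eyges table, A2={spec.a2_cm2:g} cm^2, "
            f"ref side {spec.reference_side:g} cm, noise_sd={spec.noise_sd:g}, "
            f"seed={spec.seed}"
        ),
    )


def synth_circle_polygon(
    R: float, n_vertices: int = 64, jitter_sd: float = 0.0, seed: int = 0
) -> Aperture:
    """Polygon sampled on a circle of radius R, optionally radially jittered.

    Emulates a hand-fabricated 'circular' cutout: ``n_vertices`` equally
    spaced angles with vertex radius R + N(0, jitter_sd^2). With no jitter
    and n >= 256 the equal-area circle recovers R to better than 0.1% (an
    inscribed n-gon is smaller by the factor sqrt((n/2pi) sin(2pi/n))).
    """
    if n_vertices < 8:
        raise ValueError("n_vertices must be >= 8")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    radii = np.full(n_vertices, float(R))
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        radii = radii + rng.normal(0.0, jitter_sd, size=n_vertices)
    if (radii <= 0).any():
        raise ValueError("jitter produced a non-positive vertex radius; reduce jitter_sd")
    verts = [(float(r * math.cos(a)), float(r * math.sin(a))) for r, a in zip(radii, angles)]
    return Aperture.polygon(verts)
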