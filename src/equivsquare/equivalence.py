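"""Circle <-> square field equivalence under the Fermi-Eyges model.

Setting the closed-form central-axis dose of a centered circle equal to that
of a centered square gives the exact equivalence

    R^2 = -4 A2 * ln[1 - erf^2( X / (4 sqrt(A2)) )],

so the exact equivalent square depends on the lateral-spread parameter A2.
Its two asymptotic limits bound the ratio X/R for every A2:

* A2 -> 0 (sharp pencil beams): X -> 2R, the circumscribed square;
* A2 -> infinity (broad scatter): X -> sqrt(pi) R, the equal-area square.

The practical clinical rule X = 1.83 R sits roughly midway between those
bounds (sqrt(pi) ~ 1.7725 and 2) and is used as-is for output estimation;
the exact solver is provided alongside so the A2-dependence the constant
averages away can be inspected (e.g. as ratio curves over an A2 grid).

Numerical care: 1 - erf^2(w) underflows for w >~ 6, while the equivalence
must be evaluated far into that tail (small A2). The identity
ln(1 - erf^2 w) = -w^2 + ln(erfcx w) + ln(1 + erf w), with erfcx the scaled
complementary error function, is exact and stable for every w > 0 and is
used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.special import erf, erfcx

from .engine import ScatteringModel, _resolve_a2

__all__ = [
    "RULE_RATIO",
    "RATIO_LOWER",
    "RATIO_UPPER",
    "EquivalenceResult",
    "log1m_erf2",
    "exact_radius_for_square",
    "exact_square_for_circle",
    "rule_square_for_circle",
    "rule_circle_for_square",
    "ratio_curve",
    "equivalent_square",
    "round_half_up",
]

#: Clinical equivalent-square rule for circles: X = 1.83 R.
RULE_RATIO = 1.83
#: Equal-area (large-A2) limit of X/R.
RATIO_LOWER = math.sqrt(math.pi)
#: Circumscribed-square (small-A2) limit of X/R.
RATIO_UPPER = 2.0


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero, for reported values."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def log1m_erf2(w: float) -> float:
    """ln(1 - erf^2(w)) for w > 0, stable arbitrarily far into the tail."""
    if not w > 0:
        raise ValueError(f"argument must be positive, got {w}")
    return -w * w + math.log(erfcx(w)) + math.log1p(erf(w))


def exact_radius_for_square(
    X: float, model: "ScatteringModel | float", z: float | None = None
) -> float:
    """Radius of the circle whose central-axis dose equals a square of side X.

    Direct evaluation of the exact equivalence; by construction
    dose_circle(result) == dose_square(X) for the same A2.
    """
    if not X > 0:
        raise ValueError(f"side length must be positive, got {X}")
    a2 = _resolve_a2(model, z)
    w = X / (4.0 * math.sqrt(a2))
    return math.sqrt(-4.0 * a2 * log1m_erf2(w))


def exact_square_for_circle(
    R: float, model: "ScatteringModel | float", z: float | None = None
) -> float:
    """Side of the square whose central-axis dose equals a circle of radius R.

    Solved by bracketed root-finding on X in [sqrt(pi) R, 2 R]; the asymptotic
    limits guarantee the root lies strictly inside that bracket for any A2.
    """
    if not R > 0:
        raise ValueError(f"radius must be positive, got {R}")
    a2 = _resolve_a2(model, z)

    def f(X: float) -> float:
        return exact_radius_for_square(X, a2) - R

    lo, hi = RATIO_LOWER * R, RATIO_UPPER * R
    flo, fhi = f(lo), f(hi)
    # endpoints are open limits; tiny numerical margin if a sign is lost there
    if flo > 0:
        lo *= 1.0 - 1e-9
    if fhi < 0:
        hi *= 1.0 + 1e-9
    return float(brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16))


def rule_square_for_circle(R: float) -> float:
    """Equivalent square side for a circle of radius R by the X = 1.83 R rule.

    Full precision; clinical reporting rounds to 0.1 cm via
    :func:`round_half_up`.
    """
    if not R > 0:
        raise ValueError(f"radius must be positive, got {R}")
    return RULE_RATIO * R


def rule_circle_for_square(X: float) -> float:
    """Inverse of the linear rule: radius R = X / 1.83 for a square of side X."""
    if not X > 0:
        raise ValueError(f"side length must be positive, got {X}")
    return X / RULE_RATIO


def ratio_curve(X: float, a2_grid) -> list[tuple[float, float]]:
    """Exact ratio X/R versus A2 for a fixed square side X.

    Every ratio lies strictly inside (sqrt(pi), 2) and is non-increasing in
    A2; plotting two extreme sides (e.g. X = 2 and 25 cm) over a log A2 grid
    reproduces the envelope within which any beam's equivalence must fall.
    """
    out = []
    for a2 in a2_grid:
        a2 = float(a2)
        R = exact_radius_for_square(X, a2)
        out.append((a2, X / R))
    return out


@dataclass(frozen=True)
class EquivalenceResult:
    """Equivalent-square summary for a circular field of radius ``radius_R``.

    ``rule_square_X`` is always 1.83 * R; ``exact_square_X`` (and the A2 it
    used) is present only when a scattering model was supplied. The exact
    ratio is always confined to ``ratio_bounds`` = (sqrt(pi), 2).
    """

    radius_R: float
    rule_square_X: float
    exact_square_X: float | None = None
    a2_used: float | None = None
    ratio_bounds: tuple[float, float] = (RATIO_LOWER, RATIO_UPPER)

    @property
    def rule_square_X_reported(self) -> float:
        """Rule result rounded to 0.1 cm, the precision used clinically."""
        return round_half_up(self.rule_square_X, 1)


def equivalent_square(
    R: float,
    model: "ScatteringModel | float | None" = None,
    z: float | None = None,
) -> EquivalenceResult:
    """Rule-based (and, when A2 is known, exact) equivalent square of a circle."""
    rule_X = rule_square_for_circle(R)
    if model is None:
        return EquivalenceResult(radius_R=R, rule_square_X=rule_X)
    a2 = _resolve_a2(model, z)
    return EquivalenceResult(
        radius_R=R,
        rule_square_X=rule_X,
        exact_square_X=exact_square_for_circle(R, a2),
        a2_used=a2,
    )
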