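"""Output-factor tables and the clinical output-estimation workflow.

The output factor Se(f_a, f_c) of a shaped electron field is the dose rate
per monitor unit at the nominal depth of maximum dose, relative to the
10 cm x 10 cm reference field. Clinics commission tables of Se for square
cutouts per (energy, applicator); a manual second check of a planned output
then proceeds:

* circle of radius R       -> equivalent square X = 1.83 R, interpolate;
* L x W rectangle          -> square-root rule, the geometric mean of the
                              L x L and W x W table outputs;
* irregular (star-convex)  -> equal-area circle, then the circle rule.

Interpolation is piecewise linear in side length with no extrapolation:
requests outside the commissioned range fail loudly, as a manual table
lookup would. Small-field validity warnings (loss of lateral scatter
equilibrium, depth-dose shift at the nominal d_max) are attached to each
estimate but never block it.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .aperture import Aperture, equal_area_circle
from .equivalence import rule_square_for_circle, round_half_up
from .errors import RangeError, TableFormatError

__all__ = [
    "OutputFactorTable",
    "OutputEstimate",
    "read_output_table",
    "write_output_table",
    "interpolate_se",
    "sqrt_rule_se",
    "estimate_output",
    "validity_warnings",
    "NO_LATERAL_EQUILIBRIUM",
    "PDD_SHIFT_GT_2PCT",
]

#: Field too small for lateral side-scatter electron equilibrium on axis.
NO_LATERAL_EQUILIBRIUM = "NO_LATERAL_EQUILIBRIUM"
#: Depth-dose at the nominal d_max may be depressed by more than ~2%.
PDD_SHIFT_GT_2PCT = "PDD_SHIFT_GT_2PCT"


@dataclass(frozen=True)
class OutputFactorTable:
    """Commissioned square-cutout output factors for one (energy, applicator).

    ``entries`` maps square side (cm, strictly increasing) to relative output
    Se; field sizes are defined at ``ssd_definition`` (95 cm by convention
    here) while outputs are referenced at SSD 100. When the applicator is the
    10 x 10 reference, Se(10) == 1 by normalization.
    """

    energy: float
    applicator: str
    entries: tuple[tuple[float, float], ...]
    ssd_definition: float = 95.0
    reference_note: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "entries", tuple((float(s), float(v)) for s, v in self.entries)
        )
        sides = [s for s, _ in self.entries]
        ses = [v for _, v in self.entries]
        if len(self.entries) < 2:
            raise TableFormatError("output table needs at least 2 entries")
        if any(b <= a for a, b in zip(sides, sides[1:])):
            raise TableFormatError("table sides must be strictly increasing")
        if any(not (0.0 < v < 2.0) for v in ses):
            raise TableFormatError("output factors must lie in (0, 2)")

    @property
    def side_range(self) -> tuple[float, float]:
        return self.entries[0][0], self.entries[-1][0]


@dataclass(frozen=True)
class OutputEstimate:
    """Result of the manual output check for one shaped field."""

    se_estimated: float
    equivalent_square_cm: float
    method: str  # circle_rule | sqrt_rule | equal_area_circle_rule
    warnings: tuple[str, ...] = ()
    measured_se: float | None = None

    @property
    def ratio_estimated_over_measured(self) -> float | None:
        if self.measured_se is None:
            return None
        return self.se_estimated / self.measured_se

    @property
    def ratio_reported(self) -> float | None:
        """Estimated/measured rounded to 3 decimals, as charted clinically."""
        r = self.ratio_estimated_over_measured
        return None if r is None else round_half_up(r, 3)

    @property
    def equivalent_square_reported(self) -> float:
        """Equivalent square rounded to 0.1 cm."""
        return round_half_up(self.equivalent_square_cm, 1)


def read_output_table(path) -> OutputFactorTable:
    """Read an output-factor table from CSV.

    Layout: metadata rows (``energy_mev,<val>``, ``applicator,<label>``,
    optional ``ssd_cm,<val>`` and ``note,<text>``), then the header
    ``side_cm,se`` followed by the data rows.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    meta: dict[str, str] = {}
    i = 0
    while i < len(rows):
        row = [c.strip() for c in rows[i]]
        if row and row[0] == "side_cm":
            if len(row) < 2 or row[1] != "se":
                raise TableFormatError(f"{path}: line {i + 1}: header must be 'side_cm,se'")
            break
        if row and row[0]:
            if len(row) < 2:
                raise TableFormatError(f"{path}: line {i + 1}: metadata row needs a value")
            meta[row[0]] = row[1]
        i += 1
    else:
        raise TableFormatError(f"{path}: missing 'side_cm,se' header")
    if "energy_mev" not in meta or "applicator" not in meta:
        raise TableFormatError(f"{path}: metadata must include energy_mev and applicator")
    entries = []
    for j, row in enumerate(rows[i + 1 :], start=i + 2):
        if not row or not "".join(row).strip():
            continue
        try:
            side, se = float(row[0]), float(row[1])
        except (ValueError, IndexError) as exc:
            raise TableFormatError(f"{path}: bad entry on line {j}: {row}") from exc
        if se <= 0:
            raise TableFormatError(f"{path}: non-positive output factor on line {j}")
        entries.append((side, se))
    try:
        return OutputFactorTable(
            energy=float(meta["energy_mev"]),
            applicator=meta["applicator"],
            entries=tuple(entries),
            ssd_definition=float(meta.get("ssd_cm", 95.0)),
            reference_note=meta.get("note", ""),
        )
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def write_output_table(table: OutputFactorTable, path) -> None:
    """Write a table in the CSV layout :func:`read_output_table` accepts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["energy_mev", repr(table.energy)])
        w.writerow(["applicator", table.applicator])
        w.writerow(["ssd_cm", repr(table.ssd_definition)])
        if table.reference_note:
            w.writerow(["note", table.reference_note])
        w.writerow(["side_cm", "se"])
        for side, se in table.entries:
            w.writerow([repr(side), repr(se)])


def interpolate_se(table: OutputFactorTable, X: float) -> float:
    """Se for a square of side X by piecewise-linear interpolation.

    Exact at the table knots; X outside the commissioned range raises
    :class:`RangeError` rather than extrapolating.
    """
    lo, hi = table.side_range
    if not (lo <= X <= hi):
        raise RangeError(
            f"side {X:.4g} cm outside table range [{lo:g}, {hi:g}] cm"
        )
    sides = np.array([s for s, _ in table.entries])
    ses = np.array([v for _, v in table.entries])
    return float(np.interp(X, sides, ses))


def sqrt_rule_se(table: OutputFactorTable, L: float, W: float) -> float:
    """Square-root rule: Se(L x W) = sqrt(Se(L x L) * Se(W x W)).

    Exact within the Fermi-Eyges model, where the rectangular dose
    factorizes; symmetric in (L, W).
    """
    return math.sqrt(interpolate_se(table, L) * interpolate_se(table, W))


def _equivalent_radius(aperture: Aperture) -> float:
    """Radius of the circle standing in for an aperture in small-field checks."""
    if aperture.shape_kind == "circle":
        return aperture.circle_radius
    return equal_area_circle(aperture).circle_radius


def validity_warnings(aperture: Aperture, energy: float, ep0: float) -> tuple[str, ...]:
    """Small-field validity warnings for an output estimate.

    ``energy`` is the nominal beam energy (MeV) and ``ep0`` the most probable
    energy at the surface (MeV). Using the aperture's equivalent radius R:

    * ``NO_LATERAL_EQUILIBRIUM`` when R <= 0.88 * sqrt(E_p,0) cm -- the
      central axis no longer receives full side-scatter, so tabulated
      reference dosimetry degrades;
    * ``PDD_SHIFT_GT_2PCT`` when R <= 1.8 cm for 6-15 MeV beams -- the
      depth-dose curve shifts toward the surface and the dose at the nominal
      d_max can fall more than ~2% below the true maximum. At 6 MeV the
      shift stays under 2% down to R = 1.2 cm, so the warning is suppressed
      for 6 MeV when R > 1.2 cm.

    Warnings never block an estimate; they flag where a depth-dose
    correction or a measurement is advisable.
    """
    R = _equivalent_radius(aperture)
    warnings = []
    if R <= 0.88 * math.sqrt(ep0):
        warnings.append(NO_LATERAL_EQUILIBRIUM)
    if 6.0 <= energy <= 15.0 and R <= 1.8:
        if not (energy == 6.0 and R > 1.2):
            warnings.append(PDD_SHIFT_GT_2PCT)
    return tuple(warnings)


def estimate_output(
    table: OutputFactorTable,
    aperture: Aperture,
    measured_se: float | None = None,
    energy: float | None = None,
    ep0: float | None = None,
) -> OutputEstimate:
    """Estimate the relative output of a shaped field from a square-cutout table.

    Dispatches on aperture shape: circles use the 1.83 R rule then table
    interpolation; rectangles use the square-root rule; star-convex polygons
    are reduced to their equal-area circle first. ``energy`` defaults to the
    table's energy and ``ep0`` to ``energy`` (nominal ~ most probable surface
    energy) for the validity warnings. When ``measured_se`` is given the
    estimated/measured ratio is available on the result.
    """
    energy = table.energy if energy is None else float(energy)
    ep0 = energy if ep0 is None else float(ep0)

    if aperture.shape_kind == "rectangle":
        L, W = aperture.length_L, aperture.width_W
        try:
            se = sqrt_rule_se(table, L, W)
        except RangeError as exc:
            raise RangeError(f"rectangle {L:g} x {W:g} cm: {exc}") from exc
        x_eq = math.sqrt(L * W)  # geometric-mean side, for reporting only
        method = "sqrt_rule"
    else:
        if aperture.shape_kind == "circle":
            radius = aperture.circle_radius
            method = "circle_rule"
        else:
            radius = equal_area_circle(aperture).circle_radius
            method = "equal_area_circle_rule"
        x_eq = rule_square_for_circle(radius)
        try:
            se = interpolate_se(table, x_eq)
        except RangeError as exc:
            raise RangeError(f"equivalent square X={x_eq:.3f} cm: {exc}") from exc

    return OutputEstimate(
        se_estimated=se,
        equivalent_square_cm=x_eq,
        method=method,
        warnings=validity_warnings(aperture, energy, ep0),
        measured_se=None if measured_se is None else float(measured_se),
    )
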