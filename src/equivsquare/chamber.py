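"""Partial-volume (volume-averaging) correction for plane-parallel chambers.

A plane-parallel ionization chamber of collecting radius R_c reads the dose
averaged over its collecting area. For a peaked small-field profile that
average sits below the central-axis dose D0, so the reading must be scaled
up: D0 = D_mean * CF with

    CF^{-1} = (2 / R_c^2) * integral_0^{R_c} r f(r) dr,

where f(r) is the normalized radial beam profile (f(0) = 1). The formula is
the area average of an axisymmetric profile over the collecting disk; no
depth extent or chamber perturbation effects are modelled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .errors import RangeError, TableFormatError

__all__ = ["RadialProfile", "ChamberSpec", "correction_factor", "read_profile_csv", "write_profile_csv"]


@dataclass(frozen=True)
class RadialProfile:
    """Sampled normalized beam profile f(r): radii in cm starting at 0, f(0) = 1."""

    radii: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "radii", tuple(float(v) for v in self.radii))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        r, f = self.radii, self.values
        if len(r) != len(f) or len(r) < 2:
            raise ValueError("profile needs >= 2 (r, f) samples of equal length")
        if r[0] != 0.0:
            raise ValueError("profile must start at r = 0")
        if abs(f[0] - 1.0) > 1e-9:
            raise ValueError(f"profile must be normalized to f(0) = 1, got {f[0]}")
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("radii must be strictly increasing")
        if any(v <= 0 for v in f):
            raise ValueError("profile values must be positive")

    @classmethod
    def from_pairs(cls, pairs) -> "RadialProfile":
        return cls(tuple(float(r) for r, _ in pairs), tuple(float(v) for _, v in pairs))


@dataclass(frozen=True)
class ChamberSpec:
    """Collecting radius of the chamber in cm (0.25 for a 5 mm diameter)."""

    collecting_radius: float = 0.25

    def __post_init__(self):
        if not self.collecting_radius > 0:
            raise ValueError("collecting radius must be positive")


def correction_factor(profile: RadialProfile, chamber: ChamberSpec) -> float:
    """Volume-averaging correction CF = D0 / D_mean for a sampled profile.

    f is linearly interpolated between samples; the moment integral
    int r f(r) dr is then piecewise quadratic/cubic and is evaluated in
    closed form segment by segment, so the only approximation is the linear
    interpolation of the profile itself. CF >= 1 whenever f is non-increasing
    from f(0) = 1; CF depends only on f over [0, R_c].
    """
    rc = chamber.collecting_radius
    r = np.asarray(profile.radii)
    f = np.asarray(profile.values)
    if rc > r[-1] + 1e-12:
        raise RangeError(
            f"profile covers r <= {r[-1]:g} cm, short of collecting radius {rc:g} cm"
        )
    moment = 0.0
    for r0, r1, f0, f1 in zip(r, r[1:], f, f[1:]):
        if r0 >= rc:
            break
        rb = min(r1, rc)
        m = (f1 - f0) / (r1 - r0)
        # int_{r0}^{rb} u (f0 + m (u - r0)) du, closed form
        moment += (f0 - m * r0) * (rb**2 - r0**2) / 2.0 + m * (rb**3 - r0**3) / 3.0
    return float(rc * rc / (2.0 * moment))


def read_profile_csv(path) -> RadialProfile:
    """Read a radial profile from a two-column CSV with header r_cm,f."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or [c.strip() for c in rows[0][:2]] != ["r_cm", "f"]:
        raise TableFormatError(f"{path}: expected header 'r_cm,f' on line 1")
    pairs = []
    for i, row in enumerate(rows[1:], start=2):
        if not row or not "".join(row).strip():
            continue
        try:
            pairs.append((float(row[0]), float(row[1])))
        except (ValueError, IndexError) as exc:
            raise TableFormatError(f"{path}: bad sample on line {i}: {row}") from exc
    try:
        return RadialProfile.from_pairs(pairs)
    except ValueError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def write_profile_csv(profile: RadialProfile, path) -> None:
    """Write a radial profile as a two-column CSV (header r_cm,f)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["r_cm", "f"])
        for r, v in zip(profile.radii, profile.values):
            w.writerow([repr(r), repr(v)])
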