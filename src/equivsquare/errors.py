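"""Exception hierarchy shared across the package."""


class EquivSquareError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(EquivSquareError, ValueError):
    """Invalid or unsupported aperture geometry."""


class UnsupportedGeometryError(GeometryError):
    """Geometry valid in itself but outside the model's domain of validity
    (e.g. evaluation point outside the aperture for the polar dose form)."""


class RangeError(EquivSquareError, ValueError):
    """Requested value outside the tabulated / covered range.

    Raised instead of extrapolating: output tables, scattering-power curves
    and radial profiles are only trusted where data exist.
    """


class TableFormatError(EquivSquareError, ValueError):
    """Malformed CSV input (output table, profile or scattering curve)."""
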