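import numpy as np
import pytest

from equivsquare import SyntheticTableSpec, synth_output_table


def riemann_disk_dose(x: float, y: float, R: float, a2: float, h: float = 0.01) -> float:
    """Brute-force 2-D Riemann-sum convolution of the Gaussian pencil-beam
    kernel over a centered disk of radius R, evaluated at (x, y).

    Independent of the package's polar-quadrature path: this integrates the
    Cartesian double integral directly on an h-spaced midpoint grid.
    """
    xs = np.arange(-R + h / 2, R, h)
    X, Y = np.meshgrid(xs, xs)
    inside = X**2 + Y**2 <= R**2
    k = np.exp(-((X[inside] - x) ** 2 + (Y[inside] - y) ** 2) / (4.0 * a2))
    return float(k.sum() * h * h / (4.0 * np.pi * a2))


@pytest.fixture
def riemann_oracle():
    return riemann_disk_dose


@pytest.fixture
def fe_table():
    """Noiseless synthetic output-factor table, A2 = 0.2 cm^2, sides 2-10 cm."""
    return synth_output_table(SyntheticTableSpec(a2_cm2=0.2))
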