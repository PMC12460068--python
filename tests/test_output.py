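import math

import numpy as np
import pytest

from equivsquare import (
    Aperture,
    NO_LATERAL_EQUILIBRIUM,
    PDD_SHIFT_GT_2PCT,
    OutputFactorTable,
    RangeError,
    TableFormatError,
    dose_rect,
    dose_square,
    estimate_output,
    interpolate_se,
    read_output_table,
    sqrt_rule_se,
    validity_warnings,
    write_output_table,
)


def make_table(entries, energy=9.0, applicator="10x10"):
    return OutputFactorTable(energy=energy, applicator=applicator, entries=tuple(entries))


class TestTableIO:
    def test_round_trip(self, tmp_path, fe_table):
        p = tmp_path / "table.csv"
        write_output_table(fe_table, p)
        back = read_output_table(p)
        assert back == fe_table

    def test_minimal_table(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("energy_mev,6\napplicator,6x6\nside_cm,se\n2.0,0.9\n3.0,0.95\n")
        t = read_output_table(p)
        assert len(t.entries) == 2
        assert t.ssd_definition == 95.0

    def test_duplicate_side_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("energy_mev,6\napplicator,6x6\nside_cm,se\n2.0,0.9\n2.0,0.95\n")
        with pytest.raises(TableFormatError, match="strictly increasing"):
            read_output_table(p)

    def test_missing_header(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("energy_mev,6\napplicator,6x6\n2.0,0.9\n")
        with pytest.raises(TableFormatError):
            read_output_table(p)

    def test_negative_value_reports_line(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("energy_mev,6\napplicator,6x6\nside_cm,se\n2.0,0.9\n3.0,-0.1\n")
        with pytest.raises(TableFormatError, match="line 5"):
            read_output_table(p)

    def test_too_few_entries(self):
        with pytest.raises(TableFormatError):
            make_table([(2.0, 0.9)])


class TestInterpolation:
    def test_exact_at_knots(self, fe_table):
        for side, se in fe_table.entries:
            assert interpolate_se(fe_table, side) == se

    def test_linear_midpoint(self):
        t = make_table([(4.0, 0.90), (6.0, 0.94)])
        assert interpolate_se(t, 5.0) == pytest.approx(0.92, rel=1e-12)

    @pytest.mark.parametrize("X", [1.0, 12.0])
    def test_no_extrapolation(self, fe_table, X):
        with pytest.raises(RangeError):
            interpolate_se(fe_table, X)


class TestSqrtRule:
    def test_square_identity(self, fe_table):
        assert sqrt_rule_se(fe_table, 6.0, 6.0) == pytest.approx(
            interpolate_se(fe_table, 6.0), rel=1e-14
        )

    def test_constant_table(self):
        t = make_table([(2.0, 0.9), (10.0, 0.9)])
        assert sqrt_rule_se(t, 3.0, 7.0) == pytest.approx(0.9, rel=1e-12)

    def test_symmetry(self, fe_table):
        assert sqrt_rule_se(fe_table, 6.0, 3.0) == sqrt_rule_se(fe_table, 3.0, 6.0)

    def test_matches_engine_on_synthetic_table(self, fe_table):
        # exact within the model up to table-interpolation error
        a2 = 0.2
        expected = dose_rect(6.0, 3.0, a2) / dose_square(10.0, a2)
        assert sqrt_rule_se(fe_table, 6.0, 3.0) == pytest.approx(expected, abs=1e-3)


class TestEstimateOutput:
    def test_circle_interpolates_at_rule_square(self):
        t = make_table([(5.0, 0.96), (6.0, 0.98)])
        est = estimate_output(t, Aperture.circle(3.0))
        assert est.method == "circle_rule"
        assert est.equivalent_square_cm == pytest.approx(5.49)
        assert est.equivalent_square_reported == pytest.approx(5.5)
        assert est.se_estimated == pytest.approx(0.96 + 0.02 * 0.49, rel=1e-12)

    def test_reference_square_gives_unity(self, fe_table):
        est = estimate_output(fe_table, Aperture.rectangle(10.0, 10.0))
        assert est.method == "sqrt_rule"
        assert est.se_estimated == pytest.approx(1.0, rel=1e-12)

    def test_ratio_reporting(self):
        t = make_table([(10.5, 0.987), (11.5, 0.987)])
        est = estimate_output(t, Aperture.circle(6.0), measured_se=0.970)
        assert est.ratio_estimated_over_measured == pytest.approx(0.987 / 0.970)
        assert est.ratio_reported == pytest.approx(1.018)

    def test_no_ratio_without_measurement(self, fe_table):
        est = estimate_output(fe_table, Aperture.circle(3.0))
        assert est.measured_se is None and est.ratio_estimated_over_measured is None

    def test_polygon_uses_equal_area_circle(self, fe_table):
        n, r = 128, 3.0
        poly = Aperture.polygon(
            [(r * math.cos(a), r * math.sin(a)) for a in np.linspace(0, 2 * math.pi, n, endpoint=False)]
        )
        est = estimate_output(fe_table, poly)
        assert est.method == "equal_area_circle_rule"
        circle_est = estimate_output(fe_table, Aperture.circle(r))
        assert est.se_estimated == pytest.approx(circle_est.se_estimated, rel=1e-3)

    def test_range_error_names_equivalent_square(self, fe_table):
        with pytest.raises(RangeError, match="X=12.810"):
            estimate_output(fe_table, Aperture.circle(7.0))


class TestValidityWarnings:
    def test_large_field_clean(self):
        assert validity_warnings(Aperture.circle(5.0), 6.0, 6.0) == ()

    def test_small_field_high_energy_both(self):
        w = validity_warnings(Aperture.circle(1.5), 15.0, 15.0)
        assert NO_LATERAL_EQUILIBRIUM in w and PDD_SHIFT_GT_2PCT in w

    def test_6mev_carve_out(self):
        # at 6 MeV the depth-dose shift stays under 2% down to R = 1.2 cm
        w = validity_warnings(Aperture.circle(1.5), 6.0, 6.0)
        assert w == (NO_LATERAL_EQUILIBRIUM,)
        w = validity_warnings(Aperture.circle(1.1), 6.0, 6.0)
        assert PDD_SHIFT_GT_2PCT in w

    def test_monotone_in_radius(self):
        radii = np.linspace(5.0, 0.5, 19)
        prev: set = set()
        for R in radii:
            cur = set(validity_warnings(Aperture.circle(R), 9.0, 9.0))
            assert prev.issubset(cur)
            prev = cur

    def test_estimate_attaches_warnings(self):
        t = make_table([(2.0, 0.8), (6.0, 0.95)], energy=12.0)
        est = estimate_output(t, Aperture.circle(1.5))
        assert NO_LATERAL_EQUILIBRIUM in est.warnings
        assert PDD_SHIFT_GT_2PCT in est.warnings


class TestClinicalTableReproduction:
    def test_reported_equivalent_squares(self, fe_table):
        # clinical radii and the equivalent squares charted for them
        expected = {2.0: 3.7, 6.0: 11.0, 6.5: 11.9, 3.0: 5.5}
        big = make_table([(2.0, 0.8), (13.0, 1.05)])
        for R, X_rep in expected.items():
            est = estimate_output(big, Aperture.circle(R))
            assert est.equivalent_square_reported == pytest.approx(X_rep)
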