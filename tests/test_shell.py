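"""Closed-form shell model: frozen worked examples, algebraic properties,
and a high-precision symbolic oracle for the coefficient formulas."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corneamech import (
    CorneaGeometry,
    ModelConstants,
    ShellCoefficients,
    TonometryPair,
    coefficient_b,
    coefficient_c,
    ecalc,
    eiopg,
    ioptcalc,
    predicted_iopg,
    stiffness,
    validate_parses,
)
from corneamech.exceptions import (
    DegenerateModelError,
    InvalidConstantsError,
    InvalidGeometryError,
    InvalidInputError,
)

# geometry/pressure strategies spanning the physiological range
geometries = st.builds(
    CorneaGeometry,
    radius_mm=st.floats(6.5, 9.5),
    thickness_mm=st.floats(0.35, 0.75),
)
pressures = st.floats(5.0, 40.0)


class TestCoefficients:
    @pytest.mark.parametrize(
        "r, t, expected",
        [
            (7.8, 0.52, 357.3868812424714),
            (7.75, 0.5499, 314.79491646382604),
        ],
    )
    def test_b_worked_examples(self, r, t, expected, constants):
        assert coefficient_b(CorneaGeometry(r, t), constants) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "r, t, expected",
        [
            (7.75, 0.5499, 176.58525545678242),
            (7.8, 0.52, 189.57669954435408),
        ],
    )
    def test_c_worked_examples(self, r, t, expected, constants):
        assert coefficient_c(CorneaGeometry(r, t), constants) == pytest.approx(
            expected, rel=1e-12
        )

    def test_symbolic_oracle_on_grid(self, constants):
        """B and C match an independent sympy evaluation on an (R, t) grid."""
        sympy = pytest.importorskip("sympy")
        R_, t_, nu_, A_ = sympy.symbols("R t nu A", positive=True)
        b_expr = sympy.Rational(6, 10) * sympy.pi * R_ * (R_ - t_ / 2) * sympy.sqrt(
            1 - nu_**2
        ) / t_**2
        c_expr = 2 * sympy.pi * R_ * (R_ - t_ / 2) / ((1 - nu_) * A_ * t_)
        for r in [6.5 + 0.3 * i for i in range(10)]:
            for t in [0.35 + 0.04 * j for j in range(10)]:
                subs = {R_: r, t_: t, nu_: sympy.Rational(49, 100), A_: sympy.Rational(735, 100)}
                geom = CorneaGeometry(r, t)
                assert coefficient_b(geom, constants) == pytest.approx(
                    float(b_expr.subs(subs).evalf(30)), rel=1e-12
                )
                assert coefficient_c(geom, constants) == pytest.approx(
                    float(c_expr.subs(subs).evalf(30)), rel=1e-12
                )

    def test_poisson_enters_b_only_through_sqrt_factor(self):
        geom = CorneaGeometry(7.75, 0.55)
        ratio = coefficient_b(geom, ModelConstants(poisson_ratio=0.0)) / coefficient_b(
            geom, ModelConstants(poisson_ratio=0.49)
        )
        assert ratio == pytest.approx(1.0 / math.sqrt(1 - 0.49**2), rel=1e-12)

    def test_doubling_area_halves_c(self, mean_geometry):
        c1 = coefficient_c(mean_geometry, ModelConstants(applanation_area_mm2=7.35))
        c2 = coefficient_c(mean_geometry, ModelConstants(applanation_area_mm2=14.70))
        assert c2 == pytest.approx(c1 / 2, rel=1e-14)

    @given(r=st.floats(6.5, 9.5), t1=st.floats(0.35, 0.74), dt=st.floats(0.001, 0.01))
    @settings(max_examples=50)
    def test_b_and_c_decrease_with_thickness(self, r, t1, dt):
        g1, g2 = CorneaGeometry(r, t1), CorneaGeometry(r, t1 + dt)
        assert coefficient_b(g2) < coefficient_b(g1)
        assert coefficient_c(g2) < coefficient_c(g1)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            CorneaGeometry(-7.75, 0.55)
        with pytest.raises(InvalidGeometryError):
            CorneaGeometry(7.75, 0.0)
        with pytest.raises(InvalidGeometryError):
            CorneaGeometry(0.5, 0.6)  # t >= R

    def test_implausible_geometry_warns_but_passes(self):
        with pytest.warns(UserWarning, match="thickness"):
            CorneaGeometry(7.75, 0.9 * 7.75 / 7.75)  # 0.9 mm, outside screen

    def test_invalid_constants_rejected(self):
        with pytest.raises(InvalidConstantsError):
            ModelConstants(applanation_area_mm2=0.0)
        with pytest.raises(InvalidConstantsError):
            ModelConstants(poisson_ratio=1.0)


class TestIoptcalc:
    def test_worked_example_both_variants(self, mean_coeffs, constants):
        thick = ShellCoefficients.from_geometry(CorneaGeometry(7.75, 0.65), constants)
        assert ioptcalc(15.0, thick, mean_coeffs, "printed") == pytest.approx(
            19.209561213567465, rel=1e-12
        )
        assert ioptcalc(15.0, thick, mean_coeffs, "consistency") == pytest.approx(
            12.00732254928627, rel=1e-12
        )

    @given(geom=geometries, iopg=pressures, variant=st.sampled_from(["printed", "consistency"]))
    @settings(max_examples=100)
    def test_calibration_identity(self, geom, iopg, variant):
        coeffs = ShellCoefficients.from_geometry(geom)
        assert ioptcalc(iopg, coeffs, coeffs, variant) == pytest.approx(iopg, rel=1e-12)

    def test_zero_iopg_maps_to_zero(self, mean_coeffs):
        thick = ShellCoefficients.from_geometry(CorneaGeometry(7.75, 0.65))
        assert ioptcalc(0.0, thick, mean_coeffs) == 0.0

    def test_consistency_variant_decreases_with_thickness(self, mean_coeffs):
        """Thicker corneas over-read, so the corrected IOP must fall with t."""
        prev = math.inf
        for t in (0.45, 0.50, 0.55, 0.60, 0.65):
            coeffs = ShellCoefficients.from_geometry(CorneaGeometry(7.75, t))
            val = ioptcalc(15.0, coeffs, mean_coeffs, "consistency")
            assert val < prev
            prev = val

    def test_unknown_variant_rejected(self, mean_coeffs):
        with pytest.raises(InvalidInputError):
            ioptcalc(15.0, mean_coeffs, mean_coeffs, "bogus")


class TestModulusEstimators:
    def test_ecalc_worked_example(self, mean_coeffs, constants):
        est = ecalc(TonometryPair(15.06, 16.89), mean_coeffs, constants)
        assert est.value == pytest.approx(0.2344381969706887, rel=1e-12)
        assert not est.negative_flag

    def test_eiopg_calibration_worked_example(self, mean_coeffs, constants):
        est = eiopg(15.06, mean_coeffs, mean_coeffs, constants)
        expected = 15.06 * (mean_coeffs.b_coeff - mean_coeffs.c_coeff) / 7500.0
        assert est.value == pytest.approx(expected, rel=1e-14)
        assert est.value == pytest.approx(0.2775, abs=5e-4)

    def test_zero_pressures_give_flagged_zero(self, mean_coeffs):
        est = ecalc(TonometryPair(0.0, 0.0), mean_coeffs)
        assert est.value == 0.0 and est.negative_flag

    def test_negative_result_flagged_not_clamped(self, mean_coeffs):
        est = ecalc(TonometryPair(5.0, 40.0), mean_coeffs)
        assert est.value < 0 and est.negative_flag

    @given(geom=geometries, iopg=pressures, iopt=pressures, s=st.floats(0.1, 5.0))
    @settings(max_examples=100)
    def test_degree_one_homogeneity_in_pressures(self, geom, iopg, iopt, s):
        coeffs = ShellCoefficients.from_geometry(geom)
        base = ecalc(TonometryPair(iopg, iopt), coeffs).value
        scaled = ecalc(TonometryPair(s * iopg, s * iopt), coeffs).value
        assert scaled == pytest.approx(s * base, rel=1e-10, abs=1e-12)

    @given(geom=geometries, iopg=pressures)
    @settings(max_examples=50)
    def test_eiopg_proportional_to_iopg(self, geom, iopg, calibration):
        coeffs = ShellCoefficients.from_geometry(geom)
        one = eiopg(iopg, coeffs, calibration.coefficients).value
        two = eiopg(2 * iopg, coeffs, calibration.coefficients).value
        assert two == pytest.approx(2 * one, rel=1e-10, abs=1e-12)

    def test_eiopg_equals_ecalc_when_iopt_matches(self, mean_coeffs, calibration):
        iopt = ioptcalc(15.06, mean_coeffs, calibration.coefficients)
        via_pair = ecalc(TonometryPair(15.06, iopt), mean_coeffs).value
        direct = eiopg(15.06, mean_coeffs, calibration.coefficients).value
        assert direct == pytest.approx(via_pair, rel=1e-12)

    def test_ecalc_decreases_with_thickness_at_fixed_pressures(self):
        prev = math.inf
        for t in (0.45, 0.50, 0.55, 0.60, 0.65):
            coeffs = ShellCoefficients.from_geometry(CorneaGeometry(7.75, t))
            val = ecalc(TonometryPair(15.06, 16.89), coeffs).value
            assert val < prev
            prev = val

    def test_unit_divisor_rescales_moduli_only(self, mean_geometry, mean_coeffs):
        doubled = ModelConstants(mmhg_per_mpa=15000.0)
        e1 = ecalc(TonometryPair(15.06, 16.89), mean_coeffs).value
        e2 = ecalc(TonometryPair(15.06, 16.89), mean_coeffs, doubled).value
        assert e2 == pytest.approx(e1 / 2, rel=1e-14)
        # the pressure correction is unit-free
        thick = ShellCoefficients.from_geometry(CorneaGeometry(7.75, 0.65), doubled)
        cal = ShellCoefficients.from_geometry(mean_geometry, doubled)
        assert ioptcalc(15.0, thick, cal) == pytest.approx(
            ioptcalc(
                15.0,
                ShellCoefficients.from_geometry(CorneaGeometry(7.75, 0.65)),
                ShellCoefficients.from_geometry(mean_geometry),
            ),
            rel=1e-12,
        )


class TestStiffnessAndForwardModel:
    @pytest.mark.parametrize(
        "t, e, expected",
        [(0.5499, 0.29, 0.159471), (0.550, 0.25, 0.1375), (0.55, 0.0, 0.0)],
    )
    def test_stiffness_is_exact_product(self, t, e, expected):
        assert stiffness(t, e).value == pytest.approx(expected, rel=1e-9)
        assert stiffness(t, e).value == t * e

    def test_stiffness_requires_positive_thickness(self):
        with pytest.raises(InvalidGeometryError):
            stiffness(0.0, 0.3)

    def test_predicted_iopg_worked_example(self, mean_coeffs):
        assert predicted_iopg(16.89, 0.234, mean_coeffs) == pytest.approx(
            15.0496, abs=5e-4
        )

    def test_zero_modulus_limit(self, mean_coeffs):
        assert predicted_iopg(16.89, 0.0, mean_coeffs) == pytest.approx(
            mean_coeffs.c_coeff * 16.89 / mean_coeffs.b_coeff, rel=1e-14
        )

    @given(geom=geometries, true_iop=pressures, e=st.floats(0.05, 1.0))
    @settings(max_examples=100)
    def test_round_trip_recovers_modulus(self, geom, true_iop, e):
        coeffs = ShellCoefficients.from_geometry(geom)
        reading = predicted_iopg(true_iop, e, coeffs)
        back = ecalc(TonometryPair(reading, true_iop), coeffs).value
        assert back == pytest.approx(e, rel=1e-10)

    def test_degenerate_coefficients_rejected(self):
        with pytest.raises(DegenerateModelError):
            ShellCoefficients(b_coeff=0.0, c_coeff=100.0)


class TestParseValidation:
    def test_only_default_parse_accepted(self):
        results = validate_parses()
        accepted = [key for key, res in results.items() if res["accepted"]]
        assert accepted == [("default", "default")]

    def test_alternate_c_parses_give_implausibly_stiff_corneas(self):
        results = validate_parses()
        for c_parse in ("two_in_denominator", "two_one_minus_nu_numerator"):
            assert results[("default", c_parse)]["ecalc_at_means_mpa"] > 0.5
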