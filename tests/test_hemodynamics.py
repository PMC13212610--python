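import numpy as np
import pytest

from perifem import (
    BloodModel,
    LesionAnnotation,
    Strategy,
    VesselCase,
    calibrate_peripheral_resistance,
    generate_dus_trace,
    lesion_expansion_loss,
    pressure_profile,
    solve_hyperemia,
    solve_resting,
    viscosity_from_hematocrit,
    viscous_pressure_drop,
)
from perifem.hemodynamics import MMHG_PA, total_pressure_drop

from helpers import make_gaussian_narrowing, make_tube


class TestViscosity:
    def test_plasma_limit(self):
        assert viscosity_from_hematocrit(0.0) == pytest.approx(1.2)

    def test_physiologic_hematocrit(self):
        # 1.2 * (1 + 2.5*0.45 + 6.2*0.45^2)
        assert viscosity_from_hematocrit(0.45) == pytest.approx(4.0566)

    def test_monotone_in_hematocrit(self):
        assert viscosity_from_hematocrit(0.5) > viscosity_from_hematocrit(0.4)

    @pytest.mark.parametrize("eta", [-0.01, 0.71])
    def test_out_of_range_rejected(self, eta):
        with pytest.raises(ValueError):
            viscosity_from_hematocrit(eta)


class TestViscousDrop:
    def test_zero_flow_zero_drop(self, tube, blood):
        assert viscous_pressure_drop(tube, 0.0, blood) == 0.0

    def test_uniform_tube_matches_poiseuille_closed_form(self, blood):
        tube = make_tube(radius_mm=2.0, length_mm=100.0)
        # closed form 8 mu L Q / (pi r^4) evaluated fully in SI, converted once
        dp_si = (
            8 * (blood.viscosity * 1e-3) * (1.26 * 1e-6) * 0.1
            / (np.pi * (2e-3) ** 4) / MMHG_PA
        )
        assert viscous_pressure_drop(tube, 1.26, blood) == pytest.approx(dp_si, rel=1e-3)

    def test_radius_doubling_divides_by_sixteen(self, blood):
        lo = make_tube(radius_mm=1.5)
        hi = make_tube(radius_mm=3.0)
        ratio = viscous_pressure_drop(lo, 2.0, blood) / viscous_pressure_drop(hi, 2.0, blood)
        assert ratio == pytest.approx(16.0, rel=1e-3)


class TestExpansionLoss:
    def test_zero_severity_and_zero_flow(self, blood):
        flat = LesionAnnotation(start=10.0, end=20.0, reference_radius=2.0, minimal_radius=2.0)
        assert lesion_expansion_loss(flat, 2.0, blood) == 0.0
        narrowing = LesionAnnotation(start=10.0, end=20.0, reference_radius=2.0, minimal_radius=1.0)
        assert lesion_expansion_loss(narrowing, 0.0, blood) == 0.0

    def test_hand_evaluated_oracle(self, single_lesion):
        # 60% stenosis, ref radius 2.5 mm, Q = 2 mL/s, rho = 1.06, Kt = 1.52,
        # evaluated by hand in SI: 230.3766 Pa = 1.72797 mmHg
        blood = BloodModel(hematocrit=0.42, density=1.06)
        got = lesion_expansion_loss(single_lesion, 2.0, blood, kt=1.52)
        assert got == pytest.approx(1.72797, rel=1e-4)

    def test_quadratic_in_flow(self, single_lesion, blood):
        one = lesion_expansion_loss(single_lesion, 1.0, blood)
        three = lesion_expansion_loss(single_lesion, 3.0, blood)
        assert three == pytest.approx(9.0 * one, rel=1e-12)


class TestPressureProfile:
    def test_uniform_tube_linear_decline(self, tube, blood):
        res = pressure_profile(tube, [], 1.26, blood, inlet_pressure=95.0)
        p = res.pressure
        slopes = np.diff(p) / np.diff(res.axial_position)
        assert np.allclose(slopes, slopes[0], rtol=1e-9)
        assert res.pressure[0] == 95.0
        assert res.gradient > 0

    def test_two_identical_lesions_double_the_lesion_loss(self, blood):
        tube = make_tube(radius_mm=2.5, length_mm=200.0)
        l1 = LesionAnnotation(start=40.0, end=60.0, reference_radius=2.5, minimal_radius=1.0)
        l2 = LesionAnnotation(start=120.0, end=140.0, reference_radius=2.5, minimal_radius=1.0)
        base = pressure_profile(tube, [], 2.0, blood, 95.0).gradient
        one = pressure_profile(tube, [l1], 2.0, blood, 95.0).gradient
        two = pressure_profile(tube, [l1, l2], 2.0, blood, 95.0).gradient
        assert two - base == pytest.approx(2.0 * (one - base), rel=1e-9)

    def test_total_gradient_is_sum_of_parts(self, blood):
        profile = make_gaussian_narrowing()
        lesions = [
            LesionAnnotation(start=80.0, end=120.0, reference_radius=3.0, minimal_radius=1.2),
            LesionAnnotation(start=150.0, end=170.0, reference_radius=3.0, minimal_radius=1.5),
        ]
        res = pressure_profile(profile, lesions, 2.0, blood, 95.0)
        expected = viscous_pressure_drop(profile, 2.0, blood) + sum(
            lesion_expansion_loss(les, 2.0, blood) for les in lesions
        )
        assert res.gradient == pytest.approx(expected, abs=1e-9)

    def test_nonphysical_flow_is_flagged_not_rejected(self, blood):
        tube = make_tube(radius_mm=0.5, length_mm=300.0)
        res = pressure_profile(tube, [], 3.0, blood, inlet_pressure=95.0)
        assert res.warning is not None
        assert res.distal_pressure < 0

    def test_lesion_outside_extent_rejected(self, tube, blood):
        bad = LesionAnnotation(start=90.0, end=150.0, reference_radius=2.0, minimal_radius=1.0)
        with pytest.raises(ValueError):
            pressure_profile(tube, [bad], 1.0, blood, 95.0)

    def test_monotone_and_continuous_in_flow(self, blood, single_lesion):
        tube = make_tube(radius_mm=2.5, length_mm=200.0)
        flows = np.linspace(0.0, 5.0, 41)
        drops = [total_pressure_drop(tube, [single_lesion], q, blood) for q in flows]
        assert drops[0] == 0.0
        assert np.all(np.diff(drops) > 0)


def _case(profile, lesions=(), q_target=2.0, pa=95.0, rng=None):
    rng = rng or np.random.default_rng(0)
    site = profile.axial_position[-1] - 5.0
    area = profile.cross_section_cm2(site)
    trace = generate_dus_trace(q_target, area, rng)
    return VesselCase(
        case_id="t",
        profile=profile,
        lesions=tuple(lesions),
        blood=BloodModel(hematocrit=0.42),
        inlet_pressure=pa,
        dus_trace=trace,
        dus_site_mm=site,
        dus_correction=0.0,
    )


class TestBoundaryConditions:
    def test_cfdm_uses_population_flow_regardless_of_trace(self, tube):
        case = _case(tube, q_target=3.7)
        res = solve_resting(case, Strategy.CFDM)
        assert res.flow_rate == 1.26

    def test_cfdi_recovers_the_trace_flow(self, tube):
        case = _case(tube, q_target=2.90)
        res = solve_resting(case, Strategy.CFDI)
        assert res.flow_rate == pytest.approx(2.90, rel=1e-9)

    def test_cfdi_without_trace_rejected(self, tube, blood):
        case = VesselCase(case_id="x", profile=tube, lesions=(), blood=blood, inlet_pressure=95.0)
        with pytest.raises(ValueError):
            solve_resting(case, Strategy.CFDI)

    def test_healthy_vessel_gradient_is_viscous_only(self, tube):
        case = _case(tube)
        res = solve_resting(case, Strategy.CFDM)
        assert 0 < res.gradient == pytest.approx(
            viscous_pressure_drop(tube, 1.26, case.blood), abs=1e-12
        )

    @pytest.mark.parametrize(
        ("pd", "pv", "q", "expected"), [(90.0, 0.0, 2.0, 45.0), (80.0, 10.0, 3.5, 20.0)]
    )
    def test_peripheral_resistance_calibration(self, pd, pv, q, expected):
        assert calibrate_peripheral_resistance(pd, pv, q) == pytest.approx(expected)

    def test_calibration_decreasing_in_flow(self):
        assert calibrate_peripheral_resistance(90.0, 0.0, 3.0) < calibrate_peripheral_resistance(
            90.0, 0.0, 2.0
        )

    def test_calibration_preconditions(self):
        with pytest.raises(ValueError):
            calibrate_peripheral_resistance(5.0, 10.0, 2.0)
        with pytest.raises(ValueError):
            calibrate_peripheral_resistance(90.0, 0.0, 0.0)


class TestHyperemia:
    def test_zero_vessel_resistance_triples_flow(self):
        # vessel resistance scales as r^-4: at r = 500 mm it is ~1e-11 of the
        # peripheral resistance, so the analytic limit Q* = 3 Q_rest applies
        huge = make_tube(radius_mm=500.0, length_mm=100.0)
        case = _case(huge)
        rest = solve_resting(case, Strategy.CFDI)
        hyper = solve_hyperemia(case, rest, hyperemia_factor=3.0)
        assert hyper.flow_rate == pytest.approx(3.0 * rest.flow_rate, rel=1e-9)

    def test_linear_vessel_matches_closed_form(self):
        tube = make_tube(radius_mm=1.2, length_mm=250.0)
        case = _case(tube, q_target=1.5)
        rest = solve_resting(case, Strategy.CFDI)
        r_vessel = rest.gradient / rest.flow_rate  # purely viscous: linear in Q
        r_periph = rest.distal_pressure / rest.flow_rate
        q_closed = case.inlet_pressure / (r_vessel + r_periph / 3.0)
        hyper = solve_hyperemia(case, rest, hyperemia_factor=3.0)
        assert hyper.flow_rate == pytest.approx(q_closed, rel=1e-6)

    def test_nonlinear_case_matches_grid_search_oracle(self, single_lesion):
        tube = make_tube(radius_mm=2.5, length_mm=200.0)
        case = _case(tube, lesions=[single_lesion], q_target=2.0)
        rest = solve_resting(case, Strategy.CFDI)
        hyper = solve_hyperemia(case, rest, hyperemia_factor=3.0)
        r_per = rest.distal_pressure / rest.flow_rate / 3.0
        grid = np.linspace(rest.flow_rate, 3.0 * rest.flow_rate, 20001)
        residuals = [
            abs(total_pressure_drop(tube, [single_lesion], q, case.blood) + r_per * q - 95.0)
            for q in grid
        ]
        q_grid = grid[int(np.argmin(residuals))]
        assert hyper.flow_rate == pytest.approx(q_grid, abs=float(grid[1] - grid[0]))

    def test_hyperemic_flow_bracket_and_ffr_ordering(self, single_lesion):
        tube = make_tube(radius_mm=2.5, length_mm=200.0)
        case = _case(tube, lesions=[single_lesion], q_target=2.0)
        rest = solve_resting(case, Strategy.CFDI)
        hyper = solve_hyperemia(case, rest, hyperemia_factor=3.0)
        assert rest.flow_rate < hyper.flow_rate <= 3.0 * rest.flow_rate
        # more flow, larger drop: hyperemic Pd/Pa below resting Pd/Pa
        assert hyper.distal_pressure / 95.0 < rest.distal_pressure / 95.0
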