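"""Stress routes, Young's modulus and validation metrics."""

import numpy as np
import pytest

import aortastiff as ast
from aortastiff.stiffness import STRAIN_FLOOR
from conftest import circle_section


class TestPressureSpec:
    def test_patient_style_range(self):
        # "82-120 mmHg" style record -> dP = 38 mmHg
        spec = ast.PressureSpec(p_dia_mmhg=82.0, p_sys_mmhg=120.0)
        assert spec.dp_mmhg == 38.0
        assert spec.dp_pa == pytest.approx(38 * 133.322)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            ast.PressureSpec(p_dia_mmhg=120.0, p_sys_mmhg=82.0)
        with pytest.raises(ValueError):
            ast.PressureSpec.from_dp(0.0)


class TestLaplaceStress:
    def test_direct_formula_value(self):
        # dP = 40 mmHg, rho_bar = 16 mm, delta = 2 mm -> 42.66 kPa
        sec = circle_section(radius=16.0, n=64)
        sigma = ast.laplace_stress(sec, ast.PressureSpec.from_dp(40.0), 2.0)
        assert sigma == pytest.approx(42.66, abs=0.01)

    def test_doubling_thickness_halves_stress(self):
        sec = circle_section(radius=16.0, n=64)
        p = ast.PressureSpec.from_dp(40.0)
        assert ast.laplace_stress(sec, p, 4.0) == pytest.approx(
            0.5 * ast.laplace_stress(sec, p, 2.0))

    def test_invalid_thickness(self):
        with pytest.raises(ValueError):
            ast.laplace_stress(circle_section(), ast.PressureSpec.from_dp(40.0),
                               0.0)


class TestIESectionalStress:
    def make_stress(self, n_nodes, values):
        from aortastiff.membrane import StressResult

        return StressResult(
            element_principal_pa=np.zeros((1, 2)),
            nodal_max_principal_pa=np.asarray(values, float),
            displacement_mm=np.zeros((n_nodes, 3)),
        )

    def test_uniform_field_mean_identity(self):
        sec = circle_section(n=32)
        stress = self.make_stress(32, np.full(32, 46300.0))
        assert ast.ie_sectional_stress(stress, sec) == pytest.approx(46.3)

    def test_angular_sector_mode(self):
        sec = circle_section(n=32)
        vals = np.where(sec.theta > 0, 2000.0, 1000.0)
        stress = self.make_stress(32, vals)
        full = ast.ie_sectional_stress(stress, sec)
        sector = ast.ie_sectional_stress(stress, sec, theta_range=(0.1, np.pi))
        assert sector == pytest.approx(2.0)
        assert 1.0 < full < 2.0

    def test_mesh_mismatch_rejected(self):
        sec = circle_section(n=32)
        stress = self.make_stress(8, np.zeros(8))
        with pytest.raises(ValueError):
            ast.ie_sectional_stress(stress, sec)


class TestYoungModulus:
    def test_recovers_imposed_modulus(self):
        # sigma = 42.66 kPa over eps = 0.0853 -> 0.50 MPa
        assert ast.young_modulus(42.66, 0.0853) == pytest.approx(0.50, abs=0.002)

    def test_strain_below_floor_masked(self):
        assert np.isnan(ast.young_modulus(42.66, STRAIN_FLOOR / 10))
        assert np.isnan(ast.young_modulus(42.66, np.nan))

    def test_zero_stress_reported_as_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="aortastiff"):
            assert ast.young_modulus(0.0, 0.05) == 0.0
        assert any("zero" in r.message.lower() for r in caplog.records)


class TestValidationMetrics:
    def make_profile(self, xi, est):
        n = len(xi)
        return ast.StiffnessProfile(
            xi=np.asarray(xi), stations=np.arange(n),
            epsilon=np.full(n, 0.05),
            sigma_lh_kpa=np.full(n, np.nan), sigma_ie_kpa=np.full(n, np.nan),
            e_lh_mpa=np.asarray(est), e_ie_mpa=np.asarray(est),
            mean_radius_mm=np.full(n, 16.0), m_factor=np.ones(n),
            thickness_mm=2.0, phase_label="sys",
            node_station=np.arange(n),
        )

    def test_exact_estimate_gives_zero_rmspe(self):
        prof = self.make_profile([0.2, 0.5, 0.8], [0.5, 0.5, 0.5])
        rep = ast.validate_against_reference(
            prof, ast.StiffnessField(kind="homogeneous", e_h_mpa=0.5), "LH")
        assert rep.rmspe_percent == 0.0

    def test_uniform_ten_percent_overestimate(self):
        prof = self.make_profile([0.2, 0.5, 0.8], [0.55, 0.55, 0.55])
        rep = ast.validate_against_reference(
            prof, ast.StiffnessField(kind="homogeneous", e_h_mpa=0.5), "LH")
        assert rep.rmspe_percent == pytest.approx(10.0, abs=1e-9)
        assert rep.max_rerr_percent == pytest.approx(10.0, abs=1e-9)

    def test_masked_stations_excluded(self):
        prof = self.make_profile([0.2, 0.5, 0.8], [0.5, np.nan, 0.5])
        rep = ast.validate_against_reference(
            prof, ast.StiffnessField(kind="homogeneous", e_h_mpa=0.5), "LH")
        assert rep.rmspe_percent == 0.0
        assert np.isnan(rep.rerr_percent[1])


@pytest.fixture(scope="module")
def profile(cylinder, cylinder_cl, inflated_cylinder):
    ps = ast.assemble_phase_set(cylinder, [inflated_cylinder], labels=["sys"])
    return ast.stiffness_profile(ps, cylinder_cl,
                                 ast.PressureSpec.from_dp(40.0),
                                 thickness_mm=2.0, method="both",
                                 systolic_label="sys")


class TestPipelineOnCylinder:
    def test_both_routes_recover_modulus(self, profile, soft_field):
        for meth in ("LH", "IE"):
            rep = ast.validate_against_reference(profile, soft_field, meth)
            assert rep.max_rerr_percent <= 2.0

    def test_lh_ie_agreement_on_cylinder(self, profile):
        rel = np.abs(profile.e_lh_mpa - profile.e_ie_mpa) / profile.e_ie_mpa
        assert np.nanmax(rel) <= 0.03

    def test_modulus_scales_with_assumed_thickness(self, cylinder, cylinder_cl,
                                                   inflated_cylinder, profile):
        ps = ast.assemble_phase_set(cylinder, [inflated_cylinder],
                                    labels=["sys"])
        doubled = ast.stiffness_profile(ps, cylinder_cl,
                                        ast.PressureSpec.from_dp(40.0),
                                        thickness_mm=4.0, method="both",
                                        systolic_label="sys")
        np.testing.assert_allclose(doubled.e_lh_mpa, 0.5 * profile.e_lh_mpa,
                                   rtol=1e-9)
        np.testing.assert_allclose(doubled.e_ie_mpa, 0.5 * profile.e_ie_mpa,
                                   rtol=1e-3)

    def test_curvature_factor_reported_as_one(self, profile):
        np.testing.assert_array_equal(profile.m_factor, 1.0)
        assert profile.warnings == []

    def test_systolic_phase_autoselected(self, cylinder, cylinder_cl,
                                         inflated_cylinder):
        ps = ast.assemble_phase_set(cylinder,
                                    [cylinder, inflated_cylinder],
                                    labels=["0%", "40%"])
        prof = ast.stiffness_profile(ps, cylinder_cl,
                                     ast.PressureSpec.from_dp(40.0))
        assert prof.phase_label == "40%"
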