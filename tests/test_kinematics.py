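"""Cross-sections, contour lengths, circumferential strain, phase selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import aortastiff as ast
from aortastiff.kinematics import (
    CrossSection,
    SectionError,
    StrainProfile,
    contour_length,
    extract_material_contour,
)
from conftest import circle_section


class TestExtractSection:
    def test_structured_ring_selected(self, cylinder, cylinder_cl):
        # a tolerance of half the axial spacing captures exactly one ring
        spacing = 100.0 / 39
        sec = ast.extract_section(cylinder, cylinder_cl, 20, tol=0.5 * spacing)
        assert sec.n_nodes == 32
        np.testing.assert_allclose(sec.rho, 16.0, rtol=1e-6)

    def test_zero_tolerance_rejected(self, cylinder, cylinder_cl):
        with pytest.raises(SectionError):
            ast.extract_section(cylinder, cylinder_cl, 20, tol=0.0)

    def test_tilted_plane_contour_closes(self, cylinder):
        # cut the cylinder obliquely: rho varies (ellipse) but no gap > pi/2
        from aortastiff.centerline import Centerline

        n = 10
        normal = np.array([np.sin(0.3), 0.0, np.cos(0.3)])
        cl = Centerline(
            points=np.linspace([0, 0, 10], [0, 0, 90], n),
            xi=np.linspace(0, 1, n),
            tangents=np.tile(normal, (n, 1)),
            r0_mm=np.full(n, np.inf),
            section_radius_mm=np.full(n, 16.0),
        )
        sec = ast.extract_section(cylinder, cl, 5, tol=1.8)
        assert np.ptp(sec.rho) > 0.1
        gaps = np.diff(np.concatenate([sec.theta, [sec.theta[0] + 2 * np.pi]]))
        assert gaps.max() < np.pi / 2

    def test_sparse_section_error_message(self, cylinder):
        # stations that fall between node rings catch nothing at tiny tol
        cl = ast.compute_centerline(cylinder, n_stations=37,
                                    inflow_hint=np.array([0.0, 0, 0]))
        with pytest.raises(SectionError, match="sparse|no nodes"):
            ast.extract_section(cylinder, cl, 17, tol=1e-6)


class TestContourLength:
    @pytest.mark.parametrize("n", [8, 37, 100])
    def test_circle_exact_at_any_node_count(self, n):
        sec = circle_section(radius=16.0, n=n)
        assert contour_length(sec) == pytest.approx(2 * np.pi * 16.0, rel=1e-12)

    def test_unit_circle(self):
        sec = circle_section(radius=1.0, n=100)
        assert contour_length(sec) == pytest.approx(2 * np.pi, rel=1e-12)

    def test_ellipse_matches_dense_quadrature(self):
        a, b, n = 20.0, 10.0, 200
        theta = np.sort(np.linspace(-np.pi, np.pi, n, endpoint=False))
        rho = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        sec = circle_section(n=n)
        sec.rho = rho
        # dense quadrature oracle of the radial integral (not the perimeter)
        tt = np.linspace(-np.pi, np.pi, 200001)
        rr = a * b / np.sqrt((b * np.cos(tt)) ** 2 + (a * np.sin(tt)) ** 2)
        oracle = np.trapezoid(rr, tt)
        assert contour_length(sec) == pytest.approx(oracle, rel=1e-3)
        # and it intentionally differs from the Euclidean perimeter
        assert contour_length(sec, mode="polygon") > contour_length(sec) * 1.01

    def test_invariant_under_rigid_rotation(self, cylinder, cylinder_cl):
        sec = ast.extract_section(cylinder, cylinder_cl, 20)
        length = contour_length(sec)
        # rotate the whole section set-up about z
        c, s = np.cos(0.7), np.sin(0.7)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rotated = cylinder.with_nodes(cylinder.nodes @ rot.T)
        cl_rot = ast.compute_centerline(rotated, n_stations=40,
                                        inflow_hint=np.array([0.0, 0, 0]))
        sec_rot = ast.extract_section(rotated, cl_rot, 20)
        assert contour_length(sec_rot) == pytest.approx(length, rel=1e-4)


class TestStrain:
    def test_identity_gives_zero(self, cylinder, cylinder_cl):
        sec = ast.extract_section(cylinder, cylinder_cl, 20)
        sec_sys = ast.section_in_phase(sec, cylinder)
        assert ast.circumferential_strain(sec, sec_sys) == pytest.approx(0.0,
                                                                         abs=1e-12)

    def test_thin_wall_inflation_strain(self, small_spec, cylinder, cylinder_cl):
        # L_dia = 100.53 mm, L_sys = 109.11 mm -> eps = 0.0853
        sys_mesh = ast.analytic_inflate_cylinder(small_spec, 0.5, 40.0,
                                                 mesh=cylinder)
        sec = ast.extract_section(cylinder, cylinder_cl, 20)
        l_dia = contour_length(sec)
        sec_sys = ast.section_in_phase(sec, sys_mesh)
        assert l_dia == pytest.approx(100.53, abs=0.01)
        assert contour_length(sec_sys) == pytest.approx(109.11, abs=0.02)
        eps = ast.circumferential_strain(sec, sec_sys)
        assert eps == pytest.approx(0.08533, abs=2e-4)

    @given(st.floats(0.8, 1.3))
    def test_uniform_scaling_gives_k_minus_one(self, k):
        sec = circle_section(n=48)
        scaled = CrossSection(
            station=0, xi=0.5, node_indices=sec.node_indices.copy(),
            origin=sec.origin, normal=sec.normal, basis=sec.basis,
            rho=sec.rho * k, theta=sec.theta.copy(),
        )
        eps = ast.circumferential_strain(sec, scaled)
        assert eps == pytest.approx(k - 1.0, abs=1e-9)

    def test_negative_strain_reported_not_clipped(self):
        sec = circle_section(n=48)
        shrunk = CrossSection(
            station=0, xi=0.5, node_indices=sec.node_indices.copy(),
            origin=sec.origin, normal=sec.normal, basis=sec.basis,
            rho=sec.rho * 0.95, theta=sec.theta.copy(),
        )
        assert ast.circumferential_strain(sec, shrunk) == pytest.approx(-0.05,
                                                                        abs=1e-9)

    def test_node_set_mismatch_rejected(self):
        a = circle_section(n=48)
        b = circle_section(n=48)
        b.node_indices = b.node_indices + 1
        with pytest.raises(SectionError, match="node set"):
            ast.circumferential_strain(a, b)

    def test_rigid_translation_gives_zero_strain(self, cylinder, cylinder_cl):
        moved = cylinder.with_nodes(cylinder.nodes + np.array([4.0, -7.0, 2.0]))
        sec = ast.extract_section(cylinder, cylinder_cl, 20)
        sec_sys = ast.section_in_phase(sec, moved)
        assert abs(ast.circumferential_strain(sec, sec_sys)) < 1e-9


class TestMaterialContour:
    def test_circle_contour_length_exact(self, cylinder, cylinder_cl):
        mc = extract_material_contour(cylinder, cylinder_cl, 20)
        assert mc.contour_length(cylinder) == pytest.approx(2 * np.pi * 16.0,
                                                            rel=1e-4)

    def test_strain_matches_node_sections_on_cylinder(self, small_spec,
                                                      cylinder, cylinder_cl):
        sys_mesh = ast.analytic_inflate_cylinder(small_spec, 0.5, 40.0,
                                                 mesh=cylinder)
        mc = extract_material_contour(cylinder, cylinder_cl, 20)
        eps_mc = mc.strain(cylinder, sys_mesh)
        sec = ast.extract_section(cylinder, cylinder_cl, 20)
        eps_nd = ast.circumferential_strain(
            sec, ast.section_in_phase(sec, sys_mesh))
        assert eps_mc == pytest.approx(eps_nd, abs=5e-4)
        assert mc.mean_radius_mm(sys_mesh) == pytest.approx(17.365, abs=0.02)


class TestStrainProfile:
    def test_baseline_vs_baseline_all_zero(self, cylinder, cylinder_cl):
        ps = ast.assemble_phase_set(cylinder, [cylinder], labels=["same"])
        prof = ast.strain_profile(ps, cylinder_cl, "same")
        np.testing.assert_allclose(prof.epsilon, 0.0, atol=1e-12)

    def test_analytic_inflation_flat_profile(self, small_spec, cylinder,
                                             cylinder_cl):
        sys_mesh = ast.analytic_inflate_cylinder(small_spec, 0.5, 40.0,
                                                 mesh=cylinder)
        ps = ast.assemble_phase_set(cylinder, [sys_mesh], labels=["sys"])
        prof = ast.strain_profile(ps, cylinder_cl, "sys")
        assert np.nanmean(prof.epsilon) == pytest.approx(0.08533, abs=5e-4)
        assert np.ptp(prof.epsilon) <= 0.005  # <=0.5% absolute spread

    def test_node_map_constant_within_sections(self, small_spec, cylinder,
                                               cylinder_cl):
        sys_mesh = ast.analytic_inflate_cylinder(small_spec, 0.5, 40.0,
                                                 mesh=cylinder)
        ps = ast.assemble_phase_set(cylinder, [sys_mesh], labels=["sys"])
        prof = ast.strain_profile(ps, cylinder_cl, "sys")
        valid = np.isfinite(prof.node_map)
        assert valid.sum() > 0
        assert set(np.round(prof.node_map[valid], 10)) <= set(
            np.round(prof.epsilon, 10))


class TestSystolicPhaseSelection:
    @staticmethod
    def profile(label, peak):
        xi = np.linspace(0.1, 0.9, 5)
        return StrainProfile(phase_label=label, xi=xi,
                             epsilon=np.full(5, peak), stations=np.arange(5),
                             node_map=np.full(5, peak))

    def test_argmax_selection(self):
        profs = [self.profile(lab, p) for lab, p in
                 zip(["20%", "40%", "60%", "80%"], [0.03, 0.08, 0.05, 0.02])]
        assert ast.select_systolic_phase(profs) == "40%"

    def test_single_phase(self):
        assert ast.select_systolic_phase([self.profile("20%", 0.05)]) == "20%"

    def test_tie_breaks_to_earlier_phase(self, caplog):
        import logging

        profs = [self.profile("20%", 0.05), self.profile("40%", 0.05)]
        with caplog.at_level(logging.WARNING, logger="aortastiff"):
            assert ast.select_systolic_phase(profs) == "20%"
        assert any("tie" in r.message for r in caplog.records)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ast.select_systolic_phase([])
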