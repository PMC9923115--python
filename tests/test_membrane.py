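"""Membrane solver patch tests, equilibrium determinacy and forward inflation."""

import numpy as np
import pytest

import aortastiff as ast
from aortastiff.membrane import (
    BoundaryCondition,
    MembraneError,
    MembraneModel,
    solve_membrane,
    tube_boundary_conditions,
)
from aortastiff.mesh import MMHG_TO_PA

P40 = 40.0 * MMHG_TO_PA


def sphere_model(mesh, e_pa=50e9):
    return MembraneModel(mesh=mesh, e_pa=e_pa, nu=0.0, thickness_mm=2.0,
                         pressure_pa=P40, bcs=[])


class TestPatchTests:
    def test_sphere_laplace_law(self, sphere_mesh):
        mesh = sphere_mesh(3, radius_mm=20.0)
        res = solve_membrane(sphere_model(mesh))
        analytic = P40 * 0.020 / (2 * 0.002)   # p R / (2 delta)
        err = np.abs(res.nodal_max_principal_pa / analytic - 1.0)
        assert err.max() <= 0.03

    def test_sphere_convergence_monotone(self, sphere_mesh):
        errs = []
        analytic = P40 * 0.020 / (2 * 0.002)
        for sub in (1, 2, 3):
            res = solve_membrane(sphere_model(sphere_mesh(sub, 20.0)))
            errs.append(np.mean(np.abs(res.nodal_max_principal_pa / analytic - 1)))
        assert errs[0] > errs[1] > errs[2]

    def test_tube_hoop_stress(self, cylinder):
        bcs = tube_boundary_conditions(cylinder, np.array([0.0, 0, 0]))
        res = solve_membrane(MembraneModel(
            mesh=cylinder, e_pa=50e9, nu=0.0, thickness_mm=2.0,
            pressure_pa=P40, bcs=bcs))
        hoop = P40 * 0.016 / 0.002
        mid = (cylinder.nodes[:, 2] > 30) & (cylinder.nodes[:, 2] < 70)
        err = np.abs(res.nodal_max_principal_pa[mid] / hoop - 1.0)
        assert err.max() <= 0.03

    def test_linearity_in_pressure_and_thickness(self, cylinder):
        bcs = tube_boundary_conditions(cylinder, np.array([0.0, 0, 0]))

        def solve(p, t):
            return solve_membrane(MembraneModel(
                mesh=cylinder, e_pa=50e9, nu=0.0, thickness_mm=t,
                pressure_pa=p, bcs=bcs)).nodal_max_principal_pa

        base = solve(P40, 2.0)
        np.testing.assert_allclose(solve(2 * P40, 2.0), 2 * base, rtol=1e-9)
        np.testing.assert_allclose(solve(P40, 4.0), 0.5 * base, rtol=1e-9)


class TestEquilibriumDeterminacy:
    def test_inverse_stress_independent_of_rigid_modulus(self, cylinder):
        bcs = tube_boundary_conditions(cylinder, np.array([0.0, 0, 0]))
        fields = []
        for e in (10e9, 100e9):
            res = solve_membrane(MembraneModel(
                mesh=cylinder, e_pa=e, nu=0.0, thickness_mm=2.0,
                pressure_pa=P40, bcs=bcs))
            fields.append(res.nodal_max_principal_pa)
        rel = np.abs(fields[0] - fields[1]) / np.abs(fields[1])
        assert rel.max() <= 1e-3

    def test_inverse_stress_on_inflated_cylinder(self, small_spec, cylinder):
        # hoop formula evaluated on the deformed radius 17.37 mm -> 46.3 kPa
        sys_mesh = ast.analytic_inflate_cylinder(small_spec, 0.5, 40.0,
                                                 mesh=cylinder)
        res = ast.inverse_stress_field(sys_mesh, dp_mmhg=40.0, thickness_mm=2.0,
                                       inflow_point=np.array([0.0, 0, 0]))
        r_sys = 0.0173652
        expected = P40 * r_sys / 0.002
        mid = (sys_mesh.nodes[:, 2] > 30) & (sys_mesh.nodes[:, 2] < 70)
        err = np.abs(res.nodal_max_principal_pa[mid] / expected - 1.0)
        assert err.max() <= 0.03
        assert expected / 1e3 == pytest.approx(46.3, abs=0.2)

    def test_elbow_intrados_stress_exceeds_extrados(self, elbow90):
        res = ast.inverse_stress_field(elbow90, dp_mmhg=40.0, thickness_mm=2.0,
                                       inflow_point=np.array([0.0, 0, 0]))
        # mid-bend section: intrados lies towards the bend centre (+x side
        # beyond the centerline), extrados away from it
        r0 = ast.TubeSpec(bend_angle_deg=90.0).bend_radius_mm
        center = np.array([r0, 0.0, 0.0])
        dist = np.linalg.norm(elbow90.nodes - center, axis=1)
        phi = np.arctan2(elbow90.nodes[:, 2], r0 - elbow90.nodes[:, 0])
        mid = np.abs(phi - np.pi / 4) < 0.1
        intrados = mid & (dist < r0 - 10)
        extrados = mid & (dist > r0 + 10)
        assert intrados.sum() > 0 and extrados.sum() > 0
        assert (res.nodal_max_principal_pa[intrados].mean()
                > res.nodal_max_principal_pa[extrados].mean())


class TestBoundaryConditions:
    def test_insufficient_constraints_detected(self, elbow90):
        # a bent open tube carries a net pressure force; with no ring held
        # the model rides on the stabilization springs
        with pytest.raises(MembraneError):
            solve_membrane(MembraneModel(
                mesh=elbow90, e_pa=50e9, nu=0.0, thickness_mm=2.0,
                pressure_pa=P40, bcs=[]))

    def test_bc_validation(self):
        with pytest.raises(ValueError, match="direction"):
            BoundaryCondition(nodes=np.array([0]), kind="free_radial")
        with pytest.raises(ValueError, match="unknown"):
            BoundaryCondition(nodes=np.array([0]), kind="clamped")

    def test_model_validation(self, cylinder):
        with pytest.raises(ValueError):
            MembraneModel(mesh=cylinder, e_pa=-1.0, nu=0.0, thickness_mm=2.0,
                          pressure_pa=0.0)
        with pytest.raises(ValueError):
            MembraneModel(mesh=cylinder, e_pa=1e9, nu=0.6, thickness_mm=2.0,
                          pressure_pa=0.0)


class TestForwardInflate:
    def test_zero_pressure_identity(self, cylinder, soft_field, cylinder_cl):
        out = ast.forward_inflate(cylinder, soft_field, cylinder_cl,
                                  dp_mmhg=0.0)
        np.testing.assert_allclose(out.nodes, cylinder.nodes, atol=1e-9)

    def test_linear_solve_matches_thin_wall(self, cylinder, soft_field,
                                            cylinder_cl):
        # small-strain single solve: u_r = dP r^2 / (delta E) = 1.365 mm
        out = ast.forward_inflate(cylinder, soft_field, cylinder_cl,
                                  dp_mmhg=40.0, linear=True)
        mid = (cylinder.nodes[:, 2] > 30) & (cylinder.nodes[:, 2] < 70)
        u_r = (np.linalg.norm(out.nodes[mid, :2], axis=1)
               - np.linalg.norm(cylinder.nodes[mid, :2], axis=1))
        assert u_r.mean() == pytest.approx(1.365, rel=0.02)

    def test_converged_solve_matches_finite_inflation(self, inflated_cylinder,
                                                      cylinder):
        # fixed point r_dia / (1 - dP r/(delta E)) = 17.492 mm
        mid = (cylinder.nodes[:, 2] > 30) & (cylinder.nodes[:, 2] < 70)
        r = np.linalg.norm(inflated_cylinder.nodes[mid, :2], axis=1)
        assert r.mean() == pytest.approx(17.492, rel=0.005)

    def test_step_field_displacement_ratio(self, cylinder, cylinder_cl):
        fld = ast.StiffnessField(kind="proximal_distal", e_p_mpa=2.0,
                                 e_d_mpa=0.5, transition_xi=0.5)
        out = ast.forward_inflate(cylinder, fld, cylinder_cl, dp_mmhg=40.0)
        u_r = (np.linalg.norm(out.nodes[:, :2], axis=1) - 16.0)
        z = cylinder.nodes[:, 2]
        prox = u_r[(z > 15) & (z < 35)].mean()
        dist = u_r[(z > 65) & (z < 85)].mean()
        # thin-wall: u ~ 1/E per segment away from the transition
        assert prox / dist == pytest.approx(0.25, rel=0.1)
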