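"""Shared fixtures: small structured tubes and their centerlines.

Fixture meshes are generated at reduced resolution (32 x 40) so the unit
suite stays fast; the acceptance tests build the full-resolution study
geometries themselves.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import aortastiff as ast

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def circle_section(radius: float = 16.0, n: int = 64, station: int = 0):
    """Synthetic circular cross-section used by formula-level tests."""
    from aortastiff.kinematics import CrossSection

    theta = np.sort(np.linspace(-np.pi, np.pi, n, endpoint=False))
    basis = np.array([[1.0, 0, 0], [0, 1.0, 0]])
    return CrossSection(
        station=station, xi=0.5,
        node_indices=np.arange(n),
        origin=np.zeros(3), normal=np.array([0.0, 0, 1]), basis=basis,
        rho=np.full(n, radius), theta=theta,
    )


@pytest.fixture(scope="session")
def small_spec() -> ast.TubeSpec:
    return ast.TubeSpec(n_circumferential=32, n_axial=40)


@pytest.fixture(scope="session")
def cylinder(small_spec) -> ast.SurfaceMesh:
    return ast.make_tube(small_spec)


@pytest.fixture(scope="session")
def cylinder_cl(cylinder) -> ast.Centerline:
    return ast.compute_centerline(cylinder, n_stations=40,
                                  inflow_hint=np.array([0.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def elbow90(small_spec) -> ast.SurfaceMesh:
    return ast.make_tube(ast.TubeSpec(bend_angle_deg=90.0,
                                      n_circumferential=32, n_axial=40))


@pytest.fixture(scope="session")
def elbow90_cl(elbow90) -> ast.Centerline:
    return ast.compute_centerline(elbow90, n_stations=40,
                                  inflow_hint=np.array([0.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def soft_field() -> ast.StiffnessField:
    return ast.StiffnessField(kind="homogeneous", e_h_mpa=0.5)


@pytest.fixture(scope="session")
def inflated_cylinder(small_spec, cylinder, soft_field, cylinder_cl):
    """Forward-pressurized cylinder (40 mmHg, E = 0.5 MPa, delta = 2 mm)."""
    return ast.forward_inflate(cylinder, soft_field, cylinder_cl, dp_mmhg=40.0)


@pytest.fixture(scope="session")
def sphere_mesh():
    import trimesh

    def build(subdivisions: int = 3, radius_mm: float = 20.0) -> ast.SurfaceMesh:
        ico = trimesh.creation.icosphere(subdivisions=subdivisions,
                                         radius=radius_mm)
        from aortastiff.surfaces import orient_outward

        mesh = ast.SurfaceMesh(nodes=np.asarray(ico.vertices, float),
                               triangles=np.asarray(ico.faces))
        return orient_outward(mesh)

    return build
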