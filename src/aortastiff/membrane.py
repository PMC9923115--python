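"""Linear membrane finite-element solver (constant-strain triangles).

Used twice by the pipeline:

* forward, with the soft imposed modulus field, to generate "systolic"
  validation surfaces by pressurizing a diastolic geometry; and
* inverse, with a practically undeformable material (E >= 10 GPa), to
  evaluate the equilibrium wall tension of the pressurized systolic
  surface.  Membrane tension in a pressurized membrane is statically
  determinate, so the inverse stresses depend on morphology only — they
  are insensitive to the chosen rigid modulus (asserted by tests).

Elements are flat constant-strain triangles carrying the plane-stress
constitutive law in their own plane; internal pressure is applied as
consistent nodal loads along element outward normals (p*A/3 per vertex).
Pure membranes on curved open surfaces admit near-singular normal
(inextensional) modes, so a small artificial normal-spring stabilization
is added; the sphere and cylinder patch tests bound its bias well below
a percent.

The forward problem is solved with a co-rotational Newton scheme: element
strains are engineering strains measured in each triangle's own rotated
frame, internal forces balance the follower pressure on the *deformed*
configuration, and the tangent includes the initial-stress (geometric)
stiffness, which is what physically stabilizes a tensioned membrane
against inextensional ovalization modes.  The converged systolic surface
therefore satisfies exactly the relation the downstream estimator assumes
— membrane stress of the deformed geometry equal to the imposed modulus
times the engineering strain — so parameter recovery is limited by
discretization, not by the solver.  For a thin cylinder the converged
radius is the closed-form fixed point r_dia / (1 - dP r/(delta E)).

Internally the solver works in SI units (m, Pa); the public surface keeps
mesh coordinates in mm and accepts pressures in mmHg where noted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve

from .centerline import Centerline
from .mesh import MMHG_TO_PA, SurfaceMesh
from .surfaces import boundary_rings
from .synthetic import StiffnessField, evaluate_field

__all__ = [
    "BoundaryCondition",
    "MembraneModel",
    "StressResult",
    "solve_membrane",
    "forward_inflate",
    "inverse_stress_field",
    "tube_boundary_conditions",
]

log = logging.getLogger("aortastiff")

#: rigid modulus for the inverse (equilibrium) solve; any value > 10 GPa
#: gives the same stresses to within the stabilization noise.
RIGID_MODULUS_PA = 50e9

#: relative stiffness of the artificial normal springs.
NORMAL_SPRING_REL = 1e-6
#: tiny isotropic grounding that removes residual rigid-body modes
#: (needed for closed surfaces such as the sphere patch test).
ISO_SPRING_REL = 1e-9

#: penalty factor for directional boundary constraints.
PENALTY_REL = 1e7


class MembraneError(RuntimeError):
    """Raised for singular or non-converged membrane solves."""


@dataclass(frozen=True)
class BoundaryCondition:
    """Constraint on one set of nodes (typically a boundary ring).

    kind
        ``fixed``       — all three displacement components zero;
        ``free_radial`` — component along ``direction`` zero, in-plane
                          (radial) motion free: the "arch plane" condition;
        ``axial_only``  — motion allowed only along ``direction``.
    """

    nodes: np.ndarray
    kind: str
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "free_radial", "axial_only"):
            raise ValueError(f"unknown boundary condition kind {self.kind!r}")
        if self.kind != "fixed" and self.direction is None:
            raise ValueError(f"{self.kind} requires a direction vector")


@dataclass
class MembraneModel:
    """One linear static membrane problem.

    ``e_pa`` may be a scalar or a per-element array; ``pressure_pa`` acts
    along element outward normals (mesh winding must be outward).
    """

    mesh: SurfaceMesh
    e_pa: np.ndarray | float
    nu: float
    thickness_mm: float
    pressure_pa: float
    bcs: list[BoundaryCondition] = field(default_factory=list)

    def __post_init__(self) -> None:
        e = np.broadcast_to(np.asarray(self.e_pa, float),
                            (self.mesh.n_triangles,)).copy()
        if np.any(e <= 0):
            raise ValueError("element moduli must be positive")
        self.e_pa = e
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class StressResult:
    """Outcome of one membrane solve.

    element_principal_pa : (n_tris, 2) in-plane principal stresses, major
    first; nodal_max_principal_pa : per-node area-weighted average of the
    adjacent elements' major principal stress; displacement_mm : nodal
    displacement field.
    """

    element_principal_pa: np.ndarray
    nodal_max_principal_pa: np.ndarray
    displacement_mm: np.ndarray

    def nodal_max_principal_kpa(self) -> np.ndarray:
        return self.nodal_max_principal_pa / 1e3


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _element_operators(nodes_m: np.ndarray, tris: np.ndarray):
    """Per-element frames, areas, B-matrices and 2D->3D transformations."""
    p1, p2, p3 = (nodes_m[tris[:, i]] for i in range(3))
    v12, v13 = p2 - p1, p3 - p1
    n = np.cross(v12, v13)
    double_area = np.linalg.norm(n, axis=1)
    if np.any(double_area < 1e-30):
        raise MembraneError("degenerate element during assembly")
    nh = n / double_area[:, None]
    area = 0.5 * double_area
    e1 = v12 / np.linalg.norm(v12, axis=1, keepdims=True)
    e2 = np.cross(nh, e1)

    x2 = np.sum(v12 * e1, axis=1)
    x3 = np.sum(v13 * e1, axis=1)
    y3 = np.sum(v13 * e2, axis=1)
    # local node coords: (0,0), (x2,0), (x3,y3)
    b = np.stack([-y3, y3, np.zeros_like(y3)], axis=1)          # y_j - y_k
    c = np.stack([x3 - x2, -x3, x2], axis=1)                    # x_k - x_j

    m = len(tris)
    bmat = np.zeros((m, 3, 6))
    bmat[:, 0, 0::2] = b
    bmat[:, 1, 1::2] = c
    bmat[:, 2, 0::2] = c
    bmat[:, 2, 1::2] = b
    bmat /= double_area[:, None, None]

    tmat = np.zeros((m, 6, 9))
    for j in range(3):
        tmat[:, 2 * j, 3 * j:3 * j + 3] = e1
        tmat[:, 2 * j + 1, 3 * j:3 * j + 3] = e2
    return nh, area, bmat, tmat


def _material_matrix(model: MembraneModel):
    """Material stiffness, pressure loads and element operators."""
    mesh = model.mesh
    nodes_m = mesh.nodes * 1e-3
    tris = mesh.triangles
    t = model.thickness_mm * 1e-3
    nh, area, bmat, tmat = _element_operators(nodes_m, tris)

    nu = model.nu
    dmat = np.zeros((len(tris), 3, 3))
    coef = model.e_pa / (1.0 - nu**2)
    dmat[:, 0, 0] = dmat[:, 1, 1] = coef
    dmat[:, 0, 1] = dmat[:, 1, 0] = coef * nu
    dmat[:, 2, 2] = coef * (1.0 - nu) / 2.0

    k2 = np.einsum("mji,mjk,mkl->mil", bmat, dmat, bmat)
    k2 *= (t * area)[:, None, None]
    k9 = np.einsum("mji,mjk,mkl->mil", tmat, k2, tmat)

    dofs = (3 * tris[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 9)
    rows = np.repeat(dofs, 9, axis=1).ravel()
    cols = np.tile(dofs, (1, 9)).ravel()
    ndof = 3 * mesh.n_nodes
    kmat = coo_matrix((k9.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    # consistent pressure loads along outward normals
    f_el = (model.pressure_pa * area / 3.0)[:, None] * nh
    fvec = np.zeros(ndof)
    for j in range(3):
        np.add.at(fvec.reshape(-1, 3), tris[:, j], f_el)
    return kmat, fvec, (nh, area, bmat, tmat, dmat)


def _springs(model: MembraneModel, material_diag: np.ndarray) -> csr_matrix:
    """Stabilization springs plus boundary-condition penalty blocks."""
    mesh = model.mesh
    tris = mesh.triangles
    nh, area, _, _ = _element_operators(mesh.nodes * 1e-3, tris)
    mean_diag = material_diag.mean()
    node_n = np.zeros((mesh.n_nodes, 3))
    for j in range(3):
        np.add.at(node_n, tris[:, j], nh * area[:, None])
    norms = np.linalg.norm(node_n, axis=1, keepdims=True)
    node_n = np.divide(node_n, norms, out=np.zeros_like(node_n),
                       where=norms > 1e-30)
    blocks = (NORMAL_SPRING_REL * mean_diag
              * np.einsum("ni,nj->nij", node_n, node_n))
    blocks += ISO_SPRING_REL * mean_diag * np.eye(3)[None, :, :]

    alpha = PENALTY_REL * material_diag.max()
    for bc in model.bcs:
        nodes = np.asarray(bc.nodes, dtype=np.int64)
        if bc.kind == "fixed":
            blocks[nodes] += alpha * np.eye(3)
        else:
            d = np.asarray(bc.direction, float)
            d = d / np.linalg.norm(d)
            proj = np.outer(d, d)
            if bc.kind == "free_radial":
                blocks[nodes] += alpha * proj   # constrain along direction
            else:  # axial_only: constrain everything orthogonal to direction
                blocks[nodes] += alpha * (np.eye(3) - proj)
    return _block_diag(blocks)


def _spring_matrix(model: MembraneModel) -> csr_matrix:
    kmat, _, _ = _material_matrix(model)
    return _springs(model, kmat.diagonal())


def _assemble(model: MembraneModel):
    kmat, fvec, ops = _material_matrix(model)
    kmat = kmat + _springs(model, kmat.diagonal())
    return kmat, fvec, ops


def _block_diag(blocks: np.ndarray) -> csr_matrix:
    """Sparse block-diagonal matrix from (n, 3, 3) nodal blocks."""
    n = blocks.shape[0]
    base = 3 * np.arange(n)[:, None, None]
    rows = (base + np.arange(3)[None, :, None] + np.zeros((1, 1, 3), int)).ravel()
    cols = (base + np.zeros((1, 3, 1), int) + np.arange(3)[None, None, :]).ravel()
    return coo_matrix((blocks.ravel(), (rows, cols)),
                      shape=(3 * n, 3 * n)).tocsr()


def solve_membrane(model: MembraneModel) -> StressResult:
    """Solve the linear static membrane problem.

    Returns element principal stresses, nodal maximal principal stress
    (area-weighted over adjacent elements) and the displacement field.
    Raises :class:`MembraneError` for singular/non-finite solves
    (insufficient constraints).
    """
    if not model.bcs and model.pressure_pa != 0 and boundary_rings(model.mesh):
        raise MembraneError(
            "open surface under pressure with no boundary conditions: the "
            "static problem is unsupported (insufficient constraints)"
        )
    kmat, fvec, (nh, area, bmat, tmat, dmat) = _assemble(model)
    u = spsolve(kmat.tocsc(), fvec)
    if not np.all(np.isfinite(u)):
        raise MembraneError("membrane solve produced non-finite displacements "
                            "(insufficient constraints?)")
    extent_m = 1e-3 * np.ptp(model.mesh.nodes, axis=0).max()
    if np.abs(u).max() > 10.0 * extent_m:
        raise MembraneError(
            "membrane displacements exceed 10x the mesh extent — the model "
            "is riding on the stabilization springs (insufficient constraints)"
        )
    resid = np.linalg.norm(kmat @ u - fvec)
    fnorm = np.linalg.norm(fvec)
    if fnorm > 0 and resid > 1e-5 * fnorm:
        raise MembraneError(f"sparse solve residual too large: {resid:.3e} "
                            f"(|f| = {fnorm:.3e})")

    tris = model.mesh.triangles
    u_el = u.reshape(-1, 3)[tris].reshape(len(tris), 9)
    u_loc = np.einsum("mij,mj->mi", tmat, u_el)
    strain = np.einsum("mij,mj->mi", bmat, u_loc)
    stress = np.einsum("mij,mj->mi", dmat, strain)
    sx, sy, txy = stress[:, 0], stress[:, 1], stress[:, 2]
    center = 0.5 * (sx + sy)
    radius = np.sqrt((0.5 * (sx - sy)) ** 2 + txy**2)
    principal = np.stack([center + radius, center - radius], axis=1)

    nodal = np.zeros(model.mesh.n_nodes)
    wsum = np.zeros(model.mesh.n_nodes)
    for j in range(3):
        np.add.at(nodal, tris[:, j], principal[:, 0] * area)
        np.add.at(wsum, tris[:, j], area)
    nodal /= wsum
    return StressResult(
        element_principal_pa=principal,
        nodal_max_principal_pa=nodal,
        displacement_mm=u.reshape(-1, 3) * 1e3,
    )


# ---------------------------------------------------------------------------
# pipeline-facing drivers
# ---------------------------------------------------------------------------

def tube_boundary_conditions(
    mesh: SurfaceMesh, inflow_point: np.ndarray
) -> list[BoundaryCondition]:
    """Valve-plane / arch-plane conditions for an open tube.

    The boundary ring nearest ``inflow_point`` is fully fixed (the "valve
    plane"); the other ring is constrained along its own plane normal and
    left radially free (the "arch plane").
    """
    rings = boundary_rings(mesh)
    if len(rings) != 2:
        raise MembraneError(f"expected 2 boundary rings, found {len(rings)}")
    cents = [mesh.nodes[r].mean(axis=0) for r in rings]
    inflow_point = np.asarray(inflow_point, float)
    i_in = int(np.argmin([np.linalg.norm(c - inflow_point) for c in cents]))
    i_out = 1 - i_in
    pts = mesh.nodes[rings[i_out]]
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
    return [
        BoundaryCondition(nodes=rings[i_in], kind="fixed"),
        BoundaryCondition(nodes=rings[i_out], kind="free_radial", direction=vt[2]),
    ]


def _corot_internal(nodes0_m, nodes_m, tris, dmat, t):
    """Co-rotational element state: internal forces, tangent blocks, stress.

    Strains are engineering strains of each triangle measured in its own
    current frame against the baseline shape; exact for rigid motion,
    accurate to O(strain x in-element rotation) otherwise.
    """
    def local_frame(nodes):
        p1, p2, p3 = (nodes[tris[:, i]] for i in range(3))
        v12, v13 = p2 - p1, p3 - p1
        n = np.cross(v12, v13)
        dbl = np.linalg.norm(n, axis=1)
        nh = n / dbl[:, None]
        e1 = v12 / np.linalg.norm(v12, axis=1, keepdims=True)
        e2 = np.cross(nh, e1)
        x2 = np.sum(v12 * e1, axis=1)
        x3 = np.sum(v13 * e1, axis=1)
        y3 = np.sum(v13 * e2, axis=1)
        return nh, 0.5 * dbl, e1, e2, x2, x3, y3

    nh0, a0, _, _, x2_0, x3_0, y3_0 = local_frame(nodes0_m)
    nh, a_c, e1, e2, x2, x3, y3 = local_frame(nodes_m)

    m = len(tris)
    # baseline B matrix (constant; strains measured against baseline shape)
    b = np.stack([-y3_0, y3_0, np.zeros(m)], axis=1)
    c = np.stack([x3_0 - x2_0, -x3_0, x2_0], axis=1)
    bmat = np.zeros((m, 3, 6))
    bmat[:, 0, 0::2] = b
    bmat[:, 1, 1::2] = c
    bmat[:, 2, 0::2] = c
    bmat[:, 2, 1::2] = b
    bmat /= (2.0 * a0)[:, None, None]

    # local displacements: node1 pinned, edge 1-2 along e1 in both frames
    d_loc = np.zeros((m, 6))
    d_loc[:, 2] = x2 - x2_0
    d_loc[:, 4] = x3 - x3_0
    d_loc[:, 5] = y3 - y3_0

    strain = np.einsum("mij,mj->mi", bmat, d_loc)
    # the estimator's constitutive frame: Cauchy stress proportional to the
    # engineering strain (what a linear-elastic material in a commercial
    # large-deflection solve effectively imposes)
    stress = np.einsum("mij,mj->mi", dmat, strain)      # (sx, sy, txy) local

    tmat = np.zeros((m, 6, 9))
    for j in range(3):
        tmat[:, 2 * j, 3 * j:3 * j + 3] = e1
        tmat[:, 2 * j + 1, 3 * j:3 * j + 3] = e2

    # internal force: Cauchy stress acting on the *current* configuration
    b_cur3 = np.stack([-y3, y3, np.zeros(m)], axis=1)
    c_cur3 = np.stack([x3 - x2, -x3, x2], axis=1)
    bmat_c = np.zeros((m, 3, 6))
    bmat_c[:, 0, 0::2] = b_cur3
    bmat_c[:, 1, 1::2] = c_cur3
    bmat_c[:, 2, 0::2] = c_cur3
    bmat_c[:, 2, 1::2] = b_cur3
    bmat_c /= (2.0 * a_c)[:, None, None]

    f_loc = (t * a_c)[:, None] * np.einsum("mji,mj->mi", bmat_c, stress)
    f_int9 = np.einsum("mji,mj->mi", tmat, f_loc)

    kmat2 = np.einsum("mji,mjk,mkl->mil", bmat_c, dmat, bmat_c) \
        * (t * a_c)[:, None, None]
    kmat9 = np.einsum("mji,mjk,mkl->mil", tmat, kmat2, tmat)

    # geometric (initial stress) stiffness from the current configuration
    grads = np.stack([b_cur3, c_cur3], axis=1) / (2.0 * a_c)[:, None, None]
    sig2 = np.empty((m, 2, 2))
    sig2[:, 0, 0] = stress[:, 0]
    sig2[:, 1, 1] = stress[:, 1]
    sig2[:, 0, 1] = sig2[:, 1, 0] = stress[:, 2]
    kg3 = np.einsum("mai,mab,mbj->mij", grads, sig2, grads) \
        * (t * a_c)[:, None, None]
    kg9 = np.einsum("mij,ab->miajb", kg3, np.eye(3)).reshape(m, 9, 9)

    return f_int9, kmat9 + kg9, stress, nh, a_c


def forward_inflate(
    mesh: SurfaceMesh,
    fld: StiffnessField,
    cl: Centerline,
    nu: float = 0.0,
    thickness_mm: float = 2.0,
    dp_mmhg: float = 40.0,
    bcs: list[BoundaryCondition] | None = None,
    n_increments: int = 3,
    max_newton: int = 30,
    rtol: float = 1e-8,
    linear: bool = False,
) -> SurfaceMesh:
    """Pressurize a diastolic surface under an imposed modulus field.

    Element moduli are the field evaluated at each element's centerline
    coordinate (mean of its nodes' projected xi).  The equilibrium of the
    deformed configuration is found by incremental co-rotational Newton
    iteration (see module docstring); ``linear=True`` instead performs a
    single small-strain solve on the undeformed geometry.  The mesh
    winding must be outward.
    """
    if bcs is None:
        bcs = tube_boundary_conditions(mesh, cl.points[0])
    centroids = mesh.nodes[mesh.triangles].mean(axis=1)
    el_xi = cl.xi[cl.nearest_station(centroids)]
    e_el = np.asarray(evaluate_field(fld, el_xi), float) * 1e6

    if linear:
        model = MembraneModel(
            mesh=mesh, e_pa=e_el, nu=nu, thickness_mm=thickness_mm,
            pressure_pa=dp_mmhg * MMHG_TO_PA, bcs=bcs,
        )
        res = solve_membrane(model)
        return mesh.with_nodes(mesh.nodes + res.displacement_mm)

    tris = mesh.triangles
    nodes0 = mesh.nodes * 1e-3
    t = thickness_mm * 1e-3
    dp_pa = dp_mmhg * MMHG_TO_PA
    ndof = 3 * mesh.n_nodes

    dmat = np.zeros((len(tris), 3, 3))
    coef = e_el / (1.0 - nu**2)
    dmat[:, 0, 0] = dmat[:, 1, 1] = coef
    dmat[:, 0, 1] = dmat[:, 1, 0] = coef * nu
    dmat[:, 2, 2] = coef * (1.0 - nu) / 2.0

    dofs = (3 * tris[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 9)
    rows = np.repeat(dofs, 9, axis=1).ravel()
    cols = np.tile(dofs, (1, 9)).ravel()

    # linear springs: stabilization + boundary penalties (forces kept in
    # the residual so the converged solution is penalty-consistent)
    probe = MembraneModel(mesh=mesh, e_pa=e_el, nu=nu,
                          thickness_mm=thickness_mm, pressure_pa=0.0, bcs=bcs)
    k_springs = _spring_matrix(probe)

    u = np.zeros(ndof)
    for inc in range(1, max(1, n_increments) + 1):
        p_load = dp_pa * inc / max(1, n_increments)
        converged = False
        best_rel = np.inf
        stall = 0
        for it in range(max_newton):
            nodes_m = nodes0 + u.reshape(-1, 3)
            f_int9, ktan9, _, nh, a_c = _corot_internal(
                nodes0, nodes_m, tris, dmat, t)
            f_ext = np.zeros(ndof)
            f_el = (p_load * a_c / 3.0)[:, None] * nh
            for j in range(3):
                np.add.at(f_ext.reshape(-1, 3), tris[:, j], f_el)
            f_int = np.zeros(ndof)
            for j in range(3):
                np.add.at(f_int.reshape(-1, 3), tris[:, j],
                          f_int9[:, 3 * j:3 * j + 3])
            resid = f_ext - f_int - k_springs @ u
            rnorm = np.linalg.norm(resid)
            ref = max(np.linalg.norm(f_ext), 1e-30)
            rel = rnorm / ref
            if rel < rtol:
                converged = True
                break
            # the tangent omits the follower-load term, so convergence can
            # stall at a small linear rate; accept a stalled residual well
            # below any physically meaningful level
            stall = stall + 1 if rel > 0.5 * best_rel else 0
            best_rel = min(best_rel, rel)
            if stall >= 3 and best_rel < 1e-5:
                converged = True
                break
            kmat = coo_matrix((ktan9.ravel(), (rows, cols)),
                              shape=(ndof, ndof)).tocsr() + k_springs
            du = spsolve(kmat.tocsc(), resid)
            if not np.all(np.isfinite(du)):
                raise MembraneError("forward Newton step produced non-finite "
                                    "update (membrane instability?)")
            u = u + du
        if not converged:
            raise MembraneError(
                f"forward inflation did not converge at load increment "
                f"{inc}/{n_increments} (residual {rnorm / ref:.2e})"
            )
    disp_mm = u.reshape(-1, 3) * 1e3
    if np.abs(disp_mm).max() > 0.5 * np.abs(mesh.nodes).max():
        raise MembraneError("forward inflation produced implausibly large "
                            "displacements; check units and pressure")
    return mesh.with_nodes(mesh.nodes + disp_mm)


def inverse_stress_field(
    sys_mesh: SurfaceMesh,
    dp_mmhg: float,
    thickness_mm: float,
    bcs: list[BoundaryCondition] | None = None,
    inflow_point: np.ndarray | None = None,
    e_pa: float = RIGID_MODULUS_PA,
    nu: float = 0.0,
) -> StressResult:
    """Equilibrium wall stress of the pressurized systolic surface.

    Loads the deformed (systolic) geometry with the internal pressure
    difference and a practically undeformable material; the returned nodal
    maximal principal stress field feeds the sectional inverse-engineering
    stress.  The result is insensitive to ``e_pa`` (any value > 10 GPa).
    """
    if bcs is None:
        if inflow_point is None:
            raise MembraneError(
                "inverse solve needs either explicit bcs or an inflow point "
                "to orient the tube boundary conditions"
            )
        bcs = tube_boundary_conditions(sys_mesh, inflow_point)
    model = MembraneModel(
        mesh=sys_mesh, e_pa=e_pa, nu=nu, thickness_mm=thickness_mm,
        pressure_pa=dp_mmhg * MMHG_TO_PA, bcs=bcs,
    )
    return solve_membrane(model)
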