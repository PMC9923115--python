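"""Synthetic validation geometries, stiffness fields and analytic oracles.

The validation study runs entirely on generated data: a straight cylinder
and 45/90-degree elbows (diameter 32 mm, centerline arc length 100 mm,
wall thickness 2 mm), and a smoothly curved, radius-varying "aorta-like"
tube standing in for a segmented patient geometry.  Stiffness fields are
either homogeneous or a proximal/distal step along the normalized
centerline coordinate xi.

"Length 100 mm" for the elbows is interpreted as the centerline arc
length; with R0 = arc_length / bend_angle this reproduces the curvature
factors m = 0.93 (45 deg) and 0.86 (90 deg) exactly, so the interpretation
is adopted as definitive.  Surfaces are generated at the mid-wall, which
keeps the Laplace mean-radius usage consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import MMHG_TO_PA, SurfaceMesh

__all__ = [
    "TubeSpec",
    "StiffnessField",
    "make_tube",
    "make_aortic_tube",
    "evaluate_field",
    "analytic_inflate_cylinder",
]


@dataclass(frozen=True)
class TubeSpec:
    """Parameters of an idealized tube fixture.

    diameter_mm and arc_length_mm follow the validation designs (32 / 100 by
    default); ``bend_angle_deg`` 0 gives a straight cylinder, otherwise the
    centerline is a circular arc of radius ``arc_length / angle_rad``.
    Node counts default to 64 circumferential x 80 axial so that every
    cross-section contour carries >= 50 nodes.
    """

    diameter_mm: float = 32.0
    arc_length_mm: float = 100.0
    bend_angle_deg: float = 0.0
    wall_thickness_mm: float = 2.0
    n_circumferential: int = 64
    n_axial: int = 80

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.arc_length_mm <= 0:
            raise ValueError("diameter and arc length must be positive")
        if not 0.0 <= self.bend_angle_deg <= 180.0:
            raise ValueError("bend angle must be within [0, 180] degrees")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be positive")
        if self.n_circumferential < 8 or self.n_axial < 10:
            raise ValueError("need >= 8 circumferential and >= 10 axial nodes")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    @property
    def bend_radius_mm(self) -> float:
        """Centerline arc radius R0 (inf for a straight tube)."""
        if self.bend_angle_deg == 0:
            return np.inf
        return self.arc_length_mm / np.deg2rad(self.bend_angle_deg)


@dataclass(frozen=True)
class StiffnessField:
    """Imposed Young's modulus distribution along xi (MPa).

    ``homogeneous`` uses ``e_h_mpa`` everywhere; ``proximal_distal`` steps
    from ``e_p_mpa`` to ``e_d_mpa`` at ``transition_xi`` (right-closed: the
    transition station itself takes the distal value).
    """

    kind: str = "homogeneous"
    e_h_mpa: float = 0.5
    e_p_mpa: float = 2.0
    e_d_mpa: float = 0.5
    transition_xi: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("homogeneous", "proximal_distal"):
            raise ValueError(f"unknown stiffness field kind {self.kind!r}")
        if min(self.e_h_mpa, self.e_p_mpa, self.e_d_mpa) <= 0:
            raise ValueError("moduli must be positive")
        if self.kind == "proximal_distal" and not 0 < self.transition_xi < 1:
            raise ValueError("transition_xi must lie strictly inside (0, 1)")

    def describe(self) -> str:
        if self.kind == "homogeneous":
            return f"homogeneous E = {self.e_h_mpa} MPa"
        return (f"proximal/distal E = {self.e_p_mpa}/{self.e_d_mpa} MPa, "
                f"step at xi = {self.transition_xi}")


def evaluate_field(field: StiffnessField, xi) -> np.ndarray | float:
    """Reference modulus (MPa) at normalized centerline coordinate(s) xi."""
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr < 0) or np.any(xi_arr > 1):
        raise ValueError("xi out of range [0, 1]")
    if field.kind == "homogeneous":
        out = np.full_like(xi_arr, field.e_h_mpa)
    else:
        out = np.where(xi_arr < field.transition_xi, field.e_p_mpa, field.e_d_mpa)
    return float(out) if np.isscalar(xi) or xi_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# structured tube construction
# ---------------------------------------------------------------------------

def _structured_tube(
    centers: np.ndarray,
    tangents: np.ndarray,
    radii: np.ndarray,
    n_circ: int,
) -> SurfaceMesh:
    """Triangulated tube around a centerline, one node ring per station.

    Ring frames are parallel-transported (rotation minimizing) along the
    centerline to avoid twist.  Node ordering is (axial ring, circumferential
    index); triangles wind so that normals point radially outward.
    """
    n_ax = len(centers)
    # rotation-minimizing frames by double reflection
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ref @ t0) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t0, ref)
    e1 /= np.linalg.norm(e1)
    frames = [e1]
    for i in range(1, n_ax):
        v1 = centers[i] - centers[i - 1]
        c1 = v1 @ v1
        rL = frames[-1] - (2.0 / c1) * (v1 @ frames[-1]) * v1
        tL = tangents[i - 1] - (2.0 / c1) * (v1 @ tangents[i - 1]) * v1
        v2 = tangents[i] - tL
        c2 = v2 @ v2
        if c2 > 1e-30:
            e = rL - (2.0 / c2) * (v2 @ rL) * v2
        else:
            e = rL
        e = e - (e @ tangents[i]) * tangents[i]
        e /= np.linalg.norm(e)
        frames.append(e)
    frames = np.asarray(frames)
    e2 = np.cross(tangents, frames)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)

    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    ct, st = np.cos(theta), np.sin(theta)
    nodes = (
        centers[:, None, :]
        + radii[:, None, None] * (ct[None, :, None] * frames[:, None, :]
                                  + st[None, :, None] * e2[:, None, :])
    ).reshape(-1, 3)

    tris = []
    for ia in range(n_ax - 1):
        base0 = ia * n_circ
        base1 = (ia + 1) * n_circ
        ic = np.arange(n_circ)
        icn = (ic + 1) % n_circ
        # outward winding: (ring i, ic) -> (ring i, ic+1) -> (ring i+1, ic)
        tris.append(np.stack([base0 + ic, base0 + icn, base1 + ic], axis=1))
        tris.append(np.stack([base0 + icn, base1 + icn, base1 + ic], axis=1))
    triangles = np.vstack(tris)
    mesh = SurfaceMesh(nodes=nodes, triangles=triangles)
    # enforce outward orientation regardless of frame handedness
    from .surfaces import orient_outward

    return orient_outward(mesh, reference_points=centers)


def make_tube(spec: TubeSpec) -> SurfaceMesh:
    """Structured triangle mesh of a straight or elbow tube mid-surface.

    The tube is open at both ends (two boundary rings).  For a bend, the
    centerline is a circular arc in the x-z plane of radius
    ``arc_length / angle_rad``; a straight tube runs along +z.
    """
    n_ax, n_circ = spec.n_axial, spec.n_circumferential
    s = np.linspace(0.0, spec.arc_length_mm, n_ax)
    if spec.bend_angle_deg == 0:
        centers = np.stack([np.zeros(n_ax), np.zeros(n_ax), s], axis=1)
        tangents = np.tile([0.0, 0.0, 1.0], (n_ax, 1))
    else:
        r0 = spec.bend_radius_mm
        phi = s / r0
        centers = np.stack(
            [r0 * (1.0 - np.cos(phi)), np.zeros(n_ax), r0 * np.sin(phi)], axis=1
        )
        tangents = np.stack([np.sin(phi), np.zeros(n_ax), np.cos(phi)], axis=1)
    radii = np.full(n_ax, spec.radius_mm)
    return _structured_tube(centers, tangents, radii, n_circ)


def make_aortic_tube(
    seed: int = 0, n_circumferential: int = 64, n_axial: int = 100
) -> SurfaceMesh:
    """Curved, radius-varying tube emulating an ascending-aorta geometry.

    Synthetic stand-in for a segmented patient aorta (which is not
    distributed with imaging studies): a root bulge, an ascending segment
    and arch-like curvature with a centerline arc radius near 80 mm, so
    that the curvature factor along the ascending portion sits in the
    0.85-0.95 band reported for real ascending aortas.  Deterministic for
    a given seed; the seed drives only small smooth shape perturbations.
    """
    rng = np.random.RandomState(seed)
    arc_length = 160.0
    bend_angle = np.deg2rad(110.0)
    r0 = arc_length / bend_angle  # ~83 mm
    n_ax = n_axial
    s = np.linspace(0.0, arc_length, n_ax)
    xi = s / arc_length
    phi = s / r0
    centers = np.stack(
        [r0 * (1.0 - np.cos(phi)), np.zeros(n_ax), r0 * np.sin(phi)], axis=1
    )
    # mild out-of-plane sweep plus seeded low-frequency perturbation (mm)
    centers[:, 1] = 6.0 * np.sin(np.pi * xi)
    amp = rng.uniform(0.5, 1.0, size=2)
    pha = rng.uniform(0, 2 * np.pi, size=2)
    centers[:, 1] += amp[0] * np.sin(2 * np.pi * xi + pha[0]) * np.sin(np.pi * xi)
    centers[:, 0] += amp[1] * np.sin(2 * np.pi * xi + pha[1]) * np.sin(np.pi * xi)

    tangents = np.gradient(centers, s, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    # radius profile: root bulge, gentle distal taper, ~25% total variation
    radii = 16.0 * (
        1.0
        + 0.15 * np.exp(-(((xi - 0.15) / 0.12) ** 2))
        - 0.12 * xi
        + 0.01 * rng.uniform(-1, 1) * np.sin(2 * np.pi * xi)
    )
    return _structured_tube(centers, tangents, radii, n_circumferential)


# ---------------------------------------------------------------------------
# analytic inflation oracles (straight cylinder only)
# ---------------------------------------------------------------------------

def analytic_inflate_cylinder(
    spec: TubeSpec,
    e_mpa: float,
    dp_mmhg: float,
    model: str = "thin",
    nu: float = 0.0,
    mesh: SurfaceMesh | None = None,
) -> SurfaceMesh:
    """Closed-form pressurized deformation of the straight cylinder.

    Models
    ------
    ``thin``
        Linearized thin-wall hoop response: radius scaled by
        ``1 + dP r / (delta E)`` (plane stress, zero axial displacement).
    ``thin_finite``
        Equilibrium-consistent finite inflation,
        ``r_sys = r / (1 - dP r / (delta E))`` — the fixed point at which
        the hoop stress of the deformed radius equals E times the
        engineering hoop strain.  This is the oracle for pipeline
        self-consistency checks, since both stress routes evaluate the
        deformed configuration.
    ``thick``
        Lame thick-cylinder radial displacement evaluated at the mid-wall
        radius (inner/outer radii r -/+ delta/2).

    Pass ``mesh`` to deform an existing cylinder mesh built from ``spec``
    (otherwise a fresh one is generated).  The straight axis is +z.
    """
    if spec.bend_angle_deg != 0:
        raise ValueError("analytic inflation requires a straight cylinder spec")
    if model not in ("thin", "thin_finite", "thick"):
        raise ValueError(f"unknown model {model!r}")
    base = mesh if mesh is not None else make_tube(spec)
    r = spec.radius_mm * 1e-3
    delta = spec.wall_thickness_mm * 1e-3
    p = dp_mmhg * MMHG_TO_PA
    e_pa = e_mpa * 1e6
    if model == "thin":
        factor = 1.0 + p * r / (delta * e_pa)
    elif model == "thin_finite":
        x = p * r / (delta * e_pa)
        if x >= 1:
            raise ValueError("pressure exceeds the thin-wall inflation limit")
        factor = 1.0 / (1.0 - x)
    else:
        a = r - delta / 2.0
        b = r + delta / 2.0
        u = (p * a**2 * r) / (e_pa * (b**2 - a**2)) * (
            (1.0 - nu) + (1.0 + nu) * (b / r) ** 2
        )
        factor = 1.0 + u / r
    nodes = base.nodes.copy()
    nodes[:, :2] *= factor
    return base.with_nodes(nodes)
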