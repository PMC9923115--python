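"""Cross-section extraction, contour lengths and circumferential strain.

For every interior centerline station, the nodes within a distance
threshold of the station plane form a closed contour.  The contour is
sorted by the polar angle in the section plane and its radial contour
length

    L(xi) = integral of rho(theta) d(theta)

is evaluated by trapezoidal quadrature over the sorted nodes (with
wraparound).  Note this is deliberately *not* the Euclidean polygon
perimeter (available as an alternative mode): for near-circular aortic
sections the two differ negligibly, and the integral form is what the
strain definition uses.  Circumferential strain between the diastolic and
systolic configurations of the *same mapped node set* is the relative
contour-length change

    eps_theta(xi) = (L_sys(xi) - L_dia(xi)) / L_dia(xi).

The section plane basis is fixed on the diastolic configuration and
transported unchanged to systole (the origin is translated by the mean
nodal displacement), so diastolic and systolic node angles are
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .centerline import Centerline
from .mesh import PhaseSet, SurfaceMesh
from .surfaces import loop_centroid, plane_cut_chains, realize_chain

__all__ = [
    "CrossSection",
    "MaterialContour",
    "StrainProfile",
    "extract_section",
    "extract_material_contour",
    "section_in_phase",
    "contour_length",
    "circumferential_strain",
    "strain_profile",
    "select_systolic_phase",
]

log = logging.getLogger("aortastiff")

#: minimum node count for a usable contour
MIN_SECTION_NODES = 8
#: maximum tolerated angular gap (rad) before a contour counts as incomplete
MAX_THETA_GAP = np.pi / 2
#: default tolerance = TOL_FACTOR x local axial node spacing
TOL_FACTOR = 0.6


class SectionError(ValueError):
    """Raised for sparse or incomplete cross-section contours."""


@dataclass
class CrossSection:
    """Mapped node subset of one centerline station.

    Polar coordinates (rho mm, theta rad) live in the section plane basis;
    nodes are stored sorted by ascending theta.
    """

    station: int
    xi: float
    node_indices: np.ndarray
    origin: np.ndarray
    normal: np.ndarray
    basis: np.ndarray          # (2, 3) in-plane unit vectors
    rho: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.node_indices)
        if n < MIN_SECTION_NODES:
            raise SectionError(
                f"sparse section at station {self.station} ({n} nodes); "
                "increase tol or mesh resolution"
            )
        if np.any(self.rho <= 0):
            raise SectionError(f"non-positive radius at station {self.station}")
        gaps = np.diff(np.concatenate([self.theta, [self.theta[0] + 2 * np.pi]]))
        if gaps.max() >= MAX_THETA_GAP:
            raise SectionError(
                f"incomplete contour at station {self.station} "
                f"(max angular gap {np.degrees(gaps.max()):.1f} deg)"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_indices)

    @property
    def mean_radius_mm(self) -> float:
        """Mean nodal radial coordinate rho-bar (mm)."""
        return float(np.mean(self.rho))


def _section_basis(normal: np.ndarray) -> np.ndarray:
    """Deterministic in-plane basis orthogonal to the plane normal."""
    normal = normal / np.linalg.norm(normal)
    seed = np.eye(3)[int(np.argmin(np.abs(normal)))]
    e1 = seed - (seed @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return np.stack([e1, e2])


def _local_axial_spacing(
    mesh: SurfaceMesh, origin: np.ndarray, normal: np.ndarray
) -> float:
    """Mean out-of-plane extent of the mesh edges crossing the plane."""
    d = (mesh.nodes - origin) @ normal
    e = mesh.edges()
    crossing = d[e[:, 0]] * d[e[:, 1]] < 0
    if not np.any(crossing):
        raise SectionError("station plane does not cross the surface")
    return float(np.mean(np.abs(d[e[crossing, 0]] - d[e[crossing, 1]])))


def extract_section(
    mesh: SurfaceMesh,
    cl: Centerline,
    station: int,
    tol: float | None = None,
) -> CrossSection:
    """Nodes of one cross-section contour on the (diastolic) mesh.

    Selects nodes within ``tol`` (mm) of the station plane — default
    0.6 x the local axial node spacing estimated from edge statistics —
    and within 2.5 x the local mean section radius in-plane (guard
    against touching branches), converts them to polar coordinates in the
    section basis and sorts by theta.
    """
    origin = cl.points[station]
    normal = cl.tangents[station]
    if tol is None:
        tol = TOL_FACTOR * _local_axial_spacing(mesh, origin, normal)
    if tol <= 0:
        raise SectionError("section tolerance must be positive")
    d = (mesh.nodes - origin) @ normal
    candidates = np.flatnonzero(np.abs(d) < tol)
    if candidates.size == 0:
        raise SectionError(f"no nodes within tol={tol:.3g} mm of station {station}")
    basis = _section_basis(normal)
    rel = mesh.nodes[candidates] - origin
    uv = rel @ basis.T
    rho = np.linalg.norm(uv, axis=1)
    r_guard = 2.5 * cl.section_radius_mm[station]
    keep = rho < r_guard
    candidates, uv, rho = candidates[keep], uv[keep], rho[keep]
    theta = np.arctan2(uv[:, 1], uv[:, 0])
    order = np.argsort(theta, kind="stable")
    return CrossSection(
        station=station, xi=float(cl.xi[station]),
        node_indices=candidates[order], origin=origin, normal=normal,
        basis=basis, rho=rho[order], theta=theta[order],
    )


def section_in_phase(section: CrossSection, phase_mesh: SurfaceMesh) -> CrossSection:
    """The same material contour evaluated in another phase.

    Reuses the diastolic node set and plane basis; the plane origin is
    translated by the mean nodal displacement so rigid translation does
    not masquerade as strain.
    """
    pts = phase_mesh.nodes[section.node_indices]
    # diastolic in-plane positions, recovered from the stored polar coords
    dia_pts = (
        section.origin
        + np.outer(section.rho * np.cos(section.theta), section.basis[0])
        + np.outer(section.rho * np.sin(section.theta), section.basis[1])
    )
    origin = section.origin + (pts.mean(axis=0) - dia_pts.mean(axis=0))
    uv = (pts - origin) @ section.basis.T
    rho = np.linalg.norm(uv, axis=1)
    theta = np.arctan2(uv[:, 1], uv[:, 0])
    order = np.argsort(theta, kind="stable")
    return CrossSection(
        station=section.station, xi=section.xi,
        node_indices=section.node_indices[order],
        origin=origin, normal=section.normal, basis=section.basis,
        rho=rho[order], theta=theta[order],
    )


@dataclass
class MaterialContour:
    """Cross-section contour built from plane-edge intersections.

    Stores the crossed mesh edges and interpolation weights, so the
    *material-corresponding* contour can be realized on any connectivity-
    identical phase mesh — node-threshold sampling instead picks whole
    nodes near the plane, which on curved tubes injects a small
    station-dependent bias into the contour length.  The diastolic
    realization is exactly planar by construction.
    """

    station: int
    xi: float
    edges: np.ndarray       # (k, 2) node indices
    weights: np.ndarray     # (k,) interpolation parameters
    origin: np.ndarray
    normal: np.ndarray
    basis: np.ndarray       # (2, 3) in-plane unit vectors

    @property
    def n_points(self) -> int:
        return len(self.edges)

    def points(self, mesh: SurfaceMesh) -> np.ndarray:
        """Contour points realized on one phase of the mapped mesh."""
        return realize_chain(mesh, self.edges, self.weights)

    def polar(self, mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
        """(rho, theta) in the section basis about the contour centroid.

        Points keep their chain order (already ordered along the
        contour), so theta is monotonic modulo wraparound.
        """
        pts = self.points(mesh)
        center, _ = loop_centroid(pts)
        uv = (pts - center) @ self.basis.T
        return np.linalg.norm(uv, axis=1), np.arctan2(uv[:, 1], uv[:, 0])

    def contour_length(self, mesh: SurfaceMesh, mode: str = "radial_integral") -> float:
        """Sectional contour length L (mm) on one phase realization."""
        pts = self.points(mesh)
        if mode == "polygon":
            closed = np.vstack([pts, pts[:1]])
            return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
        if mode != "radial_integral":
            raise ValueError(f"unknown contour-length mode {mode!r}")
        rho, theta = self.polar(mesh)
        dtheta = np.abs(_wrap_angle(np.diff(np.concatenate([theta, theta[:1]]))))
        rho_next = np.roll(rho, -1)
        return float(np.sum(0.5 * (rho + rho_next) * dtheta))

    def mean_radius_mm(self, mesh: SurfaceMesh) -> float:
        """Perimeter-weighted mean radial coordinate rho-bar (mm)."""
        pts = self.points(mesh)
        _, r = loop_centroid(pts)
        return float(r)

    def sample_mean(self, nodal_values: np.ndarray, mesh: SurfaceMesh) -> float:
        """Perimeter-weighted contour mean of a per-node field.

        Values are interpolated onto the contour points with the stored
        edge weights (the contour analogue of the ring-average of nodal
        stresses).
        """
        vals = ((1.0 - self.weights) * nodal_values[self.edges[:, 0]]
                + self.weights * nodal_values[self.edges[:, 1]])
        pts = self.points(mesh)
        closed = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        w = seg + np.roll(seg, 1)
        return float(np.sum(vals * w) / np.sum(w))

    def strain(self, dia_mesh: SurfaceMesh, sys_mesh: SurfaceMesh) -> float:
        """Circumferential strain between two phase realizations."""
        l_dia = self.contour_length(dia_mesh)
        if l_dia <= 0:
            raise SectionError("non-positive diastolic contour length")
        return (self.contour_length(sys_mesh) - l_dia) / l_dia


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def extract_material_contour(
    mesh: SurfaceMesh, cl: Centerline, station: int
) -> MaterialContour:
    """Material cross-section contour of one centerline station.

    Cuts the baseline surface with the station plane and keeps the closed
    intersection chain nearest the centerline point (guarded to 2.5 x the
    local mean radius).
    """
    origin = cl.points[station]
    normal = cl.tangents[station]
    chains = [
        (e, w) for e, w in plane_cut_chains(mesh, origin, normal)
        if len(e) >= MIN_SECTION_NODES
    ]
    if not chains:
        raise SectionError(f"station plane {station} does not cut the surface")
    pts = [realize_chain(mesh, e, w) for e, w in chains]
    cents = [loop_centroid(p)[0] for p in pts]
    dists = [np.linalg.norm(c - origin) for c in cents]
    best = int(np.argmin(dists))
    if dists[best] > 2.5 * cl.section_radius_mm[station]:
        raise SectionError(
            f"no contour near the centerline at station {station} "
            "(branch or non-tubular surface?)"
        )
    edges, weights = chains[best]
    return MaterialContour(
        station=station, xi=float(cl.xi[station]),
        edges=edges, weights=weights, origin=origin, normal=normal,
        basis=_section_basis(normal),
    )


def contour_length(section: CrossSection, mode: str = "radial_integral") -> float:
    """Sectional contour length L (mm).

    ``radial_integral`` (default) evaluates the radial contour length
    integral of rho(theta) d(theta) by trapezoid over sorted node pairs
    with wraparound — exact (2*pi*rho) for a circle at any node count.
    ``polygon`` returns the Euclidean polygon perimeter instead.
    """
    if mode == "polygon":
        pts = (
            np.outer(section.rho * np.cos(section.theta), section.basis[0])
            + np.outer(section.rho * np.sin(section.theta), section.basis[1])
        )
        closed = np.vstack([pts, pts[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    if mode != "radial_integral":
        raise ValueError(f"unknown contour-length mode {mode!r}")
    rho = np.concatenate([section.rho, section.rho[:1]])
    theta = np.concatenate([section.theta, [section.theta[0] + 2 * np.pi]])
    dtheta = np.diff(theta)
    return float(np.sum(0.5 * (rho[:-1] + rho[1:]) * dtheta))


def circumferential_strain(dia: CrossSection, sys: CrossSection) -> float:
    """Relative sectional contour-length change (dimensionless)."""
    if not np.array_equal(np.sort(dia.node_indices), np.sort(sys.node_indices)):
        raise SectionError(
            "diastolic and systolic sections must share the same mapped node set"
        )
    l_dia = contour_length(dia)
    l_sys = contour_length(sys)
    if l_dia <= 0:
        raise SectionError("non-positive diastolic contour length")
    eps = (l_sys - l_dia) / l_dia
    if eps < 0:
        log.warning("negative circumferential strain %.4g at station %d",
                    eps, dia.station)
    return eps


@dataclass
class StrainProfile:
    """Circumferential strain as a function of xi for one phase."""

    phase_label: str
    xi: np.ndarray
    epsilon: np.ndarray
    stations: np.ndarray
    node_map: np.ndarray      # per-node strain (NaN outside any section)

    def max_strain(self) -> float:
        return float(np.nanmax(self.epsilon))


def strain_profile(
    phases: PhaseSet,
    cl: Centerline,
    phase_label: str,
    tol: float | None = None,
    end_fraction: float | None = None,
    section_mode: str = "contour",
) -> StrainProfile:
    """Strain at every interior station of one phase versus the baseline.

    ``section_mode`` "contour" (default) uses material plane-edge
    contours; "nodes" uses the node-threshold sections.  The per-node map
    assigns each node its section's single strain value (the method
    resolves one value per centerline slice); nodes whose nearest station
    is masked carry NaN.
    """
    if section_mode not in ("contour", "nodes"):
        raise ValueError(f"unknown section mode {section_mode!r}")
    sys_mesh = phases.phase(phase_label)
    stations = np.flatnonzero(cl.interior_mask(end_fraction))
    if stations.size == 0:
        raise SectionError("no interior stations left after end masking")
    eps = np.empty(len(stations))
    xi = cl.xi[stations]
    section_values: dict[int, float] = {}
    for k, st in enumerate(stations):
        try:
            if section_mode == "contour":
                mc = extract_material_contour(phases.baseline, cl, int(st))
                eps[k] = mc.strain(phases.baseline, sys_mesh)
            else:
                dia_sec = extract_section(phases.baseline, cl, int(st), tol=tol)
                sys_sec = section_in_phase(dia_sec, sys_mesh)
                eps[k] = circumferential_strain(dia_sec, sys_sec)
        except SectionError as exc:
            raise SectionError(f"station {st}: {exc}") from exc
        section_values[int(st)] = eps[k]
    node_station = cl.nearest_station(phases.baseline.nodes)
    node_map = np.array([
        section_values.get(int(s), np.nan) for s in node_station
    ])
    return StrainProfile(
        phase_label=phase_label, xi=xi, epsilon=eps,
        stations=stations, node_map=node_map,
    )


def select_systolic_phase(profiles: list[StrainProfile]) -> str:
    """Label of the phase with the greatest profile maximum.

    Ties are broken towards the earliest phase in the given order, with a
    logged warning.
    """
    if not profiles:
        raise ValueError("no strain profiles given")
    maxima = np.array([p.max_strain() for p in profiles])
    best = int(np.argmax(maxima))
    ties = np.flatnonzero(maxima == maxima[best])
    if len(ties) > 1:
        log.warning(
            "systolic-phase tie between %s; choosing the earliest",
            [profiles[i].phase_label for i in ties],
        )
        best = int(ties[0])
    return profiles[best].phase_label
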