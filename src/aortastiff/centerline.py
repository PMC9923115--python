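"""Centerline extraction and the curvature effect factor.

The centerline is computed on the diastolic (baseline) configuration only;
node mapping transports the resulting cross-sections to every other phase.
A marching-centroid scheme walks the tubular surface from the inflow
boundary ring: the surface is cut with a plane normal to the current
direction, the cut-ring centroid becomes the next centerline sample, and
the polyline is finally spline-smoothed and resampled to equally spaced
stations.

The curvature effect factor

    m = (R0 - r) / (R0 - r/2)

(R0 centerline radius of curvature, r section radius) quantifies how bend
curvature distorts the straight-tube stress state; the Laplace hoop-stress
route is trusted where m is close to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splprep

from .mesh import SurfaceMesh
from .surfaces import boundary_rings, loop_centroid, plane_cut_loops

__all__ = ["Centerline", "compute_centerline", "curvature_factor"]

log = logging.getLogger("aortastiff")

#: curvatures below this (1/mm) are treated as straight (R0 = +inf);
#: avoids huge unstable radii from circle-fit noise.
CURVATURE_THRESHOLD = 1e-4


@dataclass
class Centerline:
    """Ordered centerline polyline with arc-length parameterization.

    points : (n, 3) mm, ordered from the inflow ("valve") end to the
    outflow ("arch") end; xi in [0, 1] is the normalized arc length;
    tangents are unit vectors; r0_mm the per-point radius of curvature
    (+inf where straight); section_radius_mm the local mean section
    radius.
    """

    points: np.ndarray
    xi: np.ndarray
    tangents: np.ndarray
    r0_mm: np.ndarray
    section_radius_mm: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.diff(self.xi) > 0)
                and np.isclose(self.xi[0], 0) and np.isclose(self.xi[-1], 1)):
            raise ValueError("xi must increase strictly from 0 to 1")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("tangents must be unit vectors")

    @property
    def n_stations(self) -> int:
        return len(self.points)

    def arc_length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def curvature_factors(self) -> np.ndarray:
        """Per-station m = (R0 - r)/(R0 - r/2)."""
        return np.array([
            curvature_factor(r0, r)
            for r0, r in zip(self.r0_mm, self.section_radius_mm)
        ])

    def interior_mask(self, end_fraction: float | None = None) -> np.ndarray:
        """Stations clear of the boundary-condition-affected tube ends.

        The default exclusion is geometry-aware: boundary effects on a
        clamped membrane tube decay over a Saint-Venant length set by the
        *section radius*, not the tube length, so the mask spans
        ``max(5%, 0.75 r̄ / L)`` of xi at each end (r̄ the median section
        radius, L the arc length).  Pass an explicit fraction to
        override.
        """
        if end_fraction is None:
            end_fraction = max(
                0.05,
                0.75 * float(np.median(self.section_radius_mm))
                / max(self.arc_length_mm(), 1e-9),
            )
        return (self.xi >= end_fraction) & (self.xi <= 1.0 - end_fraction)

    def nearest_station(self, points: np.ndarray) -> np.ndarray:
        """Index of the closest station for each query point."""
        from scipy.spatial import cKDTree

        _, idx = cKDTree(self.points).query(np.atleast_2d(points))
        return idx


def curvature_factor(r0_mm: float, r_mm: float) -> float:
    """Curvature effect factor m = (R0 - r)/(R0 - r/2); 1.0 when straight."""
    if r_mm <= 0:
        raise ValueError("section radius must be positive")
    if np.isinf(r0_mm):
        return 1.0
    if r0_mm <= r_mm:
        raise ValueError(
            f"section radius ({r_mm} mm) exceeds bend radius ({r0_mm} mm)"
        )
    return (r0_mm - r_mm) / (r0_mm - r_mm / 2.0)


class CenterlineError(ValueError):
    """Raised when a surface cannot be traversed as a tube."""


def _ring_info(mesh: SurfaceMesh, ring: np.ndarray):
    pts = mesh.nodes[ring]
    centroid = pts.mean(axis=0)
    # plane normal by SVD of the ring points
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[2]
    radius = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    return centroid, normal, radius


def compute_centerline(
    mesh: SurfaceMesh,
    n_stations: int = 50,
    inflow_hint: np.ndarray | None = None,
    step_factor: float = 0.25,
    smoothing_mm: float = 0.0,
) -> Centerline:
    """Marching-centroid centerline of an open tubular surface.

    Starts at the centroid of the inflow boundary ring (nearest to
    ``inflow_hint`` if given, else the first ring found), repeatedly cuts
    the surface with a plane normal to the running direction, and takes
    each cut-ring (perimeter-weighted) centroid as the next sample.  The
    samples are interpolated with a parametric spline (set ``smoothing_mm``
    to the expected centroid noise to smooth instead, e.g. for segmented
    patient surfaces) and resampled to ``n_stations`` equal-arc-length
    stations; tangents come from the spline derivative and the radius of
    curvature from a circle fit over a sliding window spanning about
    +/- 0.75 local section radii.
    """
    if n_stations < 4:
        raise CenterlineError("need at least 4 stations")
    rings = boundary_rings(mesh)
    if len(rings) != 2:
        raise CenterlineError(
            f"expected a tubular surface with 2 boundary rings, found {len(rings)}"
        )
    infos = [_ring_info(mesh, r) for r in rings]
    if inflow_hint is not None:
        hint = np.asarray(inflow_hint, float)
        order = np.argsort([np.linalg.norm(c - hint) for c, _, _ in infos])
        infos = [infos[i] for i in order]
    c_in, n_in, r_in = infos[0]
    c_out, _, r_out = infos[1]

    interior = mesh.nodes.mean(axis=0)
    direction = n_in if n_in @ (interior - c_in) > 0 else -n_in

    samples = [c_in]
    radii = [r_in]
    point = c_in.copy()
    step = step_factor * r_in
    max_steps = int(20.0 * np.linalg.norm(c_out - c_in) / step) + 200
    for _ in range(max_steps):
        target = point + step * direction
        loops = plane_cut_loops(mesh, target, direction)
        loops = [lp for lp in loops if len(lp) >= 6]
        if not loops:
            break
        cents_radii = [loop_centroid(lp) for lp in loops]
        dists = [np.linalg.norm(c - target) for c, _ in cents_radii]
        best = int(np.argmin(dists))
        if dists[best] > 2.5 * max(r_in, r_out):
            raise CenterlineError(
                "plane cut wandered off the tube (non-tubular surface?)"
            )
        c, r_local = cents_radii[best]
        new_dir = c - point
        nn = np.linalg.norm(new_dir)
        if nn < 1e-9:
            break
        new_dir /= nn
        direction = 0.5 * direction + 0.5 * new_dir
        direction /= np.linalg.norm(direction)
        samples.append(c)
        radii.append(r_local)
        point = c
        step = step_factor * r_local
        if np.linalg.norm(c - c_out) < max(step, 0.75 * r_out):
            break
    samples.append(c_out)
    radii.append(r_out)
    samples = np.asarray(samples)
    radii = np.asarray(radii)
    if len(samples) < 4:
        raise CenterlineError("marching produced too few samples (short tube?)")

    # correction passes: re-cut every sample with the tangent estimated from
    # its neighbours; the true centerline is a fixed point of this update
    guard = 2.5 * max(r_in, r_out)
    for _ in range(3):
        refined = samples.copy()
        for i in range(1, len(samples) - 1):
            tang = samples[i + 1] - samples[i - 1]
            tang /= np.linalg.norm(tang)
            loops = [lp for lp in plane_cut_loops(mesh, samples[i], tang)
                     if len(lp) >= 6]
            if not loops:
                continue
            cents_radii = [loop_centroid(lp) for lp in loops]
            best = int(np.argmin(
                [np.linalg.norm(c - samples[i]) for c, _ in cents_radii]))
            c_best, r_best = cents_radii[best]
            if np.linalg.norm(c_best - samples[i]) < guard:
                refined[i] = c_best
                radii[i] = r_best
        samples = refined

    # drop consecutive duplicates before spline fitting
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    samples, radii = samples[keep], radii[keep]

    u_chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(samples, axis=0), axis=1))]
    )
    u_chord /= u_chord[-1]
    k = min(3, len(samples) - 1)
    # smoothing budget: marching centroids carry ~smoothing_mm of noise
    s_budget = len(samples) * smoothing_mm**2
    tck, _ = splprep(samples.T, u=u_chord, s=s_budget, k=k)

    # equal-arc-length resampling via a dense evaluation
    u_dense = np.linspace(0, 1, 40 * n_stations)
    dense = np.asarray(splev(u_dense, tck)).T
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    )
    targets = np.linspace(0, arc[-1], n_stations)
    u_eq = np.interp(targets, arc, u_dense)
    points = np.asarray(splev(u_eq, tck)).T
    deriv = np.asarray(splev(u_eq, tck, der=1)).T
    tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
    xi = targets / arc[-1]

    section_radius = np.interp(u_eq, u_chord, radii)
    # curvature window spans about +/- 0.75 local section radii of arc so
    # the fitted sagitta stays well above residual centroid noise
    spacing = arc[-1] / (n_stations - 1)
    half_pts = max(2, int(np.ceil(0.75 * np.median(section_radius) / spacing)))
    r0 = _radius_of_curvature(points, window=2 * half_pts + 1)
    return Centerline(
        points=points, xi=xi, tangents=tangents,
        r0_mm=r0, section_radius_mm=section_radius,
    )


def _radius_of_curvature(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-point R0 from a circle fit over a sliding window (mm)."""
    n = len(points)
    half = window // 2
    out = np.full(n, np.inf)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        pts = points[lo:hi]
        if len(pts) < 3:
            continue
        centroid = pts.mean(axis=0)
        q = pts - centroid
        _, sv, vt = np.linalg.svd(q, full_matrices=False)
        if sv[1] < 1e-7 * sv[0]:   # colinear window: straight
            continue
        uv = q @ vt[:2].T  # in best-fit plane
        # Kasa algebraic circle fit: |p|^2 = 2 c.p + rho
        a_mat = np.column_stack([2 * uv, np.ones(len(uv))])
        b_vec = np.sum(uv**2, axis=1)
        sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
        radius = np.sqrt(max(sol[2] + sol[0] ** 2 + sol[1] ** 2, 0.0))
        if radius > 0 and 1.0 / radius >= CURVATURE_THRESHOLD:
            out[i] = radius
    return out
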