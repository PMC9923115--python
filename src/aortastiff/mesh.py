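"""Surface-mesh data model and triangle-surface I/O.

The unit of exchange between all pipeline stages is :class:`SurfaceMesh`, a
triangulated luminal (or mid-wall) vessel surface with node coordinates in
millimetres and fixed 0-based connectivity.  :class:`PhaseSet` bundles a
baseline (diastolic) mesh with connectivity-identical meshes for the other
cardiac phases, so that node ``i`` denotes the same material point in every
phase.

Supported formats: STL (binary/ascii) and PLY via :mod:`trimesh`, and ascii
VTK XML PolyData (``.vtp``) through a minimal native reader/writer so that
per-node scalar arrays (strain, stress, modulus, error maps) survive a
round trip and open directly in ParaView.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SurfaceMesh",
    "PhaseSet",
    "read_surface",
    "write_surface",
    "assemble_phase_set",
    "MMHG_TO_PA",
]

log = logging.getLogger("aortastiff")

#: Pressure unit conversion applied once at the input boundary.
MMHG_TO_PA = 133.322

#: Triangles with area below this (mm^2) are considered degenerate.
DEGENERATE_AREA = 1e-12


class MeshError(ValueError):
    """Raised for invalid surface meshes or unreadable surface files."""


def _triangle_areas(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = nodes[triangles]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )


@dataclass
class SurfaceMesh:
    """Triangulated vessel surface.

    Parameters
    ----------
    nodes
        ``(n_nodes, 3)`` float array, coordinates in mm.
    triangles
        ``(n_tris, 3)`` int array of 0-based node indices.
    point_data
        Optional named per-node scalar arrays (length ``n_nodes``).
    require_connected
        Pipeline inputs must be a single connected component; set to False
        for intermediate fragments.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    point_data: dict[str, np.ndarray] = field(default_factory=dict)
    require_connected: bool = True

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(np.asarray(self.nodes, dtype=float))
        self.triangles = np.ascontiguousarray(
            np.asarray(self.triangles, dtype=np.int64)
        )
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) array")
        if len(self.nodes) == 0 or len(self.triangles) == 0:
            raise MeshError("empty mesh")
        if not np.all(np.isfinite(self.nodes)):
            raise MeshError("non-finite node coordinates")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.nodes):
            raise MeshError("triangle index out of range")
        areas = _triangle_areas(self.nodes, self.triangles)
        if np.any(areas < DEGENERATE_AREA):
            bad = int(np.argmin(areas))
            raise MeshError(
                f"degenerate (zero-area) triangle at index {bad}; "
                "meshes are rejected at load, not repaired"
            )
        if self.require_connected and self._n_components() != 1:
            raise MeshError("mesh is not a single connected component")
        self.point_data = {
            k: np.asarray(v, dtype=float) for k, v in self.point_data.items()
        }
        for name, arr in self.point_data.items():
            if arr.shape[0] != len(self.nodes):
                raise MeshError(
                    f"point_data array {name!r} has length {arr.shape[0]}, "
                    f"expected {len(self.nodes)}"
                )

    # -- basic descriptors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        """Per-triangle areas (mm^2)."""
        return _triangle_areas(self.nodes, self.triangles)

    def triangle_normals(self) -> np.ndarray:
        """Unit normals following the stored winding order."""
        p = self.nodes[self.triangles]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) sorted-index array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def with_nodes(self, nodes: np.ndarray, **point_data: np.ndarray) -> "SurfaceMesh":
        """Copy with replaced coordinates (same connectivity)."""
        return SurfaceMesh(
            nodes=nodes,
            triangles=self.triangles.copy(),
            point_data=dict(point_data) if point_data else dict(self.point_data),
            require_connected=self.require_connected,
        )

    def same_connectivity(self, other: "SurfaceMesh") -> bool:
        return (
            self.n_nodes == other.n_nodes
            and self.triangles.shape == other.triangles.shape
            and bool(np.array_equal(self.triangles, other.triangles))
        )

    def _n_components(self) -> int:
        e = self.edges()
        n = self.n_nodes
        adj = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
        )
        ncomp, _ = connected_components(adj, directed=False)
        return int(ncomp)


@dataclass
class PhaseSet:
    """A baseline mesh plus connectivity-identical meshes per cardiac phase.

    ``provenance`` records whether the phase meshes came pre-mapped (e.g.
    structured forward-simulation output) or were produced by RBF morphing.
    """

    baseline: SurfaceMesh
    phases: list[SurfaceMesh]
    labels: list[str]
    provenance: str = "pre-mapped"

    def __post_init__(self) -> None:
        if len(self.phases) != len(self.labels):
            raise MeshError("phases and labels differ in length")
        if len(self.labels) != len(set(self.labels)):
            raise MeshError("phase labels must be unique")
        if self.provenance not in ("pre-mapped", "morphed"):
            raise MeshError(f"unknown provenance {self.provenance!r}")
        for label, ph in zip(self.labels, self.phases):
            if not self.baseline.same_connectivity(ph):
                raise MeshError(
                    f"phase {label!r} does not share baseline connectivity"
                )

    def __len__(self) -> int:
        return len(self.phases)

    def phase(self, label: str) -> SurfaceMesh:
        try:
            return self.phases[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no phase labelled {label!r}") from None


def assemble_phase_set(
    baseline: SurfaceMesh,
    phases: list[SurfaceMesh],
    labels: list[str] | None = None,
) -> PhaseSet:
    """Bundle pre-mapped phase meshes (validation path) into a PhaseSet.

    All phase meshes must be connectivity-identical to the baseline; nodes
    are assumed to be already mapped (same material point at every phase).
    """
    if labels is None:
        labels = [f"phase{i}" for i in range(len(phases))]
    return PhaseSet(baseline=baseline, phases=list(phases), labels=list(labels),
                    provenance="pre-mapped")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRIMESH_FORMATS = {"stl", "ply"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _TRIMESH_FORMATS | {"vtp"}:
        raise MeshError(f"unsupported surface format {fmt!r} (use stl, ply or vtp)")
    return fmt


def read_surface(path: str | Path, format: str | None = None) -> SurfaceMesh:
    """Read a triangle surface from STL, PLY or ascii VTP.

    Coordinates are interpreted as millimetres.  STL files store a triangle
    soup; exactly coincident vertices are welded back into shared nodes (in
    first-occurrence order), which restores connectivity but not necessarily
    the original node ordering.  PLY and VTP preserve node order exactly.
    """
    path = Path(path)
    if not path.is_file():
        raise MeshError(f"no such surface file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "vtp":
        return _read_vtp(path)
    loaded = trimesh.load(str(path), file_type=fmt, process=False)
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if len(geoms) != 1:
            raise MeshError(f"{path}: expected a single surface, got a scene")
        loaded = geoms[0]
    if not isinstance(loaded, trimesh.Trimesh):
        raise MeshError(f"{path}: not a triangle surface (non-triangular cells?)")
    v = np.asarray(loaded.vertices, dtype=float)
    f = np.asarray(loaded.faces, dtype=np.int64)
    if f.size == 0:
        raise MeshError(f"{path}: empty mesh")
    if f.shape[1] != 3:
        raise MeshError(f"{path}: non-triangular cells")
    if fmt == "stl":
        v, f = _weld_vertices(v, f)
    return SurfaceMesh(nodes=v, triangles=f)


def _weld_vertices(v: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge exactly coincident vertices, keeping first-occurrence order."""
    _, first, inverse = np.unique(
        v.round(decimals=10), axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return v[first[order]], rank[inverse][f]


def write_surface(
    mesh: SurfaceMesh, path: str | Path, format: str | None = None
) -> None:
    """Write a surface to STL, PLY or ascii VTP.

    Per-node arrays are preserved only by VTP; for STL/PLY they are dropped
    with a logged warning.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "vtp":
        _write_vtp(mesh, path)
        return
    if mesh.point_data:
        log.warning(
            "format %s does not support point data; dropping arrays %s",
            fmt, sorted(mesh.point_data),
        )
    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.triangles, process=False)
    try:
        tm.export(str(path), file_type=fmt)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise MeshError(f"cannot write {path}: {exc}") from exc


# -- minimal ascii VTK XML PolyData ----------------------------------------

def _write_vtp(mesh: SurfaceMesh, path: Path) -> None:
    n, m = mesh.n_nodes, mesh.n_triangles

    def da(parent, name, arr, ncomp):
        el = ET.SubElement(parent, "DataArray")
        el.set("type", "Float64" if arr.dtype.kind == "f" else "Int64")
        el.set("Name", name)
        if ncomp != 1:
            el.set("NumberOfComponents", str(ncomp))
        el.set("format", "ascii")
        el.text = " ".join(repr(x) if isinstance(x, float) else str(x)
                           for x in arr.ravel().tolist())
        return el

    root = ET.Element("VTKFile", type="PolyData", version="1.0",
                      byte_order="LittleEndian")
    piece = ET.SubElement(
        ET.SubElement(root, "PolyData"), "Piece",
        NumberOfPoints=str(n), NumberOfVerts="0", NumberOfLines="0",
        NumberOfStrips="0", NumberOfPolys=str(m),
    )
    if mesh.point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, arr in mesh.point_data.items():
            da(pd, name, arr, 1)
    pts = ET.SubElement(piece, "Points")
    da(pts, "Points", mesh.nodes, 3)
    polys = ET.SubElement(piece, "Polys")
    da(polys, "connectivity", mesh.triangles, 1)
    da(polys, "offsets", np.arange(3, 3 * m + 1, 3, dtype=np.int64), 1)
    try:
        ET.ElementTree(root).write(str(path), xml_declaration=True)
    except OSError as exc:  # pragma: no cover
        raise MeshError(f"cannot write {path}: {exc}") from exc


def _read_vtp(path: Path) -> SurfaceMesh:
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise MeshError(f"{path}: not a valid VTP/XML file: {exc}") from exc
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise MeshError(f"{path}: no PolyData piece")

    def parse(el):
        if el.get("format", "ascii") != "ascii":
            raise MeshError(f"{path}: only ascii VTP is supported")
        text = el.text or ""
        dtype = float if el.get("type", "").startswith("Float") else np.int64
        return np.array(text.split(), dtype=float).astype(dtype)

    pts_el = piece.find("./Points/DataArray")
    conn_el = piece.find("./Polys/DataArray[@Name='connectivity']")
    off_el = piece.find("./Polys/DataArray[@Name='offsets']")
    if pts_el is None or conn_el is None or off_el is None:
        raise MeshError(f"{path}: missing Points or Polys arrays")
    nodes = parse(pts_el).reshape(-1, 3)
    conn = parse(conn_el)
    offsets = parse(off_el)
    sizes = np.diff(np.concatenate([[0], offsets]))
    if not np.all(sizes == 3):
        raise MeshError(f"{path}: non-triangular cells")
    triangles = conn.reshape(-1, 3)
    point_data = {}
    pd = piece.find("PointData")
    if pd is not None:
        for el in pd.findall("DataArray"):
            point_data[el.get("Name", "scalars")] = parse(el).astype(float)
    return SurfaceMesh(nodes=nodes, triangles=triangles, point_data=point_data)
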