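"""Triangulated-surface data model and spatial operators.

All spatial structure used by the pipeline lives here: per-node
(barycentric) areas, the edge-weighted adjacency graph, Dijkstra geodesic
distances, ordered one-ring neighborhoods (needed by phase-singularity
detection), synthetic ellipsoid meshes, and ascii OFF/PLY I/O.

Coordinates are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "MeshError",
    "build_ellipsoid_mesh",
    "node_areas",
    "geodesic_distance",
    "geodesic_distances_from",
    "one_ring_cycle",
    "read_mesh",
    "write_mesh",
]


class MeshError(ValueError):
    """Raised for invalid meshes or malformed mesh files."""


@dataclass(frozen=True)
class TriMesh:
    """Closed, consistently oriented triangulated surface.

    Parameters
    ----------
    vertices : (N, 3) float array, mm
    faces : (F, 3) int array
        Counter-clockwise orientation viewed from outside.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (N, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (F, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshError("face index out of range")
        if any(len(set(face)) != 3 for face in f.tolist()):
            raise MeshError("degenerate face (repeated vertex index)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- basic counts ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # -- derived structure -------------------------------------------------
    @cached_property
    def face_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[:,0] < e[:,1]."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    @cached_property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric edge-length-weighted adjacency (CSR)."""
        i, j = self.edges.T
        w = self.edge_lengths
        n = self.n_nodes
        a = sp.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])),
                          shape=(n, n))
        return a.tocsr()

    @cached_property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length)."""
        p = self.vertices[self.faces]
        fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2*area*normal
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def validate(self) -> None:
        """Check closedness/orientation/connectivity invariants."""
        directed = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                              self.faces[:, [2, 0]]])
        key = directed[:, 0] * self.n_nodes + directed[:, 1]
        if len(np.unique(key)) != len(key):
            raise MeshError("inconsistent orientation: repeated directed edge")
        rev = directed[:, 1] * self.n_nodes + directed[:, 0]
        if not np.isin(key, rev).all():
            raise MeshError("open surface: edge without opposite-direction twin")
        ncomp, _ = connected_components(self.adjacency, directed=False)
        if ncomp != 1:
            raise MeshError(f"edge graph has {ncomp} connected components")

    def nearest_node(self, point) -> int:
        d = np.linalg.norm(self.vertices - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


def build_ellipsoid_mesh(semi_axes, subdivision_level: int) -> TriMesh:
    """Closed triangulation of an ellipsoid by anisotropically scaled icosphere.

    ``N = 10 * 4**level + 2`` vertices; level 0 is the icosahedron.
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    if semi_axes.shape != (3,) or np.any(semi_axes <= 0):
        raise MeshError(f"semi_axes must be 3 positive lengths, got {semi_axes}")
    if subdivision_level < 0:
        raise MeshError("subdivision_level must be >= 0")
    ico = _trimesh.creation.icosphere(subdivisions=int(subdivision_level),
                                      radius=1.0)
    return TriMesh(np.asarray(ico.vertices) * semi_axes, np.asarray(ico.faces))


def node_areas(mesh: TriMesh, convention: str = "barycentric") -> np.ndarray:
    """Per-node area A_n (mm^2).

    ``barycentric`` (default): one third of the summed incident-face areas,
    which conserves total surface area. ``incident``: the raw incident-face
    sum (each face counted at all three corners).
    """
    fa = mesh.face_areas
    out = np.zeros(mesh.n_nodes)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], fa)
    if convention == "barycentric":
        out /= 3.0
    elif convention != "incident":
        raise ValueError(f"unknown convention {convention!r}")
    return out


def geodesic_distances_from(mesh: TriMesh, src) -> np.ndarray:
    """Dijkstra distances (mm) from source node(s) to all nodes."""
    d = dijkstra(mesh.adjacency, directed=False, indices=src)
    if np.any(np.isinf(d)):
        warnings.warn("mesh has nodes unreachable from source; "
                      "infinite distances returned")
    return d


def geodesic_distance(mesh: TriMesh, src: int, dst: int) -> float:
    """Shortest-path distance on the edge graph between two nodes (mm)."""
    n = mesh.n_nodes
    if not (0 <= src < n and 0 <= dst < n):
        raise IndexError(f"node index out of range [0, {n})")
    return float(geodesic_distances_from(mesh, src)[dst])


def one_ring_cycle(mesh: TriMesh, node: int) -> np.ndarray:
    """Neighbors of ``node`` ordered as a closed cycle.

    The order follows face orientation (counter-clockwise seen from
    outside). Raises :class:`MeshError` for boundary nodes (open fan);
    singularity detection skips those.
    """
    mask = np.any(mesh.faces == node, axis=1)
    incident = mesh.faces[mask]
    if len(incident) == 0:
        raise MeshError(f"node {node} has no incident faces")
    # within each incident face, the directed boundary edge opposite the node
    nxt = {}
    for face in incident.tolist():
        k = face.index(node)
        a, b = face[(k + 1) % 3], face[(k + 2) % 3]
        if a in nxt:
            raise MeshError(f"non-manifold fan at node {node}")
        nxt[a] = b
    start = incident[0][(list(incident[0]).index(node) + 1) % 3]
    cycle = [int(start)]
    while True:
        cur = cycle[-1]
        if cur not in nxt:
            raise MeshError(f"open fan at boundary node {node}")
        nxt_node = nxt.pop(cur)
        if nxt_node == cycle[0]:
            break
        cycle.append(int(nxt_node))
        if len(cycle) > len(incident):
            raise MeshError(f"fan at node {node} does not close")
    if nxt:
        raise MeshError(f"fan at node {node} does not visit all faces")
    return np.asarray(cycle, dtype=np.int64)


# ---------------------------------------------------------------------------
# ascii OFF / PLY I/O
# ---------------------------------------------------------------------------

def _parse_error(path, lineno, msg):
    return MeshError(f"{path}:{lineno}: {msg}")


def _read_off(path) -> TriMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    # strip comments / blanks, keep original line numbers
    rows = [(i + 1, ln.strip()) for i, ln in enumerate(lines)
            if ln.strip() and not ln.strip().startswith("#")]
    if not rows or rows[0][1] != "OFF":
        raise _parse_error(path, rows[0][0] if rows else 1,
                           "missing OFF header")
    try:
        nv, nf, _ = (int(t) for t in rows[1][1].split()[:3])
    except (ValueError, IndexError):
        raise _parse_error(path, rows[1][0], "bad count line") from None
    body = rows[2:]
    if len(body) < nv + nf:
        raise _parse_error(path, rows[1][0],
                           f"expected {nv} vertices + {nf} faces, "
                           f"found {len(body)} data lines")
    verts = np.empty((nv, 3))
    for k in range(nv):
        lineno, ln = body[k]
        parts = ln.split()
        if len(parts) < 3:
            raise _parse_error(path, lineno, "vertex line needs 3 coordinates")
        try:
            verts[k] = [float(p) for p in parts[:3]]
        except ValueError:
            raise _parse_error(path, lineno, "non-numeric coordinate") from None
    faces = np.empty((nf, 3), dtype=np.int64)
    for k in range(nf):
        lineno, ln = body[nv + k]
        parts = ln.split()
        try:
            cnt = int(parts[0])
        except (ValueError, IndexError):
            raise _parse_error(path, lineno, "bad face line") from None
        if cnt != 3:
            raise _parse_error(path, lineno,
                               f"only triangles supported, face has {cnt} "
                               "vertices")
        if len(parts) < 4:
            raise _parse_error(path, lineno, "truncated face line")
        faces[k] = [int(p) for p in parts[1:4]]
    return TriMesh(verts, faces)


def _read_ply(path) -> TriMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise _parse_error(path, 1, "missing ply magic")
    nv = nf = None
    fmt = None
    header_end = None
    for i, ln in enumerate(lines[1:], start=2):
        t = ln.split()
        if not t:
            continue
        if t[0] == "format":
            fmt = t[1]
        elif t[0] == "element" and t[1] == "vertex":
            nv = int(t[2])
        elif t[0] == "element" and t[1] == "face":
            nf = int(t[2])
        elif t[0] == "end_header":
            header_end = i
            break
    if header_end is None:
        raise _parse_error(path, len(lines), "no end_header")
    if fmt != "ascii":
        raise _parse_error(path, 1, f"only ascii PLY supported, got {fmt!r}")
    if nv is None or nf is None:
        raise _parse_error(path, 1, "missing vertex/face element counts")
    body = lines[header_end:]
    if len(body) < nv + nf:
        raise _parse_error(path, header_end,
                           "fewer data lines than declared elements")
    verts = np.empty((nv, 3))
    for k in range(nv):
        parts = body[k].split()
        try:
            verts[k] = [float(p) for p in parts[:3]]
        except (ValueError, IndexError):
            raise _parse_error(path, header_end + 1 + k,
                               "bad vertex line") from None
    faces = np.empty((nf, 3), dtype=np.int64)
    for k in range(nf):
        lineno = header_end + 1 + nv + k
        parts = body[nv + k].split()
        cnt = int(parts[0])
        if cnt != 3:
            raise _parse_error(path, lineno,
                               f"only triangular faces supported, got a "
                               f"{cnt}-gon")
        faces[k] = [int(p) for p in parts[1:4]]
    return TriMesh(verts, faces)


def read_mesh(path) -> TriMesh:
    """Read an ascii OFF or PLY mesh (format chosen by extension)."""
    p = str(path)
    if p.lower().endswith(".off"):
        return _read_off(p)
    if p.lower().endswith(".ply"):
        return _read_ply(p)
    raise MeshError(f"unsupported mesh extension: {p}")


def write_mesh(mesh: TriMesh, path) -> None:
    """Write an ascii OFF or PLY mesh (format chosen by extension)."""
    p = str(path)
    if p.lower().endswith(".off"):
        with open(p, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_nodes} {mesh.n_faces} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif p.lower().endswith(".ply"):
        with open(p, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_nodes}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise MeshError(f"unsupported mesh extension: {p}")
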