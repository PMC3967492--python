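"""Triangle-mesh container, file I/O and adjacency structures.

Everything downstream (tensor voting, segmentation, sharpening) works on the
indexed :class:`TriangleMesh` plus the derived :class:`FaceAttributes` and
:class:`Adjacency`.  Face normals are always recomputed from geometry; normals
stored in files are never trusted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriangleMesh",
    "FaceAttributes",
    "Adjacency",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "compute_face_attributes",
    "build_adjacency",
]

_FORMATS = ("obj", "ply", "stl", "off")


class MeshValidationError(ValueError):
    """Raised when a mesh violates the structural invariants."""


@dataclass
class TriangleMesh:
    """Indexed triangle mesh: ``vertices`` (n, 3) float64, ``faces`` (m, 3) int64.

    Invariants (checked by :meth:`validate`): all face indices in range, no
    face repeats a vertex, every face has nonzero area, and the mesh is
    edge-manifold (each edge shared by at most two faces; boundary allowed).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def validate(self) -> "TriangleMesh":
        v, f = self.vertices, self.faces
        if len(f) == 0:
            raise MeshValidationError("mesh has no faces")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= len(v):
            raise MeshValidationError("face indices out of range")
        repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if repeated.any():
            raise MeshValidationError(
                f"faces repeating a vertex: {np.nonzero(repeated)[0].tolist()}"
            )
        areas = _face_areas(v, f)
        degenerate = np.nonzero(areas <= 0.0)[0]
        if len(degenerate):
            raise MeshValidationError(f"zero-area faces: {degenerate.tolist()}")
        edges = _sorted_edges(f).reshape(-1, 2)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if (counts > 2).any():
            raise MeshValidationError(
                f"non-manifold edges shared by >2 faces: {int((counts > 2).sum())}"
            )
        return self


@dataclass
class FaceAttributes:
    """Per-face unit normal, area and barycenter."""

    normals: np.ndarray  # (m, 3) unit vectors
    areas: np.ndarray  # (m,) strictly positive
    barycenters: np.ndarray  # (m, 3)


@dataclass
class Adjacency:
    """One-ring neighbourhoods and the dual graph of a mesh.

    ``vertex_faces[i]``  – faces incident to vertex i (the one-ring N_v).
    ``face_neighbors[k]`` – faces sharing at least one vertex with face k
    (excluding k itself); this wider stencil is what the normal filter uses.
    ``face_edge_neighbors[k]`` – faces sharing an edge with face k (≤ 3).
    ``dual_edges`` – (E, 2) array, one row per interior mesh edge.
    """

    vertex_faces: list = field(default_factory=list)
    face_neighbors: list = field(default_factory=list)
    face_edge_neighbors: list = field(default_factory=list)
    dual_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    e1 = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    e2 = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def _sorted_edges(faces: np.ndarray) -> np.ndarray:
    """All 3m directed face edges with sorted endpoints, shape (m, 3, 2)."""
    e = np.stack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=1
    )
    return np.sort(e, axis=2)


def _infer_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext not in _FORMATS:
        raise ValueError(f"cannot infer mesh format from {path!r}")
    return ext


def read_mesh(path: str, fmt: str = "auto", merge_tol: float | None = None) -> TriangleMesh:
    """Load a mesh from OBJ/PLY/STL/OFF and validate it.

    STL stores a triangle soup, so vertices are merged by exact coordinate
    equality (scanner exports are written from indexed meshes).  Pass
    ``merge_tol`` to merge by a coordinate tolerance instead (all formats).
    """
    fmt = _infer_format(path, fmt)
    try:
        tm = _trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # pragma: no cover - trimesh error variety
        raise IOError(f"failed to parse {path!r} as {fmt}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise IOError(f"{path!r} contains no triangle faces")
    v = np.asarray(tm.vertices, dtype=np.float64)
    f = np.asarray(tm.faces, dtype=np.int64)
    if fmt == "stl" or merge_tol is not None:
        v, f = _merge_vertices(v, f, merge_tol)
    return TriangleMesh(v, f).validate()


def _merge_vertices(v: np.ndarray, f: np.ndarray, tol: float | None):
    key = v if tol is None else np.round(v / tol) * tol
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    # keep original coordinates of the first occurrence of each key
    first = np.full(len(uniq), -1, dtype=np.int64)
    order = np.arange(len(v))[::-1]
    first[inverse[order]] = order
    return v[first], inverse[f]


def write_mesh(mesh: TriangleMesh, path: str, fmt: str = "auto") -> None:
    """Write a mesh; format inferred from the extension unless given."""
    fmt = _infer_format(path, fmt)
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    try:
        tm.export(path, file_type=fmt)
    except Exception as exc:  # pragma: no cover
        raise IOError(f"failed to write {path!r}: {exc}") from exc


def compute_face_attributes(mesh: TriangleMesh) -> FaceAttributes:
    """Unit normals (winding order), areas and barycenters for every face."""
    v, f = mesh.vertices, mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    cross = np.cross(e1, e2)
    norms = np.linalg.norm(cross, axis=1)
    if (norms == 0.0).any():
        raise MeshValidationError("zero-area face encountered")
    normals = cross / norms[:, None]
    return FaceAttributes(
        normals=normals,
        areas=0.5 * norms,
        barycenters=v[f].mean(axis=1),
    )


def build_adjacency(mesh: TriangleMesh) -> Adjacency:
    """One-ring neighbourhoods plus the face dual graph."""
    f = mesh.faces
    m = len(f)
    vertex_faces: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for k in range(m):
        for vid in f[k]:
            vertex_faces[vid].append(k)
    vf = [np.asarray(lst, dtype=np.int64) for lst in vertex_faces]

    face_neighbors = []
    for k in range(m):
        nb = np.concatenate([vf[vid] for vid in f[k]])
        nb = np.unique(nb)
        face_neighbors.append(nb[nb != k])

    edges = _sorted_edges(f).reshape(-1, 2)
    owner = np.repeat(np.arange(m), 3)
    uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
    buckets: list[list[int]] = [[] for _ in range(len(uniq))]
    for row, eid in enumerate(inverse):
        buckets[eid].append(owner[row])
    dual = [sorted(b) for b in buckets if len(b) == 2]
    dual_edges = (
        np.asarray(dual, dtype=np.int64) if dual else np.empty((0, 2), np.int64)
    )
    edge_nb: list[list[int]] = [[] for _ in range(m)]
    for a, b in dual_edges:
        edge_nb[a].append(b)
        edge_nb[b].append(a)
    return Adjacency(
        vertex_faces=vf,
        face_neighbors=face_neighbors,
        face_edge_neighbors=[np.asarray(x, dtype=np.int64) for x in edge_nb],
        dual_edges=dual_edges,
    )
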