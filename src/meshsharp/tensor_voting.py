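"""Per-vertex normal voting tensors.

The normal tensor at a vertex accumulates weighted outer products of the unit
normals of its one-ring faces,

    A_v = sum_j w_j n_j n_j^T,
    w_j = (area(f_j) / area_max) * exp(-||c_j - v|| / (sigma / 3)),

where area_max is the largest incident-face area, c_j the face barycenter and
sigma a bounding-box scale of the one-ring.  The sorted eigenvalues
(s1 >= s2 >= s3 >= 0) of A_v classify the local structure: one dominant
eigenvalue on smooth patches, two comparable ones across a sharp edge, three
comparable ones at a corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import Adjacency, FaceAttributes, TriangleMesh

__all__ = [
    "VertexTensor",
    "tensor_weights",
    "vertex_normal_tensor",
    "compute_vertex_tensors",
]

_EIG_CLAMP = 1e-12


@dataclass
class VertexTensor:
    """Symmetric PSD 3x3 tensor with its sorted eigen-system.

    ``eigenvalues`` are sorted descending and clamped at zero from below;
    ``eigenvectors[:, i]`` is the unit eigenvector of ``eigenvalues[i]``,
    sign-normalised so its first nonzero component is positive.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


def _one_ring_scale(vertex: int, mesh: TriangleMesh, adj: Adjacency, mode: str) -> float:
    """Bounding scale sigma of the one-ring vertex set.

    The default "longest" is the longest edge of the axis-aligned bounding
    box of the ring vertices; "diagonal" is that box's diagonal.  Both are
    frame-dependent.  "diameter" (max pairwise vertex distance, scaled to a
    box edge) is the rotation-invariant alternative: use it when exact
    equivariance of the tensor under rigid motions matters more than
    matching the axis-aligned convention.
    """
    faces = adj.vertex_faces[vertex]
    ring = np.unique(mesh.faces[faces].ravel())
    pts = mesh.vertices[ring]
    if mode == "diameter":
        # ring diameter scaled to a box edge: a square-ish ring of diameter
        # d has tight bounding-box edges of about d/sqrt(2)
        diff = pts[:, None, :] - pts[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2).max() / 2.0))
    extent = pts.max(axis=0) - pts.min(axis=0)
    if mode == "longest":
        return float(extent.max())
    if mode == "diagonal":
        return float(np.linalg.norm(extent))
    raise ValueError(f"unknown bbox mode {mode!r}")


def tensor_weights(
    vertex: int,
    mesh: TriangleMesh,
    attrs: FaceAttributes,
    adj: Adjacency,
    bbox_mode: str = "longest",
) -> np.ndarray:
    """Voting weights w_j for every face incident to ``vertex`` (in (0, 1])."""
    faces = adj.vertex_faces[vertex]
    if len(faces) == 0:
        raise ValueError(f"vertex {vertex} has no incident faces")
    areas = attrs.areas[faces]
    dist = np.linalg.norm(attrs.barycenters[faces] - mesh.vertices[vertex], axis=1)
    sigma = _one_ring_scale(vertex, mesh, adj, bbox_mode)
    if sigma > 0.0:
        decay = np.exp(-dist / (sigma / 3.0))
    else:  # fully degenerate ring collapsed to a point
        decay = np.ones_like(dist)
    return (areas / areas.max()) * decay


def _eigen_system(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(tensor)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    if (vals < -_EIG_CLAMP).any():
        raise ValueError("normal tensor has a significantly negative eigenvalue")
    vals = np.clip(vals, 0.0, None)
    # deterministic sign: first component with magnitude > clamp is positive
    for i in range(3):
        col = vecs[:, i]
        nz = np.nonzero(np.abs(col) > _EIG_CLAMP)[0]
        if len(nz) and col[nz[0]] < 0:
            vecs[:, i] = -col
    return vals, vecs


def vertex_normal_tensor(
    vertex: int,
    weights: np.ndarray,
    attrs: FaceAttributes,
    adj: Adjacency,
) -> VertexTensor:
    """Accumulate the weighted outer products of one-ring face normals."""
    faces = adj.vertex_faces[vertex]
    n = attrs.normals[faces]
    tensor = np.einsum("j,ja,jb->ab", weights, n, n)
    vals, vecs = _eigen_system(tensor)
    return VertexTensor(tensor=tensor, eigenvalues=vals, eigenvectors=vecs)


def compute_vertex_tensors(
    mesh: TriangleMesh,
    attrs: FaceAttributes,
    adj: Adjacency,
    bbox_mode: str = "longest",
) -> np.ndarray:
    """Sorted eigenvalue triples (n_vertices, 3) of every vertex tensor."""
    out = np.empty((mesh.n_vertices, 3))
    for v in range(mesh.n_vertices):
        w = tensor_weights(v, mesh, attrs, adj, bbox_mode=bbox_mode)
        out[v] = vertex_normal_tensor(v, w, attrs, adj).eigenvalues
    return out
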