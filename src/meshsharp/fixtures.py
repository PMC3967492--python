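"""Synthetic meshes emulating scanner-blurred edges, with exact ground truth.

Scanned dental and mechanical surfaces blur sharp creases into rounded
fillets.  These generators build such surfaces analytically so every test has
ground truth: the sharp counterpart (same topology), per-simplex region masks
(flat / fillet band / corner patch), the exact fillet radius and the adjacent
plane normals.

The rounding construction is a Minkowski offset: a point p sampled on the
sharp surface is clamped onto the inner (inset-by-r) solid at q and displaced
to q + r * (p - q)/||p - q||.  Flat-region samples are fixed points of this
map, so blurred and sharp meshes agree exactly there; edge samples land on
circular arcs of radius exactly r about the inset edge line, corners on
spherical patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import TriangleMesh

__all__ = [
    "FixtureBundle",
    "EdgeInfo",
    "FLAT",
    "FILLET",
    "CORNER",
    "make_filleted_box",
    "make_rounded_disk",
    "make_canonical_one_ring",
    "add_vertex_noise",
]

FLAT, FILLET, CORNER = 0, 1, 2


@dataclass
class EdgeInfo:
    """A sharp edge line segment and the outward normals of its two flanks."""

    point_a: np.ndarray
    point_b: np.ndarray
    normals: tuple


@dataclass
class FixtureBundle:
    """Blurred mesh, its ideal sharp counterpart and the ground truth."""

    blurred: TriangleMesh
    sharp: TriangleMesh
    vertex_mask: np.ndarray  # per-vertex region code FLAT/FILLET/CORNER
    face_mask: np.ndarray  # per-face code: max over the face's vertices
    fillet_radius: float
    plane_normals: list = field(default_factory=list)
    edges: list = field(default_factory=list)  # EdgeInfo sharp edge skeleton


# ---------------------------------------------------------------------------
# filleted box


def _cube_surface_grid(dims, resolution):
    """Welded triangulation of a box surface; integer lattice keys make the
    seam welding exact.  Returns (vertices, faces) with outward winding."""
    dims = np.asarray(dims, dtype=np.float64)
    m = np.maximum(2, np.round(dims / resolution).astype(int))
    # u/v axes chosen so that e_u x e_v points along the outward normal
    face_axes = {
        (2, +1): (0, 1), (2, -1): (1, 0),
        (0, +1): (1, 2), (0, -1): (2, 1),
        (1, +1): (2, 0), (1, -1): (0, 2),
    }
    key_to_id: dict[tuple, int] = {}
    verts: list[np.ndarray] = []
    faces: list[tuple] = []

    def vid(ikey):
        if ikey not in key_to_id:
            key_to_id[ikey] = len(verts)
            p = np.array(ikey, dtype=np.float64) / 2.0  # keys are doubled ints
            verts.append(p * dims / m)
        return key_to_id[ikey]

    for (axis, sign), (ua, va) in face_axes.items():
        mu, mv = m[ua], m[va]
        w_fixed = m[axis] if sign > 0 else 0
        for iu in range(mu):
            for iv in range(mv):
                def key(du, dv):
                    ik = [0, 0, 0]
                    ik[axis] = 2 * w_fixed
                    ik[ua] = 2 * (iu + du)
                    ik[va] = 2 * (iv + dv)
                    return tuple(ik)

                a = vid(key(0, 0))
                b = vid(key(1, 0))
                c = vid(key(1, 1))
                d = vid(key(0, 1))
                faces.append((a, b, c))
                faces.append((a, c, d))
    v = np.asarray(verts) - dims / 2.0  # center at origin
    return v, np.asarray(faces, dtype=np.int64), m


def _round_points(points, inner_lo, inner_hi, radius):
    """Clamp-and-offset rounding; returns rounded points and per-point count
    of clamped coordinates (0/1 flat, 2 edge, 3 corner)."""
    q = np.clip(points, inner_lo, inner_hi)
    d = points - q
    dist = np.linalg.norm(d, axis=1)
    clamped = (np.abs(d) > 1e-12).sum(axis=1)
    out = points.copy()
    mask = dist > 0
    out[mask] = q[mask] + radius * d[mask] / dist[mask, None]
    return out, clamped


def make_filleted_box(
    dims=(1.0, 1.0, 1.0), fillet_radius: float = 0.1, resolution: float = 0.05
) -> FixtureBundle:
    """Axis-aligned box whose 12 edges are circular fillets of exact radius.

    ``resolution`` is the target mesh edge length on the sharp box.  The
    fillet band must span at least ~2 triangles (4 * fillet_radius /
    resolution >= 2) or a ValueError is raised; >= 6 is recommended for
    measurement-quality bands.
    """
    dims = np.asarray(dims, dtype=np.float64)
    r = float(fillet_radius)
    if not (0.0 < r < dims.min() / 2.0):
        raise ValueError("fillet_radius must be in (0, min(dims)/2)")
    if 4.0 * r / resolution < 2.0 - 1e-9:
        raise ValueError(
            "resolution too coarse to resolve the fillet band "
            f"(need resolution <= {2.0 * r:.4g})"
        )
    sharp_v, faces, _ = _cube_surface_grid(dims, resolution)
    half = dims / 2.0
    blurred_v, clamped = _round_points(sharp_v, -(half - r), half - r, r)
    vertex_mask = np.where(clamped >= 3, CORNER, np.where(clamped == 2, FILLET, FLAT))
    face_mask = vertex_mask[faces].max(axis=1)
    sharp = TriangleMesh(sharp_v, faces).validate()
    blurred = TriangleMesh(blurred_v, faces.copy()).validate()

    normals = [np.array(n, dtype=float) for n in
               [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]]
    edges = []
    for axis in range(3):
        a1, a2 = [a for a in range(3) if a != axis]
        for s1 in (-1, 1):
            for s2 in (-1, 1):
                pa = np.zeros(3)
                pb = np.zeros(3)
                pa[axis], pb[axis] = -half[axis], half[axis]
                for a, s in ((a1, s1), (a2, s2)):
                    pa[a] = pb[a] = s * half[a]
                n1 = np.zeros(3)
                n1[a1] = s1
                n2 = np.zeros(3)
                n2[a2] = s2
                edges.append(EdgeInfo(pa, pb, (n1, n2)))
    return FixtureBundle(
        blurred=blurred,
        sharp=sharp,
        vertex_mask=vertex_mask,
        face_mask=face_mask,
        fillet_radius=r,
        plane_normals=normals,
        edges=edges,
    )


# ---------------------------------------------------------------------------
# rounded disk


def make_rounded_disk(
    radius: float = 1.0,
    height: float = 0.4,
    rim_radius: float = 0.08,
    resolution: float = 0.08,
) -> FixtureBundle:
    """Closed cylinder whose two rims are toroidally rounded (radius
    ``rim_radius``); the sharp counterpart has true 90-degree rims."""
    R, H, r = float(radius), float(height), float(rim_radius)
    if not (0.0 < r < H / 2.0 and r < R):
        raise ValueError("need 0 < rim_radius < height/2 and < radius")
    n_theta = max(8, int(round(2.0 * np.pi * R / resolution)))
    # sharp profile in (rho, z): bottom cap, side, top cap
    n_cap = max(2, int(round(R / resolution)))
    n_side = max(2, int(round(H / resolution)))
    prof = []
    for t in np.linspace(0.0, R, n_cap + 1)[:-1]:
        prof.append((t, 0.0))
    for z in np.linspace(0.0, H, n_side + 1):
        prof.append((R, z))
    for t in np.linspace(R, 0.0, n_cap + 1)[1:]:
        prof.append((t, H))
    prof = np.asarray(prof)
    rounded, clamped = _round_points(
        np.column_stack([prof, np.zeros(len(prof))]),
        np.array([-np.inf, r, -np.inf]),
        np.array([R - r, H - r, np.inf]),
        r,
    )
    prof_round = rounded[:, :2]
    prof_mask = np.where(clamped >= 2, FILLET, FLAT)

    def revolve(profile):
        thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
        verts = [np.array([0.0, 0.0, profile[0, 1]])]  # bottom axis point
        ring_ids = []
        for rho, z in profile:
            if rho <= 1e-12:
                continue
            ids = []
            for th in thetas:
                ids.append(len(verts))
                verts.append(np.array([rho * np.cos(th), rho * np.sin(th), z]))
            ring_ids.append(ids)
        top_id = len(verts)
        verts.append(np.array([0.0, 0.0, profile[-1, 1]]))
        faces = []
        first = ring_ids[0]
        for t in range(n_theta):
            faces.append((0, first[(t + 1) % n_theta], first[t]))
        for ra, rb in zip(ring_ids[:-1], ring_ids[1:]):
            for t in range(n_theta):
                t2 = (t + 1) % n_theta
                faces.append((ra[t], ra[t2], rb[t2]))
                faces.append((ra[t], rb[t2], rb[t]))
        last = ring_ids[-1]
        for t in range(n_theta):
            faces.append((top_id, last[t], last[(t + 1) % n_theta]))
        return np.asarray(verts), np.asarray(faces, dtype=np.int64)

    sharp_v, faces = revolve(prof)
    blur_v, faces2 = revolve(prof_round)
    assert np.array_equal(faces, faces2)
    # per-vertex mask follows the profile rows that generated each vertex
    ring_rows = [idx for idx, (rho, _) in enumerate(prof) if rho > 1e-12]
    vertex_mask = np.zeros(len(sharp_v), dtype=np.int64)
    vid = 1
    for row in ring_rows:
        for _ in range(n_theta):
            vertex_mask[vid] = prof_mask[row]
            vid += 1
    face_mask = vertex_mask[faces].max(axis=1)
    axis = np.array([0.0, 0.0, 1.0])
    return FixtureBundle(
        blurred=TriangleMesh(blur_v, faces.copy()).validate(),
        sharp=TriangleMesh(sharp_v, faces).validate(),
        vertex_mask=vertex_mask,
        face_mask=face_mask,
        fillet_radius=r,
        plane_normals=[axis, -axis],
        edges=[],
    )


# ---------------------------------------------------------------------------
# canonical one-rings


def make_canonical_one_ring(
    kind: str,
    n_faces: int = 8,
    dihedral_deg: float = 90.0,
    radius: float = 1.0,
) -> tuple[TriangleMesh, int]:
    """Single-vertex fan realising a canonical local structure.

    ``kind='flat'``: planar fan (all normals identical).
    ``kind='edge'``: two congruent planar half-fans meeting along a crease
    through the center at the given dihedral angle (normals span exactly two
    directions).
    ``kind='corner'``: three planar sectors with mutually orthogonal normals.

    Returns (mesh, center vertex id); the center vertex is id 0.
    """
    if n_faces < 3:
        raise ValueError("need at least 3 faces")
    if kind == "flat":
        angles = np.linspace(0.0, 2.0 * np.pi, n_faces + 1)
        ring = np.column_stack(
            [radius * np.cos(angles), radius * np.sin(angles), np.zeros_like(angles)]
        )[:-1]
        verts = np.vstack([[0.0, 0.0, 0.0], ring])
        faces = [(0, 1 + t, 1 + (t + 1) % n_faces) for t in range(n_faces)]
        return TriangleMesh(verts, np.asarray(faces)).validate(), 0
    if kind == "edge":
        theta = np.deg2rad(dihedral_deg)
        if not (0.0 < theta < np.pi):
            raise ValueError("dihedral angle must be in (0, 180) degrees")
        half = n_faces // 2
        if half < 1 or n_faces != 2 * half:
            raise ValueError("edge fan needs an even face count")
        # crease along y; each half-fan spans 180 degrees in its own plane
        fold = (np.pi - theta) / 2.0  # rotate each half about y by +/- fold
        verts = [np.array([0.0, 0.0, 0.0])]
        faces = []

        def half_fan(sign):
            base = len(verts)
            angles = np.linspace(0.0, np.pi, half + 1)
            c, s = np.cos(sign * fold), np.sin(sign * fold)
            for a in angles:
                p = np.array([sign * radius * np.sin(a), -radius * np.cos(a), 0.0])
                # rotate about y axis, tilting the plane out of z=0
                verts.append(np.array([c * p[0], p[1], s * p[0]]))
            for t in range(half):
                if sign > 0:
                    faces.append((0, base + t, base + t + 1))
                else:
                    faces.append((0, base + t + 1, base + t))

        half_fan(+1)
        half_fan(-1)
        return TriangleMesh(np.asarray(verts), np.asarray(faces)).validate(), 0
    if kind == "corner":
        per = max(1, n_faces // 3)
        verts = [np.array([0.0, 0.0, 0.0])]
        faces = []
        frames = [  # (u, v) spanning each sector plane; normal = u x v
            (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
            (np.array([0, 1.0, 0]), np.array([0, 0, 1.0])),
            (np.array([0, 0, 1.0]), np.array([1.0, 0, 0])),
        ]
        for u, v in frames:
            base = len(verts)
            angles = np.linspace(0.0, np.pi / 2.0, per + 1)
            for a in angles:
                verts.append(radius * (np.cos(a) * u + np.sin(a) * v))
            for t in range(per):
                faces.append((0, base + t, base + t + 1))
        return TriangleMesh(np.asarray(verts), np.asarray(faces)).validate(), 0
    raise ValueError(f"unknown one-ring kind {kind!r}")


def add_vertex_noise(mesh: TriangleMesh, sigma: float, seed: int = 0) -> TriangleMesh:
    """Isotropic Gaussian vertex displacement (scanner-noise emulation)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=mesh.vertices.shape)
    return TriangleMesh(mesh.vertices + noise, mesh.faces.copy())
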