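"""Quantitative mesh comparison: Hausdorff deviation and edge profiles.

The symmetric Hausdorff distance localises where sharpening changed the
surface; the edge-profile analysis cuts cross-sections perpendicular to a
ground-truth sharp edge, fits the two planar flanks and a least-squares
circle to the transition points, and reports the residual fillet radius that
the sharpness parameter alpha controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh

from .fixtures import FixtureBundle
from .mesh_core import TriangleMesh

__all__ = [
    "DeviationReport",
    "EdgeProfile",
    "SectionFit",
    "hausdorff",
    "point_surface_distances",
    "edge_profile",
]


@dataclass
class DeviationReport:
    """Vertex-sampled deviations between two surfaces."""

    dist_a_to_b: np.ndarray  # per vertex of A, distance to surface B
    dist_b_to_a: np.ndarray
    hausdorff: float  # max of the two directed maxima
    quantiles: dict  # {"p50": ..., "p90": ..., "p99": ..., "max": ...}


@dataclass
class SectionFit:
    """One cross-section: fitted flank opening angle and arc radius."""

    edge_index: int
    t: float  # position along the edge in [0, 1]
    angle_deg: float
    radius: float
    n_transition: int


@dataclass
class EdgeProfile:
    sections: list

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.sections])

    @property
    def angles(self) -> np.ndarray:
        return np.array([s.angle_deg for s in self.sections])

    def median_radius(self) -> float:
        return float(np.median(self.radii))


def _as_trimesh(mesh: TriangleMesh) -> _trimesh.Trimesh:
    return _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)


def _point_triangle_distance_sq(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Squared distances between every point and every triangle.

    ``points`` (p, 3), ``tri`` (t, 3, 3) -> (p, t).  Projects each point onto
    each triangle plane, clamps barycentric coordinates edge-by-edge.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    d = points[:, None, :] - a[None, :, :]  # (p, t, 3)
    d00 = np.einsum("tj,tj->t", ab, ab)
    d01 = np.einsum("tj,tj->t", ab, ac)
    d11 = np.einsum("tj,tj->t", ac, ac)
    e0 = np.einsum("ptj,tj->pt", d, ab)
    e1 = np.einsum("ptj,tj->pt", d, ac)
    det = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    v = (d11 * e0 - d01 * e1) / det
    w = (d00 * e1 - d01 * e0) / det
    u = 1.0 - v - w
    inside = (u >= 0) & (v >= 0) & (w >= 0)
    # clamp to the three edges and take the best
    def seg(pa, pe, ee):
        t = np.clip(np.einsum("ptj,tj->pt", pa, pe) / np.maximum(ee, 1e-300), 0, 1)
        diff = pa - t[:, :, None] * pe[None, :, :]
        return np.einsum("ptj,ptj->pt", diff, diff)
    bc = c - b
    d_b = points[:, None, :] - b[None, :, :]
    best_edge = np.minimum(
        seg(d, ab, d00),
        np.minimum(seg(d, ac, d11), seg(d_b, bc, np.einsum("tj,tj->t", bc, bc))),
    )
    proj = a[None] + v[:, :, None] * ab[None] + w[:, :, None] * ac[None]
    diffp = points[:, None, :] - proj
    plane = np.einsum("ptj,ptj->pt", diffp, diffp)
    return np.where(inside, plane, best_edge)


def point_surface_distances(
    points: np.ndarray, mesh: TriangleMesh, chunk: int = 128
) -> np.ndarray:
    """Unsigned distance from each point to the closest triangle of ``mesh``.

    Exact (every point against every triangle), evaluated in chunks to bound
    memory; adequate and fully deterministic at fixture resolutions.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = mesh.vertices[mesh.faces]
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        d2 = _point_triangle_distance_sq(points[s : s + chunk], tri)
        out[s : s + chunk] = np.sqrt(d2.min(axis=1))
    return out


def hausdorff(mesh_a: TriangleMesh, mesh_b: TriangleMesh) -> DeviationReport:
    """Vertex-sampled symmetric Hausdorff deviation between two meshes."""
    if mesh_a.n_faces == 0 or mesh_b.n_faces == 0:
        raise ValueError("empty mesh")
    d_ab = point_surface_distances(mesh_a.vertices, mesh_b)
    d_ba = point_surface_distances(mesh_b.vertices, mesh_a)
    h = float(max(d_ab.max(), d_ba.max()))
    both = np.concatenate([d_ab, d_ba])
    quant = {
        "p50": float(np.percentile(both, 50)),
        "p90": float(np.percentile(both, 90)),
        "p99": float(np.percentile(both, 99)),
        "max": h,
    }
    return DeviationReport(d_ab, d_ba, h, quant)


def _fit_circle_radius(points_2d: np.ndarray, window: float) -> float:
    """Least-squares radius of the arc joining two perpendicular flanks.

    The flank lines are the coordinate axes of the section frame, so a
    transition arc tangent to both has center (c, c) and radius c.  Fitting
    that one-parameter family is robust to the point scatter a jagged crease
    produces, where an unconstrained circle fit is ill-posed.
    """
    from scipy.optimize import minimize_scalar

    def cost(c):
        d = np.hypot(points_2d[:, 0] - c, points_2d[:, 1] - c)
        return float(((d - c) ** 2).sum())

    res = minimize_scalar(cost, bounds=(0.0, window), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def edge_profile(
    bundle: FixtureBundle,
    sharpened: TriangleMesh,
    n_sections: int = 8,
    flank_tol_deg: float = 5.0,
    window_factor: float = 4.0,
) -> EdgeProfile:
    """Residual fillet radius and flank angle along every ground-truth edge.

    For each section plane perpendicular to a sharp edge line, the surface
    cross-section near the edge is split into flank points (within
    ``flank_tol_deg`` of one of the two known flank lines) and transition
    points (off both flanks); the transition points get a least-squares
    circle, the flanks get total-least-squares lines whose opening angle is
    reported.  Sections with too few intersection points are skipped.
    """
    tm = _as_trimesh(sharpened)
    window = window_factor * bundle.fillet_radius
    sections: list[SectionFit] = []
    for eidx, edge in enumerate(bundle.edges):
        pa, pb = np.asarray(edge.point_a), np.asarray(edge.point_b)
        axis = pb - pa
        length = np.linalg.norm(axis)
        axis = axis / length
        n1, n2 = (np.asarray(n) for n in edge.normals)
        # in-plane flank directions away from the edge: along each face
        u1 = -n2 - (-n2 @ axis) * axis
        u2 = -n1 - (-n1 @ axis) * axis
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        inset = max(2.0 * bundle.fillet_radius, 0.15 * length)
        for t in np.linspace(inset / length, 1.0 - inset / length, n_sections):
            origin = pa + t * length * axis
            segs = _trimesh.intersections.mesh_plane(tm, axis, origin)
            if len(segs) == 0:
                continue
            pts3 = np.unique(np.asarray(segs).reshape(-1, 3), axis=0)
            rel = pts3 - origin
            # project into the section plane, coordinates along (u1, u2-ish)
            e1 = u1
            e2 = u2 - (u2 @ e1) * e1
            e2 /= np.linalg.norm(e2)
            p2 = np.column_stack([rel @ e1, rel @ e2])
            rad = np.linalg.norm(p2, axis=1)
            keep = (rad > 1e-9) & (rad < window)
            p2 = p2[keep]
            if len(p2) < 4:
                continue
            fit = _classify_and_fit(p2, u1 @ e1, u1 @ e2, u2 @ e1, u2 @ e2,
                                    np.deg2rad(flank_tol_deg))
            if fit is None:
                continue
            angle_deg, radius, n_trans = fit
            sections.append(SectionFit(eidx, float(t), angle_deg, radius, n_trans))
    return EdgeProfile(sections=sections)


def _classify_and_fit(p2, u1x, u1y, u2x, u2y, tol):
    u1 = np.array([u1x, u1y])
    u2 = np.array([u2x, u2y])
    rad = np.linalg.norm(p2, axis=1)
    cross1 = p2[:, 0] * u1[1] - p2[:, 1] * u1[0]
    cross2 = p2[:, 0] * u2[1] - p2[:, 1] * u2[0]
    ang1 = np.arcsin(np.clip(np.abs(cross1) / rad, 0, 1))
    ang2 = np.arcsin(np.clip(np.abs(cross2) / rad, 0, 1))
    flank1 = (ang1 <= tol) & (p2 @ u1 > 0)
    flank2 = (ang2 <= tol) & (p2 @ u2 > 0)
    transition = ~(flank1 | flank2)
    angle_deg = float("nan")
    if flank1.sum() >= 2 and flank2.sum() >= 2:
        d1 = _principal_direction(p2[flank1])
        d2 = _principal_direction(p2[flank2])
        angle_deg = float(np.degrees(np.arccos(np.clip(np.abs(d1 @ d2), 0, 1))))
    if transition.sum() >= 3:
        radius = _fit_circle_radius(p2[transition], float(rad.max()))
    else:
        radius = 0.0
    return angle_deg, radius, int(transition.sum())


def _principal_direction(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]
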