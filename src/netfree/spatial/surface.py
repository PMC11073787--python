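"""2D diffusion of surface molecules on a triangulated mesh.

A step is a Gaussian displacement in the plane of the molecule's current
triangle.  When the path leaves the triangle it is *unfolded* across the
shared edge into the neighbor's plane (rotation about the edge), so path
length is preserved on the curved surface.  Edges without a partner inside
the allowed triangle set are reflective.  The walk ends at a destination
tile; if that tile is occupied the molecule stays where it started
(surface volume exclusion).
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from ..geometry import TriangleMesh
from ..surfgrid import SurfaceGrid

__all__ = ["surface_walk", "triangle_basis", "barycentric_of_point"]

_MAX_EDGE_EVENTS = 200


def triangle_basis(mesh: TriangleMesh, tri: int):
    """Orthonormal in-plane basis (u, v) and unit normal of a triangle
    (cached per mesh)."""
    cache = getattr(mesh, "_tri_basis", None)
    if cache is None:
        cache = {}
        object.__setattr__(mesh, "_tri_basis", cache)
    hit = cache.get(tri)
    if hit is None:
        a = mesh.vertices[mesh.triangles[tri][0]]
        b = mesh.vertices[mesh.triangles[tri][1]]
        c = mesh.vertices[mesh.triangles[tri][2]]
        u = b - a
        u = u / np.linalg.norm(u)
        n = np.cross(b - a, c - a)
        n = n / np.linalg.norm(n)
        v = np.cross(n, u)
        hit = (u, v, n)
        cache[tri] = hit
    return hit


def barycentric_of_point(mesh: TriangleMesh, tri: int, p) -> np.ndarray:
    return mesh.barycentric(tri, p)


def tri_step_data(mesh: TriangleMesh, tri: int):
    """(u, v, M) for fast in-plane stepping: a 2D displacement (du, dv) in
    the (u, v) basis changes the barycentric coordinates by M @ (du, dv).
    Cached per mesh."""
    cache = getattr(mesh, "_tri_step", None)
    if cache is None:
        cache = {}
        object.__setattr__(mesh, "_tri_step", cache)
    hit = cache.get(tri)
    if hit is None:
        u, v, _ = triangle_basis(mesh, tri)
        a, e1, e2 = mesh.edges_cache()
        e1t, e2t = e1[tri], e2[tri]
        g11 = float(np.dot(e1t, e1t))
        g12 = float(np.dot(e1t, e2t))
        g22 = float(np.dot(e2t, e2t))
        det = g11 * g22 - g12 * g12
        row_u = (g22 * e1t - g12 * e2t) / det  # gradient of b1
        row_v = (g11 * e2t - g12 * e1t) / det  # gradient of b2
        m = np.empty((3, 2))
        m[1, 0] = np.dot(row_u, u)
        m[1, 1] = np.dot(row_u, v)
        m[2, 0] = np.dot(row_v, u)
        m[2, 1] = np.dot(row_v, v)
        m[0] = -(m[1] + m[2])
        hit = (u, v, m)
        cache[tri] = hit
    return hit


def _project_to_triangle(mesh: TriangleMesh, tri: int, p) -> np.ndarray:
    a = mesh.vertices[mesh.triangles[tri][0]]
    _, _, n = triangle_basis(mesh, tri)
    p = np.asarray(p, dtype=float)
    return p - np.dot(p - a, n) * n


def _edge_geometry(mesh: TriangleMesh, tri: int, edge: int):
    """Edge opposite vertex ``edge``: endpoints and outward in-plane
    perpendicular (cached per mesh)."""
    cache = getattr(mesh, "_edge_geom", None)
    if cache is None:
        cache = {}
        object.__setattr__(mesh, "_edge_geom", cache)
    hit = cache.get((tri, edge))
    if hit is None:
        t = mesh.triangles[tri]
        va = mesh.vertices[t[(edge + 1) % 3]]
        vb = mesh.vertices[t[(edge + 2) % 3]]
        e = vb - va
        e = e / np.linalg.norm(e)
        _, _, n = triangle_basis(mesh, tri)
        m = np.cross(e, n)  # in-plane, perpendicular to edge
        # orient away from the opposite vertex (the triangle interior)
        opp = mesh.vertices[t[edge]]
        if np.dot(m, opp - va) > 0:
            m = -m
        hit = (va, vb, e, m)
        cache[(tri, edge)] = hit
    return hit


def surface_walk(grid: SurfaceGrid, tri: int, pos: np.ndarray,
                 disp2d: np.ndarray,
                 allowed: Optional[set[int]] = None
                 ) -> tuple[int, np.ndarray]:
    """Walk a 2D displacement from ``pos`` on triangle ``tri``.

    ``disp2d`` is expressed in the starting triangle's (u, v) basis.
    ``allowed`` restricts the walk to a triangle subset (region fencing);
    crossing its boundary reflects.  Returns (triangle, end point)."""
    mesh = grid.mesh
    u, v, _ = triangle_basis(mesh, tri)
    d = disp2d[0] * u + disp2d[1] * v
    p = _project_to_triangle(mesh, tri, pos)

    partner_of = grid._edge_partner
    for _ in range(_MAX_EDGE_EVENTS):
        if np.linalg.norm(d) < 1e-15:
            break
        bary_target = barycentric_of_point(mesh, tri, p + d)
        if np.all(bary_target >= -1e-12):
            p = p + d
            d = np.zeros(3)
            break
        # first edge crossed: smallest positive fraction where a
        # barycentric coordinate of p + f*d reaches 0
        b_now = barycentric_of_point(mesh, tri, p)
        best_f, best_edge = None, None
        for edge in range(3):
            db = bary_target[edge] - b_now[edge]
            if db >= -1e-15:
                continue
            f = b_now[edge] / (-db)
            if f < -1e-9:
                continue
            f = max(f, 0.0)
            if best_f is None or f < best_f:
                best_f, best_edge = f, edge
        if best_edge is None:  # numerical corner: clamp inside
            p = p + d
            d = np.zeros(3)
            break
        va, vb, e, m_out = _edge_geometry(mesh, tri, best_edge)
        p_hit = p + best_f * d
        d_rem = (1.0 - best_f) * d

        t = mesh.triangles[tri]
        key = (int(t[(best_edge + 2) % 3]), int(t[(best_edge + 1) % 3]))
        partner = partner_of.get(key)
        if partner is not None and (allowed is None or partner[0] in allowed):
            ntri = partner[0]
            # rotate remaining displacement about the edge into the
            # neighbor's plane: keep the e-component, map the outward
            # perpendicular of this face onto the inward one of the next
            _, _, _, m_out2 = _edge_geometry(mesh, ntri, _opposite_edge(
                mesh, ntri, key))
            d_e = np.dot(d_rem, e)
            d_m = np.dot(d_rem, m_out)
            d = d_e * e - d_m * m_out2
            tri = ntri
            p = _project_to_triangle(mesh, tri, p_hit)
        else:
            # reflective boundary: mirror the perpendicular component
            d = d_rem - 2.0 * np.dot(d_rem, m_out) * m_out
            p = p_hit - 1e-12 * m_out
    b = barycentric_of_point(mesh, tri, p)
    b = np.clip(b, 0.0, 1.0)
    b = b / b.sum()
    return tri, p


def _opposite_edge(mesh: TriangleMesh, tri: int,
                   directed_edge: tuple[int, int]) -> int:
    """Local edge index of ``tri`` whose endpoints are the directed edge."""
    t = mesh.triangles[tri]
    a, b = directed_edge
    for edge in range(3):
        ea, eb = int(t[(edge + 1) % 3]), int(t[(edge + 2) % 3])
        if (ea, eb) == (a, b) or (eb, ea) == (a, b):
            return edge
    raise ValueError("edge not found on triangle")
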