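"""Triangulated-mesh geometry.

Meshes are plain numpy arrays: ``vertices`` (n, 3) in μm and ``triangles``
(m, 3) vertex indices with counter-clockwise winding seen from outside, so
the right-hand normal points outward.  Compartment meshes must be closed
2-manifolds with consistent winding.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["TriangleMesh", "MeshDiagnostics", "make_box", "validate_mesh",
           "ray_mesh_intersections", "point_containment", "read_obj",
           "write_obj", "GeometryObject", "RayHit", "EPSILON"]

#: intersection tolerance (μm); also the post-reflection offset
EPSILON = 1e-12
#: triangles below this area (μm²) are degenerate
DEGENERATE_AREA = 1e-12


@dataclass
class TriangleMesh:
    vertices: np.ndarray   # (n, 3) float64, μm
    triangles: np.ndarray  # (m, 3) int64
    #: named triangle subsets (OBJ groups)
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")

    # -- per-triangle quantities (cached: meshes are immutable once built) --

    def corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cache = getattr(self, "_corners", None)
        if cache is None:
            v = self.vertices
            t = self.triangles
            cache = (v[t[:, 0]].copy(), v[t[:, 1]].copy(),
                     v[t[:, 2]].copy())
            object.__setattr__(self, "_corners", cache)
        return cache

    def edges_cache(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(a, e1, e2) = (first corner, b-a, c-a), cached for ray tests."""
        cache = getattr(self, "_edges", None)
        if cache is None:
            a, b, c = self.corners()
            cache = (a, b - a, c - a)
            object.__setattr__(self, "_edges", cache)
        return cache

    def normals(self, normalized: bool = True) -> np.ndarray:
        attr = "_normals_unit" if normalized else "_normals_raw"
        cache = getattr(self, attr, None)
        if cache is None:
            a, b, c = self.corners()
            n = np.cross(b - a, c - a)
            if normalized:
                norm = np.linalg.norm(n, axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                n = n / norm
            object.__setattr__(self, attr, n)
            cache = n
        return cache

    def areas(self) -> np.ndarray:
        a, b, c = self.corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.areas().sum())

    def volume(self) -> float:
        """Enclosed volume by the divergence theorem (signed; positive for
        outward winding)."""
        a, b, c = self.corners()
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def barycentric(self, tri: int, point) -> np.ndarray:
        """Barycentric coordinates of a (near-)in-plane point (cached Gram
        inverses; meshes are immutable)."""
        cache = getattr(self, "_gram", None)
        if cache is None:
            a, e1, e2 = self.edges_cache()
            g11 = np.einsum("ij,ij->i", e1, e1)
            g12 = np.einsum("ij,ij->i", e1, e2)
            g22 = np.einsum("ij,ij->i", e2, e2)
            det = g11 * g22 - g12 * g12
            det[det == 0] = 1.0
            cache = (a, e1, e2, g11, g12, g22, det)
            object.__setattr__(self, "_gram", cache)
        a, e1, e2, g11, g12, g22, det = cache
        r = np.asarray(point, dtype=float) - a[tri]
        b1 = float(np.dot(e1[tri], r))
        b2 = float(np.dot(e2[tri], r))
        u = (g22[tri] * b1 - g12[tri] * b2) / det[tri]
        v = (g11[tri] * b2 - g12[tri] * b1) / det[tri]
        return np.array([1.0 - u - v, u, v])

    def region_triangles(self, name: Optional[str]) -> np.ndarray:
        if name is None:
            return np.arange(len(self.triangles))
        if name not in self.regions:
            raise KeyError(f"mesh has no region {name!r}")
        return np.asarray(self.regions[name], dtype=np.int64)


@dataclass
class MeshDiagnostics:
    open_edges: list[tuple[int, int]]
    inconsistent_edges: list[tuple[int, int]]
    degenerate_triangles: list[int]

    @property
    def is_closed_manifold(self) -> bool:
        return not (self.open_edges or self.inconsistent_edges
                    or self.degenerate_triangles)


def make_box(center, dimensions) -> TriangleMesh:
    """Axis-aligned box of the given (x, y, z) edge lengths, 12 triangles,
    outward normals.  Face regions are named ``-x,+x,-y,+y,-z,+z``."""
    center = np.asarray(center, dtype=float)
    dims = np.asarray(dimensions, dtype=float)
    if np.any(dims <= 0):
        raise ValueError("box dimensions must be positive")
    h = dims / 2.0
    # 8 corners, bit i of index selects +h along axis i
    corners = np.array([[sx, sy, sz] for sz in (-1, 1)
                        for sy in (-1, 1) for sx in (-1, 1)], dtype=float)
    verts = center + corners * h

    # each face: 4 corner indices in CCW order viewed from outside
    faces = {
        "-x": (0, 4, 6, 2), "+x": (1, 3, 7, 5),
        "-y": (0, 1, 5, 4), "+y": (2, 6, 7, 3),
        "-z": (0, 2, 3, 1), "+z": (4, 5, 7, 6),
    }
    tris = []
    regions = {}
    for name, (a, b, c, d) in faces.items():
        regions[name] = np.array([len(tris), len(tris) + 1])
        tris.append((a, b, c))
        tris.append((a, c, d))
    mesh = TriangleMesh(verts, np.array(tris), regions)
    assert mesh.volume() > 0
    return mesh


def validate_mesh(mesh: TriangleMesh) -> MeshDiagnostics:
    """Report open edges, winding inconsistencies, degenerate triangles."""
    degenerate = list(np.nonzero(mesh.areas() <= DEGENERATE_AREA)[0])
    # directed edge census: a closed consistently wound surface uses every
    # undirected edge exactly twice, once per direction
    directed: dict[tuple[int, int], int] = {}
    for tri in mesh.triangles:
        for k in range(3):
            e = (int(tri[k]), int(tri[(k + 1) % 3]))
            directed[e] = directed.get(e, 0) + 1
    open_edges = []
    inconsistent = []
    seen = set()
    for (a, b), n in directed.items():
        if (b, a) in seen or (a, b) in seen:
            continue
        seen.add((a, b))
        m = directed.get((b, a), 0)
        if n == 1 and m == 1:
            continue
        if n + m == 1:
            open_edges.append((a, b))
        else:
            inconsistent.append((a, b))
    return MeshDiagnostics(open_edges, inconsistent,
                           [int(i) for i in degenerate])


@dataclass(frozen=True)
class RayHit:
    fraction: float      # distance along the displacement, in [0, 1]
    triangle: int
    point: np.ndarray
    side: str            # "front" (outside) | "back" (inside)
    barycentric: tuple[float, float, float]


def ray_mesh_intersections(origin, displacement, mesh: TriangleMesh,
                           triangle_indices: Optional[np.ndarray] = None
                           ) -> list[RayHit]:
    """All intersections of the segment origin→origin+displacement with the
    mesh, sorted by distance (Möller–Trumbore, vectorized over triangles).

    Edge/vertex grazing tie-break: among coincident hits only the lowest
    triangle index is kept, so a segment through a shared edge counts one
    crossing."""
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(displacement, dtype=float)
    a, e1, e2 = mesh.edges_cache()
    if triangle_indices is not None:
        a, e1, e2 = (a[triangle_indices], e1[triangle_indices],
                     e2[triangle_indices])
        tri_ids = np.asarray(triangle_indices)
    else:
        tri_ids = np.arange(len(mesh.triangles))
    pvec = _cross(np.broadcast_to(d, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(np.abs(det) > 1e-300, 1.0 / det, 0.0)
        tvec = origin - a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = _cross(tvec, e1)
        v = np.dot(qvec, d) * inv_det
        t = np.einsum("ij,ij->i", qvec, e2) * inv_det
    ok = (np.abs(det) > 1e-300) \
        & (u >= -EPSILON) & (v >= -EPSILON) & (u + v <= 1 + EPSILON) \
        & (t >= -EPSILON) & (t <= 1 + EPSILON)
    hits: list[RayHit] = []
    order = np.argsort(t[ok], kind="stable")
    idx_ok = np.nonzero(ok)[0][order]
    last_t = None
    for i in idx_ok:
        ti = float(np.clip(t[i], 0.0, 1.0))
        if last_t is not None and abs(ti - last_t) <= EPSILON:
            continue  # grazing duplicate: keep lowest-index (stable sort)
        last_t = ti
        side = "front" if det[i] > 0 else "back"
        w = 1.0 - u[i] - v[i]
        hits.append(RayHit(ti, int(tri_ids[i]), origin + ti * d, side,
                           (float(w), float(u[i]), float(v[i]))))
    return hits


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise 3-vector cross product (avoids np.cross overhead)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


def first_hit(origin: np.ndarray, displacement: np.ndarray,
              mesh: TriangleMesh, min_fraction: float = 1e-12):
    """Nearest valid intersection, or None.  Lean path for the inner
    diffusion loop; same semantics as :func:`ray_mesh_intersections` for
    the first hit (lowest triangle index wins ties via argmin)."""
    a, e1, e2 = mesh.edges_cache()
    pvec = _cross(displacement, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(np.abs(det) > 1e-300, 1.0 / det, 0.0)
        tvec = origin - a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = _cross(tvec, e1)
        v = qvec @ displacement * inv_det
        t = np.einsum("ij,ij->i", qvec, e2) * inv_det
    ok = (np.abs(det) > 1e-300) \
        & (u >= -EPSILON) & (v >= -EPSILON) & (u + v <= 1 + EPSILON) \
        & (t > min_fraction) & (t <= 1 + EPSILON)
    if not ok.any():
        return None
    tt = np.where(ok, t, np.inf)
    i = int(np.argmin(tt))
    frac = float(min(t[i], 1.0))
    w = 1.0 - u[i] - v[i]
    return RayHit(frac, i, origin + frac * displacement,
                  "front" if det[i] > 0 else "back",
                  (float(w), float(u[i]), float(v[i])))


_CONTAINMENT_DIR = np.array([0.7390871, 0.5389713, 0.4048627])  # irrational-ish


def point_containment(point, mesh: TriangleMesh) -> bool:
    """True if the point is inside the closed mesh (surface counts inside).

    Parity of crossings along a fixed slightly irrational direction, long
    enough to leave the bounding box."""
    point = np.asarray(point, dtype=float)
    lo, hi = mesh.bounds()
    span = float(np.linalg.norm(hi - lo)) + 1.0
    hits = ray_mesh_intersections(point, _CONTAINMENT_DIR * 2.0 * span, mesh)
    for h in hits:
        if h.fraction <= EPSILON:
            return True  # on the surface
    return len(hits) % 2 == 1


# ---------------------------------------------------------------------------
# Wavefront OBJ (triangles only)
# ---------------------------------------------------------------------------

def read_obj(text: str) -> TriangleMesh:
    """Parse an OBJ file: ``v`` and ``f`` records (1-based indices,
    triangles only), ``g`` records as named regions.  Normals are
    recomputed from winding, never read."""
    verts: list[list[float]] = []
    tris: list[tuple[int, int, int]] = []
    regions: dict[str, list[int]] = {}
    group: Optional[str] = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "v":
            if len(parts) < 4:
                raise ValueError(f"OBJ line {lineno}: bad vertex")
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            if len(parts) != 4:
                raise ValueError(
                    f"OBJ line {lineno}: only triangular faces supported")
            ids = []
            for tok in parts[1:]:
                i = int(tok.split("/")[0])
                ids.append(i - 1 if i > 0 else len(verts) + i)
            if group is not None:
                regions.setdefault(group, []).append(len(tris))
            tris.append(tuple(ids))  # type: ignore[arg-type]
        elif parts[0] == "g":
            group = parts[1] if len(parts) > 1 else None
        # vn/vt/usemtl/o/s silently ignored
    return TriangleMesh(np.array(verts, dtype=float),
                        np.array(tris, dtype=np.int64),
                        {k: np.array(v) for k, v in regions.items()})


def write_obj(mesh: TriangleMesh) -> str:
    out = ["# triangulated mesh (μm)"]
    for v in mesh.vertices:
        out.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    tri_region: dict[int, str] = {}
    for name, ids in mesh.regions.items():
        for i in ids:
            tri_region[int(i)] = name
    current = None
    for i, tri in enumerate(mesh.triangles):
        r = tri_region.get(i)
        if r != current:
            out.append(f"g {r}" if r is not None else "g")
            current = r
        out.append(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}")
    return "\n".join(out) + "\n"


@dataclass
class GeometryObject:
    """A mesh bound into a model: optional 3D compartment inside it and 2D
    compartment on its surface."""

    name: str
    mesh: TriangleMesh
    compartment_3d: Optional[str] = None
    compartment_2d: Optional[str] = None
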