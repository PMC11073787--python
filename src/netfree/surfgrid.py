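"""Barycentric surface tiling.

Each mesh triangle of area A is subdivided into n² congruent tiles with
n = ceil(sqrt(A·σ)) strips, σ being the requested grid density in
tiles/μm², so the realized density n²/A is always ≥ σ.  A tile holds at
most one surface molecule — the only volume exclusion in the simulator.

Tile addressing inside a triangle with corners (A, B, C): a point with
barycentric coordinates (b0, b1, b2) lies in the cell
(i, j, k) = (⌊n·b0⌋, ⌊n·b1⌋, ⌊n·b2⌋); i+j+k = n−1 for an upward tile and
n−2 for a downward one.  Tiles are numbered strip-major: row r (counted
from corner A) occupies local ids r² … (r+1)²−1, alternating up/down.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import TriangleMesh

__all__ = ["SurfaceGrid", "tile_surface"]


@dataclass
class SurfaceGrid:
    mesh: TriangleMesh
    density: float                     # requested σ, tiles/μm²
    subdivisions: np.ndarray           # per-triangle n
    offsets: np.ndarray                # per-triangle first global tile id
    n_tiles: int
    occupancy: dict[int, int] = field(default_factory=dict)  # tile -> mol id

    # -- id arithmetic ------------------------------------------------------

    def triangle_of_tile(self, tile: int) -> int:
        t = int(np.searchsorted(self.offsets, tile, side="right") - 1)
        return t

    def local_id(self, tri: int, i: int, j: int, k: int) -> int:
        n = int(self.subdivisions[tri])
        r = n - 1 - i
        if i + j + k == n - 1:       # upward tile
            return r * r + 2 * j
        if i + j + k == n - 2:       # downward tile
            return r * r + 2 * j + 1
        raise ValueError("bad tile coordinates")

    def tile_id(self, tri: int, i: int, j: int, k: int) -> int:
        return int(self.offsets[tri]) + self.local_id(tri, i, j, k)

    def coords_of(self, tile: int) -> tuple[int, int, int, int, bool]:
        """tile -> (triangle, i, j, k, is_up)."""
        tri = self.triangle_of_tile(tile)
        n = int(self.subdivisions[tri])
        local = tile - int(self.offsets[tri])
        r = int(np.floor(np.sqrt(local)))
        rem = local - r * r
        j = rem // 2
        up = rem % 2 == 0
        if up:
            i, k = n - 1 - r, r - j
        else:
            i, k = n - 1 - r, r - 1 - j
        return tri, i, j, k, up

    def tiles_of_triangle(self, tri: int) -> range:
        n = int(self.subdivisions[tri])
        start = int(self.offsets[tri])
        return range(start, start + n * n)

    # -- geometry -----------------------------------------------------------

    def tile_area(self, tri: int) -> float:
        n = int(self.subdivisions[tri])
        return float(self.mesh.areas()[tri]) / (n * n)

    def tile_at_barycentric(self, tri: int, bary) -> int:
        n = int(self.subdivisions[tri])
        b = np.clip(np.asarray(bary, dtype=float), 0.0, 1.0)
        ijk = np.minimum(np.floor(b * n).astype(int), n - 1)
        s = int(ijk.sum())
        # floors can land off the lattice when the point sits on a tile
        # boundary; nudge toward the nearest valid cell (s = n-1 up tile,
        # s = n-2 down tile)
        while s > n - 1:
            m = int(np.argmax(ijk - b * n))
            if ijk[m] == 0:
                m = int(np.argmax(ijk))
            ijk[m] -= 1
            s -= 1
        while s < n - 2:
            m = int(np.argmin(ijk - b * n))
            ijk[m] += 1
            s += 1
        i, j, k = (int(x) for x in ijk)
        return self.tile_id(tri, i, j, k)

    def tile_center(self, tile: int) -> np.ndarray:
        tri, i, j, k, up = self.coords_of(tile)
        n = int(self.subdivisions[tri])
        off = 1.0 / 3.0 if up else 2.0 / 3.0
        b = (np.array([i, j, k], dtype=float) + off) / n
        a, bb, c = (self.mesh.vertices[self.mesh.triangles[tri][m]]
                    for m in range(3))
        return b[0] * a + b[1] * bb + b[2] * c

    # -- adjacency ----------------------------------------------------------

    def tile_from_bary_fast(self, tri: int, b0: float, b1: float,
                            b2: float) -> int:
        """Scalar tile lookup for a point known to lie inside the
        triangle (barycentrics non-negative)."""
        n = int(self.subdivisions[tri])
        i = int(b0 * n)
        j = int(b1 * n)
        k = int(b2 * n)
        i = n - 1 if i >= n else i
        j = n - 1 if j >= n else j
        k = n - 1 if k >= n else k
        s = i + j + k
        while s > n - 1:
            # on a boundary: lower the coordinate with the largest excess
            ei, ej, ek = i - b0 * n, j - b1 * n, k - b2 * n
            if ei >= ej and ei >= ek and i > 0:
                i -= 1
            elif ej >= ek and j > 0:
                j -= 1
            else:
                k -= 1
            s -= 1
        while s < n - 2:
            ei, ej, ek = i - b0 * n, j - b1 * n, k - b2 * n
            if ei <= ej and ei <= ek:
                i += 1
            elif ej <= ek:
                j += 1
            else:
                k += 1
            s += 1
        r = n - 1 - i
        if s == n - 1:
            return int(self.offsets[tri]) + r * r + 2 * j
        return int(self.offsets[tri]) + r * r + 2 * j + 1

    def neighbors_cached(self, tile: int, region_key=None,
                         region: Optional[np.ndarray] = None) -> list[int]:
        cache = getattr(self, "_neighbor_cache", None)
        if cache is None:
            cache = {}
            self._neighbor_cache = cache
        key = (tile, region_key)
        hit = cache.get(key)
        if hit is None:
            hit = self.neighbors(tile, region)
            cache[key] = hit
        return hit

    def neighbors(self, tile: int,
                  region: Optional[np.ndarray] = None) -> list[int]:
        """Edge-sharing tiles, including across triangle boundaries.

        ``region`` restricts to a triangle subset: edges leading out of the
        region are treated as walls (no neighbor)."""
        tri, i, j, k, up = self.coords_of(tile)
        n = int(self.subdivisions[tri])
        out = []
        if up:
            for (di, dj, dk), edge in (((-1, 0, 0), 0), ((0, -1, 0), 1),
                                       ((0, 0, -1), 2)):
                ii, jj, kk = i + di, j + dj, k + dk
                if min(ii, jj, kk) >= 0:
                    out.append(self.tile_id(tri, ii, jj, kk))
                else:
                    out.extend(self._cross_edge_neighbors(
                        tri, edge, i, j, k, region))
        else:
            for (di, dj, dk) in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                out.append(self.tile_id(tri, i + di, j + dj, k + dk))
        return out

    def _edge_interval(self, tri: int, edge: int, i: int, j: int,
                       k: int) -> tuple[float, float]:
        """Parameter interval of an up boundary tile along the directed
        triangle edge.  edge 0 = BC (i=0), 1 = CA (j=0), 2 = AB (k=0)."""
        n = int(self.subdivisions[tri])
        if edge == 0:      # along B->C, parameter = b2
            lo = k / n
        elif edge == 1:    # along C->A, parameter = b0
            lo = i / n
        else:              # along A->B, parameter = b1
            lo = j / n
        return lo, lo + 1.0 / n

    def _directed_edge(self, tri: int, edge: int) -> tuple[int, int]:
        t = self.mesh.triangles[tri]
        if edge == 0:
            return int(t[1]), int(t[2])
        if edge == 1:
            return int(t[2]), int(t[0])
        return int(t[0]), int(t[1])

    def _edge_tiles(self, tri: int, edge: int):
        """All (tile id, lo, hi) boundary tiles of a triangle edge."""
        n = int(self.subdivisions[tri])
        out = []
        for m in range(n):
            if edge == 0:
                i, k = 0, m
                j = n - 1 - k
            elif edge == 1:
                j, i = 0, m
                k = n - 1 - i
            else:
                k, j = 0, m
                i = n - 1 - j
            lo, hi = self._edge_interval(tri, edge, i, j, k)
            out.append((self.tile_id(tri, i, j, k), lo, hi))
        return out

    def _cross_edge_neighbors(self, tri: int, edge: int, i: int, j: int,
                              k: int,
                              region: Optional[np.ndarray]) -> list[int]:
        a, b = self._directed_edge(tri, edge)
        partner = self._edge_partner.get((b, a))
        if partner is None:
            return []
        ptri, pedge = partner
        if region is not None and ptri not in set(int(x) for x in region):
            return []
        lo, hi = self._edge_interval(tri, edge, i, j, k)
        out = []
        for (tid, plo, phi) in self._edge_tiles(ptri, pedge):
            # partner edge runs b->a: flip parameter
            flo, fhi = 1.0 - phi, 1.0 - plo
            if min(hi, fhi) - max(lo, flo) > 1e-12:
                out.append(tid)
        return out

    def __post_init__(self):
        # directed edge (a, b) -> (triangle, local edge index)
        self._edge_partner: dict[tuple[int, int], tuple[int, int]] = {}
        for t in range(len(self.mesh.triangles)):
            for e in range(3):
                self._edge_partner[self._directed_edge(t, e)] = (t, e)

    # -- occupancy ----------------------------------------------------------

    def occupant(self, tile: int) -> Optional[int]:
        return self.occupancy.get(tile)

    def place(self, tile: int, mol_id: int) -> None:
        if tile in self.occupancy:
            raise ValueError(f"tile {tile} already occupied")
        self.occupancy[tile] = mol_id

    def vacate(self, tile: int) -> None:
        self.occupancy.pop(tile, None)

    def vacant_tiles(self, triangles: Optional[np.ndarray] = None
                     ) -> np.ndarray:
        tris = (range(len(self.mesh.triangles)) if triangles is None
                else triangles)
        out = []
        for t in tris:
            for tid in self.tiles_of_triangle(int(t)):
                if tid not in self.occupancy:
                    out.append(tid)
        return np.array(out, dtype=np.int64)

    def realized_density(self) -> float:
        return self.n_tiles / self.mesh.area()


def tile_surface(mesh: TriangleMesh, density: float) -> SurfaceGrid:
    """Tile a mesh at requested grid density σ (tiles/μm²)."""
    if density <= 0:
        raise ValueError("grid density must be positive")
    areas = mesh.areas()
    n = np.maximum(1, np.ceil(np.sqrt(areas * density))).astype(np.int64)
    counts = n * n
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return SurfaceGrid(mesh, density, n, offsets, int(counts.sum()))
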