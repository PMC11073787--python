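"""Spatial model objects: meshes bound to compartments, per-species wall
behavior, release sites, and callback registrations."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ..bngl.types import ComplexGraph
from ..geometry import TriangleMesh
from ..surfgrid import SurfaceGrid

__all__ = ["REFLECTIVE", "TRANSPARENT", "ABSORPTIVE", "SurfaceClassRule",
           "SpatialObject", "ReleaseSite", "CallbackRegistration",
           "SurfacePlacementError"]

REFLECTIVE = "reflective"
TRANSPARENT = "transparent"
ABSORPTIVE = "absorptive"


class SurfacePlacementError(RuntimeError):
    pass


@dataclass
class SurfaceClassRule:
    """Wall behavior for listed species (by elementary molecule name);
    ``species=None`` applies to all.  ``region=None`` covers the whole
    mesh.  Unlisted species on a compartment boundary default to
    reflective."""

    behavior: str
    species: Optional[Sequence[str]] = None
    region: Optional[str] = None

    def applies_to(self, molecule_names: set[str]) -> bool:
        if self.species is None:
            return True
        return bool(molecule_names & set(self.species))


@dataclass
class SpatialObject:
    """A triangulated mesh placed in the world.

    ``compartment_3d`` names the volume compartment inside the (closed)
    mesh; ``compartment_2d`` the membrane compartment on its surface.
    ``fences`` confines 2D diffusion of listed species (by elementary
    molecule name) to a named triangle region."""

    name: str
    mesh: TriangleMesh
    compartment_3d: Optional[str] = None
    compartment_2d: Optional[str] = None
    surface_classes: list[SurfaceClassRule] = field(default_factory=list)
    fences: dict[str, set[str]] = field(default_factory=dict)
    #: convex meshes with purely reflective behavior allow a fast path in
    #: the diffusion step (set by make_box-based constructors)
    convex: bool = False
    grid: Optional[SurfaceGrid] = None
    #: set automatically for axis-aligned boxes: (lo, hi, {(axis, side):
    #: triangle index array}) enabling analytic wall hits
    box_data: Optional[tuple] = None

    def detect_box(self) -> None:
        """Detect an axis-aligned box mesh and precompute face data."""
        verts = self.mesh.vertices
        lo, hi = self.mesh.bounds()
        onface = np.isclose(verts, lo) | np.isclose(verts, hi)
        if len(self.mesh.triangles) != 12 or not np.all(onface):
            return
        normals = self.mesh.normals()
        faces: dict[tuple[int, int], list[int]] = {}
        for t, n in enumerate(normals):
            ax = int(np.argmax(np.abs(n)))
            if abs(abs(n[ax]) - 1.0) > 1e-9:
                return
            side = 1 if n[ax] > 0 else 0
            faces.setdefault((ax, side), []).append(t)
        if sorted(faces) != [(a, s) for a in range(3) for s in (0, 1)]:
            return
        self.box_data = (lo, hi,
                         {k: np.array(v) for k, v in faces.items()})
        self.convex = True

    def behavior_for(self, molecule_names: set[str],
                     triangle: int) -> str:
        for rule in self.surface_classes:
            if rule.region is not None:
                region = set(int(x) for x in
                             self.mesh.region_triangles(rule.region))
                if triangle not in region:
                    continue
            if rule.applies_to(molecule_names):
                return rule.behavior
        return REFLECTIVE

    def reflective_only(self) -> bool:
        return all(r.behavior == REFLECTIVE for r in self.surface_classes)

    def allowed_triangles(self, molecule_names: set[str]
                          ) -> Optional[set[int]]:
        """Triangle set a confined surface species may walk on."""
        for region, names in self.fences.items():
            if molecule_names & names:
                return set(int(x) for x in
                           self.mesh.region_triangles(region))
        return None


@dataclass
class ReleaseSite:
    """Creation of molecules at a scheduled time.

    shape:
      * ``"volume"`` — uniform inside the object's mesh (``amount`` = count)
      * ``"surface_count"`` — ``amount`` molecules on vacant tiles of
        ``region`` (whole surface when None)
      * ``"surface_density"`` — ``amount`` in N/μm²; count = round(density
        × region area)
      * ``"points"`` — explicit coordinate list
    """

    name: str
    graph: ComplexGraph
    shape: str
    object_name: Optional[str] = None
    amount: float = 0.0
    region: Optional[str] = None
    points: Optional[np.ndarray] = None
    time: float = 0.0
    compartment: Optional[str] = None

    def __post_init__(self):
        if self.shape not in ("volume", "surface_count", "surface_density",
                              "points"):
            raise ValueError(f"unknown release shape {self.shape!r}")
        if self.amount < 0:
            raise ValueError("release amount must be non-negative")


@dataclass
class CallbackRegistration:
    """Synchronous simulation callbacks.

    kind ``"reaction"``: ``fn(time, rule_name, position, context)`` fires
    when any of ``rule_names`` occurs.  kind ``"wall_hit"``:
    ``fn(time, species_key, object_name, triangle, point, context)`` fires
    when a listed species hits the object (optionally a named region)."""

    kind: str
    fn: Callable
    context: object = None
    rule_names: Optional[Sequence[str]] = None
    object_name: Optional[str] = None
    region: Optional[str] = None
    species: Optional[Sequence[str]] = None
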