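"""Model assembly: BNGL import into a spatial model, compartment-to-mesh
mapping, observables, and BNGL export.

A :class:`ModelBundle` collects everything a run needs — chemistry
(species + rules), geometry objects, the initial state (releases), the
observables, and the simulation configuration — mirroring the
parameters / subsystem / geometry / instantiation / observables layout as
a convention, not a requirement.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .bngl.parser import parse_bngl
from .bngl.types import BnglError, BnglModel, Compartment, Observable
from .bngl.writer import write_bngl
from .geometry import GeometryObject, TriangleMesh, make_box
from .spatial.config import SimulationConfig
from .spatial.objects import ReleaseSite, SpatialObject
from .spatial.world import World

__all__ = ["ModelBundle", "load_bngl_into_model", "ALL_SECTIONS"]

ALL_SECTIONS = ("parameters", "molecule types", "compartments",
                "seed species", "observables", "reaction rules")

#: tolerated relative mismatch between a compartment's declared size and
#: the mesh mapped onto it
VOLUME_TOLERANCE = 0.01


@dataclass
class ModelBundle:
    model: BnglModel
    objects: list[SpatialObject] = field(default_factory=list)
    releases: list[ReleaseSite] = field(default_factory=list)
    observables: list[Observable] = field(default_factory=list)
    config: SimulationConfig = field(default_factory=SimulationConfig)
    #: spatial-only features that a BNGL export cannot express
    spatial_notes: list[str] = field(default_factory=list)

    def make_world(self, seed: Optional[int] = None,
                   iterations: Optional[int] = None) -> World:
        cfg = self.config
        if seed is not None or iterations is not None:
            kwargs = {f: getattr(cfg, f)
                      for f in cfg.__dataclass_fields__}  # type: ignore
            if seed is not None:
                kwargs["seed"] = seed
            if iterations is not None:
                kwargs["iterations"] = iterations
            cfg = SimulationConfig(**kwargs)
        return World(self.model, cfg, self.objects, self.releases,
                     self.observables or None)

    def export_bngl(self) -> tuple[str, list[str]]:
        """Best-effort BNGL text plus warnings for untranslatable spatial
        features (never silently dropped)."""
        warnings = list(self.spatial_notes)
        self.model.spatial_notes = warnings  # type: ignore[attr-defined]
        text = write_bngl(self.model)
        return text, warnings


def _compartment_volume_with_children(model: BnglModel,
                                      comp: Compartment) -> float:
    total = comp.size if comp.dimensionality == 3 else 0.0
    for child in model.compartments.values():
        if child.parent == comp.name:
            total += _compartment_volume_with_children(model, child)
    return total


def _auto_geometry(model: BnglModel) -> list[SpatialObject]:
    """One axis-aligned box per 3D compartment, nested per the hierarchy,
    sized so each box's enclosed volume matches the compartment plus its
    descendants."""
    objects = []
    for comp in model.compartments.values():
        if comp.dimensionality != 3:
            continue
        total = _compartment_volume_with_children(model, comp)
        side = total ** (1.0 / 3.0)
        mesh = make_box((0.0, 0.0, 0.0), (side, side, side))
        membrane = None
        if comp.parent is not None:
            membrane = comp.parent  # 2D parent compartment
        obj = SpatialObject(name=f"box_{comp.name}", mesh=mesh,
                            compartment_3d=comp.name,
                            compartment_2d=membrane, convex=True)
        objects.append(obj)
    return objects


def _check_mesh_volume(comp: Compartment, mesh: TriangleMesh) -> None:
    if comp.dimensionality == 3:
        vol = mesh.volume()
        if not math.isclose(vol, comp.size, rel_tol=VOLUME_TOLERANCE):
            raise BnglError(
                f"mesh mapped to compartment {comp.name} encloses "
                f"{vol:.6g} μm³ but the compartment declares "
                f"{comp.size:.6g} μm³ (>1% mismatch)")
    else:
        area = mesh.area()
        if not math.isclose(area, comp.size, rel_tol=VOLUME_TOLERANCE):
            raise BnglError(
                f"mesh mapped to membrane {comp.name} has area "
                f"{area:.6g} μm² but the compartment declares "
                f"{comp.size:.6g} μm² (>1% mismatch)")


def load_bngl_into_model(source: str, sections: Sequence[str] | str = "all",
                         compartment_meshes: Optional[dict] = None,
                         base: Optional[ModelBundle] = None,
                         config: Optional[SimulationConfig] = None
                         ) -> ModelBundle:
    """Build (or extend) a runnable spatial model from BNGL text or path.

    ``sections`` selects which parts to import (``"all"`` or a subset of
    :data:`ALL_SECTIONS`).  ``compartment_meshes`` maps 3D compartment
    names to :class:`TriangleMesh`/``GeometryObject`` replacing the
    auto-generated box; mesh volume must match the declared compartment
    size within 1%."""
    if "\n" not in source:
        with open(source) as fh:
            source = fh.read()
    parsed = parse_bngl(source)
    if sections == "all":
        wanted = set(ALL_SECTIONS)
    else:
        wanted = set(sections)
        unknown = wanted - set(ALL_SECTIONS)
        if unknown:
            raise BnglError(f"unknown sections {sorted(unknown)}")

    if base is None:
        bundle = ModelBundle(BnglModel(),
                             config=config or SimulationConfig())
    else:
        bundle = base
        if config is not None:
            bundle.config = config
    model = bundle.model

    if "parameters" in wanted:
        model.parameters.update(parsed.parameters)
    if "molecule types" in wanted:
        model.molecule_types.update(parsed.molecule_types)
    if "compartments" in wanted:
        model.compartments.update(parsed.compartments)
    if "observables" in wanted:
        model.observables.extend(parsed.observables)
        bundle.observables.extend(parsed.observables)
    if "reaction rules" in wanted:
        model.rules.extend(parsed.rules)
    if "seed species" in wanted:
        model.seed_species.extend(parsed.seed_species)

    # geometry: meshes for compartments (auto boxes unless replaced)
    if "compartments" in wanted and model.compartments and \
            not bundle.objects:
        auto = _auto_geometry(model)
        compartment_meshes = compartment_meshes or {}
        for obj in auto:
            replacement = compartment_meshes.get(obj.compartment_3d)
            if replacement is not None:
                if isinstance(replacement, GeometryObject):
                    mesh = replacement.mesh
                else:
                    mesh = replacement
                _check_mesh_volume(
                    model.compartments[obj.compartment_3d], mesh)
                obj = SpatialObject(name=obj.name, mesh=mesh,
                                    compartment_3d=obj.compartment_3d,
                                    compartment_2d=obj.compartment_2d)
                obj.detect_box()
            bundle.objects.append(obj)
    elif not model.compartments and not bundle.objects and \
            "seed species" in wanted and parsed.seed_species:
        # compartment-free model: a unit box keeps releases bounded
        bundle.objects.append(SpatialObject(
            "box_world", make_box((0, 0, 0), (1.0, 1.0, 1.0)), convex=True))
        bundle.spatial_notes.append(
            "auto-generated 1 μm³ bounding box (model declares no "
            "compartments)")

    if "seed species" in wanted:
        _seed_releases(bundle, parsed)
    return bundle


def _seed_releases(bundle: ModelBundle, parsed: BnglModel) -> None:
    model = bundle.model
    by_3d = {o.compartment_3d: o for o in bundle.objects
             if o.compartment_3d}
    by_2d = {o.compartment_2d: o for o in bundle.objects
             if o.compartment_2d}
    default_obj = bundle.objects[0] if bundle.objects else None
    for i, ss in enumerate(parsed.seed_species):
        comp = ss.graph.compartment
        is_surface = any(model.molecule_types[m.name].is_surface
                         for m in ss.graph.molecules)
        if is_surface:
            obj = by_2d.get(comp) if comp else default_obj
            if obj is None:
                raise BnglError(
                    f"seed species {i}: no membrane object for "
                    f"compartment {comp!r}")
            bundle.releases.append(ReleaseSite(
                name=f"seed_{i}", graph=ss.graph, shape="surface_count",
                object_name=obj.name, amount=ss.count,
                compartment=comp))
        else:
            obj = by_3d.get(comp) if comp else default_obj
            if obj is None:
                raise BnglError(
                    f"seed species {i}: no volume object for "
                    f"compartment {comp!r}")
            bundle.releases.append(ReleaseSite(
                name=f"seed_{i}", graph=ss.graph, shape="volume",
                object_name=obj.name, amount=ss.count,
                compartment=comp))
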