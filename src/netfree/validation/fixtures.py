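"""Fixture models for validation: each couples a BNGL file from
``netfree.fixtures`` with geometry and run configuration and builds a
ready-to-run world."""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional

import numpy as np

from ..bngl.parser import parse_bngl, parse_complex
from ..geometry import make_box
from ..model import ModelBundle, load_bngl_into_model
from ..spatial.config import SimulationConfig
from ..spatial.objects import (TRANSPARENT, ReleaseSite, SpatialObject,
                               SurfaceClassRule)
from ..spatial.world import World
from .clock import ClockParameters, HybridClockRun

__all__ = ["FixtureModel", "get_fixture", "fixture_bngl", "FIXTURES"]


def fixture_bngl(name: str) -> str:
    """BNGL source text of a named fixture file."""
    return (resources.files("netfree.fixtures") / f"{name}.bngl"
            ).read_text()


@dataclass
class FixtureModel:
    name: str
    bngl_name: str
    config: dict = field(default_factory=dict)
    builder: Optional[Callable] = None
    text_fn: Optional[Callable[[], str]] = None

    @property
    def bngl_text(self) -> str:
        if self.text_fn is not None:
            return self.text_fn()
        return fixture_bngl(self.bngl_name)

    def model(self):
        return parse_bngl(self.bngl_text)

    def make_config(self, seed: int,
                    iterations: Optional[int] = None) -> SimulationConfig:
        cfg = dict(self.config)
        cfg["seed"] = seed
        if iterations is not None:
            cfg["iterations"] = iterations
        return SimulationConfig.from_dict(cfg)

    def build(self, seed: int, iterations: Optional[int] = None):
        """A runnable world (or hybrid driver) for one seed."""
        cfg = self.make_config(seed, iterations)
        if self.builder is not None:
            return self.builder(self, cfg)
        bundle = load_bngl_into_model(self.bngl_text, "all", config=cfg)
        return bundle.make_world()


# ---------------------------------------------------------------------------
# special builders
# ---------------------------------------------------------------------------

_SURFACE_REGION = "-z"
_MEMBRANE_SPECIES = {"M"}


def _membrane_builder(fx: FixtureModel, cfg: SimulationConfig) -> World:
    mesh = make_box((0.0, 0.0, 0.0), (0.47, 0.47, 0.5))
    bundle = load_bngl_into_model(fx.bngl_text, "all",
                                  compartment_meshes={"CP": mesh},
                                  config=cfg)
    for obj in bundle.objects:
        obj.fences[_SURFACE_REGION] = set(_MEMBRANE_SPECIES)
    for rel in bundle.releases:
        if rel.shape == "surface_count":
            rel.region = _SURFACE_REGION
    return bundle.make_world()


def _hybrid_builder(fx: FixtureModel, cfg: SimulationConfig):
    bundle = load_bngl_into_model(fx.bngl_text, "all", config=cfg)
    world = bundle.make_world()
    params = ClockParameters.from_model(bundle.model, cfg.time_step)
    return HybridClockRun(world, params, cfg.iterations)


def _psd_spine_builder(fx: FixtureModel, cfg: SimulationConfig) -> World:
    """Dendritic-spine-head geometry: a 0.5³ μm box containing a
    0.05 × 0.4 × 0.4 μm slab (the postsynaptic density) near the top
    face, reflective to kinase K but transparent to calcium."""
    model = parse_bngl(fx.bngl_text)
    spine = SpatialObject("spine", make_box((0, 0, 0), (0.5, 0.5, 0.5)),
                          convex=True)
    psd = SpatialObject(
        "psd", make_box((0.2, 0.0, 0.0), (0.05, 0.4, 0.4)),
        surface_classes=[SurfaceClassRule(TRANSPARENT, species=["Ca"])])
    releases = [
        ReleaseSite("k_psd", parse_complex("K(c)"), "volume",
                    object_name="psd", amount=40),
        ReleaseSite("k_out", parse_complex("K(c)"), "volume",
                    object_name="spine", amount=40),
        ReleaseSite("ca", parse_complex("Ca(k)"), "volume",
                    object_name="spine", amount=200),
    ]
    return World(model, cfg, [spine, psd], releases)


def _camkii_bngl() -> str:
    """A dodecameric ring of identical kinase subunits: a combinatorially
    explosive molecule type (2¹² ring states before symmetry) exercised
    network-free.  SYNTHETIC structural fixture."""
    n = 12
    mols = []
    for i in range(n):
        mols.append(f"CK(l!{i + 1},r!{(i + 1) % n + 1},T~U)")
    ring = ".".join(mols)
    return f"""
begin parameters
  k_base 500
  k_spread 20000
  k_deph 2000
  MCELL_DIFFUSION_CONSTANT_3D_CK 1e-6
end parameters
begin molecule types
  CK(l,r,T~U~P)
end molecule types
begin compartments
  CP 3 0.015625
end compartments
begin seed species
  @CP:{ring} 20
end seed species
begin observables
  Molecules phosphorylated CK(T~P)
end observables
begin reaction rules
  basal:  CK(T~U) -> CK(T~P) k_base
  spread: CK(T~U,r!1).CK(T~P,l!1) -> CK(T~P,r!1).CK(T~P,l!1) k_spread
  deph:   CK(T~P) -> CK(T~U) k_deph
end reaction rules
"""


def _camkii_builder(fx: FixtureModel, cfg: SimulationConfig) -> World:
    bundle = load_bngl_into_model(fx.bngl_text, "all", config=cfg)
    return bundle.make_world()


FIXTURES: dict[str, FixtureModel] = {
    "wellmixed_abc": FixtureModel(
        "wellmixed_abc", "wellmixed_abc",
        config=dict(time_step=1e-6, iterations=800)),
    "snare": FixtureModel(
        "snare", "snare",
        config=dict(time_step=1e-6, iterations=1000)),
    "membrane_localization": FixtureModel(
        "membrane_localization", "membrane_localization",
        config=dict(time_step=1e-6, iterations=1500, output_cadence=50),
        builder=_membrane_builder),
    "autophosphorylation": FixtureModel(
        "autophosphorylation", "autophosphorylation",
        config=dict(time_step=2e-6, iterations=15000,
                    interaction_radius=0.1, output_cadence=25)),
    "psd_spine": FixtureModel(
        "psd_spine", "psd_spine",
        config=dict(time_step=1e-6, iterations=200),
        builder=_psd_spine_builder),
    "clock_particle": FixtureModel(
        "clock_particle", "clock_particle",
        config=dict(time_step=4e-6, iterations=4500,
                    interaction_radius=0.1, output_cadence=10)),
    "clock_hybrid": FixtureModel(
        "clock_hybrid", "clock_hybrid",
        config=dict(time_step=4e-6, iterations=4500,
                    interaction_radius=0.1, output_cadence=10),
        builder=_hybrid_builder),
    "camkii_ring": FixtureModel(
        "camkii_ring", "",
        config=dict(time_step=1e-6, iterations=300),
        builder=_camkii_builder, text_fn=_camkii_bngl),
}


def get_fixture(name: str) -> FixtureModel:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have "
                       f"{sorted(FIXTURES)}")
    return FIXTURES[name]
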