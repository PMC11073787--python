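"""Network-free species/reaction caches and bounded network expansion.

Species and the reactions applicable to them are created on demand when a
pair of reactants first meets (direct rule evaluation), cached, and
periodically evicted once no instances of a species remain.  The full
network is never needed at simulation time; :func:`expand_network` exists
as a bounded utility for validation against well-mixed solvers.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

from ..bngl.canonical import canonical_form
from ..bngl.types import (BnglError, BnglModel, ComplexGraph, MoleculeType,
                          ReactionRule)
from .compartments import (resolve_compartment_classes,
                           uses_compartment_classes, validate_class_usage)
from .diffusion import derive_diffusion_constant
from .matching import Embedding, match_pattern
from .rewrite import RuleActions, apply_rule, interpret_rule

__all__ = ["Species", "Pathway", "RxnClass", "RuleEngine",
           "ConcreteReaction", "NetworkExpansion", "expand_network",
           "BoundedExpansionError", "write_net"]


class BoundedExpansionError(BnglError):
    """Species or reaction limit exceeded during network expansion."""


@dataclass
class Species:
    """A concrete chemical species: canonical graph + compartment."""

    label: str
    graph: ComplexGraph
    compartment: Optional[str]
    key: str
    is_surface: bool = False
    diffusion_constant: Optional[float] = None  # cm²/s, derived lazily
    count: int = 0  # live instances in the world

    def __hash__(self):
        return hash(self.key)


@dataclass(frozen=True)
class Pathway:
    """One concrete reaction channel of a rule for fixed reactant species.

    ``reactant_keys`` is ordered to match ``rule.reactants``; each
    automorphism-distinct embedding combination is its own pathway at the
    rule's full rate constant (direct-evaluation convention, no symmetry
    division)."""

    rule_name: str
    rate: float
    reactant_keys: tuple[str, ...]
    product_keys: tuple[str, ...]


@dataclass
class RxnClass:
    """All cached pathways for a reactant species (pair)."""

    reactant_keys: tuple[str, ...]
    pathways: list[Pathway] = field(default_factory=list)


def _species_compartment(graph: ComplexGraph,
                         types: dict[str, MoleculeType]) -> Optional[str]:
    return graph.compartment


class RuleEngine:
    """Model-wide rule evaluation with species and reaction caches."""

    def __init__(self, model: BnglModel):
        self.model = model
        self.types = model.molecule_types
        self.rules: list[ReactionRule] = list(model.rules)
        for r in self.rules:
            validate_class_usage(r, self.types)
        self._actions: dict[int, RuleActions] = {}
        self.species: dict[str, Species] = {}
        self._unimol: dict[str, RxnClass] = {}
        self._bimol: dict[tuple[str, str], RxnClass] = {}

    # -- species interning --------------------------------------------------

    def intern_species(self, graph: ComplexGraph,
                       compartment: Optional[str] = None) -> Species:
        comp = compartment if compartment is not None else graph.compartment
        label = canonical_form(graph, self.types)
        key = f"{label}@{comp}" if comp else label
        sp = self.species.get(key)
        if sp is None:
            g = graph.copy()
            g.compartment = comp
            is_surface = any(self.types[m.name].is_surface
                             for m in g.molecules)
            sp = Species(label, g, comp, key, is_surface=is_surface)
            self.species[key] = sp
        return sp

    def ensure_species(self, key: str) -> Species:
        """Species for a cache key, reconstituting it from the canonical
        label if cache cleanup evicted the entry."""
        sp = self.species.get(key)
        if sp is not None:
            return sp
        from ..bngl.parser import parse_complex
        label, sep, comp = key.rpartition("@")
        if not sep:
            label, comp = key, None
        return self.intern_species(parse_complex(label), comp or None)

    def diffusion_of(self, sp: Species) -> float:
        if sp.diffusion_constant is None:
            d, surf = derive_diffusion_constant(sp.graph, self.types)
            sp.diffusion_constant = d
            sp.is_surface = surf
        return sp.diffusion_constant

    # -- rule machinery -----------------------------------------------------

    def _rule_actions(self, ri: int, rule: ReactionRule) -> RuleActions:
        if ri not in self._actions:
            self._actions[ri] = interpret_rule(rule, self.types)
        return self._actions[ri]

    def _concrete_rule(self, rule: ReactionRule,
                       species: list[Species]) -> Optional[ReactionRule]:
        """Resolve @IN/@OUT for this reactant set (None if unresolvable)."""
        if not uses_compartment_classes(rule):
            return rule
        surf = [sp for sp in species if sp.is_surface]
        if len(surf) != 1 or surf[0].compartment is None:
            return None
        try:
            return resolve_compartment_classes(rule, surf[0].compartment,
                                               self.model)
        except BnglError:
            return None

    @staticmethod
    def _compartment_ok(pattern: ComplexGraph, sp: Species) -> bool:
        if pattern.compartment is None:
            return True
        return pattern.compartment == sp.compartment

    def _product_species(self, rule: ReactionRule, actions: RuleActions,
                         species: list[Species],
                         embs: list[Embedding]) -> tuple[str, ...]:
        prods = apply_rule(rule, [sp.graph for sp in species], embs,
                           self.types, actions)
        keys = []
        for pc in prods:
            comp = self._product_compartment(pc, species)
            keys.append(self.intern_species(pc.graph, comp).key)
        return tuple(sorted(keys))

    def _product_compartment(self, pc, species: list[Species]
                             ) -> Optional[str]:
        """Compartment of one product complex.

        A surface product lives in the membrane compartment of its surface
        reactant.  A volume product takes, in order: an explicit product
        annotation, the compartment of a volume reactant it descends from,
        the compartment inside the membrane it was released from (a
        molecule unbinding from a membrane complex enters the enclosed
        volume), or finally the first reactant's compartment."""
        product_is_surface = any(self.types[m.name].is_surface
                                 for m in pc.graph.molecules)
        surface_comp = None
        inherited_volume = None
        explicit = None
        for entry in pc.provenance:
            if entry[0] == "old":
                sp = species[entry[1]]
                if sp.is_surface:
                    if sp.compartment is not None:
                        surface_comp = sp.compartment
                elif inherited_volume is None:
                    inherited_volume = sp.compartment
            else:  # ("new", pattern compartment)
                if entry[1] is not None and explicit is None:
                    explicit = entry[1]
        if product_is_surface:
            if surface_comp is not None:
                return surface_comp
            for sp in species:
                if sp.is_surface and sp.compartment is not None:
                    return sp.compartment
            return explicit
        if explicit is not None:
            return explicit
        if inherited_volume is not None:
            return inherited_volume
        membrane = surface_comp or next(
            (sp.compartment for sp in species
             if sp.is_surface and sp.compartment is not None), None)
        if membrane is not None:
            inner = self.model.inner_compartment(membrane)
            if inner is not None:
                return inner
        return species[0].compartment if species else None

    def _pathways_for(self, species: list[Species]) -> list[Pathway]:
        """Direct rule evaluation for a concrete reactant set."""
        arity = len(species)
        out: list[Pathway] = []
        for ri, rule in enumerate(self.rules):
            if rule.arity() != arity:
                continue
            concrete = self._concrete_rule(rule, species)
            if concrete is None:
                continue
            actions = self._rule_actions(ri, rule)
            orderings: Iterable[tuple[Species, ...]]
            if arity == 1:
                orderings = [(species[0],)]
            elif species[0].key == species[1].key:
                orderings = [(species[0], species[1])]
            else:
                orderings = [(species[0], species[1]),
                             (species[1], species[0])]
            for ordered in orderings:
                if not all(self._compartment_ok(p, sp) for p, sp in
                           zip(concrete.reactants, ordered)):
                    continue
                emb_lists = [match_pattern(p, sp.graph)
                             for p, sp in zip(concrete.reactants, ordered)]
                if not all(emb_lists):
                    continue
                for combo in itertools.product(*emb_lists):
                    product_keys = self._product_species(
                        concrete, actions, list(ordered), list(combo))
                    out.append(Pathway(
                        rule_name=rule.name, rate=rule.rate,
                        reactant_keys=tuple(sp.key for sp in ordered),
                        product_keys=product_keys))
        return out

    # -- cache access -------------------------------------------------------

    def lookup_unimolecular(self, sp: Species) -> RxnClass:
        rc = self._unimol.get(sp.key)
        if rc is None:
            rc = RxnClass((sp.key,), self._pathways_for([sp]))
            self._unimol[sp.key] = rc
        return rc

    def lookup_or_expand(self, sp1: Species, sp2: Species) -> RxnClass:
        """Pathways for an unordered species pair; cached after first call."""
        key = tuple(sorted((sp1.key, sp2.key)))
        rc = self._bimol.get(key)
        if rc is None:
            a, b = ((sp1, sp2) if (sp1.key, sp2.key) == key
                    else (sp2, sp1))
            rc = RxnClass(key, self._pathways_for([a, b]))
            self._bimol[key] = rc
        return rc

    def cleanup_caches(self) -> int:
        """Evict zero-instance species and reaction classes that reference
        them; returns the number of evicted objects."""
        dead = {k for k, sp in self.species.items() if sp.count == 0}
        if not dead:
            return 0
        evicted = 0
        for k in dead:
            del self.species[k]
            evicted += 1
        for k in [k for k in self._unimol if k in dead]:
            del self._unimol[k]
            evicted += 1
        for pair in [p for p in self._bimol
                     if p[0] in dead or p[1] in dead]:
            del self._bimol[pair]
            evicted += 1
        return evicted


# ---------------------------------------------------------------------------
# bounded full expansion (validation utility)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcreteReaction:
    """A fully concrete reaction, merged over contributing rules.

    ``rate`` is the summed per-instance (pair) rate constant: one rule
    contributes its rate once per automorphism-distinct embedding, and
    rules producing the identical (reactants, products) transition add up,
    exactly as a mass-action network requires."""

    reactants: tuple[str, ...]  # sorted species keys
    products: tuple[str, ...]   # sorted species keys
    rate: float
    rules: tuple[str, ...]


@dataclass
class NetworkExpansion:
    engine: RuleEngine
    species: list[Species]
    reactions: list[ConcreteReaction]

    def species_keys(self) -> list[str]:
        return [sp.key for sp in self.species]


def expand_network(model: BnglModel, max_species: int = 5000,
                   max_reactions: int = 50000) -> NetworkExpansion:
    """Fixed-point expansion from the seed species.

    Raises :class:`BoundedExpansionError` when the limits are exceeded
    (rule-based models may describe unbounded networks; the spatial engine
    never needs this expansion)."""
    engine = RuleEngine(model)
    seeds = [engine.intern_species(ss.graph) for ss in model.seed_species]
    known: dict[str, Species] = {}
    frontier: list[Species] = []
    for sp in sorted(seeds, key=lambda s: s.key):
        if sp.key not in known:
            known[sp.key] = sp
            frontier.append(sp)

    merged: dict[tuple, dict] = {}

    def note_pathways(pathways: list[Pathway]) -> list[str]:
        new_keys = []
        for pw in pathways:
            rkey = tuple(sorted(pw.reactant_keys))
            entry_key = (rkey, pw.product_keys)
            entry = merged.get(entry_key)
            if entry is None:
                merged[entry_key] = {"rate": pw.rate,
                                     "rules": {pw.rule_name}}
                if len(merged) > max_reactions:
                    raise BoundedExpansionError(
                        f"reaction limit {max_reactions} exceeded")
            else:
                entry["rate"] += pw.rate
                entry["rules"].add(pw.rule_name)
            for k in pw.product_keys:
                if k not in known:
                    sp = engine.species[k]
                    known[k] = sp
                    frontier.append(sp)
                    new_keys.append(k)
                    if len(known) > max_species:
                        raise BoundedExpansionError(
                            f"species limit {max_species} exceeded")
        return new_keys

    processed: set[str] = set()
    visited_classes: set[tuple] = set()
    while frontier:
        sp = frontier.pop(0)
        if sp.key in processed:
            continue
        processed.add(sp.key)
        note_pathways(engine.lookup_unimolecular(sp).pathways)
        for other_key in sorted(known):
            other = known[other_key]
            pair = tuple(sorted((sp.key, other_key)))
            if pair in visited_classes:
                continue  # each reaction class contributes exactly once
            visited_classes.add(pair)
            note_pathways(engine.lookup_or_expand(sp, other).pathways)

    species = [known[k] for k in sorted(known)]
    reactions = [ConcreteReaction(rk, pk, v["rate"],
                                  tuple(sorted(v["rules"])))
                 for (rk, pk), v in sorted(merged.items())]
    return NetworkExpansion(engine, species, reactions)


def write_net(expansion: NetworkExpansion) -> str:
    """Plain-text reaction list (species index table + reaction triples)."""
    idx = {sp.key: i + 1 for i, sp in enumerate(expansion.species)}
    out = ["begin species"]
    for sp in expansion.species:
        out.append(f"  {idx[sp.key]} {sp.key}")
    out.append("end species")
    out.append("begin reactions")
    for rx in expansion.reactions:
        lhs = ",".join(str(idx[k]) for k in rx.reactants)
        rhs = ",".join(str(idx[k]) for k in rx.products)
        out.append(f"  {lhs} {rhs} {rx.rate!r} # {'+'.join(rx.rules)}")
    out.append("end reactions")
    return "\n".join(out) + "\n"
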