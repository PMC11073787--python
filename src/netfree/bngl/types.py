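"""Core graph types for rule-based (BNGL) chemistry.

A *complex* is an undirected bipartite graph of elementary molecules and
their components (binding sites / state variables).  The same structure
doubles as a fully specified *species* (connected, no wildcards, every
stateful component has a state) and as a *pattern* (partially specified,
used by rules and observables).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "ANY_BOND",
    "EXISTS_BOND",
    "ComponentType",
    "MoleculeType",
    "ComponentInstance",
    "MoleculeInstance",
    "ComplexGraph",
    "Compartment",
    "ReactionRule",
    "SeedSpecies",
    "Observable",
    "BnglModel",
    "BnglError",
    "NotASpeciesError",
]

#: pattern wildcard: the component may be bound or unbound (``!?``)
ANY_BOND = "?"
#: pattern wildcard: the component must be bound to something (``!+``)
EXISTS_BOND = "+"

#: compartment classes resolved at simulation time for volume+surface rules
IN_CLASS = "IN"
OUT_CLASS = "OUT"


class BnglError(ValueError):
    """Model-level error (syntax, undeclared identifier, invalid graph)."""


class NotASpeciesError(BnglError):
    """A pattern (wildcards / unset states / disconnected) used as a species."""


@dataclass(frozen=True)
class ComponentType:
    name: str
    states: tuple[str, ...] = ()

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise BnglError(f"duplicate state names in component {self.name}")


@dataclass
class MoleculeType:
    """An elementary molecule type (BioNetGen 'molecule type').

    Exactly one of ``diffusion_constant_3d`` / ``diffusion_constant_2d``
    should be set before spatial simulation; a 2D constant marks the type as
    a surface molecule.  Units: cm^2/s.
    """

    name: str
    components: tuple[ComponentType, ...] = ()
    diffusion_constant_3d: Optional[float] = None
    diffusion_constant_2d: Optional[float] = None

    def __post_init__(self):
        by_name: dict[str, tuple[str, ...]] = {}
        for c in self.components:
            if c.name in by_name and by_name[c.name] != c.states:
                raise BnglError(
                    f"duplicate component {c.name} of {self.name} "
                    "declared with different state sets"
                )
            by_name[c.name] = c.states
        for d in (self.diffusion_constant_3d, self.diffusion_constant_2d):
            if d is not None and d < 0:
                raise BnglError(f"negative diffusion constant for {self.name}")

    @property
    def is_surface(self) -> bool:
        return self.diffusion_constant_2d is not None

    @property
    def diffusion_constant(self) -> Optional[float]:
        if self.diffusion_constant_2d is not None:
            return self.diffusion_constant_2d
        return self.diffusion_constant_3d

    def component_names(self) -> list[str]:
        return [c.name for c in self.components]


@dataclass
class ComponentInstance:
    """One component of a molecule instance.

    ``bond`` is ``None`` (unbound), an integer bond id local to the complex
    expression, or one of the pattern wildcards :data:`ANY_BOND` /
    :data:`EXISTS_BOND`.
    """

    name: str
    state: Optional[str] = None
    bond: object = None  # None | int | "?" | "+"

    def is_wild(self) -> bool:
        return self.bond in (ANY_BOND, EXISTS_BOND)

    def copy(self) -> "ComponentInstance":
        return ComponentInstance(self.name, self.state, self.bond)


@dataclass
class MoleculeInstance:
    name: str
    components: list[ComponentInstance] = field(default_factory=list)

    def copy(self) -> "MoleculeInstance":
        return MoleculeInstance(self.name, [c.copy() for c in self.components])


class ComplexGraph:
    """A complex: molecules + components with states and bonds.

    Bonds are encoded through shared integer bond ids on component
    instances; ids are local to this graph.  ``compartment`` is an optional
    compartment name or one of the classes ``"IN"`` / ``"OUT"``.
    """

    def __init__(self, molecules: Iterable[MoleculeInstance],
                 compartment: Optional[str] = None):
        self.molecules: list[MoleculeInstance] = list(molecules)
        self.compartment = compartment
        self._validate_bonds()

    # -- construction helpers ------------------------------------------------

    def copy(self) -> "ComplexGraph":
        return ComplexGraph([m.copy() for m in self.molecules], self.compartment)

    def _validate_bonds(self):
        seen: dict[int, int] = {}
        for m in self.molecules:
            for c in m.components:
                if isinstance(c.bond, int):
                    seen[c.bond] = seen.get(c.bond, 0) + 1
        for bid, n in seen.items():
            if n != 2:
                raise BnglError(f"bond !{bid} has {n} endpoints (need 2)")

    # -- bond topology -------------------------------------------------------

    def bond_map(self) -> dict[int, list[tuple[int, int]]]:
        """bond id -> the two (molecule index, component index) endpoints."""
        out: dict[int, list[tuple[int, int]]] = {}
        for mi, m in enumerate(self.molecules):
            for ci, c in enumerate(m.components):
                if isinstance(c.bond, int):
                    out.setdefault(c.bond, []).append((mi, ci))
        return out

    def partner_of(self) -> dict[tuple[int, int], tuple[int, int]]:
        """(mol, comp) -> bonded (mol, comp) for every bound component."""
        out = {}
        for ends in self.bond_map().values():
            (a, b) = ends
            out[a] = b
            out[b] = a
        return out

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.molecules))}
        for ends in self.bond_map().values():
            (ai, _), (bi, _) = ends
            adj[ai].add(bi)
            adj[bi].add(ai)
        return adj

    def connected_components(self) -> list[list[int]]:
        adj = self.adjacency()
        seen: set[int] = set()
        comps = []
        for start in range(len(self.molecules)):
            if start in seen:
                continue
            stack, group = [start], []
            seen.add(start)
            while stack:
                i = stack.pop()
                group.append(i)
                for j in adj[i]:
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            comps.append(sorted(group))
        return comps

    def is_connected(self) -> bool:
        return len(self.connected_components()) <= 1

    def subgraph(self, mol_indices: list[int]) -> "ComplexGraph":
        """Extract the induced subgraph (bond ids renumbered)."""
        idx = {mi: k for k, mi in enumerate(mol_indices)}
        mols = [self.molecules[mi].copy() for mi in mol_indices]
        # renumber bonds; drop bonds leaving the subset (caller's duty to avoid)
        remap: dict[int, int] = {}
        for m in mols:
            for c in m.components:
                if isinstance(c.bond, int):
                    if c.bond not in remap:
                        remap[c.bond] = len(remap) + 1
                    c.bond = remap[c.bond]
        g = ComplexGraph.__new__(ComplexGraph)
        g.molecules = mols
        g.compartment = self.compartment
        g._validate_bonds()
        del idx
        return g

    # -- species checks ------------------------------------------------------

    def check_species(self, types: dict[str, MoleculeType]) -> None:
        """Raise :class:`NotASpeciesError` unless this graph is a species."""
        if not self.molecules:
            raise NotASpeciesError("empty graph is not a species")
        if not self.is_connected():
            raise NotASpeciesError("species graph must be connected")
        if self.compartment in (IN_CLASS, OUT_CLASS):
            raise NotASpeciesError("species cannot carry an @IN/@OUT class")
        for m in self.molecules:
            mt = types.get(m.name)
            if mt is None:
                raise BnglError(f"undeclared molecule type {m.name}")
            listed = [c.name for c in m.components]
            if sorted(listed) != sorted(mt.component_names()):
                raise NotASpeciesError(
                    f"species molecule {m.name} must list all components"
                )
            states = {c.name: c.states for c in mt.components}
            for c in m.components:
                if c.is_wild():
                    raise NotASpeciesError(
                        f"wildcard bond on {m.name}({c.name}) in species"
                    )
                allowed = states[c.name]
                if allowed and c.state is None:
                    raise NotASpeciesError(
                        f"unset state on {m.name}({c.name}) in species"
                    )
                if c.state is not None and allowed and c.state not in allowed:
                    raise BnglError(
                        f"state {c.state} not allowed for {m.name}({c.name})"
                    )

    def is_species(self, types: dict[str, MoleculeType]) -> bool:
        try:
            self.check_species(types)
            return True
        except BnglError:
            return False

    # -- misc ----------------------------------------------------------------

    def molecule_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.molecules:
            out[m.name] = out.get(m.name, 0) + 1
        return out

    def __repr__(self):
        from .writer import format_complex
        return f"ComplexGraph({format_complex(self)!r})"


@dataclass
class Compartment:
    """A BNGL compartment: 3D volume (μm³) or 2D membrane (μm²)."""

    name: str
    dimensionality: int
    size: float
    parent: Optional[str] = None

    def __post_init__(self):
        if self.dimensionality not in (2, 3):
            raise BnglError(f"compartment {self.name}: dimension must be 2 or 3")
        if self.size <= 0:
            raise BnglError(f"compartment {self.name}: size must be positive")


@dataclass
class ReactionRule:
    """A graph-transformation rule.

    Reversible rules are split into two unidirectional rules at parse time;
    ``name`` then carries ``_rev`` for the backward direction.
    """

    name: str
    reactants: list[ComplexGraph]
    products: list[ComplexGraph]
    rate: float

    def __post_init__(self):
        if not (1 <= len(self.reactants) <= 2):
            raise BnglError(f"rule {self.name}: 1 or 2 reactant patterns required")
        if self.rate < 0:
            raise BnglError(f"rule {self.name}: negative rate")

    def arity(self) -> int:
        return len(self.reactants)


@dataclass
class SeedSpecies:
    graph: ComplexGraph
    count: float  # non-negative; fractional counts rounded at release


@dataclass
class Observable:
    kind: str  # "Molecules" | "Species"
    name: str
    patterns: list[ComplexGraph]

    def __post_init__(self):
        if self.kind not in ("Molecules", "Species"):
            raise BnglError(f"observable {self.name}: kind must be "
                            "Molecules or Species")


@dataclass
class BnglModel:
    parameters: dict[str, float] = field(default_factory=dict)
    molecule_types: dict[str, MoleculeType] = field(default_factory=dict)
    compartments: dict[str, Compartment] = field(default_factory=dict)
    seed_species: list[SeedSpecies] = field(default_factory=list)
    observables: list[Observable] = field(default_factory=list)
    rules: list[ReactionRule] = field(default_factory=list)

    def inner_compartment(self, membrane: str) -> Optional[str]:
        """The 3D compartment directly inside a 2D membrane."""
        for c in self.compartments.values():
            if c.dimensionality == 3 and c.parent == membrane:
                return c.name
        return None

    def outer_compartment(self, membrane: str) -> Optional[str]:
        """The 3D compartment directly outside a 2D membrane."""
        m = self.compartments.get(membrane)
        if m is None or m.parent is None:
            return None
        return m.parent
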