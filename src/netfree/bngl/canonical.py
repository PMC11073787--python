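"""Canonical labeling of species graphs.

Two species graphs are isomorphic iff their canonical labels are equal.
The label is computed by iterative partition refinement on
(molecule name, component multiset, bond neighborhood) followed by
individualization-refinement search over the remaining symmetry,
keeping the lexicographically smallest serialization.  Handles highly
symmetric complexes (rings of identical subunits) in polynomial-ish time
at desk scale; a leaf-count guard catches pathological cases.
"""
from __future__ import annotations

from .types import ComplexGraph, MoleculeType, NotASpeciesError

__all__ = ["canonical_form", "canonical_graph"]

_MAX_LEAVES = 20000


def _initial_colors(g: ComplexGraph) -> list:
    cols = []
    for m in g.molecules:
        comp_sig = tuple(sorted(
            (c.name, c.state or "", isinstance(c.bond, int))
            for c in m.components))
        cols.append((m.name, comp_sig))
    return _compress(cols)


def _compress(cols: list) -> list[int]:
    order = {c: i for i, c in enumerate(sorted(set(cols), key=repr))}
    return [order[c] for c in cols]


def _refine_step(g: ComplexGraph, cols: list[int],
                 partner: dict) -> list[int]:
    new = []
    for mi, m in enumerate(g.molecules):
        edges = []
        for ci, c in enumerate(m.components):
            if isinstance(c.bond, int):
                pj, pc = partner[(mi, ci)]
                pcomp = g.molecules[pj].components[pc]
                edges.append((c.name, c.state or "",
                              pcomp.name, pcomp.state or "", cols[pj]))
        new.append((cols[mi], tuple(sorted(edges))))
    return _compress(new)


def _refine_to_stable(g: ComplexGraph, cols: list[int],
                      partner: dict) -> list[int]:
    n_classes = len(set(cols))
    while True:
        nxt = _refine_step(g, cols, partner)
        if len(set(nxt)) == n_classes:
            return nxt
        n_classes = len(set(nxt))
        cols = nxt


def _serialize(g: ComplexGraph, order: list[int], partner: dict) -> str:
    """Serialize with a fixed molecule order: bond ids assigned on first
    encounter, components within a molecule in a canonical order."""
    pos = {mi: k for k, mi in enumerate(order)}
    bond_ids: dict[frozenset, int] = {}

    def comp_key(mi, ci):
        c = g.molecules[mi].components[ci]
        if isinstance(c.bond, int):
            pj, pc = partner[(mi, ci)]
            pk = (1, pos[pj], g.molecules[pj].components[pc].name,
                  g.molecules[pj].components[pc].state or "")
        else:
            pk = (0, -1, "", "")
        return (c.name, c.state or "", pk)

    parts = []
    for mi in order:
        m = g.molecules[mi]
        comp_order = sorted(range(len(m.components)),
                            key=lambda ci: comp_key(mi, ci))
        toks = []
        for ci in comp_order:
            c = m.components[ci]
            t = c.name
            if c.state is not None:
                t += f"~{c.state}"
            if isinstance(c.bond, int):
                key = frozenset([(mi, ci), partner[(mi, ci)]])
                if key not in bond_ids:
                    bond_ids[key] = len(bond_ids) + 1
                t += f"!{bond_ids[key]}"
            toks.append(t)
        parts.append(f"{m.name}({','.join(toks)})")
    return ".".join(parts)


def canonical_form(g: ComplexGraph,
                   types: dict[str, MoleculeType] | None = None) -> str:
    """Canonical label of a species graph.

    Invariant under permutation of molecule order, of same-named component
    order, and of bond-id relabeling.  Raises :class:`NotASpeciesError`
    for wildcards / unset states / disconnected graphs (full validity also
    needs ``types``)."""
    if types is not None:
        g.check_species(types)
    else:
        if not g.is_connected():
            raise NotASpeciesError("species graph must be connected")
        for m in g.molecules:
            for c in m.components:
                if c.is_wild():
                    raise NotASpeciesError("wildcard in species graph")

    partner = g.partner_of()
    cols = _refine_to_stable(g, _initial_colors(g), partner)
    state = {"leaves": 0, "best": None}
    _search(g, cols, partner, state)
    assert state["best"] is not None
    return state["best"]


def _search(g: ComplexGraph, cols: list[int], partner: dict,
            state: dict) -> None:
    n = len(cols)
    classes: dict[int, list[int]] = {}
    for mi, c in enumerate(cols):
        classes.setdefault(c, []).append(mi)
    target = None
    for c in sorted(classes):
        if len(classes[c]) > 1:
            target = classes[c]
            break
    if target is None:
        state["leaves"] += 1
        if state["leaves"] > _MAX_LEAVES:
            raise NotASpeciesError(
                "complex too symmetric for canonical search guard")
        order = [mi for _, mi in sorted(zip(cols, range(n)))]
        s = _serialize(g, order, partner)
        if state["best"] is None or s < state["best"]:
            state["best"] = s
        return
    for mi in target:
        ind = [c * 2 for c in cols]
        ind[mi] -= 1  # individualize: strictly smaller, unique color
        refined = _refine_to_stable(g, _compress(ind), partner)
        _search(g, refined, partner, state)


def canonical_graph(g: ComplexGraph,
                    types: dict[str, MoleculeType] | None = None
                    ) -> tuple[str, ComplexGraph]:
    """Canonical label plus a graph re-parsed from it (normalized
    storage)."""
    from .parser import parse_complex
    label = canonical_form(g, types)
    norm = parse_complex(label)
    norm.compartment = g.compartment
    return label, norm
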