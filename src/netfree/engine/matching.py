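"""Subgraph matching of patterns onto species.

An *embedding* maps every pattern molecule and every listed pattern
component onto the species graph, respecting names, set states, and bond
constraints.  Embeddings that differ only by an automorphism of the
pattern are collapsed to one representative (NFsim convention), so a
symmetric pattern does not double-count a single chemical event.
"""
from __future__ import annotations

from dataclasses import dataclass

from ..bngl.types import ANY_BOND, EXISTS_BOND, ComplexGraph

__all__ = ["Embedding", "match_pattern", "pattern_automorphisms"]


@dataclass(frozen=True)
class Embedding:
    """mol_map[i] = species molecule index for pattern molecule i;
    comp_map[(i, ci)] = (species molecule index, species component index)."""

    mol_map: tuple[int, ...]
    comp_map: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def comp_dict(self) -> dict[tuple[int, int], tuple[int, int]]:
        return dict(self.comp_map)


def _find_embeddings(pattern: ComplexGraph, target: ComplexGraph,
                     exact: bool) -> list[Embedding]:
    """Backtracking search.  ``exact`` demands wildcard-for-wildcard and
    state-for-state equality (used for automorphisms)."""
    p_partner = pattern.partner_of()
    t_partner = target.partner_of()
    n_p = len(pattern.molecules)

    mol_map: list[int | None] = [None] * n_p
    comp_map: dict[tuple[int, int], tuple[int, int]] = {}
    used_t: set[int] = set()
    results: list[Embedding] = []

    def comp_ok(pm, pc, tm, tc) -> bool:
        pcomp = pattern.molecules[pm].components[pc]
        tcomp = target.molecules[tm].components[tc]
        if pcomp.name != tcomp.name:
            return False
        if exact:
            if pcomp.state != tcomp.state or \
                    _bond_class(pcomp.bond) != _bond_class(tcomp.bond):
                return False
        else:
            if pcomp.state is not None and pcomp.state != tcomp.state:
                return False
            if pcomp.bond is None and tcomp.bond is not None:
                return False  # listed without bond syntax means unbound
            if pcomp.bond == EXISTS_BOND and tcomp.bond is None:
                return False
            if isinstance(pcomp.bond, int) and not isinstance(tcomp.bond, int):
                return False
        return True

    def bonds_ok() -> bool:
        # every pattern bond whose two endpoints are currently mapped must
        # map onto an actual bond of the target
        for (a, b) in _pattern_bonds(p_partner):
            if a in comp_map and b in comp_map:
                ta, tb = comp_map[a], comp_map[b]
                if t_partner.get(ta) != tb:
                    return False
        return True

    def assign_components(pm: int, tm: int, pc: int,
                          used_c: set[int]) -> bool:
        pmol = pattern.molecules[pm]
        tmol = target.molecules[tm]
        if pc == len(pmol.components):
            return place_molecule(pm + 1)
        found = False
        for tc in range(len(tmol.components)):
            if tc in used_c or not comp_ok(pm, pc, tm, tc):
                continue
            comp_map[(pm, pc)] = (tm, tc)
            used_c.add(tc)
            if bonds_ok():
                if assign_components(pm, tm, pc + 1, used_c):
                    found = True
            used_c.discard(tc)
            del comp_map[(pm, pc)]
        return found

    def place_molecule(pm: int) -> bool:
        if pm == n_p:
            results.append(Embedding(tuple(mol_map),  # type: ignore[arg-type]
                                     tuple(sorted(comp_map.items()))))
            return True
        found = False
        for tm in range(len(target.molecules)):
            if tm in used_t:
                continue
            if pattern.molecules[pm].name != target.molecules[tm].name:
                continue
            if exact and len(pattern.molecules[pm].components) != \
                    len(target.molecules[tm].components):
                continue
            mol_map[pm] = tm
            used_t.add(tm)
            if assign_components(pm, tm, 0, set()):
                found = True
            used_t.discard(tm)
            mol_map[pm] = None
        return found

    place_molecule(0)
    return results


def _bond_class(bond) -> object:
    if isinstance(bond, int):
        return "bonded"
    return bond  # None | "?" | "+"


def _pattern_bonds(partner: dict) -> list[tuple[tuple[int, int],
                                                tuple[int, int]]]:
    out = []
    for a, b in partner.items():
        if a < b:
            out.append((a, b))
    return out


def pattern_automorphisms(pattern: ComplexGraph) -> list[Embedding]:
    """All structure-preserving self-mappings of a pattern."""
    return _find_embeddings(pattern, pattern, exact=True)


def match_pattern(pattern: ComplexGraph, species: ComplexGraph,
                  collapse: bool = True) -> list[Embedding]:
    """All embeddings of ``pattern`` into ``species``.

    With ``collapse=True`` (the default) embeddings equivalent under an
    automorphism of the pattern are reported once.
    """
    embs = _find_embeddings(pattern, species, exact=False)
    if not collapse or len(embs) <= 1:
        return embs
    auts = pattern_automorphisms(pattern)
    if len(auts) <= 1:
        return embs
    kept: list[Embedding] = []
    seen: set[tuple] = set()
    for e in embs:
        cd = e.comp_dict()
        sigs = []
        for a in auts:
            ad = a.comp_dict()
            # e composed with automorphism a: pattern node x -> e[a(x)]
            mm = tuple(e.mol_map[a.mol_map[i]] for i in range(len(e.mol_map)))
            cm = tuple(sorted((x, cd[ad[x]]) for x in cd))
            sigs.append((mm, cm))
        sig = min(sigs)
        if sig not in seen:
            seen.add(sig)
            kept.append(e)
    return kept


def count_embeddings(pattern: ComplexGraph, species: ComplexGraph) -> int:
    """Number of automorphism-distinct embeddings (observable counting)."""
    return len(match_pattern(pattern, species))
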