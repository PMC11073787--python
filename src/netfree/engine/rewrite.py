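"""Applying reaction rules as graph rewrites.

A rule is interpreted once into a set of *actions* (state changes, bond
create/delete, molecule create/delete) by mapping product patterns onto
reactant patterns: molecules correspond by name in order of appearance,
components by name in order of listing (the BioNetGen convention).  At
simulation time the actions are pushed through a concrete embedding onto
the reactant species, and each connected component of the rewritten graph
is one product species.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ..bngl.types import (ANY_BOND, EXISTS_BOND, BnglError, ComplexGraph,
                          ComponentInstance, MoleculeInstance, MoleculeType,
                          ReactionRule)
from .matching import Embedding

__all__ = ["RuleActions", "interpret_rule", "apply_rule", "ProductComplex"]

# node addressing: reactant pattern node = (pattern index, molecule index)
RNode = tuple[int, int]


@dataclass
class RuleActions:
    """The graph diff of a rule, in reactant-pattern coordinates."""

    # (pattern, mol, comp) -> new state
    state_changes: dict[tuple[int, int, int], str] = field(default_factory=dict)
    # unordered pairs of (pattern, mol, comp) endpoints to connect
    bond_creates: list[tuple[tuple[int, int, int], tuple[int, int, int]]] = \
        field(default_factory=list)
    # (pattern, mol, comp) whose bond (if any) is severed
    bond_deletes: list[tuple[int, int, int]] = field(default_factory=list)
    # reactant molecules deleted outright
    mol_deletes: list[RNode] = field(default_factory=list)
    # molecules created: (template MoleculeInstance, product compartment)
    mol_creates: list[tuple[MoleculeInstance, str | None]] = \
        field(default_factory=list)
    # bonds between a created molecule's component and either another created
    # molecule ('new', idx, comp) or a reactant node ('old', pat, mol, comp)
    new_bonds: list[tuple[tuple, tuple]] = field(default_factory=list)
    # ('new', idx) or ('old', pat, mol): molecules of each product pattern
    # complex, for compartment bookkeeping
    product_groups: list[list[tuple]] = field(default_factory=list)


def _occurrences(graphs: list[ComplexGraph]):
    """name -> ordered list of (graph index, molecule index)."""
    out: dict[str, list[tuple[int, int]]] = {}
    for gi, g in enumerate(graphs):
        for mi, m in enumerate(g.molecules):
            out.setdefault(m.name, []).append((gi, mi))
    return out


def _comp_occurrences(mol: MoleculeInstance):
    out: dict[str, list[int]] = {}
    for ci, c in enumerate(mol.components):
        out.setdefault(c.name, []).append(ci)
    return out


def interpret_rule(rule: ReactionRule,
                   types: dict[str, MoleculeType]) -> RuleActions:
    """Compute the action set of a rule (raises on inconsistent rules)."""
    acts = RuleActions()
    r_occ = _occurrences(rule.reactants)
    p_occ = _occurrences(rule.products)

    # molecule correspondence by (name, occurrence order)
    surviving: dict[tuple[int, int], RNode] = {}   # product node -> reactant
    created: dict[tuple[int, int], int] = {}       # product node -> new index
    for name, plist in p_occ.items():
        rlist = r_occ.get(name, [])
        for k, pnode in enumerate(plist):
            if k < len(rlist):
                surviving[pnode] = rlist[k]
            else:
                pmol = rule.products[pnode[0]].molecules[pnode[1]]
                idx = len(acts.mol_creates)
                comp = rule.products[pnode[0]].compartment
                acts.mol_creates.append(
                    (_instantiate(pmol, types, rule.name), comp))
                created[pnode] = idx
    for name, rlist in r_occ.items():
        plist = p_occ.get(name, [])
        for k, rnode in enumerate(rlist):
            if k >= len(plist):
                acts.mol_deletes.append(rnode)

    # component correspondence + state/bond diffs for surviving molecules
    def comp_node(pnode, ci):
        """product component -> action-space node."""
        if pnode in surviving:
            rp, rm = surviving[pnode]
            rmol = rule.reactants[rp].molecules[rm]
            pmol = rule.products[pnode[0]].molecules[pnode[1]]
            pname = pmol.components[ci].name
            p_list = _comp_occurrences(pmol)[pname]
            r_list = _comp_occurrences(rmol).get(pname, [])
            k = p_list.index(ci)
            if k >= len(r_list):
                raise BnglError(
                    f"rule {rule.name}: product lists component {pname} of "
                    f"{pmol.name} more often than the reactant pattern")
            return ("old", rp, rm, r_list[k])
        return ("new", created[pnode], ci)

    r_partner = {pi: g.partner_of() for pi, g in enumerate(rule.reactants)}
    p_partner = {pi: g.partner_of() for pi, g in enumerate(rule.products)}

    # reactant-side bond set in action coordinates
    r_bonds: set[frozenset] = set()
    for pi, partner in r_partner.items():
        for (a, b) in partner.items():
            if a < b:
                r_bonds.add(frozenset([("old", pi, a[0], a[1]),
                                       ("old", pi, b[0], b[1])]))

    p_bonds: set[frozenset] = set()
    explicit_unbind: set[tuple] = set()
    for pnode, psurv in list(surviving.items()) + \
            [(n, None) for n in created]:
        pg = rule.products[pnode[0]]
        pmol = pg.molecules[pnode[1]]
        for ci, pc in enumerate(pmol.components):
            node = comp_node(pnode, ci)
            # state updates
            if pc.state is not None and node[0] == "old":
                _, rp, rm, rc = node
                rstate = rule.reactants[rp].molecules[rm].components[rc].state
                if rstate != pc.state:
                    acts.state_changes[(rp, rm, rc)] = pc.state
            # bonds
            if isinstance(pc.bond, int):
                pj = p_partner[pnode[0]].get((pnode[1], ci))
                assert pj is not None
                other = comp_node((pnode[0], pj[0]), pj[1])
                p_bonds.add(frozenset([node, other]))
            elif pc.bond is None and node[0] == "old":
                _, rp, rm, rc = node
                rbond = rule.reactants[rp].molecules[rm].components[rc].bond
                if rbond is not None and rbond != EXISTS_BOND:
                    # bound/any in reactant, unbound in product
                    explicit_unbind.add(node)
            # pc.bond wildcards in product mean "unchanged"

    for b in r_bonds - p_bonds:
        a, c = tuple(b)
        acts.bond_deletes.extend([a[1:], c[1:]])
    for node in explicit_unbind:
        if not any(node in pair for pair in
                   (tuple(b) for b in r_bonds - p_bonds)):
            acts.bond_deletes.append(node[1:])
    for b in p_bonds - r_bonds:
        a, c = tuple(b)
        if a[0] == "old" and c[0] == "old":
            acts.bond_creates.append((a[1:], c[1:]))
        else:
            acts.new_bonds.append((a, c))

    # product grouping (for compartment assignment)
    for pi, pg in enumerate(rule.products):
        group = []
        for mi in range(len(pg.molecules)):
            pnode = (pi, mi)
            if pnode in surviving:
                group.append(("old",) + surviving[pnode])
            else:
                group.append(("new", created[pnode]))
        acts.product_groups.append(group)
    return acts


def _instantiate(pmol: MoleculeInstance, types: dict[str, MoleculeType],
                 rule_name: str) -> MoleculeInstance:
    mt = types.get(pmol.name)
    if mt is None:
        raise BnglError(f"rule {rule_name}: undeclared product molecule "
                        f"{pmol.name}")
    listed = {c.name: c for c in pmol.components}
    comps = []
    for ct in mt.components:
        if ct.name in listed:
            src = listed[ct.name]
            if ct.states and src.state is None:
                raise BnglError(
                    f"rule {rule_name}: created molecule {pmol.name} leaves "
                    f"state of {ct.name} unspecified")
            comps.append(ComponentInstance(ct.name, src.state, src.bond))
        else:
            if ct.states:
                raise BnglError(
                    f"rule {rule_name}: created molecule {pmol.name} must "
                    f"specify component {ct.name}")
            comps.append(ComponentInstance(ct.name))
    return MoleculeInstance(pmol.name, comps)


@dataclass
class ProductComplex:
    graph: ComplexGraph
    # per molecule of the graph: ("old", reactant graph index, molecule index
    # in the combined reactant graph) or ("new", product-pattern compartment)
    provenance: list[tuple]


def apply_rule(rule: ReactionRule, reactants: list[ComplexGraph],
               embeddings: list[Embedding],
               types: dict[str, MoleculeType],
               actions: RuleActions | None = None) -> list[ProductComplex]:
    """Rewrite concrete reactant species through a chosen embedding.

    ``reactants[i]`` is matched by ``rule.reactants[i]`` via
    ``embeddings[i]``.  Returns one :class:`ProductComplex` per connected
    component of the rewritten graph.
    """
    if len(reactants) != len(rule.reactants) or \
            len(embeddings) != len(rule.reactants):
        raise BnglError(f"rule {rule.name}: embedding/reactant arity mismatch")
    acts = actions if actions is not None else interpret_rule(rule, types)

    # --- build combined mutable graph -------------------------------------
    mols: list[MoleculeInstance] = []
    origin: list[tuple[int, int]] = []   # (reactant graph idx, local mol idx)
    offsets = []
    next_bond = 1
    for gi, g in enumerate(reactants):
        offsets.append(len(mols))
        remap: dict[int, int] = {}
        for mi, m in enumerate(g.molecules):
            mm = m.copy()
            for c in mm.components:
                if isinstance(c.bond, int):
                    if c.bond not in remap:
                        remap[c.bond] = next_bond
                        next_bond += 1
                    c.bond = remap[c.bond]
            mols.append(mm)
            origin.append((gi, mi))

    def target_pair(node: tuple[int, int, int]) -> tuple[int, int]:
        """action node (pattern, mol, comp) -> (global mol, comp)."""
        pi, pm, pc = node
        tm, tc = embeddings[pi].comp_dict()[(pm, pc)]
        return (offsets[pi] + tm, tc)

    # --- apply actions -----------------------------------------------------
    for (pi, pm, pc), new_state in acts.state_changes.items():
        gm, gc = target_pair((pi, pm, pc))
        mols[gm].components[gc].state = new_state

    def sever(gm: int, gc: int):
        bond = mols[gm].components[gc].bond
        if not isinstance(bond, int):
            return
        for om in mols:
            for oc in om.components:
                if oc.bond == bond:
                    oc.bond = None

    for node in acts.bond_deletes:
        gm, gc = target_pair(node)
        sever(gm, gc)

    deleted_globals: set[int] = set()
    for (pi, pm) in acts.mol_deletes:
        gm = offsets[pi] + embeddings[pi].mol_map[pm]
        deleted_globals.add(gm)
        for gc in range(len(mols[gm].components)):
            sever(gm, gc)

    new_offset = len(mols)
    new_compartments: list[str | None] = []
    for template, comp in acts.mol_creates:
        mols.append(template.copy())
        origin.append((-1, len(new_compartments)))
        new_compartments.append(comp)

    def any_node_target(node: tuple) -> tuple[int, int]:
        if node[0] == "old":
            return target_pair(node[1:])
        _, new_idx, ci = node
        return (new_offset + new_idx, ci)

    for (a, b) in acts.bond_creates:
        ga, gb = target_pair(a), target_pair(b)
        sever(*ga)
        sever(*gb)
        mols[ga[0]].components[ga[1]].bond = next_bond
        mols[gb[0]].components[gb[1]].bond = next_bond
        next_bond += 1
    for (a, b) in acts.new_bonds:
        ga, gb = any_node_target(a), any_node_target(b)
        sever(*ga)
        sever(*gb)
        mols[ga[0]].components[ga[1]].bond = next_bond
        mols[gb[0]].components[gb[1]].bond = next_bond
        next_bond += 1

    # --- collect connected components of the survivors ---------------------
    keep = [i for i in range(len(mols)) if i not in deleted_globals]
    whole = ComplexGraph.__new__(ComplexGraph)
    whole.molecules = [mols[i] for i in keep]
    whole.compartment = None
    whole._validate_bonds()
    back = {k: i for k, i in enumerate(keep)}

    out = []
    for group in whole.connected_components():
        sub = whole.subgraph(group)
        prov = []
        for local in group:
            gi = back[local]
            og, om = origin[gi]
            if og >= 0:
                prov.append(("old", og, om))
            else:
                prov.append(("new", new_compartments[om]))
        out.append(ProductComplex(sub, prov))
    return out
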