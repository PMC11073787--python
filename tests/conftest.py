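import numpy as np
import pytest

from netfree.bngl import parse_bngl


FIG10_BNGL = """\
# minimal compartmental model: 100 A + 100 B in CP, A + B -> C
begin model
begin parameters
  k_on 1.66
  n0 100
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_B 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_C 1e-6
end parameters
begin molecule types
  A()
  B()
  C()
end molecule types
begin compartments
  CP 3 1.0
end compartments
begin seed species
  @CP:A() n0
  B()@CP n0
end seed species
begin observables
  Molecules A_total A()
  Molecules C_total C()
end observables
begin reaction rules
  bind: A() + B() -> C() k_on
end reaction rules
end model
"""


@pytest.fixture
def fig10_model():
    return parse_bngl(FIG10_BNGL)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_species(rng, n_mols=None):
    """A random connected species graph over two molecule types with
    duplicate-named stateful components (for isomorphism property tests)."""
    from netfree.bngl.types import (ComplexGraph, ComponentInstance,
                                    MoleculeInstance)
    if n_mols is None:
        n_mols = int(rng.integers(1, 6))
    mols = []
    for _ in range(n_mols):
        if rng.random() < 0.5:
            comps = [ComponentInstance("c0", rng.choice(["R", "S"])),
                     ComponentInstance("c0", rng.choice(["R", "S"]))]
            mols.append(MoleculeInstance("A", comps))
        else:
            comps = [ComponentInstance("c1", rng.choice(["U", "V"])),
                     ComponentInstance("c2", rng.choice(["X", "Y"]))]
            mols.append(MoleculeInstance("B", comps))
    # connect in a random tree through free components
    bond = 1
    for i in range(1, n_mols):
        j = int(rng.integers(0, i))
        ci = _free_comp(mols[i], rng)
        cj = _free_comp(mols[j], rng)
        if ci is None or cj is None:
            continue
        mols[i].components[ci].bond = bond
        mols[j].components[cj].bond = bond
        bond += 1
    g = ComplexGraph(mols)
    comps = g.connected_components()
    if len(comps) > 1:
        g = g.subgraph(comps[0])
    return g


def _free_comp(mol, rng):
    free = [i for i, c in enumerate(mol.components) if c.bond is None]
    if not free:
        return None
    return int(rng.choice(free))


def shuffled_copy(g, rng):
    """The same species with molecule order, component order of duplicate
    components, and bond ids randomly permuted."""
    from netfree.bngl.types import ComplexGraph
    g = g.copy()
    order = rng.permutation(len(g.molecules))
    mols = [g.molecules[i] for i in order]
    bond_map = {}
    for m in mols:
        if len(m.components) == 2 and \
                m.components[0].name == m.components[1].name and \
                rng.random() < 0.5:
            m.components.reverse()
        for c in m.components:
            if isinstance(c.bond, int):
                if c.bond not in bond_map:
                    bond_map[c.bond] = int(rng.integers(100, 10_000)) \
                        + len(bond_map)
                c.bond = bond_map[c.bond]
    return ComplexGraph(mols)


def nx_isomorphic(g1, g2):
    """Brute-force isomorphism oracle via networkx VF2 on the bipartite
    molecule/component graph."""
    import networkx as nx

    def to_nx(g):
        G = nx.Graph()
        partner = g.partner_of()
        for mi, m in enumerate(g.molecules):
            G.add_node(("m", mi), kind="mol", name=m.name)
            for ci, c in enumerate(m.components):
                G.add_node(("c", mi, ci), kind="comp", name=c.name,
                           state=c.state)
                G.add_edge(("m", mi), ("c", mi, ci), kind="part")
        for (a, b) in partner.items():
            if a < b:
                G.add_edge(("c",) + a, ("c",) + b, kind="bond")
        return G

    return nx.is_isomorphic(
        to_nx(g1), to_nx(g2),
        node_match=lambda a, b: (a["kind"], a["name"],
                                 a.get("state")) == (b["kind"], b["name"],
                                                     b.get("state")),
        edge_match=lambda a, b: a["kind"] == b["kind"])
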