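"""Pattern matching, graph rewriting, caches, network expansion,
compartment classes, diffusion derivation, and unit conversion."""
import math

import pytest

from netfree.bngl import (BnglError, format_complex, parse_bngl,
                          parse_complex)
from netfree.bngl.types import ReactionRule
from netfree.engine import (BoundedExpansionError, RuleEngine, apply_rule,
                            derive_diffusion_constant, expand_network,
                            match_pattern, resolve_compartment_classes,
                            write_net)
from netfree.units import (BNG, MCELL_DEFAULT, SURF_SURF, UNI, VOL_VOL,
                           convert_rate_units)
from netfree.validation import fixture_bngl


TYPES = parse_bngl("""
begin molecule types
  A(c0~R~S,c0~R~S)
  B(c1~U~V,c2~X~Y)
end molecule types
""").molecule_types


class TestMatchPattern:
    def test_state_constrained(self):
        embs = match_pattern(parse_complex("A(c0~R)"),
                             parse_complex("A(c0~R,c0~S)"))
        assert len(embs) == 1
        # the embedding lands on the R-state component
        (_, (tm, tc)), = embs[0].comp_map
        assert tc == 0 or tc == 1

    def test_molecule_level(self):
        assert len(match_pattern(parse_complex("A()"),
                                 parse_complex("A(c0~R,c0~S)"))) == 1

    def test_listed_component_means_unbound(self):
        species = parse_complex("A(c0~R!1,c0~S).B(c1~U!1,c2~X)")
        embs = match_pattern(parse_complex("A(c0)"), species)
        assert len(embs) == 1
        (_, (tm, tc)), = embs[0].comp_map
        assert species.molecules[tm].components[tc].bond is None

    def test_symmetric_pattern_collapsed(self):
        # both components in state R: two raw embeddings related by the
        # pattern automorphism collapse to one
        embs = match_pattern(parse_complex("A(c0~R)"),
                             parse_complex("A(c0~R,c0~R)"))
        assert len(embs) == 2  # distinct targets: no automorphism collapse
        embs2 = match_pattern(parse_complex("A(c0~R,c0~R)"),
                              parse_complex("A(c0~R,c0~R)"))
        assert len(embs2) == 1

    def test_exists_bond_wildcard(self):
        species = parse_complex("A(c0~R!1,c0~S).B(c1~U!1,c2~X)")
        assert len(match_pattern(parse_complex("A(c0!+)"), species)) == 1
        assert len(match_pattern(parse_complex("B(c2!+)"), species)) == 0
        assert len(match_pattern(parse_complex("B(c2!?)"), species)) == 1


class TestApplyRule:
    def _rule(self, text):
        m = parse_bngl("""
begin molecule types
  A(c0~R~S,c0~R~S)
  B(c1~U~V,c2~X~Y)
  C()
end molecule types
begin reaction rules
""" + "  r: " + text + "\n" + """
end reaction rules
""")
        return m.rules[0], m.molecule_types

    def test_bond_create_and_state_change(self):
        rule, types = self._rule(
            "A(c0~R) + B(c1~U) -> A(c0~S!1).B(c1~U!1) 1.0")
        sA = parse_complex("A(c0~R,c0~S)")
        sB = parse_complex("B(c1~U,c2~X)")
        prods = apply_rule(rule, [sA, sB],
                           [match_pattern(rule.reactants[0], sA)[0],
                            match_pattern(rule.reactants[1], sB)[0]], types)
        assert len(prods) == 1  # one connected product component
        g = prods[0].graph
        assert len(g.bond_map()) == 1
        states = sorted(c.state for m in g.molecules
                        for c in m.components if c.name == "c0")
        assert states == ["S", "S"]  # matched c0 flipped R -> S

    def test_molecule_replacement(self):
        rule, types = self._rule("A() + B() -> C() 1.0")
        sA, sB = parse_complex("A(c0~R,c0~R)"), parse_complex("B(c1~U,c2~X)")
        prods = apply_rule(rule, [sA, sB],
                           [match_pattern(rule.reactants[0], sA)[0],
                            match_pattern(rule.reactants[1], sB)[0]], types)
        assert [p.graph.molecules[0].name for p in prods] == ["C"]

    def test_unbinding_splits_dimer(self):
        rule, types = self._rule(
            "A(c0~S!1).B(c1~U!1) -> A(c0~S) + B(c1~U) 1.0")
        dimer = parse_complex("A(c0~S!1,c0~R).B(c1~U!1,c2~Y)")
        prods = apply_rule(rule, [dimer],
                           [match_pattern(rule.reactants[0], dimer)[0]],
                           types)
        assert len(prods) == 2
        labels = sorted(format_complex(p.graph) for p in prods)
        # jointly isomorphic to the monomers with the bond removed
        assert labels == ["A(c0~S,c0~R)", "B(c1~U,c2~Y)"] or \
            labels == sorted(["A(c0~R,c0~S)", "B(c1~U,c2~Y)"])
        for p in prods:
            assert not p.graph.bond_map()

    def test_molecule_conservation(self):
        """Elementary molecules are conserved except for explicit
        create/delete."""
        rule, types = self._rule(
            "A(c0~R) + B(c1~U) -> A(c0~S!1).B(c1~U!1) 1.0")
        sA, sB = parse_complex("A(c0~R,c0~R)"), parse_complex("B(c1~U,c2~X)")
        prods = apply_rule(rule, [sA, sB],
                           [match_pattern(rule.reactants[0], sA)[0],
                            match_pattern(rule.reactants[1], sB)[0]], types)
        before = {"A": 1, "B": 1}
        after: dict = {}
        for p in prods:
            for name, n in p.graph.molecule_counts().items():
                after[name] = after.get(name, 0) + n
        assert after == before


class TestCaches:
    def _engine(self):
        return RuleEngine(parse_bngl("""
begin molecule types
  A()
  B()
  C()
end molecule types
begin reaction rules
  bind: A() + B() -> C() 2.0
end reaction rules
"""))

    def test_lookup_pathway(self):
        eng = self._engine()
        a = eng.intern_species(parse_complex("A()"))
        b = eng.intern_species(parse_complex("B()"))
        rc = eng.lookup_or_expand(a, b)
        assert len(rc.pathways) == 1
        assert rc.pathways[0].product_keys == ("C()",)

    def test_empty_class_still_cached(self):
        eng = self._engine()
        a = eng.intern_species(parse_complex("A()"))
        c = eng.intern_species(parse_complex("C()"))
        rc = eng.lookup_or_expand(a, c)
        assert rc.pathways == []
        assert eng.lookup_or_expand(c, a) is rc  # object-level cache hit

    def test_order_symmetric(self):
        eng = self._engine()
        a = eng.intern_species(parse_complex("A()"))
        b = eng.intern_species(parse_complex("B()"))
        assert eng.lookup_or_expand(a, b) is eng.lookup_or_expand(b, a)

    def test_cleanup_evicts_only_dead(self):
        eng = self._engine()
        a = eng.intern_species(parse_complex("A()"))
        b = eng.intern_species(parse_complex("B()"))
        eng.lookup_or_expand(a, b)
        a.count = 3
        b.count = 1
        c = eng.species["C()"]
        assert c.count == 0
        n = eng.cleanup_caches()
        assert n >= 1
        assert "C()" not in eng.species
        assert "A()" in eng.species and "B()" in eng.species
        assert eng.cleanup_caches() == 0


class TestExpandNetwork:
    def test_single_rule(self):
        m = parse_bngl("""
begin molecule types
  A()
  B()
  C()
end molecule types
begin seed species
  A() 10
  B() 10
end seed species
begin reaction rules
  bind: A() + B() -> C() 1.0
end reaction rules
""")
        ex = expand_network(m)
        assert len(ex.species) == 3
        assert len(ex.reactions) == 1
        net = write_net(ex)
        assert "begin reactions" in net

    def test_two_site_phosphorylation(self):
        """Two independent sites, forward only: 4 species, 4 reactions
        (hand enumeration)."""
        m = parse_bngl("""
begin molecule types
  S(a~0~1,b~0~1)
end molecule types
begin seed species
  S(a~0,b~0) 5
end seed species
begin reaction rules
  pa: S(a~0) -> S(a~1) 1.0
  pb: S(b~0) -> S(b~1) 1.0
end reaction rules
""")
        ex = expand_network(m)
        assert len(ex.species) == 4
        assert len(ex.reactions) == 4

    def test_seed_order_irrelevant(self):
        text = """
begin molecule types
  A()
  B()
  C()
end molecule types
begin seed species
  {seeds}
end seed species
begin reaction rules
  bind: A() + B() <-> C() 1.0, 2.0
end reaction rules
"""
        ex1 = expand_network(parse_bngl(text.format(seeds="A() 1\n  B() 1")))
        ex2 = expand_network(parse_bngl(text.format(seeds="B() 1\n  A() 1")))
        as_set = lambda ex: {(r.reactants, r.products, r.rate)
                             for r in ex.reactions}
        assert as_set(ex1) == as_set(ex2)

    def test_limits(self):
        # unbounded polymerization must hit the species limit
        m = parse_bngl("""
begin molecule types
  P(l,r)
end molecule types
begin seed species
  P(l,r) 10
end seed species
begin reaction rules
  grow: P(r) + P(l) -> P(r!1).P(l!1) 1.0
end reaction rules
""")
        with pytest.raises(BoundedExpansionError):
            expand_network(m, max_species=20)


class TestCompartmentClasses:
    MODEL = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-6
  MCELL_DIFFUSION_CONSTANT_2D_T 1e-8
end parameters
begin molecule types
  A()
  T()
end molecule types
begin compartments
  EC 3 1.0
  PM 2 0.1 EC
  CP 3 0.5 PM
end compartments
""")

    def test_worked_transport_example(self):
        rule = ReactionRule("t", [parse_complex("A()@OUT"),
                                  parse_complex("T()")],
                            [parse_complex("A()@IN"),
                             parse_complex("T()")], 1.0)
        conc = resolve_compartment_classes(rule, "PM", self.MODEL)
        assert conc.reactants[0].compartment == "EC"
        assert conc.products[0].compartment == "CP"
        assert conc.products[1].compartment == "PM"

    def test_rule_without_classes_unchanged(self):
        rule = ReactionRule("t", [parse_complex("A()@EC"),
                                  parse_complex("T()")],
                            [parse_complex("A()@CP"),
                             parse_complex("T()")], 1.0)
        assert resolve_compartment_classes(rule, "PM", self.MODEL) is rule

    def test_two_volume_reactants_rejected(self):
        rule = ReactionRule("t", [parse_complex("A()@IN"),
                                  parse_complex("A()@OUT")],
                            [parse_complex("A()@IN"),
                             parse_complex("A()@OUT")], 1.0)
        with pytest.raises(BnglError):
            resolve_compartment_classes(rule, "PM", self.MODEL)

    def test_missing_inner_compartment(self):
        model = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-6
  MCELL_DIFFUSION_CONSTANT_2D_T 1e-8
end parameters
begin molecule types
  A()
  T()
end molecule types
begin compartments
  EC 3 1.0
  PM 2 0.1 EC
end compartments
""")
        rule = ReactionRule("t", [parse_complex("A()@IN"),
                                  parse_complex("T()")],
                            [parse_complex("A()@OUT"),
                             parse_complex("T()")], 1.0)
        with pytest.raises(BnglError, match="no @IN"):
            resolve_compartment_classes(rule, "PM", model)


class TestDiffusionDerivation:
    TYPES = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_V 8e-6
  MCELL_DIFFUSION_CONSTANT_3D_W 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_Z 0
  MCELL_DIFFUSION_CONSTANT_2D_S 1e-8
end parameters
begin molecule types
  V(b,b)
  W(b)
  Z(b)
  S(b)
end molecule types
""").molecule_types

    def test_monomer(self):
        d, surf = derive_diffusion_constant(parse_complex("V(b,b)"),
                                            self.TYPES)
        assert d == 8e-6 and not surf

    def test_zero_subunit_pins_complex(self):
        g = parse_complex("V(b!1,b).Z(b!1)")
        d, _ = derive_diffusion_constant(g, self.TYPES)
        assert d == 0.0

    def test_volume_homodimer(self):
        g = parse_complex("V(b!1,b).V(b!1,b)")
        d, _ = derive_diffusion_constant(g, self.TYPES)
        assert d == pytest.approx(8e-6 * 2 ** (-1.0 / 3.0))

    def test_surface_complex_uses_surface_subunits(self):
        g = parse_complex("V(b!1,b).S(b!1)")
        d, surf = derive_diffusion_constant(g, self.TYPES)
        assert surf
        assert d == pytest.approx(1e-8)  # only the surface subunit counts
        g2 = parse_complex("S(b!1).S(b!2).V(b!1,b!2)")
        d2, _ = derive_diffusion_constant(g2, self.TYPES)
        assert d2 == pytest.approx(1e-8 * 2 ** (-0.5))


class TestUnitConversion:
    def test_unimolecular_unchanged(self):
        assert convert_rate_units(7.0, UNI, MCELL_DEFAULT, BNG) == 7.0

    def test_molar_to_um3(self):
        k = convert_rate_units(1e9, VOL_VOL, MCELL_DEFAULT, BNG)
        assert k == pytest.approx(1e9 * 1e15 / 6.02214076e23)
        assert k == pytest.approx(1.6605, rel=1e-3)

    def test_surface_thin_volume(self):
        assert convert_rate_units(1.0, SURF_SURF, MCELL_DEFAULT, BNG) == \
            pytest.approx(0.01)

    def test_round_trip_inverse(self):
        for ctx in (VOL_VOL, SURF_SURF, UNI):
            k = 3.7
            back = convert_rate_units(
                convert_rate_units(k, ctx, MCELL_DEFAULT, BNG),
                ctx, BNG, MCELL_DEFAULT)
            assert back == pytest.approx(k)

    def test_unknown_context(self):
        with pytest.raises(ValueError):
            convert_rate_units(1.0, "nope", BNG, BNG)


class TestSnareExpansion:
    def test_counts(self):
        m = parse_bngl(fixture_bngl("snare"))
        ex = expand_network(m)
        assert len(ex.reactions) == 126
        snare_states = [s for s in ex.species if "snare" in s.key]
        assert len(snare_states) == 36
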