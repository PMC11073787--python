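"""Parsing, canonical labels, state enumeration, and BNGL round-trips."""
import numpy as np
import pytest

from netfree.bngl import (BnglError, BnglSyntaxError, NotASpeciesError,
                          canonical_form, count_molecule_states,
                          enumerate_molecule_states, evaluate_expression,
                          format_complex, parse_bngl, parse_complex,
                          parse_molecule_type, write_bngl)
from netfree.validation import fixture_bngl

from conftest import FIG10_BNGL, nx_isomorphic, random_species, shuffled_copy


class TestParser:
    def test_minimal_compartmental_file(self, fig10_model):
        m = fig10_model
        assert set(m.compartments) == {"CP"}
        assert m.compartments["CP"].size == 1.0
        assert len(m.seed_species) == 2
        # both @C: prefix and species@C suffix dialects accepted
        for ss in m.seed_species:
            assert ss.graph.compartment == "CP"
            assert ss.count == 100
        assert len(m.rules) == 1
        assert m.rules[0].rate == pytest.approx(1.66)

    def test_empty_sections_ok(self):
        m = parse_bngl("begin parameters\nend parameters\n"
                       "begin molecule types\nend molecule types\n")
        assert not m.parameters and not m.molecule_types

    def test_duplicate_component_molecule_type(self):
        mt = parse_molecule_type("A(c0~R~S,c0~R~S)")
        assert [c.name for c in mt.components] == ["c0", "c0"]
        assert all(c.states == ("R", "S") for c in mt.components)

    def test_expression_arithmetic(self):
        params = {"a": 3.0, "b": 2.0}
        assert evaluate_expression("a*(b+1)^2 - 4/b", params) == 25.0
        assert evaluate_expression("2^3^2", params) == 512.0  # right assoc

    def test_undeclared_identifier(self):
        with pytest.raises(BnglError, match="undeclared"):
            parse_bngl("begin parameters\n x missing_name*2\n"
                       "end parameters\n")

    def test_functions_unsupported(self):
        with pytest.raises(BnglError, match="not supported"):
            parse_bngl("begin functions\n f() = 1\nend functions\n")

    def test_syntax_error_carries_line(self):
        with pytest.raises(BnglSyntaxError, match="line 2"):
            parse_bngl("begin molecule types\n A(c0~~)\n"
                       "end molecule types\n")

    def test_line_continuation_and_comments(self):
        m = parse_bngl("begin parameters\n"
                       "  x 1 + \\\n    2  # sum\n"
                       "end parameters\n")
        assert m.parameters["x"] == 3.0

    def test_reversible_rule_split(self):
        m = parse_bngl(FIG10_BNGL.replace(
            "bind: A() + B() -> C() k_on",
            "bind: A() + B() <-> C() k_on, 2.5"))
        assert [r.name for r in m.rules] == ["bind", "bind_rev"]
        assert m.rules[1].rate == 2.5
        assert len(m.rules[1].reactants) == 1


class TestCanonicalForm:
    def test_storage_order_irrelevant(self):
        a = parse_complex("A(c0~R,c0~S)")
        b = parse_complex("A(c0~S,c0~R)")
        assert canonical_form(a) == canonical_form(b)

    def test_bond_relabeling(self):
        a = parse_complex("A(c0~R!1,c0~S).B(c1~U!1,c2~X)")
        b = parse_complex("B(c2~X,c1~U!7).A(c0~S,c0~R!7)")
        assert canonical_form(a) == canonical_form(b)

    def test_rejects_patterns(self):
        with pytest.raises(NotASpeciesError):
            canonical_form(parse_complex("A(c0!+)"))
        with pytest.raises(NotASpeciesError):
            canonical_form(parse_complex("A(c0!1).B(c1!1).C()"))

    def test_symmetric_ring(self):
        def ring(states):
            n = len(states)
            return parse_complex(".".join(
                f"K(l!{i + 1},r!{(i + 1) % n + 1},T~{states[i]})"
                for i in range(n)))
        base = ["U", "P", "U", "U", "P", "U"]
        lab = canonical_form(ring(base))
        for k in range(1, 6):
            assert canonical_form(ring(base[k:] + base[:k])) == lab
        assert canonical_form(ring(["U"] * 6)) != lab

    def test_label_equality_iff_isomorphic(self, rng):
        """Property: on random species pairs, label equality must agree
        with a brute-force VF2 isomorphism check."""
        graphs = [random_species(rng) for _ in range(40)]
        for g in graphs:
            assert canonical_form(g) == canonical_form(shuffled_copy(g, rng))
        for _ in range(60):
            i, j = rng.integers(0, len(graphs), size=2)
            same_label = canonical_form(graphs[i]) == \
                canonical_form(graphs[j])
            assert same_label == nx_isomorphic(graphs[i], graphs[j])


class TestEnumeration:
    def test_ten_sites_three_states(self):
        mt = parse_molecule_type(
            "A(" + ",".join(f"s{i}~U~P~B" for i in range(10)) + ")")
        assert count_molecule_states(mt) == 59049

    def test_analytic_product_for_distinct_names(self, rng):
        """Property: with all component names distinct, the count is the
        product of the per-component state multiplicities."""
        for _ in range(10):
            n = int(rng.integers(1, 5))
            sizes = [int(rng.integers(1, 4)) for _ in range(n)]
            decl = ",".join(
                f"c{i}" + "".join(f"~s{j}" for j in range(k))
                for i, k in enumerate(sizes))
            mt = parse_molecule_type(f"X({decl})")
            assert count_molecule_states(mt) == int(np.prod(sizes))

    def test_duplicate_names_deduplicate(self):
        # two interchangeable two-state sites: 3 distinct, not 4
        mt = parse_molecule_type("A(c0~R~S,c0~R~S)")
        assert count_molecule_states(mt) == 3

    def test_no_components(self):
        assert count_molecule_states(parse_molecule_type("X()")) == 1

    def test_enumerated_species_are_valid(self):
        mt = parse_molecule_type("A(c~0~1,d)")
        species = enumerate_molecule_states(mt)
        assert len(species) == 2
        for g in species:
            canonical_form(g)  # raises if not a species


class TestRoundTrip:
    @pytest.mark.parametrize("name", [
        "wellmixed_abc", "snare", "membrane_localization",
        "autophosphorylation", "clock_particle", "clock_hybrid",
        "psd_spine"])
    def test_parse_write_parse_identity(self, name):
        m1 = parse_bngl(fixture_bngl(name))
        m2 = parse_bngl(write_bngl(m1))
        assert set(m2.molecule_types) == set(m1.molecule_types)
        assert m2.parameters == m1.parameters
        assert {(c.name, c.dimensionality, c.size, c.parent)
                for c in m2.compartments.values()} == \
               {(c.name, c.dimensionality, c.size, c.parent)
                for c in m1.compartments.values()}
        assert len(m2.rules) == len(m1.rules)
        for r1, r2 in zip(m1.rules, m2.rules):
            assert r1.name == r2.name and r1.rate == r2.rate
            assert [format_complex(g) for g in r1.reactants] == \
                   [format_complex(g) for g in r2.reactants]
        assert [(s.count, format_complex(s.graph))
                for s in m1.seed_species] == \
               [(s.count, format_complex(s.graph))
                for s in m2.seed_species]

    def test_snare_model_shape(self):
        m = parse_bngl(fixture_bngl("snare"))
        assert len(m.molecule_types) == 3
        # ten rule statements; reversible ones split at parse
        names = {r.name.removesuffix("_rev") for r in m.rules}
        assert len(names) == 10

    def test_spatial_features_warned_not_dropped(self):
        m = parse_bngl(FIG10_BNGL)
        m.spatial_notes = ["release of A onto mesh region 'top'"]
        warnings = []
        text = write_bngl(m, warn=warnings)
        assert warnings == ["release of A onto mesh region 'top'"]
        assert "A()" in text
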