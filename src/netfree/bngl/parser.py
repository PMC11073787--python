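"""Parser for the supported BNGL dialect.

Sections: parameters, molecule types, compartments, seed species (or
species), observables, reaction rules; ``begin model``/``end model``
optional; ``#`` comments; ``\\`` line continuation.  Parameter expressions
support ``+ - * / ^`` and parentheses.  BNGL functions are rejected as
unsupported.  Both compartment spellings ``@C:species`` and ``species@C``
are accepted.  Identifiers are case-sensitive.
"""
from __future__ import annotations

import re
from typing import Optional

from .types import (ANY_BOND, EXISTS_BOND, BnglError, BnglModel, Compartment,
                    ComponentInstance, ComponentType, ComplexGraph,
                    MoleculeInstance, MoleculeType, Observable, ReactionRule,
                    SeedSpecies)

__all__ = ["parse_bngl", "parse_complex", "parse_molecule_type",
           "evaluate_expression", "BnglSyntaxError"]

_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"

#: parameter-name prefixes carrying spatial molecule attributes (cm²/s)
DIFF3_PREFIX = "MCELL_DIFFUSION_CONSTANT_3D_"
DIFF2_PREFIX = "MCELL_DIFFUSION_CONSTANT_2D_"


class BnglSyntaxError(BnglError):
    def __init__(self, msg: str, line: int, col: int = 0):
        super().__init__(f"line {line}, col {col}: {msg}")
        self.line = line
        self.col = col


# ---------------------------------------------------------------------------
# expression evaluation (+ - * / ^, parentheses, names)
# ---------------------------------------------------------------------------

_EXPR_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>" + _IDENT + r")"
    r"|(?P<op>[-+*/^()]))")


def _tokenize_expr(text: str, line: int):
    pos, out = 0, []
    while pos < len(text):
        m = _EXPR_TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise BnglSyntaxError(f"bad expression near {text[pos:]!r}",
                                      line, pos)
            break
        out.append(m)
        pos = m.end()
    return out


def evaluate_expression(text: str, params: dict[str, float],
                        line: int = 0) -> float:
    """Evaluate an arithmetic expression over known parameter values."""
    toks = _tokenize_expr(text, line)
    pos = 0

    def peek():
        return toks[pos] if pos < len(toks) else None

    def take():
        nonlocal pos
        t = toks[pos]
        pos += 1
        return t

    def atom() -> float:
        t = peek()
        if t is None:
            raise BnglSyntaxError("unexpected end of expression", line)
        if t.group("num"):
            take()
            return float(t.group("num"))
        if t.group("name"):
            take()
            name = t.group("name")
            if name not in params:
                raise BnglError(f"line {line}: undeclared identifier {name!r}")
            return params[name]
        if t.group("op") == "(":
            take()
            v = expr()
            t2 = peek()
            if t2 is None or t2.group("op") != ")":
                raise BnglSyntaxError("missing )", line)
            take()
            return v
        if t.group("op") == "-":
            take()
            return -atom()
        if t.group("op") == "+":
            take()
            return atom()
        raise BnglSyntaxError(f"unexpected {t.group(0)!r}", line)

    def power() -> float:
        base = atom()
        t = peek()
        if t is not None and t.group("op") == "^":
            take()
            return base ** power()  # right-associative
        return base

    def term() -> float:
        v = power()
        while True:
            t = peek()
            if t is not None and t.group("op") in ("*", "/"):
                take()
                rhs = power()
                v = v * rhs if t.group("op") == "*" else v / rhs
            else:
                return v

    def expr() -> float:
        t = peek()
        v = term()
        while True:
            t = peek()
            if t is not None and t.group("op") in ("+", "-"):
                take()
                rhs = term()
                v = v + rhs if t.group("op") == "+" else v - rhs
            else:
                return v

    v = expr()
    if pos != len(toks):
        raise BnglSyntaxError(f"trailing tokens in expression {text!r}", line)
    return v


# ---------------------------------------------------------------------------
# complex / pattern parsing
# ---------------------------------------------------------------------------

_COMPLEX_TOKEN = re.compile(
    r"(?P<name>" + _IDENT + r")"
    r"|(?P<punct>[().,~!@:])"
    r"|(?P<digits>\d+)"
    r"|(?P<wild>[?+])")


def parse_complex(text: str, line: int = 0) -> ComplexGraph:
    """Parse one complex / pattern expression, e.g.
    ``@EC:A(c0~R!1,c1).B(c2!1)`` or ``A(c)@IN``."""
    text = text.strip()
    compartment: Optional[str] = None
    m = re.match(r"^@(" + _IDENT + r"):", text)
    if m:
        compartment = m.group(1)
        text = text[m.end():]
    m = re.search(r"@(" + _IDENT + r")$", text)
    if m and compartment is None:
        compartment = m.group(1)
        text = text[:m.start()]

    pos = 0
    mols: list[MoleculeInstance] = []

    def err(msg):
        raise BnglSyntaxError(msg, line, pos)

    def take(kind=None, value=None):
        nonlocal pos
        if pos >= len(text):
            err("unexpected end of complex")
        mt = _COMPLEX_TOKEN.match(text, pos)
        if not mt:
            err(f"bad token near {text[pos:]!r}")
        if kind and not mt.group(kind):
            err(f"expected {kind}, got {mt.group(0)!r}")
        if value and mt.group(0) != value:
            err(f"expected {value!r}, got {mt.group(0)!r}")
        pos = mt.end()
        return mt

    def peek_char():
        return text[pos] if pos < len(text) else ""

    while True:
        name = take("name").group("name")
        comps: list[ComponentInstance] = []
        if peek_char() == "(":
            take(value="(")
            if peek_char() != ")":
                while True:
                    cname = take("name").group("name")
                    state = None
                    bond: object = None
                    while peek_char() in "~!":
                        ch = peek_char()
                        take(value=ch)
                        if ch == "~":
                            t = _COMPLEX_TOKEN.match(text, pos)
                            if t and (t.group("name") or t.group("digits")):
                                state = t.group(0)
                                pos = t.end()
                            else:
                                err("missing state after ~")
                        else:  # bond
                            t = _COMPLEX_TOKEN.match(text, pos)
                            if t and t.group("digits"):
                                bond = int(t.group(0))
                                pos = t.end()
                            elif t and t.group("wild"):
                                bond = (ANY_BOND if t.group(0) == "?"
                                        else EXISTS_BOND)
                                pos = t.end()
                            else:
                                err("missing bond id after !")
                    comps.append(ComponentInstance(cname, state, bond))
                    if peek_char() == ",":
                        take(value=",")
                        continue
                    break
            take(value=")")
        mols.append(MoleculeInstance(name, comps))
        if peek_char() == ".":
            take(value=".")
            continue
        break
    if pos != len(text):
        raise BnglSyntaxError(f"trailing text {text[pos:]!r} in complex",
                              line, pos)
    return ComplexGraph(mols, compartment)


def parse_molecule_type(text: str, line: int = 0) -> MoleculeType:
    """Parse a molecule-type declaration, e.g. ``A(c0~R~S,c0~R~S)``."""
    text = text.strip()
    m = re.match(r"^(" + _IDENT + r")(?:\((.*)\))?$", text)
    if not m:
        raise BnglSyntaxError(f"bad molecule type {text!r}", line)
    name, body = m.group(1), m.group(2)
    comps: list[ComponentType] = []
    if body:
        for part in _split_commas(body):
            bits = part.split("~")
            cname = bits[0].strip()
            if not re.fullmatch(_IDENT, cname):
                raise BnglSyntaxError(f"bad component {part!r}", line)
            states = tuple(s.strip() for s in bits[1:])
            if any(not s for s in states):
                raise BnglSyntaxError(f"empty state name in {part!r}", line)
            comps.append(ComponentType(cname, states))
    return MoleculeType(name, tuple(comps))


def _split_commas(text: str) -> list[str]:
    """Split on top-level commas (no nesting in our dialect)."""
    return [p for p in (s.strip() for s in text.split(",")) if p]


def _split_patterns(text: str) -> list[str]:
    """Split a pattern list on whitespace and commas outside parens."""
    out, cur, depth = [], [], 0
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth == 0 and (ch.isspace() or ch == ","):
            if cur:
                out.append("".join(cur))
                cur = []
            continue
        cur.append(ch)
    if cur:
        out.append("".join(cur))
    return out


# ---------------------------------------------------------------------------
# file-level parsing
# ---------------------------------------------------------------------------

_SECTION_ALIASES = {
    "parameters": "parameters",
    "molecule types": "molecule types",
    "compartments": "compartments",
    "seed species": "seed species",
    "species": "seed species",
    "observables": "observables",
    "reaction rules": "reaction rules",
    "functions": "functions",
    "model": "model",
}


def _logical_lines(text: str):
    """Yield (lineno, content) with comments stripped and ``\\`` joins."""
    raw = text.splitlines()
    i = 0
    while i < len(raw):
        lineno = i + 1
        line = raw[i]
        while line.rstrip().endswith("\\"):
            line = line.rstrip()[:-1]
            i += 1
            line += " " + (raw[i] if i < len(raw) else "")
        i += 1
        hash_pos = line.find("#")
        if hash_pos >= 0:
            line = line[:hash_pos]
        line = line.strip()
        if line:
            yield lineno, line


def parse_bngl(text: str) -> BnglModel:
    """Parse BNGL source into a fully resolved :class:`BnglModel`."""
    model = BnglModel()
    section: Optional[str] = None
    pending_rules: list[tuple[int, str]] = []
    pending_seeds: list[tuple[int, str, str]] = []

    for lineno, line in _logical_lines(text):
        m = re.match(r"^begin\s+(.+)$", line)
        if m:
            name = re.sub(r"\s+", " ", m.group(1).strip())
            if name not in _SECTION_ALIASES:
                raise BnglSyntaxError(f"unknown section {name!r}", lineno)
            name = _SECTION_ALIASES[name]
            if name == "functions":
                raise BnglError(
                    f"line {lineno}: BNGL functions are not supported")
            if name != "model":
                if section is not None:
                    raise BnglSyntaxError(
                        f"nested section {name!r}", lineno)
                section = name
            continue
        m = re.match(r"^end\s+(.+)$", line)
        if m:
            name = _SECTION_ALIASES.get(
                re.sub(r"\s+", " ", m.group(1).strip()))
            if name != "model":
                section = None
            continue
        if re.match(r"^(generate_network|simulate|setOption|writeXML|"
                    r"saveConcentrations|resetConcentrations)", line):
            continue  # action commands are ignored
        if section is None:
            raise BnglSyntaxError(f"statement outside any section: {line!r}",
                                  lineno)

        if section == "parameters":
            m = re.match(r"^(" + _IDENT + r")\s*=?\s*(.+)$", line)
            if not m:
                raise BnglSyntaxError(f"bad parameter line {line!r}", lineno)
            model.parameters[m.group(1)] = evaluate_expression(
                m.group(2), model.parameters, lineno)
        elif section == "molecule types":
            mt = parse_molecule_type(line, lineno)
            if mt.name in model.molecule_types:
                raise BnglError(f"line {lineno}: duplicate molecule type "
                                f"{mt.name}")
            model.molecule_types[mt.name] = mt
        elif section == "compartments":
            bits = line.split()
            if len(bits) not in (3, 4):
                raise BnglSyntaxError(f"bad compartment line {line!r}", lineno)
            name, dim = bits[0], int(bits[1])
            size = evaluate_expression(bits[2], model.parameters, lineno)
            parent = bits[3] if len(bits) == 4 else None
            model.compartments[name] = Compartment(name, dim, size, parent)
        elif section == "seed species":
            m = re.match(r"^(\S+)\s+(.+)$", line)
            if not m:
                raise BnglSyntaxError(f"bad seed species line {line!r}", lineno)
            pending_seeds.append((lineno, m.group(1), m.group(2)))
        elif section == "observables":
            bits = line.split(None, 2)
            if len(bits) != 3:
                raise BnglSyntaxError(f"bad observable line {line!r}", lineno)
            kind, name, rest = bits
            pats = [parse_complex(p, lineno)
                    for p in _split_patterns(rest)]
            model.observables.append(Observable(kind, name, pats))
        elif section == "reaction rules":
            pending_rules.append((lineno, line))
        else:  # pragma: no cover
            raise BnglSyntaxError(f"unhandled section {section}", lineno)

    _finish_compartments(model)
    for lineno, s, count_expr in pending_seeds:
        g = parse_complex(s, lineno)
        count = evaluate_expression(count_expr, model.parameters, lineno)
        if count < 0:
            raise BnglError(f"line {lineno}: negative seed count")
        model.seed_species.append(SeedSpecies(g, count))
    for lineno, line in pending_rules:
        model.rules.extend(_parse_rule_line(line, lineno, model.parameters))
    _apply_diffusion_parameters(model)
    _check_references(model)
    return model


def _finish_compartments(model: BnglModel):
    for c in model.compartments.values():
        if c.parent is not None:
            p = model.compartments.get(c.parent)
            if p is None:
                raise BnglError(f"compartment {c.name}: undeclared parent "
                                f"{c.parent}")
            if p.dimensionality == c.dimensionality:
                raise BnglError(
                    f"compartment {c.name}: parent must alternate 2D/3D")


def _apply_diffusion_parameters(model: BnglModel):
    for pname, value in model.parameters.items():
        for prefix, field in ((DIFF3_PREFIX, "diffusion_constant_3d"),
                              (DIFF2_PREFIX, "diffusion_constant_2d")):
            if pname.startswith(prefix):
                target = pname[len(prefix):]
                mt = model.molecule_types.get(target)
                if mt is None:
                    raise BnglError(
                        f"diffusion parameter {pname} references undeclared "
                        f"molecule type {target}")
                setattr(mt, field, value)


_ARROW = re.compile(r"<->|->")


def _parse_rule_line(line: str, lineno: int,
                     params: dict[str, float]) -> list[ReactionRule]:
    name = None
    m = re.match(r"^(" + _IDENT + r")\s*:\s*(.+)$", line)
    if m:
        name, line = m.group(1), m.group(2)
    arrow = _ARROW.search(line)
    if not arrow:
        raise BnglSyntaxError(f"no arrow in rule {line!r}", lineno)
    reversible = arrow.group(0) == "<->"
    lhs_text = line[:arrow.start()].strip()
    rest = line[arrow.end():].strip()

    # split products from rates: rates are the trailing comma-separated
    # expressions that are not complexes.  We scan from the right.
    rhs_text, rate_text = _split_rates(rest, lineno, reversible)
    rates = _split_commas(rate_text)
    if reversible and len(rates) != 2:
        raise BnglSyntaxError("reversible rule needs two rates", lineno)
    if not reversible and len(rates) != 1:
        raise BnglSyntaxError("rule needs exactly one rate", lineno)

    def side(text):
        text = text.strip()
        if text in ("0", ""):
            return []
        return [parse_complex(p.strip(), lineno)
                for p in re.split(r"\s+\+\s+", text)]

    lhs, rhs = side(lhs_text), side(rhs_text)
    kf = evaluate_expression(rates[0], params, lineno)
    base = name or f"rule{lineno}"
    out = [ReactionRule(base, lhs, rhs, kf)]
    if reversible:
        kr = evaluate_expression(rates[1], params, lineno)
        out.append(ReactionRule(base + "_rev",
                                [g.copy() for g in rhs],
                                [g.copy() for g in lhs], kr))
    return out


def _split_rates(rest: str, lineno: int, reversible: bool) -> tuple[str, str]:
    """Split ``A(x) + B(y)  kf, kr`` into product text and rate text."""
    n_rates = 2 if reversible else 1
    if n_rates == 2:
        comma = rest.rfind(",")
        if comma < 0:
            raise BnglSyntaxError("reversible rule needs two rates", lineno)
        tail = rest[comma + 1:]
        head = rest[:comma]
    else:
        tail = ""
        head = rest
    # last whitespace-separated token group of head is the (first) rate
    m = re.match(r"^(.*?)(?:\s+(\S+))$", head)
    if not m or not m.group(2):
        raise BnglSyntaxError(f"missing rate in rule tail {rest!r}", lineno)
    products, rate1 = m.group(1), m.group(2)
    rate_text = rate1 + ("," + tail if n_rates == 2 else "")
    return products, rate_text


def _check_references(model: BnglModel):
    def check_graph(g: ComplexGraph, where: str, pattern_ok: bool):
        if g.compartment is not None and g.compartment not in ("IN", "OUT") \
                and g.compartment not in model.compartments:
            raise BnglError(f"{where}: undeclared compartment "
                            f"@{g.compartment}")
        for mol in g.molecules:
            mt = model.molecule_types.get(mol.name)
            if mt is None:
                raise BnglError(f"{where}: undeclared molecule type "
                                f"{mol.name}")
            avail = {c.name: c.states for c in mt.components}
            for c in mol.components:
                if c.name not in avail:
                    raise BnglError(f"{where}: {mol.name} has no component "
                                    f"{c.name}")
                if c.state is not None and c.state not in avail[c.name]:
                    raise BnglError(f"{where}: bad state {mol.name}"
                                    f"({c.name}~{c.state})")

    for ss in model.seed_species:
        check_graph(ss.graph, "seed species", pattern_ok=False)
        ss.graph.check_species(model.molecule_types)
    for ob in model.observables:
        for p in ob.patterns:
            check_graph(p, f"observable {ob.name}", pattern_ok=True)
    for r in model.rules:
        for g in r.reactants + r.products:
            check_graph(g, f"rule {r.name}", pattern_ok=True)
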