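"""BNGL emission (best-effort round-trip of the in-memory model)."""
from __future__ import annotations

from .parser import DIFF2_PREFIX, DIFF3_PREFIX
from .types import BnglModel, ComplexGraph, MoleculeType, ReactionRule

__all__ = ["write_bngl", "format_complex", "format_molecule_type"]


def format_complex(g: ComplexGraph) -> str:
    parts = []
    for m in g.molecules:
        toks = []
        for c in m.components:
            t = c.name
            if c.state is not None:
                t += f"~{c.state}"
            if c.bond is not None:
                t += f"!{c.bond}"
            toks.append(t)
        parts.append(f"{m.name}({','.join(toks)})")
    text = ".".join(parts)
    if g.compartment is not None:
        text = f"@{g.compartment}:{text}"
    return text


def format_molecule_type(mt: MoleculeType) -> str:
    toks = []
    for c in mt.components:
        t = c.name
        for s in c.states:
            t += f"~{s}"
        toks.append(t)
    return f"{mt.name}({','.join(toks)})"


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def _format_rule(r: ReactionRule) -> str:
    lhs = " + ".join(format_complex(g) for g in r.reactants) or "0"
    rhs = " + ".join(format_complex(g) for g in r.products) or "0"
    return f"{r.name}: {lhs} -> {rhs} {_format_number(r.rate)}"


def write_bngl(model: BnglModel, warn: list[str] | None = None) -> str:
    """Emit BNGL text that re-parses to an equivalent model.

    Spatial-only features recorded on the model (``model.spatial_notes``,
    populated by the model-assembly layer) cannot be expressed in BNGL; they
    are reported through ``warn`` rather than silently dropped.
    """
    if warn is not None:
        warn.extend(getattr(model, "spatial_notes", []) or [])

    out = ["begin model", ""]

    out.append("begin parameters")
    for name, value in model.parameters.items():
        out.append(f"  {name} {_format_number(value)}")
    for mt in model.molecule_types.values():
        for d, prefix in ((mt.diffusion_constant_3d, DIFF3_PREFIX),
                          (mt.diffusion_constant_2d, DIFF2_PREFIX)):
            pname = prefix + mt.name
            if d is not None and pname not in model.parameters:
                out.append(f"  {pname} {_format_number(d)}")
    out.append("end parameters")
    out.append("")

    out.append("begin molecule types")
    for mt in model.molecule_types.values():
        out.append(f"  {format_molecule_type(mt)}")
    out.append("end molecule types")
    out.append("")

    if model.compartments:
        out.append("begin compartments")
        for c in model.compartments.values():
            tail = f" {c.parent}" if c.parent else ""
            out.append(f"  {c.name} {c.dimensionality} "
                       f"{_format_number(c.size)}{tail}")
        out.append("end compartments")
        out.append("")

    out.append("begin seed species")
    for ss in model.seed_species:
        out.append(f"  {format_complex(ss.graph)} {_format_number(ss.count)}")
    out.append("end seed species")
    out.append("")

    if model.observables:
        out.append("begin observables")
        for ob in model.observables:
            pats = " ".join(format_complex(p) for p in ob.patterns)
            out.append(f"  {ob.kind} {ob.name} {pats}")
        out.append("end observables")
        out.append("")

    out.append("begin reaction rules")
    for r in model.rules:
        out.append(f"  {_format_rule(r)}")
    out.append("end reaction rules")
    out.append("")
    out.append("end model")
    return "\n".join(out) + "\n"
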