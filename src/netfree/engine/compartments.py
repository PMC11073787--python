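"""Resolution of the @IN/@OUT compartment classes.

A rule like ``A@OUT + T -> A@IN + T`` is generic over membranes: at
simulation time the membrane compartment of the surface reactant picks the
concrete compartments, e.g. with hierarchy EC ⊃ PM ⊃ CP and T in PM the
rule becomes ``A@EC + T@PM -> A@CP + T@PM``.  Only bimolecular rules with
exactly one volume and one surface reactant may use the classes.
"""
from __future__ import annotations

from ..bngl.types import (BnglError, BnglModel, ComplexGraph, MoleculeType,
                          ReactionRule)

__all__ = ["uses_compartment_classes", "validate_class_usage",
           "resolve_compartment_classes", "CompartmentResolutionError"]

_CLASSES = ("IN", "OUT")


class CompartmentResolutionError(BnglError):
    pass


def uses_compartment_classes(rule: ReactionRule) -> bool:
    return any(g.compartment in _CLASSES
               for g in rule.reactants + rule.products)


def _is_surface_pattern(g: ComplexGraph,
                        types: dict[str, MoleculeType]) -> bool:
    return any(types[m.name].is_surface for m in g.molecules
               if m.name in types)


def validate_class_usage(rule: ReactionRule,
                         types: dict[str, MoleculeType]) -> None:
    """Classes are legal only on volume+surface bimolecular rules, and only
    on the volume-side patterns."""
    if not uses_compartment_classes(rule):
        return
    if len(rule.reactants) != 2:
        raise BnglError(
            f"rule {rule.name}: @IN/@OUT require a bimolecular rule")
    surf = [_is_surface_pattern(g, types) for g in rule.reactants]
    if sum(surf) != 1:
        raise BnglError(
            f"rule {rule.name}: @IN/@OUT require exactly one volume and one "
            "surface reactant")
    for g in rule.reactants + rule.products:
        if g.compartment in _CLASSES and _is_surface_pattern(g, types):
            raise BnglError(
                f"rule {rule.name}: @IN/@OUT may only annotate the volume "
                "reactant/product")


def resolve_compartment_classes(rule: ReactionRule, surface_compartment: str,
                                model: BnglModel) -> ReactionRule:
    """Return a concrete rule with @IN/@OUT replaced for the membrane
    holding the surface reactant.  Rules without classes are returned
    unchanged."""
    if not uses_compartment_classes(rule):
        return rule
    validate_class_usage(rule, model.molecule_types)
    membrane = model.compartments.get(surface_compartment)
    if membrane is None or membrane.dimensionality != 2:
        raise CompartmentResolutionError(
            f"rule {rule.name}: {surface_compartment!r} is not a membrane "
            "compartment")
    inner = model.inner_compartment(surface_compartment)
    outer = model.outer_compartment(surface_compartment)
    mapping = {"IN": inner, "OUT": outer}

    def concretize(g: ComplexGraph) -> ComplexGraph:
        if g.compartment in _CLASSES:
            target = mapping[g.compartment]
            if target is None:
                raise CompartmentResolutionError(
                    f"rule {rule.name}: membrane {surface_compartment} has "
                    f"no @{g.compartment} compartment")
            g2 = g.copy()
            g2.compartment = target
            return g2
        g2 = g.copy()
        if g2.compartment is None and _is_surface_pattern(
                g2, model.molecule_types):
            g2.compartment = surface_compartment
        return g2

    return ReactionRule(rule.name,
                        [concretize(g) for g in rule.reactants],
                        [concretize(g) for g in rule.products],
                        rule.rate)
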