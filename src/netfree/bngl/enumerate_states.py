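"""State-space enumeration for a single elementary molecule type."""
from __future__ import annotations

import itertools

from .canonical import canonical_form
from .types import ComponentInstance, ComplexGraph, MoleculeInstance, MoleculeType

__all__ = ["enumerate_molecule_states", "count_molecule_states"]


def enumerate_molecule_states(mt: MoleculeType) -> list[ComplexGraph]:
    """All distinct unbound species of one molecule type.

    The raw product of per-component state counts is reduced by canonical
    deduplication when the type carries duplicate-named components (their
    state assignments are interchangeable).
    """
    choices = []
    for c in mt.components:
        choices.append(c.states if c.states else (None,))
    seen: dict[str, ComplexGraph] = {}
    for combo in itertools.product(*choices):
        comps = [ComponentInstance(c.name, s)
                 for c, s in zip(mt.components, combo)]
        g = ComplexGraph([MoleculeInstance(mt.name, comps)])
        label = canonical_form(g)
        if label not in seen:
            seen[label] = g
    return [seen[k] for k in sorted(seen)]


def count_molecule_states(mt: MoleculeType) -> int:
    return len(enumerate_molecule_states(mt))
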