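"""Diffusion constants of complexes derived from their subunits.

Constraints honored: a single zero-diffusion subunit pins the whole
complex (D = 0); any surface subunit makes the complex a surface complex
and only surface subunits enter the combining rule.  Combining rules
(volumes / areas additive with effective radius ∝ 1/D):

* volume complex:  D = (Σᵢ Dᵢ⁻³)^(−1/3)
* surface complex: D = (Σᵢ∈surface Dᵢ⁻²)^(−1/2)
"""
from __future__ import annotations

from ..bngl.types import BnglError, ComplexGraph, MoleculeType

__all__ = ["derive_diffusion_constant"]


def derive_diffusion_constant(graph: ComplexGraph,
                              types: dict[str, MoleculeType]
                              ) -> tuple[float, bool]:
    """Return ``(D in cm²/s, is_surface)`` for a species graph."""
    subunit_types = []
    for m in graph.molecules:
        mt = types.get(m.name)
        if mt is None:
            raise BnglError(f"undeclared molecule type {m.name}")
        subunit_types.append(mt)
    is_surface = any(mt.is_surface for mt in subunit_types)

    ds = []
    for mt in subunit_types:
        d = mt.diffusion_constant
        if d is None:
            raise BnglError(f"molecule type {mt.name} has no diffusion "
                            "constant assigned")
        ds.append((d, mt.is_surface))

    if any(d == 0.0 for d, _ in ds):
        return 0.0, is_surface

    if is_surface:
        used = [d for d, surf in ds if surf]
        exponent = 2.0
    else:
        used = [d for d, _ in ds]
        exponent = 3.0
    if len(used) == 1:
        return used[0], is_surface
    total = sum(d ** (-exponent) for d in used)
    return total ** (-1.0 / exponent), is_surface
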