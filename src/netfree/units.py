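"""Unit systems and rate-constant conversions.

Two unit conventions are supported for bimolecular rate constants:

* ``MCELL_DEFAULT`` — volume-volume and volume-surface rates in M⁻¹s⁻¹,
  surface-surface rates in μm²·N⁻¹s⁻¹;
* ``BNG`` — every bimolecular rate in μm³·N⁻¹s⁻¹ (membranes interpreted
  as thin volumes of thickness 10 nm).

Unimolecular rates are s⁻¹ in both.  N denotes molecule number.
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AVOGADRO", "LITERS_PER_UM3", "M_INV_S_TO_UM3_N",
           "MEMBRANE_THICKNESS_UM", "UnitSystem", "MCELL_DEFAULT", "BNG",
           "convert_rate_units", "VOL_VOL", "VOL_SURF", "SURF_SURF", "UNI"]

AVOGADRO = 6.02214076e23
LITERS_PER_UM3 = 1e-15
#: 1 M⁻¹s⁻¹ in μm³·N⁻¹s⁻¹  (1e15/N_A ≈ 1.6605e-9)
M_INV_S_TO_UM3_N = 1.0 / (AVOGADRO * LITERS_PER_UM3)
#: membranes as thin volumes of thickness 10 nm
MEMBRANE_THICKNESS_UM = 0.01

VOL_VOL = "vol_vol"
VOL_SURF = "vol_surf"
SURF_SURF = "surf_surf"
UNI = "unimolecular"
_CONTEXTS = (VOL_VOL, VOL_SURF, SURF_SURF, UNI)


@dataclass(frozen=True)
class UnitSystem:
    name: str
    membrane_thickness: float = MEMBRANE_THICKNESS_UM

    def to_internal(self, k: float, context: str) -> float:
        """Convert a rate constant to internal units.

        Internal units: μm³·N⁻¹s⁻¹ for every bimolecular context and s⁻¹
        for unimolecular ones.
        """
        if context not in _CONTEXTS:
            raise ValueError(f"unknown reaction context {context!r}")
        if context == UNI:
            return k
        if self.name == "BNG":
            return k
        # MCELL_DEFAULT
        if context in (VOL_VOL, VOL_SURF):
            return k * M_INV_S_TO_UM3_N
        return k * self.membrane_thickness  # μm²N⁻¹s⁻¹ → μm³N⁻¹s⁻¹

    def from_internal(self, k: float, context: str) -> float:
        if context not in _CONTEXTS:
            raise ValueError(f"unknown reaction context {context!r}")
        if context == UNI:
            return k
        if self.name == "BNG":
            return k
        if context in (VOL_VOL, VOL_SURF):
            return k / M_INV_S_TO_UM3_N
        return k / self.membrane_thickness


MCELL_DEFAULT = UnitSystem("MCELL_DEFAULT")
BNG = UnitSystem("BNG")


def convert_rate_units(k: float, context: str, from_system: UnitSystem,
                       to_system: UnitSystem) -> float:
    """Convert ``k`` between unit systems for the given reaction context."""
    return to_system.from_internal(from_system.to_internal(k, context),
                                   context)
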