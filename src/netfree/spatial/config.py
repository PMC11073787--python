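"""Run configuration."""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["SimulationConfig"]


@dataclass
class SimulationConfig:
    """Simulation parameters.

    ``interaction_radius`` defaults to 1/√(π·σ) with σ the surface grid
    density, which makes the volume collision cross-section π·r_int² equal
    to one grid tile's nominal area, keeping volume and surface collision
    cross-sections commensurate.
    """

    time_step: float = 1e-6          # s
    iterations: int = 0
    seed: int = 1
    surface_grid_density: float = 1e4   # tiles/μm²
    interaction_radius: Optional[float] = None  # μm
    cleanup_interval: int = 10_000   # iterations between cache sweeps
    output_cadence: int = 1          # iterations between count samples
    rate_units: str = "BNG"          # "BNG" | "MCELL_DEFAULT"
    probability_warning: float = 1.0  # warn when p exceeds this
    max_wall_bounces: int = 100

    def __post_init__(self):
        if self.time_step <= 0:
            raise ValueError("time step must be positive")
        if self.surface_grid_density <= 0:
            raise ValueError("surface grid density must be positive")
        if self.interaction_radius is None:
            self.interaction_radius = 1.0 / math.sqrt(
                math.pi * self.surface_grid_density)
        if self.interaction_radius <= 0:
            raise ValueError("interaction radius must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
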