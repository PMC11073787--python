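"""Hybrid particle/continuum coupling for the activator-repressor clock.

The repressor R is carried as a continuous copy number rather than as
particles.  Each iteration: 1) one particle iteration runs, 2) R is
updated by an explicit-Euler finite difference driven by current particle
counts and by the discrete A→C / C-decay event counts (those events
consume / release one R each), 3) the pseudo-first-order rate of the
``A_to_C`` rule is reset to k_AR·R(t) for the next iteration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..spatial.world import World

__all__ = ["ClockParameters", "clock_hybrid_step", "HybridClockRun"]


@dataclass
class ClockParameters:
    """Hybrid-coupling constants (must equal the BNGL fixture's values)."""

    beta_r: float       # R production per mRNA, 1/s
    delta_r: float      # R degradation, 1/s
    gamma_c_pair: float  # A+R sequestration per-pair rate, 1/s
    mr_key: str         # species key of the R mRNA
    dt: float           # particle time step = Euler step, s

    @classmethod
    def from_model(cls, model, dt: float,
                   mr_key: str = "MR()@CP") -> "ClockParameters":
        p = model.parameters
        return cls(beta_r=p["betaR"], delta_r=p["deltaR"],
                   gamma_c_pair=p["gammaC"] / p["V"], mr_key=mr_key, dt=dt)


def clock_hybrid_step(world: World, r_count: float,
                      params: ClockParameters) -> float:
    """Advance the hybrid model one iteration; returns updated R."""
    before_ac = world.rxn_counts.get("A_to_C", 0)
    before_cd = world.rxn_counts.get("C_decay", 0)
    world.run_iterations(1)                                    # step 1
    d_ac = world.rxn_counts.get("A_to_C", 0) - before_ac
    d_cd = world.rxn_counts.get("C_decay", 0) - before_cd
    mr = world.molecule_count(params.mr_key)
    r_count = r_count + params.dt * (params.beta_r * mr
                                     - params.delta_r * r_count) \
        - d_ac + d_cd                                          # step 2
    if r_count < 0.0:
        warnings.warn("hybrid R copy number clamped to 0", RuntimeWarning,
                      stacklevel=2)
        r_count = 0.0
    world.set_unimolecular_rate("A_to_C",
                                params.gamma_c_pair * r_count)  # step 3
    return r_count


class HybridClockRun:
    """Drives a hybrid clock world and exposes the ensemble interface
    (``run``, ``count_times``, ``count_rows``, ``observable_names``),
    with the continuous R appended as an extra output column."""

    def __init__(self, world: World, params: ClockParameters,
                 iterations: int, r0: float = 0.0):
        self.world = world
        self.params = params
        self.iterations = iterations
        self.r = float(r0)
        self.count_times: list[float] = []
        self.count_rows: list[list[float]] = []

    def observable_names(self) -> list[str]:
        return self.world.observable_names() + ["R_count"]

    def run(self) -> None:
        w = self.world
        w.set_unimolecular_rate("A_to_C", self.params.gamma_c_pair * self.r)
        cadence = w.config.output_cadence
        for it in range(self.iterations):
            self.r = clock_hybrid_step(w, self.r, self.params)
            if (it + 1) % cadence == 0:
                self.count_times.append(w.time)
                self.count_rows.append(
                    w.observable_values() + [self.r])
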