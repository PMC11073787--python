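"""Independent well-mixed oracles: mass-action ODE integration and the
Gillespie direct-method SSA over a fully expanded reaction network.

Both use the same stochastic rate-constant convention as the spatial
engine: a bimolecular ``ConcreteReaction.rate`` k (μm³·N⁻¹s⁻¹) acts at
per-pair rate k/V, with V the effective volume of the reaction context
(a membrane is a thin volume of thickness 10 nm).  For a pair of
identical reactants the number of pairs is N(N−1)/2 (deterministic
limit x²/2).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ..engine.network import ConcreteReaction, NetworkExpansion
from ..units import MEMBRANE_THICKNESS_UM

__all__ = ["WellMixedNetwork", "build_well_mixed", "ode_oracle",
           "ssa_oracle"]


@dataclass
class WellMixedNetwork:
    species: list[str]                 # species keys, fixed order
    reactions: list[ConcreteReaction]
    #: per-reaction stochastic rate constant c (s⁻¹ units after division
    #: by effective volume for bimolecular reactions)
    c: np.ndarray
    #: per-reaction stoichiometry change vector (n_reactions, n_species)
    delta: np.ndarray
    #: per-reaction reactant index pairs: (i, -1) unimolecular, (i, j) pair
    pairs: list[tuple[int, int]]


def build_well_mixed(expansion: NetworkExpansion,
                     volumes: dict[Optional[str], float],
                     default_volume: Optional[float] = None
                     ) -> WellMixedNetwork:
    """Flatten an expanded network for the well-mixed oracles.

    ``volumes`` maps compartment name (or None) to volume in μm³; 2D
    compartments should be entered as area × 10 nm (done automatically
    when the model declares the compartment as 2D)."""
    model = expansion.engine.model
    vol_of: dict[Optional[str], float] = {}
    for name, v in volumes.items():
        comp = model.compartments.get(name) if name else None
        if comp is not None and comp.dimensionality == 2:
            # membranes are entered as areas (μm²): thin volume of 10 nm
            vol_of[name] = v * MEMBRANE_THICKNESS_UM
        else:
            vol_of[name] = v
    if default_volume is not None:
        vol_of.setdefault(None, default_volume)

    keys = expansion.species_keys()
    index = {k: i for i, k in enumerate(keys)}
    comp_of = {sp.key: sp.compartment for sp in expansion.species}
    surface = {sp.key: sp.is_surface for sp in expansion.species}

    c = np.zeros(len(expansion.reactions))
    delta = np.zeros((len(expansion.reactions), len(keys)))
    pairs: list[tuple[int, int]] = []
    for ri, rx in enumerate(expansion.reactions):
        for k in rx.reactants:
            delta[ri, index[k]] -= 1
        for k in rx.products:
            delta[ri, index[k]] += 1
        if len(rx.reactants) == 1:
            c[ri] = rx.rate
            pairs.append((index[rx.reactants[0]], -1))
        else:
            ka, kb = rx.reactants
            vol_keys = [k for k in (ka, kb) if not surface[k]]
            ctx = comp_of[vol_keys[0]] if vol_keys else comp_of[ka]
            if ctx not in vol_of and None in vol_of:
                ctx = None
            if ctx not in vol_of:
                raise ValueError(
                    f"no effective volume for compartment {ctx!r}")
            c[ri] = rx.rate / vol_of[ctx]
            pairs.append((index[ka], index[kb]))
    return WellMixedNetwork(keys, list(expansion.reactions), c, delta,
                            pairs)


def _propensities(net: WellMixedNetwork, x: np.ndarray,
                  deterministic: bool) -> np.ndarray:
    a = np.empty(len(net.c))
    for ri, (i, j) in enumerate(net.pairs):
        if j < 0:
            a[ri] = net.c[ri] * x[i]
        elif i == j:
            if deterministic:
                a[ri] = net.c[ri] * x[i] * x[i] / 2.0
            else:
                a[ri] = net.c[ri] * x[i] * (x[i] - 1.0) / 2.0
        else:
            a[ri] = net.c[ri] * x[i] * x[j]
    return a


def ode_oracle(net: WellMixedNetwork, initial: dict[str, float],
               t_grid: Sequence[float], rtol: float = 1e-8,
               atol: float = 1e-10) -> np.ndarray:
    """Deterministic mass-action trajectories on ``t_grid``.

    Returns an array (len(t_grid), n_species) in the order of
    ``net.species``.  Stiff-safe (LSODA)."""
    x0 = np.zeros(len(net.species))
    for k, v in initial.items():
        x0[net.species.index(k)] = v

    def rhs(_t, x):
        return _propensities(net, x, deterministic=True) @ net.delta

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), x0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def ssa_oracle(net: WellMixedNetwork, initial: dict[str, float],
               seed: int, t_grid: Sequence[float],
               max_events: int = 10_000_000) -> np.ndarray:
    """One exact Gillespie direct-method trajectory sampled on ``t_grid``."""
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    x = np.zeros(len(net.species))
    for k, v in initial.items():
        x[net.species.index(k)] = v
    out = np.empty((len(t_grid), len(x)))
    t = float(t_grid[0])
    gi = 0
    for _ in range(max_events):
        a = _propensities(net, x, deterministic=False)
        a_tot = float(a.sum())
        if a_tot <= 0.0:
            break
        dt = rng.exponential(1.0 / a_tot)
        t_next = t + dt
        while gi < len(t_grid) and t_grid[gi] <= t_next:
            out[gi] = x
            gi += 1
        if gi >= len(t_grid):
            return out
        t = t_next
        ri = int(np.searchsorted(np.cumsum(a), rng.random() * a_tot,
                                 side="right"))
        ri = min(ri, len(a) - 1)
        x = x + net.delta[ri]
    while gi < len(t_grid):
        out[gi] = x
        gi += 1
    return out
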