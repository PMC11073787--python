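# netfree

Network-free, rule-based stochastic reaction–diffusion simulation on
triangulated meshes.

Biochemical signaling in cells happens in small, spatially organized
volumes — membranes, scaffolds, organelles — where copy numbers are low
and well-mixed continuum models break down.  `netfree` is a desk-scale
Monte Carlo simulator for this regime, written for modelers who want to
run a rule-based (BNGL) model *spatially resolved*: volume molecules are
point particles diffusing by Brownian dynamics inside triangulated
meshes, membrane molecules live on area-filling barycentric grid tiles
(one molecule per tile), and chemistry is resolved network-free by graph
rewriting, so combinatorially explosive models (multi-subunit complexes,
polymers) never require enumerating their reaction network.

## The model

Molecules are graphs: elementary molecules carry components (binding
sites) with optional states; bonds join components.  A reaction rule is
a graph transformation with rate constant k.  Each iteration (time step
Δt, default 1 μs) a volume molecule takes a Gaussian step (variance
2DΔt per axis) and reacts with partners found within the interaction
radius r_int along its trajectory with per-collision probability

    p = k·Δt / (π·r_int²·(ℓ̄_A + ℓ̄_B)),        ℓ̄ = √(16DΔt/π),

which recovers mass action k/V in the well-mixed limit; analogous
calibrated probabilities govern volume–surface (per wall-tile hit) and
surface–surface (per adjacent-tile encounter) reactions, and
unimolecular reactions fire as exponential clocks.  Species and the
reactions applicable to a colliding pair are computed on demand, cached
with canonical graph labels, and evicted when no instances remain.
Hierarchical compartments (`@EC`, `@PM`, `@CP`, and the generic classes
`@IN`/`@OUT` for volume+surface rules) map onto meshes; a bounded network
expansion plus built-in ODE/SSA oracles support validation against
well-mixed solvers, and a hybrid coupling API lets a species be carried
as a continuous copy number updated each iteration.

See `docs/methods.md` for the full scheme, calibration constants, and
limitations.

## Worked example

`A + B -> C` with 100 copies of each in a 1 μm³ compartment:

```python
from netfree.model import load_bngl_into_model
from netfree.spatial import SimulationConfig

bngl = """
begin parameters
  k_on 1.66            # um^3/N/s  (~1e9 M^-1 s^-1)
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_B 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_C 1e-6
end parameters
begin molecule types
  A()
  B()
  C()
end molecule types
begin compartments
  CP 3 1.0
end compartments
begin seed species
  @CP:A() 100
  @CP:B() 100
end seed species
begin observables
  Molecules C_made C()
end observables
begin reaction rules
  bind: A() + B() -> C() k_on
end reaction rules
"""

bundle = load_bngl_into_model(bngl, "all",
                              config=SimulationConfig(iterations=2000,
                                                      seed=1))
world = bundle.make_world()
world.run()
print(f"t = {world.time*1e3:.1f} ms   C = {world.count_rows[-1][0]:.0f}")
```

prints

```
t = 2.0 ms   C = 26
```

— 26 of 100 possible C after 2 ms, matching the mass-action prediction
C(t) = A₀·k_pair·A₀·t/(1 + k_pair·A₀·t) ≈ 24.9 for k_pair = k/V =
1.66 s⁻¹ at t = 2 ms.  Two runs with the same seed give byte-identical
output.

The same model runs from the shell:

```
netfree run run.yaml --seed 1 --out out/      # writes out/counts.gdat
netfree run run.yaml --export-bngl model.bngl # canonical BNGL back out
netfree run run.yaml --expand-network         # concrete reaction list
```

where `run.yaml` names the BNGL file and the run configuration
(iterations, time step, grid density, seed, optional compartment→OBJ
mesh mapping).

## Bundled validation fixtures

`netfree.validation` ships runnable fixtures with the geometry and
configuration wired up: a well-mixed mass-action calibration box; a
dual-Ca²⁺-sensor vesicle-release model (36 sensor states, 126 concrete
reactions from ten rules); a membrane-localization model (volume
partners stabilized by binding a membrane lipid); a bistable kinase
autophosphorylation circuit that switches stochastically between its two
deterministic steady states; an activator–repressor gene oscillator in
pure-particle and hybrid (continuous repressor) variants; and structural
fixtures for species-selective walls and network-free handling of a
combinatorially explosive ring complex.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-derives the headline count from scratch: it parses the bundled
dual-Ca-sensor BNGL model, runs the bounded network expansion from the
seed species, and reports the number of deduplicated concrete reactions
together with the size of the expanded system.
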