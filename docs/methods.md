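# Methods

`netfree` is a particle-based stochastic reaction–diffusion simulator
with native rule-based chemistry.  Volume molecules are points diffusing
by Brownian dynamics inside triangulated meshes; surface (membrane)
molecules occupy barycentric grid tiles; chemistry is written in BNGL and
resolved *network-free*: products of a colliding pair are computed by
graph rewriting when the pair first meets, cached, and periodically
evicted, so the reaction network is never enumerated up front.

## Rule-based chemistry

A complex is an undirected bipartite graph of elementary molecules and
components (binding sites with optional states).  Species identity is a
canonical label computed by partition refinement plus
individualization–refinement search over residual symmetry, taking the
lexicographically smallest serialization.  This is exact (label equality
⇔ graph isomorphism, cross-checked against a VF2 oracle in the tests) and
handles vertex-transitive cases such as a dodecameric kinase ring in
milliseconds; a leaf-count guard (20 000) catches pathological symmetry.

Rules are interpreted once into a graph diff (state changes, bond
create/delete, molecule create/delete) by the BioNetGen correspondence
convention: molecules map between reactant and product patterns by name
in order of appearance, components by name in order of listing.  Each
embedding of the reactant patterns that is distinct modulo *pattern*
automorphisms contributes one reaction pathway at the rule's full rate
constant (direct-evaluation convention; no symmetry-factor division).
For the expanded-network utility, concrete reactions are merged by
(reactants, products) with rates summed across contributing rules and
embeddings — the form a mass-action network requires.  With that
convention the bundled dual-Ca-sensor model (ten rules, three molecule
types) expands to exactly 36 sensor states and 126 concrete reactions;
its three release channels (spontaneous, synchronous from the 5-Ca
synchronous site, asynchronous from the 2-Ca asynchronous site) produce
overlapping state transitions that a per-rule count would tally as 135.

Identical reactant pairs use the pair-counting convention: a per-pair
stochastic rate c gives propensity c·N(N−1)/2 (deterministic limit
c·x²/2) in the oracles; the spatial engine tests each unordered colliding
pair once, which is the same convention.

Reversible rules split into two unidirectional rules at parse time.
Parameter arithmetic supports `+ − * / ^` and parentheses; BNGL
*functions* are rejected as unsupported.  Diffusion constants ride along
as parameters named `MCELL_DIFFUSION_CONSTANT_3D_<type>` /
`..._2D_<type>` (cm²/s); a 2D constant marks a surface molecule type.

Complex diffusion constants derive from subunits: any zero-D subunit pins
the complex at D = 0; any surface subunit makes the complex a surface
complex and only surface subunits enter the combining rule.  Combining
rules (effective radius ∝ 1/D, volumes/areas additive):
D = (Σ Dᵢ⁻³)^(−1/3) for volume complexes, (Σ Dᵢ⁻²)^(−1/2) over surface
subunits for surface complexes.  The exact exponents are a design choice;
they satisfy the qualitative constraints (monomer identity, monotone
decrease with size, zero-D propagation) and are unit-tested as such.

## Units

Internal rate units are μm³·N⁻¹s⁻¹ for all bimolecular contexts and s⁻¹
for unimolecular ones.  Two user-facing conventions are converted at the
boundary: `MCELL_DEFAULT` (vol–vol and vol–surf in M⁻¹s⁻¹ via
10¹⁵/N_A ≈ 1.6605×10⁻⁹; surf–surf in μm²·N⁻¹s⁻¹ via the 10 nm
thin-membrane thickness) and `BNG` (everything already in μm³·N⁻¹s⁻¹).
Conversions are mutually inverse.

## The Monte Carlo step

Each iteration executes ReleaseEvent → DiffuseReactEvent →
MolRxnCountEvent → VizOutputEvent.  Counts are therefore end-of-iteration
values; an initial row is recorded at t = 0 after the first releases.
A single seeded 64-bit PCG64 stream drives everything: identical (model,
seed, configuration) reproduces output byte-for-byte, and cache cleanup
intervals provably never touch the stream (asserted by test).

**Volume step.**  Each molecule takes an isotropic Gaussian step
(variance 2DΔt per axis).  Reaction partners are molecules whose
perpendicular distance to the displacement segment is ≤ r_int with the
projection inside the segment — a pure cylinder of volume π·r_int²·ℓ, so
the per-collision probability

    p_vv = k·Δt / (π·r_int² · (ℓ̄_A + ℓ̄_B)),     ℓ̄ = √(16DΔt/π)

recovers the per-pair mass-action rate k/V exactly in the well-mixed
dilute limit (both partners move, so both orderings together sweep
ℓ̄_A + ℓ̄_B).  Candidates are tested in order of distance along the
trajectory; at most one reaction per moving molecule per step; products
appear at the collision point.  Wall hits are processed in distance order
interleaved with partner testing, including along post-reflection
segments (omitting those produced a measurable ~10% undercount near
walls).  When all candidates of a segment belong to one reaction class
the Bernoulli sequence is drawn as a single geometric variate
(statistically identical, one RNG draw).  Default
r_int = 1/√(π·σ) ties the volume collision cross-section to one surface
tile's nominal area.

Surface classes give per-species wall behavior — reflective (default for
compartment boundaries), transparent (crossing updates the molecule's
compartment), absorptive — assignable to whole meshes or named triangle
regions.  Axis-aligned boxes are detected and use analytic slab
intersections and displacement folding instead of mesh ray casts.

**Volume–surface.**  A wall hit on an occupied tile attempts a reaction
with

    p_vs = k·Δt / (A_tile · √(D·Δt/π)),

calibrated from the expected number of one-way plane crossings of a
Gaussian step (molecules at density n strike unit area n·√(DΔt/π) times
per Δt).  The provisional extra factor 4 in the specification draft did
not survive the prescribed mass-action calibration; the form above agrees
with the well-mixed oracle within 5% (the residual mid-course dip of
~4% is the physical near-wall depletion layer).  Volume products are
placed ε off the wall on the side selected by the product species'
compartment (inner compartment for a molecule released into the enclosed
volume); surface products take the freed reactant tile, else the nearest
vacant adjacent tile (error when none).

**Surface–surface.**  A surface molecule's 2D Gaussian step is unfolded
across triangle edges (rotation about the shared edge); fence regions and
mesh boundaries reflect; a move onto an occupied tile is rejected (the
molecule stays put) — the only volume exclusion in the model.  The
edge-adjacent occupants of the final tile are reaction partners with

    p_ss = k₂D·Δt / (2 · 2.85 · A_tile).

The nominal neighborhood factor is 3 (three edge-adjacent tiles, both
partners moving gives the 2); the calibrated effective value 2.85
accounts for boundary tiles with fewer reachable neighbors and for
encounter correlation of sub-tile steps, and was fixed once against the
well-mixed surface oracle (final accuracy −3…−5%, inside the 10% band).

**Unimolecular events** are exponential clocks (total cached pathway
rate), executed in time order at the start of the DiffuseReact event,
with pathway choice proportional to rate.  Clocks are redrawn on species
change and on mid-run rate updates (memoryless, so redrawing is exact).

p > 1 configurations are recorded per rule and the run-end report gives
the estimated missed-reaction fraction Σ(p−1)⁺ / Σp over collision tests.

## Geometry

Meshes are numpy vertex/triangle arrays with CCW-outward winding;
validation reports open edges, winding inconsistencies and degenerate
triangles (area ≤ 10⁻¹² μm²).  Ray casting is vectorized
Möller–Trumbore with ε = 10⁻¹² and lowest-triangle-index tie-breaking for
edge grazing; containment is crossing parity along a fixed
irrational-direction ray (surface points count inside).  The barycentric
grid subdivides a triangle of area A into n² congruent tiles with
n = ⌈√(A·σ)⌉ (the rounding rule is a documented choice; realized density
is always ≥ σ).  Tiles are strip-major indexed; adjacency includes
cross-triangle neighbors matched by overlapping edge intervals (robust to
differing n).  OBJ I/O covers `v`/`f`/`g` records, triangles only;
normals are recomputed from winding.

## BNGL import/export and compartments

`load_bngl_into_model` builds a runnable bundle from any subset of the
sections.  3D compartments become axis-aligned boxes of matching
enclosed volume (nested per the 2D/3D hierarchy) unless an explicit mesh
is supplied, in which case the mesh volume must match the declared
compartment size within 1%.  Seed species become volume or surface-count
releases.  Export back to BNGL is best-effort: spatial-only features
(mesh releases, point releases, fences) are reported as warnings, never
silently dropped.  The @IN/@OUT compartment classes are resolved per
reaction class at lookup time from the membrane compartment of the
surface reactant (only volume+surface bimolecular rules may use them).
Volume products of membrane reactions default to the compartment inside
the membrane unless annotated.

## Well-mixed oracles

`expand_network` (bounded fixed-point expansion) feeds two independent
oracles: a stiff-safe LSODA mass-action ODE integrator and an exact
Gillespie direct-method SSA, both using the thin-volume convention for
membranes (area × 10 nm).  They validate the spatial engine; the spatial
engine never calls them.

## Fixtures: what they emulate and what they do not

All fixture rate constants are synthetic but of literature-plausible
magnitude; state/reaction counts of the rule systems are
rate-independent.  The fixtures run in small boxes (0.25–0.5 μm) at
elevated rates so that the graded test suite finishes on one CPU; they
emulate the *mechanisms* (cooperative Ca binding, membrane localization,
bistable switching, transcriptional oscillation), not any measured cell.
A green test therefore establishes that the algorithms reproduce the
correct statistical mechanics at fixture scale — not that any biological
parameter set is reproduced.

* `wellmixed_abc` — A+B→C, 100+100 molecules, 0.5 μm box, D = 10⁻⁵
  cm²/s: the mass-action calibration standard (64-seed mean within 2% of
  the ODE at half-consumption).
* `snare` — dual-Ca-sensor vesicle-release model: 5 reversible
  synchronous Ca-binding rules, 2 asynchronous, spontaneous/synchronous/
  asynchronous release; 36 states (18 docked), 126 reactions.
* `membrane_localization` — volume partners bind a membrane lipid and
  dimerize in 2D.  Desk scale: 0.47×0.47×0.5 μm box (the published
  geometry uses a 5 μm-tall box), 80 copies per species, slow surface
  diffusion so 2D dimerization is diffusion-limited — which is exactly
  why the spatial result diverges from the well-mixed ODE (the test
  takes the direction of the gap from the oracle, not by assumption).
* `autophosphorylation` — kinase with positive feedback
  (trans-autophosphorylation) and a saturable phosphatase: bistable ODE
  (steady states ≈ 0.5 and ≈ 90 of 120), stochastic switching at
  particle numbers.  With the per-collision probability of phosphatase
  binding at ≈ 0.6, the diffusion-limited correction shortens the
  low-state dwell relative to the well-mixed SSA; the qualitative
  two-state structure is unaffected.
* `clock_particle` / `clock_hybrid` — activator–repressor oscillator
  (single gene copies, explicit mRNAs, A sequestered by R).  The
  published desk scaling (rates ×3600, volume ÷268, Δt = 10⁻⁷ s,
  1024 seeds) implies ~10¹³ particle-steps — far beyond a pure-Python
  budget — so the fixture applies a further documented reduction:
  concentrations ÷30 (transcription ÷s, bimolecular ×s), promoter and
  sequestration kinetics slowed (÷3; sequestration ÷90 so the hybrid
  pseudo-first-order channel satisfies γ_C·R·Δt < 1, the explicit-Euler
  stability premise), time compressed to a ~5–6 ms period, Δt = 4 μs,
  r_int = 0.1 μm, box 0.25 μm.  Hybrid coupling per iteration: (1) one
  particle iteration, (2) explicit-Euler update of the continuous R from
  β_R·MR − δ_R·R plus the discrete A→C / C-decay event counts (each
  consumes/releases one R; R < 0 clamps to 0 with a warning), (3) the
  A→C rate reset to γ_C·R(t).  The Euler step equals the particle Δt.
* `psd_spine` — spine-head box with a PSD slab reflective to kinase but
  transparent to Ca (species-selective surface classes).
* `camkii_ring` — a dodecameric ring type with ~2¹² ring states,
  exercised network-free: the species cache stays far below the
  combinatorial bound while chemistry proceeds.

## Oscillation statistics

Peak times are extracted by zero-phase moving-average smoothing (window
= 1/5 of the expected period; reflected ends) followed by local-maxima
detection with prominence ≥ 20% of the smoothed range (10% default in
the API; the clock analyses use 20% to suppress shot-noise peaks at low
copy number).  The hybrid-vs-SSA acceptance check compares ensemble mean
peak times per peak index (first three peaks, 64 seeds each) within one
SSA-ensemble SD.

## Known limitations

* Volume molecules have no excluded volume; surface exclusion is one
  molecule per tile.
* Partner positions are sampled at iteration start for the batched
  candidate search; within-iteration partner motion is ignored (no
  measurable bias in the calibration suite).
* High-probability regimes (p ≳ 0.6) shorten diffusion-limited waiting
  times; the p > 1 warning and missed-fraction report flag the extreme
  cases but moderate-p bias is the user's to manage via Δt.
* Transcellular/transmembrane reactions between separate membranes,
  checkpointing, MDL compatibility and dynamic geometry are out of
  scope.
* The slow-diffusion clock ordering (pure particle faster than hybrid
  faster than SSA at D = 10⁻⁷ cm²/s) is not asserted by the test suite:
  at desk scale the required slow-diffusion ensembles exceed the
  single-CPU budget by an order of magnitude.
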