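"""The Monte Carlo core: World state and the per-iteration event loop.

Each iteration executes, in fixed order: ReleaseEvent → DiffuseReactEvent
→ MolRxnCountEvent → VizOutputEvent.  Volume molecules take Gaussian
steps and test reaction partners within the interaction radius along
their trajectory (distance-ordered, at most one reaction per mover per
step); wall hits are processed in distance order with per-species surface
classes or volume-surface reactions; surface molecules hop on grid tiles
with volume exclusion.  A single seeded 64-bit RNG stream drives the
whole world, so identical (model, seed, config) gives identical output.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np

from ..bngl.types import BnglError, BnglModel, ComplexGraph, Observable
from ..engine.matching import count_embeddings
from ..engine.network import Pathway, RuleEngine, Species
from ..geometry import EPSILON, first_hit, ray_mesh_intersections
from ..surfgrid import tile_surface
from ..units import SURF_SURF, UNI, VOL_SURF, VOL_VOL, BNG, MCELL_DEFAULT, \
    MEMBRANE_THICKNESS_UM
from .config import SimulationConfig
from .objects import (ABSORPTIVE, REFLECTIVE, TRANSPARENT,
                      CallbackRegistration, ReleaseSite, SpatialObject,
                      SurfacePlacementError)
from .probability import (CM2_TO_UM2, reaction_probability_ss,
                          reaction_probability_vs, reaction_probability_vv)
from .surface import barycentric_of_point, surface_walk, triangle_basis

__all__ = ["World", "VolumeMolecule", "SurfaceMolecule"]


class VolumeMolecule:
    __slots__ = ("id", "species_key", "pos", "next_unimol")

    def __init__(self, mid: int, species_key: str, pos: np.ndarray,
                 next_unimol: Optional[float] = None):
        self.id = mid
        self.species_key = species_key
        self.pos = pos
        self.next_unimol = next_unimol


class SurfaceMolecule:
    __slots__ = ("id", "species_key", "object_name", "triangle", "tile",
                 "pos", "bary", "next_unimol")

    def __init__(self, mid: int, species_key: str, object_name: str,
                 triangle: int, tile: int, pos: np.ndarray,
                 bary: Optional[np.ndarray] = None,
                 next_unimol: Optional[float] = None):
        self.id = mid
        self.species_key = species_key
        self.object_name = object_name
        self.triangle = triangle
        self.tile = tile
        self.pos = pos
        self.bary = bary
        self.next_unimol = next_unimol


class World:
    """All molecule instances, geometry, caches, scheduler and RNG state."""

    def __init__(self, model: BnglModel, config: SimulationConfig,
                 objects: Iterable[SpatialObject] = (),
                 releases: Iterable[ReleaseSite] = (),
                 observables: Optional[Sequence[Observable]] = None):
        self.model = model
        self.config = config
        self.engine = RuleEngine(model)
        self.units = BNG if config.rate_units == "BNG" else MCELL_DEFAULT
        self.rng = np.random.default_rng(config.seed)
        self.objects: dict[str, SpatialObject] = {}
        for obj in objects:
            self.add_object(obj)
        self.releases: list[ReleaseSite] = list(releases)
        self.observables: list[Observable] = list(
            observables if observables is not None else model.observables)

        self.volume_molecules: dict[int, VolumeMolecule] = {}
        self.surface_molecules: dict[int, SurfaceMolecule] = {}
        self._next_id = 0
        self.iteration = 0
        self.time = 0.0

        self.rxn_counts: dict[str, int] = {}
        self.count_times: list[float] = []
        self.count_rows: list[list[float]] = []
        self._released: set[int] = set()  # release sites already executed

        self._reaction_callbacks: list[CallbackRegistration] = []
        self._wall_callbacks: list[CallbackRegistration] = []
        # rule name -> [events, sum p, sum excess(p-1)]
        self.probability_warnings: dict[str, list[float]] = {}

        self._tested_mass = 0.0
        self._missed_mass = 0.0
        self._vv_cache: dict[tuple[str, str], tuple] = {}
        self._vs_cache: dict[tuple, tuple] = {}
        self._ss_cache: dict[tuple, tuple] = {}
        self._uni_cache: dict[str, tuple] = {}
        self._emb_cache: dict[tuple, int] = {}
        self._mnames_cache: dict[str, set[str]] = {}
        self._fence_cache: dict[tuple, tuple] = {}

    # ------------------------------------------------------------------
    # setup
    # ------------------------------------------------------------------

    def add_object(self, obj: SpatialObject) -> SpatialObject:
        if obj.name in self.objects:
            raise ValueError(f"duplicate geometry object {obj.name}")
        if obj.grid is None and self._object_needs_grid(obj):
            obj.grid = tile_surface(obj.mesh, self.config.surface_grid_density)
        if obj.box_data is None:
            obj.detect_box()
        self.objects[obj.name] = obj
        return obj

    def _object_needs_grid(self, obj: SpatialObject) -> bool:
        if obj.compartment_2d is not None:
            return True
        return any(self.engine.types[name].is_surface
                   for name in self.engine.types)

    def register_callback(self, registration: CallbackRegistration) -> int:
        """Register a reaction or wall-hit callback; returns a handle."""
        if registration.kind == "reaction":
            names = set(registration.rule_names or ())
            known = {r.name for r in self.engine.rules}
            missing = names - known
            if missing:
                raise BnglError(f"unknown rule name(s) {sorted(missing)} "
                                "in callback registration")
            self._reaction_callbacks.append(registration)
            return len(self._reaction_callbacks) - 1
        if registration.kind == "wall_hit":
            if registration.object_name not in self.objects:
                raise BnglError(f"unknown geometry object "
                                f"{registration.object_name!r}")
            if registration.region is not None:
                self.objects[registration.object_name].mesh.region_triangles(
                    registration.region)
            self._wall_callbacks.append(registration)
            return len(self._wall_callbacks) - 1
        raise ValueError(f"unknown callback kind {registration.kind!r}")

    def set_unimolecular_rate(self, rule_name: str, k: float) -> None:
        """Change a unimolecular rule's rate constant mid-run (hybrid
        coupling hook).  Only the reaction classes containing the rule are
        rebuilt, and only molecules of affected species are rescheduled
        (exponential clocks are memoryless, so redrawing is exact)."""
        from dataclasses import replace as _replace
        found = False
        changed = False
        for r in self.engine.rules:
            if r.name == rule_name:
                if r.arity() != 1:
                    raise BnglError(f"rule {rule_name} is not unimolecular")
                if r.rate != k:
                    changed = True
                r.rate = k
                found = True
        if not found:
            raise BnglError(f"unknown rule {rule_name!r}")
        if not changed:
            return
        affected: set[str] = set()
        for key, rc in self.engine._unimol.items():
            if any(pw.rule_name == rule_name for pw in rc.pathways):
                rc.pathways = [
                    _replace(pw, rate=k) if pw.rule_name == rule_name
                    else pw for pw in rc.pathways]
                affected.add(key)
        for key in list(self._uni_cache):
            if key in affected:
                del self._uni_cache[key]
        for mol in self.volume_molecules.values():
            if mol.species_key in affected:
                mol.next_unimol = self._schedule_unimolecular(
                    mol.species_key)
        for mol in self.surface_molecules.values():
            if mol.species_key in affected:
                mol.next_unimol = self._schedule_unimolecular(
                    mol.species_key)

    # ------------------------------------------------------------------
    # molecule bookkeeping
    # ------------------------------------------------------------------

    def _intern(self, graph: ComplexGraph,
                compartment: Optional[str] = None) -> Species:
        return self.engine.intern_species(graph, compartment)

    def _schedule_unimolecular(self, key: str) -> Optional[float]:
        pathways, cum, k_tot = self._uni_pathways(key)
        if k_tot <= 0.0:
            return None
        return self.time + self.rng.exponential(1.0 / k_tot)

    def _uni_pathways(self, key: str):
        hit = self._uni_cache.get(key)
        if hit is None:
            sp = self.engine.species[key]
            pws = self.engine.lookup_unimolecular(sp).pathways
            rates = np.array([self.units.to_internal(p.rate, UNI)
                              for p in pws])
            cum = np.cumsum(rates)
            k_tot = float(cum[-1]) if len(cum) else 0.0
            hit = (pws, cum, k_tot)
            self._uni_cache[key] = hit
        return hit

    def add_volume_molecule(self, species: Species | str,
                            pos) -> VolumeMolecule:
        key = species if isinstance(species, str) else species.key
        sp = self.engine.species[key]
        if sp.is_surface:
            raise BnglError(f"{key} is a surface species")
        mid = self._next_id
        self._next_id += 1
        mol = VolumeMolecule(mid, key, np.asarray(pos, dtype=float))
        mol.next_unimol = self._schedule_unimolecular(key)
        self.volume_molecules[mid] = mol
        sp.count += 1
        return mol

    def add_surface_molecule(self, species: Species | str, object_name: str,
                             tile: int) -> SurfaceMolecule:
        key = species if isinstance(species, str) else species.key
        sp = self.engine.species[key]
        obj = self.objects[object_name]
        assert obj.grid is not None
        mid = self._next_id
        self._next_id += 1
        tri, i, j, k, up = obj.grid.coords_of(tile)
        n = int(obj.grid.subdivisions[tri])
        off = 1.0 / 3.0 if up else 2.0 / 3.0
        bary = (np.array([i, j, k], dtype=float) + off) / n
        a, b, c = obj.grid.mesh.corners()
        pos = bary[0] * a[tri] + bary[1] * b[tri] + bary[2] * c[tri]
        mol = SurfaceMolecule(mid, key, object_name, tri, tile, pos, bary)
        obj.grid.place(tile, mid)
        mol.next_unimol = self._schedule_unimolecular(key)
        self.surface_molecules[mid] = mol
        sp.count += 1
        return mol

    def remove_molecule(self, mid: int) -> None:
        mol = self.volume_molecules.pop(mid, None)
        if mol is None:
            smol = self.surface_molecules.pop(mid)
            self.objects[smol.object_name].grid.vacate(smol.tile)
            self.engine.species[smol.species_key].count -= 1
        else:
            self.engine.species[mol.species_key].count -= 1

    def molecule_count(self, key: str) -> int:
        sp = self.engine.species.get(key)
        return sp.count if sp else 0

    # ------------------------------------------------------------------
    # observables
    # ------------------------------------------------------------------

    def _embeddings_in(self, obs_idx: int, pattern: ComplexGraph,
                       sp: Species) -> int:
        k = (obs_idx, sp.key)
        hit = self._emb_cache.get(k)
        if hit is None:
            if pattern.compartment is not None and \
                    pattern.compartment != sp.compartment:
                hit = 0
            else:
                hit = count_embeddings(pattern, sp.graph)
            self._emb_cache[k] = hit
        return hit

    def count_observable(self, obs: Observable) -> float:
        total = 0
        idx = id(obs)
        for sp in self.engine.species.values():
            if sp.count == 0:
                continue
            for pi, pattern in enumerate(obs.patterns):
                n = self._embeddings_in((idx, pi), pattern, sp)
                if n == 0:
                    continue
                if obs.kind == "Species":
                    total += sp.count
                    break
                total += n * sp.count
        return float(total)

    def observable_values(self) -> list[float]:
        return [self.count_observable(o) for o in self.observables]

    def observable_names(self) -> list[str]:
        return [o.name for o in self.observables]

    # ------------------------------------------------------------------
    # releases
    # ------------------------------------------------------------------

    def _do_releases(self) -> None:
        t_hi = self.time + self.config.time_step
        for si, site in enumerate(self.releases):
            if si in self._released:
                continue
            if site.time <= self.time + 1e-18 or \
                    (self.time < site.time < t_hi):
                self.release_molecules(site)
                self._released.add(si)

    def release_molecules(self, site: ReleaseSite) -> list[int]:
        sp = self._intern(site.graph, site.compartment)
        created: list[int] = []
        if site.shape == "points":
            assert site.points is not None
            for p in np.atleast_2d(site.points):
                created.append(self.add_volume_molecule(sp, p).id)
            return created
        obj = self.objects[site.object_name]
        if site.shape == "volume":
            n = int(round(site.amount))
            for p in self._sample_in_mesh(obj, n):
                created.append(self.add_volume_molecule(sp, p).id)
            return created
        # surface releases
        grid = obj.grid
        assert grid is not None
        tris = obj.mesh.region_triangles(site.region)
        if site.shape == "surface_density":
            area = float(obj.mesh.areas()[tris].sum())
            n = int(round(site.amount * area))
        else:
            n = int(round(site.amount))
        vacant = grid.vacant_tiles(tris)
        if n > len(vacant):
            raise SurfacePlacementError(
                f"release {site.name}: {n} molecules exceed {len(vacant)} "
                f"vacant tiles on region {site.region or 'whole mesh'} of "
                f"{obj.name}")
        chosen = self.rng.choice(len(vacant), size=n, replace=False)
        for tile in np.sort(vacant[chosen]):
            created.append(
                self.add_surface_molecule(sp, obj.name, int(tile)).id)
        return created

    def _sample_in_mesh(self, obj: SpatialObject, n: int) -> np.ndarray:
        lo, hi = obj.mesh.bounds()
        out = np.empty((n, 3))
        have = 0
        while have < n:
            batch = self.rng.random((max(2 * (n - have), 16), 3)) \
                * (hi - lo) + lo
            if obj.convex and _is_box(obj):
                ok = np.ones(len(batch), dtype=bool)
            else:
                ok = np.array([point_in(obj, p) for p in batch])
            good = batch[ok]
            take = min(len(good), n - have)
            out[have:have + take] = good[:take]
            have += take
        return out

    # ------------------------------------------------------------------
    # probability caches
    # ------------------------------------------------------------------

    def _vv_probs(self, key_a: str, key_b: str):
        """(pathways, p array, cumulative p) for a volume-volume pair."""
        cache_key = (key_a, key_b) if key_a <= key_b else (key_b, key_a)
        hit = self._vv_cache.get(cache_key)
        if hit is None:
            sa = self.engine.species[cache_key[0]]
            sb = self.engine.species[cache_key[1]]
            pws = self.engine.lookup_or_expand(sa, sb).pathways
            da = self.engine.diffusion_of(sa)
            db = self.engine.diffusion_of(sb)
            ps = []
            for pw in pws:
                k = self.units.to_internal(pw.rate, VOL_VOL)
                p = reaction_probability_vv(
                    k, da, db, self.config.interaction_radius,
                    self.config.time_step)
                ps.append(p)
                self._note_probability(pw.rule_name, p)
            ps = np.array(ps)
            hit = (pws, ps, np.cumsum(ps) if len(ps) else np.array([]))
            self._vv_cache[cache_key] = hit
        return hit

    def _vs_probs(self, vol_key: str, surf_key: str, tile_area: float):
        ck = (vol_key, surf_key, round(tile_area, 15))
        hit = self._vs_cache.get(ck)
        if hit is not None:
            return hit
        sa = self.engine.species[vol_key]
        sb = self.engine.species[surf_key]
        pws = self.engine.lookup_or_expand(sa, sb).pathways
        d_vol = self.engine.diffusion_of(sa)
        ps = []
        for pw in pws:
            k = self.units.to_internal(pw.rate, VOL_SURF)
            p = reaction_probability_vs(k, d_vol, tile_area,
                                        self.config.time_step)
            ps.append(p)
            self._note_probability(pw.rule_name, p)
        ps = np.array(ps)
        hit = (pws, ps, (np.cumsum(ps) if len(ps) else np.array([])))
        self._vs_cache[ck] = hit
        return hit

    def _ss_probs(self, key_a: str, key_b: str, tile_area: float):
        ck = (key_a, key_b, round(tile_area, 15))
        hit = self._ss_cache.get(ck)
        if hit is not None:
            return hit
        sa = self.engine.species[key_a]
        sb = self.engine.species[key_b]
        pws = self.engine.lookup_or_expand(sa, sb).pathways
        ps = []
        for pw in pws:
            k2d = self.units.to_internal(pw.rate, SURF_SURF) \
                / MEMBRANE_THICKNESS_UM
            p = reaction_probability_ss(k2d, tile_area, self.config.time_step)
            ps.append(p)
            self._note_probability(pw.rule_name, p)
        ps = np.array(ps)
        hit = (pws, ps, (np.cumsum(ps) if len(ps) else np.array([])))
        self._ss_cache[ck] = hit
        return hit

    def _note_probability(self, rule_name: str, p: float) -> None:
        rec = self.probability_warnings.setdefault(rule_name, [0, 0.0, 0.0])
        if p > self.config.probability_warning:
            rec[0] += 1
        rec[1] = max(rec[1], p)

    def _note_collision(self, cum_p: float) -> None:
        self._tested_mass += cum_p
        if cum_p > 1.0:
            self._missed_mass += cum_p - 1.0

    def missed_reaction_report(self) -> dict:
        """p>1 warnings and the estimated fraction of missed reactions."""
        tested = self._tested_mass
        missed = self._missed_mass
        return {
            "rules_over_threshold": {
                name: {"events_over": int(rec[0]), "max_p": rec[1]}
                for name, rec in self.probability_warnings.items()
                if rec[0] > 0 or rec[1] > self.config.probability_warning},
            "estimated_missed_fraction":
                (missed / tested) if tested > 0 else 0.0,
        }

    # ------------------------------------------------------------------
    # reaction execution
    # ------------------------------------------------------------------

    def _fire_callbacks(self, rule_name: str, position: np.ndarray) -> None:
        for reg in self._reaction_callbacks:
            if reg.rule_names is None or rule_name in reg.rule_names:
                reg.fn(self.time, rule_name, np.array(position), reg.context)

    def _execute_pathway(self, pw: Pathway, consumed: list[int],
                         position: np.ndarray,
                         surface_sites: list[tuple[str, int]],
                         normal_side: float = 1.0,
                         object_name: Optional[str] = None) -> None:
        """Remove consumed molecules, create products, bump counters.

        ``surface_sites`` are (object, tile) slots freed by consumed surface
        reactants, reused for surface products.  Volume products appear at
        ``position`` (offset ε along the normal times ``normal_side`` when
        the reaction happened on a wall)."""
        freed = list(surface_sites)
        anchor = surface_sites[0] if surface_sites else None
        for mid in consumed:
            self.remove_molecule(mid)
        for key in pw.product_keys:
            sp = self.engine.ensure_species(key)
            if sp.is_surface:
                if not freed and anchor is None and object_name is None:
                    raise SurfacePlacementError(
                        f"no surface site for product {key}")
                if freed:
                    oname, tile = freed.pop(0)
                elif anchor is not None:
                    oname, tile = anchor  # place adjacent to the reactant
                else:
                    oname, tile = object_name, None  # type: ignore
                grid = self.objects[oname].grid
                if tile is None or grid.occupant(tile) is not None:
                    tile = self._nearest_vacant(oname, tile)
                self.add_surface_molecule(sp, oname, tile)
            else:
                pos = np.array(position)
                if object_name is not None or surface_sites:
                    oname = object_name or surface_sites[0][0]
                    obj = self.objects[oname]
                    tri_n = self._normal_at(obj, pos)
                    if tri_n is not None:
                        pos = pos + normal_side * 1e-9 * tri_n
                self.add_volume_molecule(sp, pos)
        self.rxn_counts[pw.rule_name] = self.rxn_counts.get(
            pw.rule_name, 0) + 1
        self._fire_callbacks(pw.rule_name, position)

    def _normal_at(self, obj: SpatialObject, pos: np.ndarray):
        # nearest triangle normal (cheap heuristic: nearest tile center not
        # needed; use closest triangle centroid)
        a, b, c = obj.mesh.corners()
        centroids = (a + b + c) / 3.0
        i = int(np.argmin(((centroids - pos) ** 2).sum(axis=1)))
        return obj.mesh.normals()[i]

    def _nearest_vacant(self, object_name: str, tile: Optional[int]) -> int:
        grid = self.objects[object_name].grid
        if tile is None:
            raise SurfacePlacementError("no tile context for surface product")
        for nb in sorted(grid.neighbors(tile)):
            if grid.occupant(nb) is None:
                return nb
        raise SurfacePlacementError(
            f"no vacant tile adjacent to {tile} on {object_name}")

    # ------------------------------------------------------------------
    # the event loop
    # ------------------------------------------------------------------

    def run_iterations(self, n: int) -> None:
        if not self.count_times:
            self._do_releases()
            self._record_counts()
        for _ in range(n):
            self._do_releases()
            self._diffuse_react()
            self.iteration += 1
            self.time = self.iteration * self.config.time_step
            self._record_counts()
            if self.config.cleanup_interval and \
                    self.iteration % self.config.cleanup_interval == 0:
                self.engine.cleanup_caches()
                self._prune_caches()

    def run(self) -> None:
        self.run_iterations(self.config.iterations)

    def _record_counts(self) -> None:
        if self.iteration % self.config.output_cadence == 0:
            self.count_times.append(self.time)
            self.count_rows.append(self.observable_values())

    def _prune_caches(self) -> None:
        live = set(self.engine.species)
        for cache in (self._uni_cache,):
            for k in [k for k in cache if k not in live]:
                del cache[k]
        for k in [k for k in self._vv_cache
                  if k[0] not in live or k[1] not in live]:
            del self._vv_cache[k]

    def _diffuse_react(self) -> None:
        self._unimolecular_pass()
        self._volume_pass()
        self._surface_pass()

    # -- unimolecular ---------------------------------------------------

    def _unimolecular_pass(self) -> None:
        t_end = self.time + self.config.time_step
        due = []
        for mid, mol in self.volume_molecules.items():
            if mol.next_unimol is not None and mol.next_unimol <= t_end:
                due.append((mol.next_unimol, mid))
        for mid, mol in self.surface_molecules.items():
            if mol.next_unimol is not None and mol.next_unimol <= t_end:
                due.append((mol.next_unimol, mid))
        for _, mid in sorted(due):
            self._execute_unimolecular(mid)

    def _execute_unimolecular(self, mid: int) -> None:
        if mid in self.volume_molecules:
            mol = self.volume_molecules[mid]
            surface_sites: list[tuple[str, int]] = []
            object_name = None
            position = mol.pos
        elif mid in self.surface_molecules:
            smol = self.surface_molecules[mid]
            surface_sites = [(smol.object_name, smol.tile)]
            object_name = smol.object_name
            position = smol.pos
            mol = smol
        else:
            return  # consumed earlier this iteration
        pws, cum, k_tot = self._uni_pathways(mol.species_key)
        if k_tot <= 0.0:
            mol.next_unimol = None
            return
        u = self.rng.random() * k_tot
        idx = int(np.searchsorted(cum, u, side="right"))
        idx = min(idx, len(pws) - 1)
        # products of a membrane-bound reactant: volume products go to the
        # compartment side encoded in the product species (inner = -normal)
        side = 1.0
        if object_name is not None:
            side = self._volume_side(pws[idx], object_name)
        self._execute_pathway(pws[idx], [mid], position, surface_sites,
                              normal_side=side, object_name=object_name)

    def _volume_side(self, pw: Pathway, object_name: str) -> float:
        obj = self.objects[object_name]
        for key in pw.product_keys:
            sp = self.engine.species[key]
            if not sp.is_surface and sp.compartment is not None:
                if sp.compartment == obj.compartment_3d:
                    return -1.0
        return 1.0

    # -- volume diffusion/reaction ---------------------------------------

    def _molecule_names(self, key: str) -> set[str]:
        names = self._mnames_cache.get(key)
        if names is None:
            names = {m.name for m in
                     self.engine.species[key].graph.molecules}
            self._mnames_cache[key] = names
        return names

    def _sigma_of(self, key: str) -> float:
        sp = self.engine.species[key]
        return math.sqrt(2.0 * self.engine.diffusion_of(sp) * CM2_TO_UM2
                         * self.config.time_step)

    def _volume_pass(self) -> None:
        if not self.volume_molecules:
            return
        ids = sorted(self.volume_molecules)
        n = len(ids)
        pos0 = np.array([self.volume_molecules[i].pos for i in ids])
        keys = [self.volume_molecules[i].species_key for i in ids]
        sigma_map = {k: self._sigma_of(k) for k in set(keys)}
        sigma = np.array([sigma_map[k] for k in keys])
        disp = self.rng.standard_normal((n, 3)) * sigma[:, None]

        # species -> rows for partner lookup
        by_species: dict[str, list[int]] = {}
        for row, k in enumerate(keys):
            by_species.setdefault(k, []).append(row)
        sp_rows = {k: np.array(v) for k, v in by_species.items()}
        reactive: dict[str, list[str]] = {}
        for ka in sorted(sp_rows):
            for kb in sorted(sp_rows):
                if kb < ka:
                    continue
                pws, ps, cum = self._vv_probs(ka, kb)
                if len(pws):
                    reactive.setdefault(ka, []).append(kb)
                    if kb != ka:
                        reactive.setdefault(kb, []).append(ka)

        r_int = self.config.interaction_radius
        r2 = r_int * r_int
        # --- batched candidate detection on the first (unreflected) segment
        cand_by_row: dict[int, list[tuple[float, int, str]]] = {}
        for ka, partners in reactive.items():
            arows = sp_rows[ka]
            starts = pos0[arows]
            dvecs = disp[arows]
            dd = np.einsum("ij,ij->i", dvecs, dvecs)
            dd_safe = np.where(dd == 0.0, 1.0, dd)
            for kb in partners:
                brows = sp_rows[kb]
                rel = pos0[brows][None, :, :] - starts[:, None, :]
                t = np.einsum("abj,aj->ab", rel, dvecs) / dd_safe[:, None]
                diff = rel - t[:, :, None] * dvecs[:, None, :]
                dist2 = np.einsum("abj,abj->ab", diff, diff)
                mask = (t >= 0.0) & (t <= 1.0) & (dist2 <= r2) \
                    & (dd[:, None] > 0.0)
                if ka == kb:
                    np.fill_diagonal(mask, False)
                ai, bi = np.nonzero(mask)
                for x, y in zip(ai, bi):
                    row = int(arows[x])
                    cand_by_row.setdefault(row, []).append(
                        (float(t[x, y]), ids[int(brows[y])], kb))

        simple_world = bool(self.objects) and all(
            o.convex and o.reflective_only() for o in self.objects.values())
        # a convex all-reflective world with no surface molecules and no
        # wall callbacks reduces to reflection off the bounding box, which
        # folds analytically (no ray casting)
        foldable = simple_world and not self.surface_molecules \
            and not self._wall_callbacks and len(self.objects) == 1 \
            and next(iter(self.objects.values())).grid is None
        box_lo = box_hi = None
        if simple_world:
            bounds = [o.mesh.bounds() for o in self.objects.values()]
            box_lo = np.max([b[0] for b in bounds], axis=0)
            box_hi = np.min([b[1] for b in bounds], axis=0)
        if simple_world:
            end_all = pos0 + disp
            needs_wall = ~(np.all(end_all > box_lo + EPSILON, axis=1)
                           & np.all(end_all < box_hi - EPSILON, axis=1))
        elif not self.objects:
            needs_wall = np.zeros(n, dtype=bool)
        else:
            needs_wall = np.ones(n, dtype=bool)

        dead: set[int] = set()
        for row in range(n):
            mid = ids[row]
            if mid in dead or mid not in self.volume_molecules:
                continue
            mol = self.volume_molecules[mid]
            start = mol.pos
            d = disp[row]
            cands = sorted(cand_by_row.get(row, ()))
            if not needs_wall[row]:
                if self._try_candidates(mol, start, d, 1.0, cands, dead):
                    continue
                mol.pos = start + d
                continue
            if foldable:
                segs = _box_polyline(start, d, box_lo, box_hi)
                reacted = False
                for si, (s0, dv) in enumerate(segs):
                    if si > 0:
                        cands = self._segment_candidates(
                            mol.species_key, s0, dv,
                            reactive.get(keys[row], ()), sp_rows, pos0,
                            ids, mid)
                    if self._try_candidates(mol, s0, dv, 1.0, cands, dead):
                        reacted = True
                        break
                if not reacted:
                    s0, dv = segs[-1]
                    mol.pos = s0 + dv
                continue
            self._walk_with_walls(mol, start, d, cands, dead,
                                  reactive.get(keys[row], ()),
                                  sp_rows, pos0, ids)

    def _try_candidates(self, mol: VolumeMolecule, start: np.ndarray,
                        d: np.ndarray, max_frac: float,
                        cands: list[tuple[float, int, str]],
                        dead: set[int]) -> bool:
        """Test partner candidates in trajectory order up to ``max_frac``;
        True when a reaction fired (the mover is consumed).

        When every candidate shares one reaction class the sequence of
        Bernoulli trials is collapsed into a single geometric draw for the
        index of the first success (statistically identical, one RNG draw
        per segment)."""
        if not cands:
            return False
        vm = self.volume_molecules
        alive = [c for c in cands
                 if c[0] <= max_frac and c[1] not in dead
                 and c[1] in vm and c[1] != mol.id]
        if not alive:
            return False
        first_pk = alive[0][2]
        if all(c[2] == first_pk for c in alive):
            pws, ps, cum = self._vv_probs(mol.species_key, first_pk)
            if not len(pws):
                return False
            ptot = float(cum[-1])
            self._tested_mass += len(alive) * ptot
            if ptot > 1.0:
                self._missed_mass += len(alive) * (ptot - 1.0)
            if ptot >= 1.0:
                k = 0
            else:
                u = self.rng.random()
                k = int(math.log(u) / math.log1p(-ptot)) if ptot > 0 \
                    else len(alive)
            if k >= len(alive):
                return False
            t_c, pid, pk = alive[k]
            if len(pws) == 1:
                idx = 0
            else:
                idx = int(np.searchsorted(cum, self.rng.random() * ptot,
                                          side="right"))
                idx = min(idx, len(pws) - 1)
            dead.add(mol.id)
            dead.add(pid)
            self._execute_pathway(pws[idx], [mol.id, pid],
                                  start + t_c * d, [])
            return True
        for t_c, pid, pk in alive:
            if pid in dead or pid not in vm:
                continue
            pws, ps, cum = self._vv_probs(mol.species_key, pk)
            u = self.rng.random()
            self._note_collision(float(cum[-1]))
            idx = int(np.searchsorted(cum, u, side="right"))
            if idx < len(pws):
                dead.add(mol.id)
                dead.add(pid)
                self._execute_pathway(pws[idx], [mol.id, pid],
                                      start + t_c * d, [])
                return True
        return False

    def _segment_candidates(self, key: str, start: np.ndarray,
                            d: np.ndarray, partner_keys,
                            sp_rows: dict[str, np.ndarray],
                            pos0: np.ndarray, ids: list[int],
                            self_id: int) -> list[tuple[float, int, str]]:
        """Candidates along one (post-reflection) segment of a mover."""
        r2 = self.config.interaction_radius ** 2
        out: list[tuple[float, int, str]] = []
        for pk in partner_keys:
            prows = sp_rows[pk]
            t, dist2 = _segment_distances(start, d, pos0[prows])
            for h in np.nonzero(dist2 <= r2)[0]:
                pid = ids[int(prows[h])]
                if pid != self_id:
                    out.append((float(t[h]), pid, pk))
        out.sort()
        return out

    def _walk_with_walls(self, mol: VolumeMolecule, start: np.ndarray,
                         d: np.ndarray,
                         first_cands: list[tuple[float, int, str]],
                         dead: set[int], partner_keys=(),
                         sp_rows: Optional[dict] = None,
                         pos0: Optional[np.ndarray] = None,
                         ids: Optional[list[int]] = None) -> None:
        """Propagate a volume molecule through wall hits in distance order,
        testing reaction partners along every sub-segment."""
        pos = start
        remaining = d
        cands = first_cands
        mnames = self._molecule_names(mol.species_key)
        for bounce in range(self.config.max_wall_bounces):
            if np.dot(remaining, remaining) == 0.0:
                break
            best = None
            for oname, obj in self.objects.items():
                if obj.box_data is not None:
                    h = _box_hit(obj, pos, remaining)
                else:
                    h = first_hit(pos, remaining, obj.mesh)
                if h is not None and (best is None
                                      or h.fraction < best[0].fraction):
                    best = (h, oname)
            if best is None:
                if self._try_candidates(mol, pos, remaining, 1.0, cands,
                                        dead):
                    return
                pos = pos + remaining
                break
            hit, oname = best
            if self._try_candidates(mol, pos, remaining, hit.fraction,
                                    cands, dead):
                return
            obj = self.objects[oname]
            tri_n = obj.mesh.normals()[hit.triangle]
            for reg in self._wall_callbacks:
                if reg.object_name != oname:
                    continue
                if reg.region is not None and hit.triangle not in set(
                        int(x) for x in
                        obj.mesh.region_triangles(reg.region)):
                    continue
                if reg.species is not None and not (mnames &
                                                    set(reg.species)):
                    continue
                reg.fn(self.time, mol.species_key, oname, hit.triangle,
                       np.array(hit.point), reg.context)
            # volume-surface reaction attempt when the tile is occupied
            if obj.grid is not None:
                tile = obj.grid.tile_at_barycentric(hit.triangle,
                                                    hit.barycentric)
                occ = obj.grid.occupant(tile)
                if occ is not None and occ in self.surface_molecules:
                    smol = self.surface_molecules[occ]
                    pws, ps, cum = self._vs_probs(
                        mol.species_key, smol.species_key,
                        obj.grid.tile_area(hit.triangle))
                    if len(pws):
                        u = self.rng.random()
                        self._note_collision(float(cum[-1]))
                        idx = int(np.searchsorted(cum, u, side="right"))
                        if idx < len(pws):
                            side = 1.0 if hit.side == "front" else -1.0
                            self._execute_pathway(
                                pws[idx], [mol.id, occ], hit.point,
                                [(oname, tile)], normal_side=side,
                                object_name=oname)
                            return
            behavior = obj.behavior_for(mnames, hit.triangle)
            frac_left = 1.0 - hit.fraction
            if behavior == ABSORPTIVE:
                self.remove_molecule(mol.id)
                return
            if behavior == TRANSPARENT:
                pos = hit.point + 1e-9 * _unit(remaining)
                remaining = frac_left * remaining
            else:
                # reflective: mirror the remaining displacement
                stay_side = tri_n if hit.side == "front" else -tri_n
                remaining = frac_left * remaining
                remaining = remaining - 2.0 * np.dot(remaining, tri_n) \
                    * tri_n
                pos = hit.point + 1e-9 * stay_side
            if sp_rows is not None and partner_keys:
                cands = self._segment_candidates(
                    mol.species_key, pos, remaining, partner_keys,
                    sp_rows, pos0, ids, mol.id)
            else:
                cands = []
        mol.pos = pos

    # -- surface diffusion/reaction --------------------------------------

    def _surface_fence(self, key: str, obj: SpatialObject):
        """(allowed triangle set, region array, cache key) for a confined
        species; cached per (species, object)."""
        cache_key = (key, obj.name)
        hit = self._fence_cache.get(cache_key)
        if hit is None:
            mnames = self._molecule_names(key)
            allowed = obj.allowed_triangles(mnames)
            if allowed is None:
                hit = (None, None, None)
            else:
                hit = (allowed, np.array(sorted(allowed)), cache_key)
            self._fence_cache[cache_key] = hit
        return hit

    def _surface_pass(self) -> None:
        if not self.surface_molecules:
            return
        from .surface import tri_step_data
        ids = sorted(self.surface_molecules)
        dead: set[int] = set()
        dt = self.config.time_step
        for mid in ids:
            if mid in dead or mid not in self.surface_molecules:
                continue
            mol = self.surface_molecules[mid]
            obj = self.objects[mol.object_name]
            grid = obj.grid
            mesh = grid.mesh
            sp = self.engine.species[mol.species_key]
            dconst = self.engine.diffusion_of(sp)
            allowed, region_arr, fence_key = self._surface_fence(
                mol.species_key, obj)
            if dconst > 0.0:
                sigma = math.sqrt(2.0 * dconst * CM2_TO_UM2 * dt)
                disp2 = self.rng.standard_normal(2) * sigma
                u, v, m3 = tri_step_data(mesh, mol.triangle)
                db = m3 @ disp2
                nb = mol.bary + db
                if nb[0] >= 0.0 and nb[1] >= 0.0 and nb[2] >= 0.0:
                    tri2 = mol.triangle
                    tile2 = grid.tile_from_bary_fast(tri2, nb[0], nb[1],
                                                     nb[2])
                    bary2 = nb
                else:
                    tri2, p2 = surface_walk(grid, mol.triangle, mol.pos,
                                            disp2, allowed)
                    bary2 = np.clip(mesh.barycentric(tri2, p2), 0.0, 1.0)
                    s = bary2.sum()
                    if s > 0:
                        bary2 = bary2 / s
                    tile2 = grid.tile_from_bary_fast(tri2, bary2[0],
                                                     bary2[1], bary2[2])
                if tile2 != mol.tile:
                    if grid.occupant(tile2) is None:
                        grid.vacate(mol.tile)
                        grid.place(tile2, mid)
                        mol.tile = tile2
                        mol.triangle = tri2
                        mol.bary = bary2
                        ca, cb, cc = mesh.corners()
                        mol.pos = bary2[0] * ca[tri2] + bary2[1] * cb[tri2] \
                            + bary2[2] * cc[tri2]
                    # occupied destination: stay at the origin tile
                else:
                    mol.bary = bary2
                    ca, cb, cc = mesh.corners()
                    mol.pos = bary2[0] * ca[tri2] + bary2[1] * cb[tri2] \
                        + bary2[2] * cc[tri2]
            # partner search: edge-adjacent occupants of the final tile
            neighbors = grid.neighbors_cached(mol.tile, fence_key,
                                              region_arr)
            occupied = [nb for nb in neighbors
                        if nb in grid.occupancy]
            if not occupied:
                continue
            for nb in sorted(occupied):
                occ = grid.occupancy.get(nb)
                if occ is None or occ == mid or occ in dead:
                    continue
                partner = self.surface_molecules.get(occ)
                if partner is None:
                    continue
                pws, ps, cum = self._ss_probs(
                    mol.species_key, partner.species_key,
                    grid.tile_area(grid.triangle_of_tile(mol.tile)))
                if not len(pws):
                    continue
                u_ = self.rng.random()
                self._note_collision(float(cum[-1]))
                idx = int(np.searchsorted(cum, u_, side="right"))
                if idx < len(pws):
                    dead.add(mid)
                    dead.add(occ)
                    self._execute_pathway(
                        pws[idx], [mid, occ], mol.pos,
                        [(mol.object_name, mol.tile),
                         (partner.object_name, partner.tile)],
                        object_name=mol.object_name)
                    break


def _box_hit(obj: SpatialObject, pos: np.ndarray, d: np.ndarray):
    """Analytic segment-box intersection (slab method) for axis-aligned
    boxes, returning the same RayHit a mesh ray cast would."""
    from ..geometry import RayHit
    lo, hi, faces = obj.box_data
    t_best, ax_best, side_best = np.inf, -1, 0
    for ax in range(3):
        dax = d[ax]
        if dax == 0.0:
            continue
        for side, plane in ((0, lo[ax]), (1, hi[ax])):
            t = (plane - pos[ax]) / dax
            if 1e-12 < t <= 1.0 and t < t_best:
                q0 = pos[(ax + 1) % 3] + t * d[(ax + 1) % 3]
                q1 = pos[(ax + 2) % 3] + t * d[(ax + 2) % 3]
                if lo[(ax + 1) % 3] - 1e-12 <= q0 <= hi[(ax + 1) % 3] + 1e-12 \
                        and lo[(ax + 2) % 3] - 1e-12 <= q1 \
                        <= hi[(ax + 2) % 3] + 1e-12:
                    t_best, ax_best, side_best = t, ax, side
    if ax_best < 0:
        return None
    point = pos + t_best * d
    # outward normal component along the hit axis
    outward = 1.0 if side_best == 1 else -1.0
    hit_from_outside = d[ax_best] * outward < 0
    tris = faces[(ax_best, side_best)]
    tri = int(tris[0])
    bary = obj.mesh.barycentric(tri, point)
    if np.any(bary < -1e-9):
        tri = int(tris[1])
        bary = obj.mesh.barycentric(tri, point)
    bary = np.clip(bary, 0.0, 1.0)
    return RayHit(float(t_best), tri, point,
                  "front" if hit_from_outside else "back",
                  (float(bary[0]), float(bary[1]), float(bary[2])))


def _box_polyline(start: np.ndarray, d: np.ndarray, lo: np.ndarray,
                  hi: np.ndarray, max_bounces: int = 64
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Specular reflection path of a displacement inside an axis-aligned
    box, as a list of (segment start, segment vector)."""
    segs = []
    pos = np.array(start, dtype=float)
    rem = np.array(d, dtype=float)
    for _ in range(max_bounces):
        t_best, ax_best = np.inf, -1
        for ax in range(3):
            if rem[ax] > 0 and pos[ax] + rem[ax] > hi[ax] - EPSILON:
                t = (hi[ax] - pos[ax]) / rem[ax]
            elif rem[ax] < 0 and pos[ax] + rem[ax] < lo[ax] + EPSILON:
                t = (lo[ax] - pos[ax]) / rem[ax]
            else:
                continue
            if t < t_best:
                t_best, ax_best = t, ax
        if ax_best < 0:
            segs.append((pos, rem))
            return segs
        t_best = max(t_best, 0.0)
        seg_vec = t_best * rem
        segs.append((pos, seg_vec))
        pos = pos + seg_vec
        rem = (1.0 - t_best) * rem
        rem[ax_best] = -rem[ax_best]
        # nudge off the wall so the next segment starts strictly inside
        pos = pos.copy()
        pos[ax_best] = np.clip(pos[ax_best], lo[ax_best] + 1e-9,
                               hi[ax_best] - 1e-9)
    segs.append((pos, rem * 0.0))
    return segs


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _segment_distances(start: np.ndarray, d: np.ndarray,
                       points: np.ndarray):
    """Fraction along the segment and squared perpendicular distance of
    each point to the segment start→start+d.

    Pure cylinder test: points whose projection falls outside [0, 1] get
    an infinite distance, so the swept volume is exactly π·r²·|d| and the
    per-collision probability formula stays calibrated."""
    dd = float(np.dot(d, d))
    rel = points - start
    if dd == 0.0:
        return np.zeros(len(points)), np.full(len(points), np.inf)
    t = rel @ d / dd
    diff = rel - np.outer(t, d)
    dist2 = np.einsum("ij,ij->i", diff, diff)
    dist2[(t < 0.0) | (t > 1.0)] = np.inf
    return t, dist2


def point_in(obj: SpatialObject, p: np.ndarray) -> bool:
    from ..geometry import point_containment
    return point_containment(p, obj.mesh)


def _is_box(obj: SpatialObject) -> bool:
    return obj.convex and len(obj.mesh.triangles) == 12
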