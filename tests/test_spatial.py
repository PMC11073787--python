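"""Monte Carlo core: displacement statistics, probabilities, the event
loop, releases, reactions, reflections, callbacks, and output."""
import math

import numpy as np
import pytest

from netfree.bngl import parse_bngl, parse_complex
from netfree.bngl.types import BnglError, Observable
from netfree.geometry import make_box
from netfree.output import (format_gdat, format_viz_frame, read_gdat,
                            world_series, write_gdat)
from netfree.spatial import (CallbackRegistration, ReleaseSite,
                             SimulationConfig, SpatialObject,
                             SurfacePlacementError, World,
                             mean_step_length, reaction_probability_ss,
                             reaction_probability_vs,
                             reaction_probability_vv, sample_displacement)
from netfree.spatial.probability import SURF_SURF_NEIGHBORHOOD


def simple_model(extra=""):
    return parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_a 1e-6
end parameters
begin molecule types
  a()
end molecule types
begin reaction rules
""" + extra + """
end reaction rules
""")


def box_world(model, observables=None, releases=(), iterations=10,
              seed=1, dims=(1.0, 1.0, 1.0), **cfg):
    config = SimulationConfig(iterations=iterations, seed=seed, **cfg)
    box = SpatialObject("box", make_box((0, 0, 0), dims), convex=True)
    return World(model, config, [box], releases, observables)


class TestDisplacement:
    def test_zero_diffusion(self, rng):
        assert np.all(sample_displacement(0.0, 1e-6, rng, 3, 100) == 0.0)

    def test_msd_3d(self, rng):
        d, dt = 1e-6, 1e-6
        steps = sample_displacement(d, dt, rng, 3, 100_000)
        msd = (steps ** 2).sum(axis=1)
        expect = 6 * d * 1e8 * dt
        sem = msd.std(ddof=1) / math.sqrt(len(msd))
        assert abs(msd.mean() - expect) < 3 * sem

    def test_msd_2d(self, rng):
        d, dt = 1e-7, 1e-6
        steps = sample_displacement(d, dt, rng, 2, 100_000)
        msd = (steps ** 2).sum(axis=1)
        expect = 4 * d * 1e8 * dt
        sem = msd.std(ddof=1) / math.sqrt(len(msd))
        assert abs(msd.mean() - expect) < 3 * sem

    def test_mean_step_length_maxwell(self, rng):
        d, dt = 1e-6, 1e-6
        steps = sample_displacement(d, dt, rng, 3, 100_000)
        lengths = np.linalg.norm(steps, axis=1)
        expect = mean_step_length(d, dt)  # sqrt(16 D dt / pi)
        sem = lengths.std(ddof=1) / math.sqrt(len(lengths))
        assert abs(lengths.mean() - expect) < 3 * sem


class TestProbabilities:
    def test_zero_rate(self):
        assert reaction_probability_vv(0.0, 1e-6, 1e-6, 0.01, 1e-6) == 0.0
        assert reaction_probability_vs(0.0, 1e-6, 1e-4, 1e-6) == 0.0
        assert reaction_probability_ss(0.0, 1e-4, 1e-6) == 0.0

    def test_vv_formula(self):
        k, da, db, r, dt = 1.66, 1e-5, 2e-5, 0.005, 1e-6
        sweep = math.sqrt(16 * da * 1e8 * dt / math.pi) + \
            math.sqrt(16 * db * 1e8 * dt / math.pi)
        expect = k * dt / (math.pi * r * r * sweep)
        assert reaction_probability_vv(k, da, db, r, dt) == \
            pytest.approx(expect)

    def test_vs_formula(self):
        k, d, area, dt = 0.5, 1e-5, 9.55e-5, 1e-6
        expect = k * dt / (area * math.sqrt(d * 1e8 * dt / math.pi))
        assert reaction_probability_vs(k, d, area, dt) == \
            pytest.approx(expect)

    def test_ss_formula(self):
        k2d, area, dt = 11.0, 9.55e-5, 1e-6
        expect = k2d * dt / (2 * SURF_SURF_NEIGHBORHOOD * area)
        assert reaction_probability_ss(k2d, area, dt) == \
            pytest.approx(expect)


class TestEventLoop:
    def test_free_diffusion_run(self):
        """Ten molecules of species 'a' for ten 1 μs iterations: all ten
        remain and simulated time is 10 μs."""
        obs = [Observable("Molecules", "a_total", [parse_complex("a()")])]
        rel = [ReleaseSite("r", parse_complex("a()"), "volume",
                           object_name="box", amount=10)]
        w = box_world(simple_model(), obs, rel, iterations=10)
        w.run()
        assert len(w.volume_molecules) == 10
        assert w.time == pytest.approx(10e-6)
        assert len(w.count_rows) == 11  # t=0 plus one row per iteration
        assert all(row == [10.0] for row in w.count_rows)

    def test_zero_iterations(self):
        rel = [ReleaseSite("r", parse_complex("a()"), "volume",
                           object_name="box", amount=5)]
        w = box_world(simple_model(), None, rel, iterations=0)
        w.run()
        assert len(w.volume_molecules) == 5
        assert w.time == 0.0

    def test_determinism_bitwise(self):
        obs = [Observable("Molecules", "a_total", [parse_complex("a()")])]

        def build():
            rel = [ReleaseSite("r", parse_complex("a()"), "volume",
                               object_name="box", amount=20)]
            return box_world(simple_model(), obs, rel, iterations=50,
                             seed=7)
        w1, w2 = build(), build()
        w1.run()
        w2.run()
        assert format_gdat(world_series(w1)) == format_gdat(world_series(w2))
        p1 = sorted((m.id, tuple(m.pos)) for m in
                    w1.volume_molecules.values())
        p2 = sorted((m.id, tuple(m.pos)) for m in
                    w2.volume_molecules.values())
        assert p1 == p2

    def test_reflective_box_never_leaks(self):
        rel = [ReleaseSite("r", parse_complex("a()"), "volume",
                           object_name="box", amount=100)]
        # D=1e-6 in a 0.2 box: most steps hit walls
        w = box_world(simple_model(), None, rel, iterations=300,
                      dims=(0.2, 0.2, 0.2))
        w.run()
        assert len(w.volume_molecules) == 100
        pos = np.array([m.pos for m in w.volume_molecules.values()])
        assert np.all(np.abs(pos) <= 0.1 + 1e-9)

    def test_specular_reflection_geometry(self):
        """A molecule aimed at a reflective wall lands at the mirror image
        of its unimpeded endpoint."""
        model = simple_model()
        w = box_world(model, None, [], iterations=0)
        sp = w.engine.intern_species(parse_complex("a()"))
        mol = w.add_volume_molecule(sp, (0.4, 0.0, 0.0))
        d = np.array([0.3, 0.02, -0.01])  # would end at x=0.7, wall at 0.5
        w._walk_with_walls(mol, np.array(mol.pos), d, [], set())
        expect = np.array([0.5 - 0.2, 0.02, -0.01])  # mirror about x=0.5
        assert np.allclose(mol.pos, expect, atol=1e-6)


class TestReactions:
    MODEL = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_B 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_C 1e-6
end parameters
begin molecule types
  A()
  B()
  C()
end molecule types
begin reaction rules
  bind: A() + B() -> C() 1e6
end reaction rules
""")

    def test_constructed_collision_fires(self):
        """A and B closer than r_int with p >> 1: the reaction fires and
        the product appears on the A-B axis."""
        w = box_world(self.MODEL, None, [], iterations=1)
        a = w.engine.intern_species(parse_complex("A()"))
        b = w.engine.intern_species(parse_complex("B()"))
        w.add_volume_molecule(a, (0.0, 0.0, 0.0))
        w.add_volume_molecule(b, (0.001, 0.0, 0.0))
        w.run_iterations(1)
        assert w.molecule_count("C()") == 1
        assert w.rxn_counts["bind"] == 1
        (c,) = [m for m in w.volume_molecules.values()
                if m.species_key == "C()"]
        assert np.linalg.norm(c.pos) < 0.1

    def test_probability_warning_reported(self):
        w = box_world(self.MODEL, None, [], iterations=1)
        a = w.engine.intern_species(parse_complex("A()"))
        b = w.engine.intern_species(parse_complex("B()"))
        w.add_volume_molecule(a, (0.0, 0.0, 0.0))
        w.add_volume_molecule(b, (0.001, 0.0, 0.0))
        w.run_iterations(1)
        report = w.missed_reaction_report()
        assert "bind" in report["rules_over_threshold"]
        assert report["estimated_missed_fraction"] > 0


class TestUnimolecular:
    DECAY = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_X 1e-6
end parameters
begin molecule types
  X()
end molecule types
begin reaction rules
  decay: X() -> 0 20000
end reaction rules
""")

    def test_no_rate_no_event(self):
        w = box_world(simple_model(), None, [], iterations=0)
        sp = w.engine.intern_species(parse_complex("a()"))
        mol = w.add_volume_molecule(sp, (0, 0, 0))
        assert mol.next_unimol is None

    def test_exponential_decay(self):
        """Ensemble decay follows N(t) = N0 exp(-k t) within a binomial
        3 sigma interval."""
        k = 20000.0
        n0 = 400
        t_obs = 5e-5
        iters = int(t_obs / 1e-6)
        survivors = 0
        n_seeds = 4
        for seed in range(n_seeds):
            rel = [ReleaseSite("r", parse_complex("X()"), "volume",
                               object_name="box", amount=n0)]
            w = box_world(self.DECAY, None, rel, iterations=iters,
                          seed=seed + 1)
            w.run()
            survivors += len(w.volume_molecules)
        p = math.exp(-k * t_obs)
        n = n0 * n_seeds
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(survivors - n * p) < 3 * sigma + 1

    def test_pathway_ratio(self):
        """Two decay pathways at 3:1 rates select products in a 3:1 ratio
        within a binomial 3 sigma interval."""
        model = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_X 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_Y 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_Z 1e-6
end parameters
begin molecule types
  X()
  Y()
  Z()
end molecule types
begin reaction rules
  to_y: X() -> Y() 30000
  to_z: X() -> Z() 10000
end reaction rules
""")
        rel = [ReleaseSite("r", parse_complex("X()"), "volume",
                           object_name="box", amount=600)]
        w = box_world(model, None, rel, iterations=400, seed=3)
        w.run()
        ny, nz = w.molecule_count("Y()"), w.molecule_count("Z()")
        n = ny + nz
        assert n > 500  # nearly all decayed
        sigma = math.sqrt(n * 0.75 * 0.25)
        assert abs(ny - 0.75 * n) < 3 * sigma


class TestReleases:
    def test_zero_count(self):
        rel = [ReleaseSite("r", parse_complex("a()"), "volume",
                           object_name="box", amount=0)]
        w = box_world(simple_model(), None, rel, iterations=1)
        w.run()
        assert not w.volume_molecules

    def test_surface_density_release_count(self):
        """Density 17000/μm² on the 0.47 × 0.47 face releases exactly
        3755 molecules."""
        model = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_2D_M 1e-8
end parameters
begin molecule types
  M()
end molecule types
""")
        config = SimulationConfig(iterations=0, seed=1,
                                  surface_grid_density=40000.0)
        box = SpatialObject("box", make_box((0, 0, 0), (0.47, 0.47, 5.0)),
                            convex=True)
        w = World(model, config, [box])
        site = ReleaseSite("m", parse_complex("M()"), "surface_density",
                           object_name="box", amount=17000.0, region="-z")
        created = w.release_molecules(site)
        assert len(created) == 3755
        face = box.mesh.regions["-z"]
        face_tiles = sum(int(box.grid.subdivisions[t]) ** 2 for t in face)
        assert face_tiles == 8978
        # occupancy is one molecule per tile
        assert len(box.grid.occupancy) == 3755

    def test_release_exceeding_vacant_tiles(self):
        model = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_2D_M 1e-8
end parameters
begin molecule types
  M()
end molecule types
""")
        config = SimulationConfig(iterations=0, surface_grid_density=100.0)
        box = SpatialObject("box", make_box((0, 0, 0), (1, 1, 1)),
                            convex=True)
        w = World(model, config, [box])
        site = ReleaseSite("m", parse_complex("M()"), "surface_count",
                           object_name="box", amount=10_000_000,
                           region="-z")
        with pytest.raises(SurfacePlacementError, match="-z"):
            w.release_molecules(site)

    def test_timed_release(self):
        obs = [Observable("Molecules", "a_total", [parse_complex("a()")])]
        rels = [ReleaseSite("r0", parse_complex("a()"), "volume",
                            object_name="box", amount=5),
                ReleaseSite("r1", parse_complex("a()"), "volume",
                            object_name="box", amount=7, time=5e-6)]
        w = box_world(simple_model(), obs, rels, iterations=10)
        w.run()
        col = [row[0] for row in w.count_rows]
        assert col[0] == 5 and col[-1] == 12
        assert 5 in col and 12 in col


class TestSurfaceExclusion:
    MODEL = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_2D_M 1e-7
end parameters
begin molecule types
  M()
end molecule types
""")

    def test_full_neighborhood_blocks_motion(self):
        """With every tile occupied no molecule can move."""
        config = SimulationConfig(iterations=5, surface_grid_density=4.0)
        box = SpatialObject("box", make_box((0, 0, 0), (1, 1, 1)),
                            convex=True)
        w = World(self.MODEL, config, [box])
        sp = w.engine.intern_species(parse_complex("M()"))
        for tile in range(box.grid.n_tiles):
            w.add_surface_molecule(sp, "box", tile)
        before = {m.id: m.tile for m in w.surface_molecules.values()}
        w.run_iterations(5)
        after = {m.id: m.tile for m in w.surface_molecules.values()}
        assert before == after

    def test_d_zero_stays_on_tile(self):
        model = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_2D_M 0
end parameters
begin molecule types
  M()
end molecule types
""")
        config = SimulationConfig(iterations=10, surface_grid_density=100.0)
        box = SpatialObject("box", make_box((0, 0, 0), (1, 1, 1)),
                            convex=True)
        w = World(model, config, [box])
        sp = w.engine.intern_species(parse_complex("M()"))
        mol = w.add_surface_molecule(sp, "box", 17)
        w.run_iterations(10)
        assert mol.tile == 17


class TestCallbacks:
    MODEL = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_X 1e-6
  MCELL_DIFFUSION_CONSTANT_3D_N 1e-6
end parameters
begin molecule types
  X()
  N()
end molecule types
begin reaction rules
  fire: X() -> 0 50000
end reaction rules
""")

    def test_unknown_trigger_rejected(self):
        w = box_world(self.MODEL, None, [], iterations=0)
        with pytest.raises(BnglError, match="unknown rule"):
            w.register_callback(CallbackRegistration(
                "reaction", lambda *a: None, rule_names=["nope"]))

    def test_event_driven_release_at_position(self):
        """A reaction callback releasing molecules at the trigger position
        (the SNARE-style neurotransmitter release pattern)."""
        rel = [ReleaseSite("r", parse_complex("X()"), "volume",
                           object_name="box", amount=30)]
        w = box_world(self.MODEL, None, rel, iterations=100)
        n_sp_key = []

        def release(time, rule_name, position, context):
            sp = w.engine.intern_species(parse_complex("N()"))
            for _ in range(context["count"]):
                w.add_volume_molecule(sp, position)
            n_sp_key.append(tuple(position))

        w.register_callback(CallbackRegistration(
            "reaction", release, context={"count": 3},
            rule_names=["fire"]))
        w.run()
        fired = w.rxn_counts.get("fire", 0)
        assert fired > 0
        assert len(n_sp_key) == fired  # invocation count == occurrences
        assert w.molecule_count("N()") == 3 * fired

    def test_no_trigger_no_invocation(self):
        w = box_world(self.MODEL, None, [], iterations=5)
        calls = []
        w.register_callback(CallbackRegistration(
            "reaction", lambda *a: calls.append(a), rule_names=["fire"]))
        w.run()
        assert calls == []

    def test_wall_hit_callback(self):
        rel = [ReleaseSite("r", parse_complex("X()"), "volume",
                           object_name="box", amount=50)]
        w = box_world(self.MODEL, None, rel, iterations=50,
                      dims=(0.1, 0.1, 0.1))
        hits = []
        w.register_callback(CallbackRegistration(
            "wall_hit", lambda *a: hits.append(a), object_name="box",
            species=["X"]))
        w.run()
        assert hits  # a 0.1 box at D=1e-6 guarantees wall traffic
        t, key, oname, tri, point, ctx = hits[0]
        assert oname == "box" and key == "X()"
        assert 0 <= tri < 12


class TestOutput:
    def test_gdat_round_trip(self, tmp_path):
        obs = [Observable("Molecules", "a_total", [parse_complex("a()")])]
        rel = [ReleaseSite("r", parse_complex("a()"), "volume",
                           object_name="box", amount=10)]
        w = box_world(simple_model(), obs, rel, iterations=5)
        w.run()
        path = tmp_path / "counts.gdat"
        write_gdat(world_series(w), path)
        df = read_gdat(path)
        assert list(df.columns) == ["a_total"]  # declaration order
        assert len(df) == 6
        assert np.allclose(df["a_total"].to_numpy(), 10.0)

    def test_gdat_header_only(self, tmp_path):
        path = tmp_path / "empty.gdat"
        write_gdat([], path)
        assert path.read_text().startswith("#")

    def test_viz_frame_contents(self):
        rel = [ReleaseSite("r", parse_complex("a()"), "volume",
                           object_name="box", amount=10)]
        w = box_world(simple_model(), None, rel, iterations=0)
        w.run()
        frame = format_viz_frame(w)
        lines = frame.strip().splitlines()
        assert len(lines) == 10
        for line, mid in zip(lines, sorted(w.volume_molecules)):
            toks = line.split()
            assert toks[0] == "a()" and int(toks[1]) == mid
            assert np.allclose([float(x) for x in toks[2:5]],
                               w.volume_molecules[mid].pos)

    def test_counts_sampled_after_diffuse_react(self):
        """Hand-stepped check of count timing: a molecule whose decay is
        scheduled inside iteration 1 must be gone in that iteration's
        count row (counts run after DiffuseReact)."""
        model = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_X 1e-6
end parameters
begin molecule types
  X()
end molecule types
begin reaction rules
  decay: X() -> 0 1e12
end reaction rules
""")
        obs = [Observable("Molecules", "x", [parse_complex("X()")])]
        rel = [ReleaseSite("r", parse_complex("X()"), "volume",
                           object_name="box", amount=4)]
        w = box_world(model, obs, rel, iterations=2)
        w.run()
        cols = [row[0] for row in w.count_rows]
        assert cols[0] == 4.0   # t=0, after release, before any diffusion
        assert cols[1] == 0.0   # decay happened within iteration 1
        assert cols[2] == 0.0


class TestObservableCounting:
    MODEL = parse_bngl("""
begin parameters
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-6
end parameters
begin molecule types
  A(c0~R~S,c0~R~S)
end molecule types
""")

    def test_molecules_counts_embeddings_species_counts_complexes(self):
        """One A(c0~R,c0~R) instance: the Molecules observable for pattern
        A(c0~R) counts 2 embeddings, the Species observable counts 1."""
        obs = [Observable("Molecules", "emb", [parse_complex("A(c0~R)")]),
               Observable("Species", "cpx", [parse_complex("A(c0~R)")])]
        w = box_world(self.MODEL, obs, [], iterations=0)
        sp = w.engine.intern_species(parse_complex("A(c0~R,c0~R)"))
        w.add_volume_molecule(sp, (0, 0, 0))
        values = dict(zip(w.observable_names(), w.observable_values()))
        assert values == {"emb": 2.0, "cpx": 1.0}

    def test_empty_world_counts_zero(self):
        obs = [Observable("Molecules", "emb", [parse_complex("A(c0~R)")])]
        w = box_world(self.MODEL, obs, [], iterations=0)
        assert w.observable_values() == [0.0]
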