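"""Oracles, ensemble machinery, oscillation analysis, and the structural
fixtures (species-selective surfaces, network-free ring complexes,
hybrid coupling mechanics)."""
import math

import numpy as np
import pytest

from netfree.bngl import parse_bngl, parse_complex
from netfree.engine import expand_network
from netfree.geometry import make_box
from netfree.validation import (build_well_mixed, fixture_bngl, get_fixture,
                                lowpass_peak_times, ode_oracle, run_ensemble,
                                ssa_oracle)
from netfree.validation.clock import ClockParameters, clock_hybrid_step


class TestOdeOracle:
    ABC = parse_bngl("""
begin molecule types
  A()
  B()
  C()
end molecule types
begin seed species
  A() 100
  B() 100
end seed species
begin reaction rules
  bind: A() + B() -> C() 2.0
end reaction rules
""")

    def test_closed_form_equal_counts(self):
        """A+B->C with equal initial counts: A(t) = A0/(1 + c A0 t)."""
        net = build_well_mixed(expand_network(self.ABC), {None: 0.5})
        c = 2.0 / 0.5
        t = np.linspace(0, 0.05, 40)
        y = ode_oracle(net, {"A()": 100, "B()": 100}, t)
        a = y[:, net.species.index("A()")]
        expect = 100.0 / (1.0 + c * 100.0 * t)
        assert np.allclose(a, expect, rtol=1e-6)

    def test_zero_rates_constant(self):
        model = parse_bngl(self.ABC and """
begin molecule types
  A()
  B()
  C()
end molecule types
begin seed species
  A() 10
  B() 5
end seed species
begin reaction rules
  bind: A() + B() -> C() 0.0
end reaction rules
""")
        net = build_well_mixed(expand_network(model), {None: 1.0})
        y = ode_oracle(net, {"A()": 10, "B()": 5}, np.linspace(0, 1, 5))
        assert np.allclose(y[-1], y[0])

    def test_snare_conservation(self):
        """Total snare count is conserved by the expanded-network ODE to
        high precision."""
        model = parse_bngl(fixture_bngl("snare"))
        ex = expand_network(model)
        net = build_well_mixed(ex, {"CP": 0.0156, "PM": 0.375})
        init = {"snare(a~0,dv~1,s~0)@PM": 70.0, "Ca()@CP": 1000.0}
        t = np.linspace(0, 1e-3, 20)
        y = ode_oracle(net, init, t)
        snare_cols = [i for i, k in enumerate(net.species) if "snare" in k]
        totals = y[:, snare_cols].sum(axis=1)
        assert np.allclose(totals, 70.0, rtol=1e-8)


class TestSsaOracle:
    def test_pure_decay_mean(self):
        model = parse_bngl("""
begin molecule types
  X()
end molecule types
begin seed species
  X() 200
end seed species
begin reaction rules
  d: X() -> 0 10.0
end reaction rules
""")
        net = build_well_mixed(expand_network(model), {None: 1.0})
        t = np.array([0.0, 0.05, 0.1])
        finals = [ssa_oracle(net, {"X()": 200}, seed, t)[-1, 0]
                  for seed in range(64)]
        expect = 200 * math.exp(-10.0 * 0.1)
        sem = np.std(finals, ddof=1) / math.sqrt(len(finals))
        assert abs(np.mean(finals) - expect) < 3 * sem + 0.5

    def test_empty_network_constant(self):
        model = parse_bngl("""
begin molecule types
  X()
end molecule types
begin seed species
  X() 7
end seed species
begin reaction rules
end reaction rules
""")
        net = build_well_mixed(expand_network(model), {None: 1.0})
        y = ssa_oracle(net, {"X()": 7}, 1, np.linspace(0, 1, 4))
        assert np.all(y == 7)

    def test_abc_ensemble_matches_ode(self):
        """SSA ensemble mean converges on the ODE solution (cross-oracle,
        512 replicas, 3 SEM)."""
        model = TestOdeOracle.ABC
        net = build_well_mixed(expand_network(model), {None: 1.0})
        t = np.array([0.0, 2e-3, 5e-3])
        runs = np.array([ssa_oracle(net, {"A()": 100, "B()": 100}, s, t)
                         for s in range(512)])
        c_idx = net.species.index("C()")
        ode = ode_oracle(net, {"A()": 100, "B()": 100}, t)[:, c_idx]
        mean = runs[:, :, c_idx].mean(axis=0)
        sem = runs[:, :, c_idx].std(axis=0, ddof=1) / math.sqrt(512)
        assert np.all(np.abs(mean[1:] - ode[1:]) < 3 * sem[1:] + 0.5)


class TestPeakAnalysis:
    def test_constant_trace_no_peaks(self):
        assert len(lowpass_peak_times(np.ones(500), 1e-3, 5e-3)) == 0

    def test_sinusoid_spacing(self):
        dt, period = 1e-3, 0.1
        t = np.arange(0, 1.0, dt)
        trace = np.sin(2 * np.pi * t / period)
        peaks = lowpass_peak_times(trace, dt, period / 5)
        spacing = np.diff(peaks)
        assert np.all(np.abs(spacing - period) <= dt + 1e-12)

    def test_noise_robust_peak_count(self, rng):
        dt, period = 1e-3, 0.1
        t = np.arange(0, 1.0, dt)
        clean = np.sin(2 * np.pi * t / period)
        noisy = clean + rng.normal(0, 0.2, len(t))  # SNR ~ 5
        n_clean = len(lowpass_peak_times(clean, dt, period / 5))
        n_noisy = len(lowpass_peak_times(noisy, dt, period / 5))
        assert n_noisy == n_clean

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lowpass_peak_times(np.ones(5), 1e-3, 1.0)


class TestEnsembles:
    def test_deterministic_fixture_zero_sd(self):
        """Seeds only affect stochastic parts: a reaction-free fixture has
        exactly zero ensemble SD in its counts."""
        fx = get_fixture("psd_spine")
        summary = run_ensemble(lambda seed: fx.build(seed, iterations=20),
                               [1, 2])
        assert np.all(summary.sd[:, 1] == 0.0)  # Ca_free never changes


class TestSelectiveSurfaces:
    def test_psd_reflects_kinase_passes_calcium(self):
        """The PSD slab is reflective to K and transparent to Ca: K
        released outside never enters, Ca equilibrates across it."""
        fx = get_fixture("psd_spine")
        world = fx.build(seed=5, iterations=300)
        world.run()
        lo = np.array([0.175, -0.2, -0.2])
        hi = np.array([0.225, 0.2, 0.2])

        def inside_psd(p):
            return np.all(p > lo) and np.all(p < hi)
        k_in = ca_in = 0
        for m in world.volume_molecules.values():
            if inside_psd(m.pos):
                if m.species_key.startswith("K"):
                    k_in += 1
                else:
                    ca_in += 1
        # 40 K were released inside the slab and stay; the other 40 stay out
        assert k_in >= 30
        assert ca_in > 0  # calcium diffused in through transparent walls
        k_positions = [m.pos for m in world.volume_molecules.values()
                       if m.species_key.startswith("K")
                       and inside_psd(m.pos)]
        assert len(k_positions) <= 45  # none of the outside K leaked in


class TestNetworkFreeRing:
    def test_species_cache_stays_small(self):
        """The dodecameric ring type has ~2^12 ring states, but the
        network-free engine only ever materializes species that actually
        occur."""
        fx = get_fixture("camkii_ring")
        world = fx.build(seed=2, iterations=250)
        world.run()
        n_seen = len(world.engine.species)
        assert n_seen < 260            # far below the 4096 ring states
        assert world.rxn_counts        # but chemistry did happen
        phos = world.count_rows[-1][0]
        assert 0 < phos <= 240


class TestHybridCoupling:
    def test_all_rates_zero_r_constant(self):
        fx = get_fixture("clock_hybrid")
        runner = fx.build(seed=1, iterations=5)
        for rule in runner.world.engine.rules:
            rule.rate = 0.0
        runner.params = ClockParameters(
            beta_r=0.0, delta_r=0.0, gamma_c_pair=0.0,
            mr_key=runner.params.mr_key, dt=runner.params.dt)
        runner.r = 11.0
        runner.run()
        assert runner.r == 11.0

    def test_euler_update_matches_linear_ode(self):
        """With frozen particle counts the R update is the explicit Euler
        scheme for dR/dt = beta*MR - delta*R (O(dt) accurate)."""
        fx = get_fixture("clock_hybrid")
        runner = fx.build(seed=1, iterations=1)
        w = runner.world
        for rule in w.engine.rules:
            rule.rate = 0.0  # freeze all chemistry
        mr_sp = w.engine.intern_species(parse_complex("MR()"), "CP")
        for _ in range(3):
            w.add_volume_molecule(mr_sp, (0.0, 0.0, 0.0))
        beta, delta = 1000.0, 400.0
        params = ClockParameters(beta_r=beta, delta_r=delta,
                                 gamma_c_pair=0.0, mr_key=mr_sp.key,
                                 dt=w.config.time_step)
        r = 5.0
        n = 200
        for _ in range(n):
            r = clock_hybrid_step(w, r, params)
        dt = w.config.time_step
        euler = 5.0
        for _ in range(n):
            euler = euler + dt * (beta * 3 - delta * euler)
        assert r == pytest.approx(euler)
        exact = beta * 3 / delta + (5.0 - beta * 3 / delta) * \
            math.exp(-delta * n * dt)
        assert r == pytest.approx(exact, rel=5 * delta * dt)

    def test_rate_tracks_r(self):
        """After each step the A->C pseudo-first-order rate equals
        gamma_c_pair times the current R."""
        fx = get_fixture("clock_hybrid")
        runner = fx.build(seed=4, iterations=1)
        w = runner.world
        params = runner.params
        r = 7.0
        r = clock_hybrid_step(w, r, params)
        rule = next(rr for rr in w.engine.rules if rr.name == "A_to_C")
        assert rule.rate == pytest.approx(params.gamma_c_pair * r)
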