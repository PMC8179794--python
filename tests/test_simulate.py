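import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcmodel import (
    CellProfile,
    StimulusProtocol,
    TraffickingParams,
    active_signal,
    build_network,
    cross_inhibition,
    dose_response_grid,
    pstat,
    simulate,
    steady_state,
    surface_fraction,
    synthesis_from_surface,
)
from gcmodel.network import assemble_rhs

from oracles import equilibrium_no_trafficking

EXAMPLE_TRAFFIC = TraffickingParams(k_endo=0.08, k_endo_active=0.8, f_sort=1 / 3,
                                    k_rec=0.1, k_deg=0.01, phi=0.5)


class TestSteadyState:
    def test_zero_synthesis_gives_zero_state(self, il2_network):
        prof = CellProfile("empty", receptor_synthesis={"IL2Ra": 0, "IL2Rb": 0, "gc": 0})
        ss = steady_state(il2_network, prof, EXAMPLE_TRAFFIC)
        assert not ss.as_vector().any()

    def test_closed_form_single_receptor(self, il2_network):
        # E = v (k_rec(1-f) + k_deg f) / (k_endo k_deg f), I = k_endo E / (phi (k_rec(1-f)+k_deg f))
        prof = CellProfile("one", receptor_synthesis={"IL2Rb": 1.0})
        ss = steady_state(il2_network, prof, EXAMPLE_TRAFFIC)
        k = il2_network.species.index("IL2Rb")
        assert ss.surface[k] == pytest.approx(262.5)
        assert ss.endosomal[k] == pytest.approx(600.0)

    def test_matches_long_time_integration(self, il2_network, rates):
        prof = CellProfile("cell", receptor_synthesis={"IL2Ra": 2.0, "IL2Rb": 0.5, "gc": 1.5})
        ss = steady_state(il2_network, prof, EXAMPLE_TRAFFIC)
        from gcmodel.network import SystemState

        zero = SystemState.zeros(il2_network)
        protocol = StimulusProtocol.single_dose("IL2", 0.0, [10_000.0])
        traj = simulate(zero, protocol, rates, EXAMPLE_TRAFFIC,
                        prof.receptor_synthesis, rtol=1e-10, atol=1e-8)
        np.testing.assert_allclose(traj.states[-1], ss.as_vector(), rtol=1e-3, atol=1e-6)

    def test_rhs_vanishes_at_steady_state(self, il2_network, rates, treg):
        ss = steady_state(il2_network, treg, EXAMPLE_TRAFFIC)
        f = assemble_rhs(il2_network, rates, EXAMPLE_TRAFFIC,
                         treg.synthesis(EXAMPLE_TRAFFIC), None)
        scale = max(ss.as_vector().max(), 1.0)
        assert np.abs(f(0.0, ss.as_vector())).max() < 1e-9 * scale


class TestSynthesisFromSurface:
    def test_inverse_of_closed_form(self):
        assert synthesis_from_surface(262.5, EXAMPLE_TRAFFIC) == pytest.approx(1.0)
        assert synthesis_from_surface(0.0, EXAMPLE_TRAFFIC) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            synthesis_from_surface(-10.0, EXAMPLE_TRAFFIC)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(surface=st.floats(1e-3, 1e6),
           k_endo=st.floats(0.01, 1.0), f_sort=st.floats(0.05, 0.95),
           k_rec=st.floats(0.001, 1.0), k_deg=st.floats(0.001, 1.0))
    def test_round_trip_identity(self, surface, k_endo, f_sort, k_rec, k_deg):
        tr = TraffickingParams(k_endo=k_endo, k_endo_active=1.0, f_sort=f_sort,
                               k_rec=k_rec, k_deg=k_deg)
        v = synthesis_from_surface(surface, tr)
        net = build_network({"IL2"})
        ss = steady_state(net, CellProfile("c", receptor_synthesis={"IL2Rb": v}), tr)
        assert ss.surface[net.species.index("IL2Rb")] == pytest.approx(surface, rel=1e-8)


class TestSimulate:
    def test_zero_dose_is_constant(self, il2_network, rates, treg, traffic):
        ss = steady_state(il2_network, treg, traffic)
        protocol = StimulusProtocol.single_dose("IL2", 0.0, np.linspace(0, 200, 5))
        traj = simulate(ss, protocol, rates, traffic, treg.synthesis(traffic))
        assert np.allclose(traj.states, traj.states[0][None, :], rtol=1e-6, atol=1e-8)

    def test_tolerance_convergence(self, il2_network, rates, treg, traffic):
        ss = steady_state(il2_network, treg, traffic)
        synth = treg.synthesis(traffic)
        protocol = StimulusProtocol.single_dose("IL2", 1.0, [500.0])
        a = simulate(ss, protocol, rates, traffic, synth, rtol=1e-8, atol=1e-8)
        b = simulate(ss, protocol, rates, traffic, synth, rtol=5e-9, atol=4e-9)
        ra = active_signal(a, "IL2")[-1]
        rb = active_signal(b, "IL2")[-1]
        assert abs(ra - rb) / ra < 1e-6

    def test_chain_mass_conserved_without_degradation(self, il2_network, rates, treg):
        tr = TraffickingParams(k_endo=0.08, k_endo_active=0.8, f_sort=1 / 3,
                               k_rec=0.1, k_deg=0.0)
        ss = steady_state(il2_network, treg, TraffickingParams())  # any valid start
        protocol = StimulusProtocol.single_dose("IL2", 1.0, np.linspace(0, 500, 6))
        traj = simulate(ss, protocol, rates, tr, None, rtol=1e-10, atol=1e-8)
        for chain in ("IL2Rb", "IL2Ra", "gc"):
            totals = [traj.state_at(k).chain_total(chain, tr.phi)
                      for k in range(len(traj.times))]
            np.testing.assert_allclose(totals, totals[0], rtol=1e-6)

    def test_converges_to_algebraic_equilibrium_without_trafficking(self, il2_network, rates, treg):
        off = TraffickingParams(k_endo=0, k_endo_active=0, k_rec=0, k_deg=0)
        from gcmodel.network import SystemState

        state0 = SystemState.zeros(il2_network)
        for rec, x in treg.receptor_surface.items():
            state0.surface[il2_network.species.index(rec)] = x
        L = 0.5
        traj = simulate(state0, StimulusProtocol.single_dose("IL2", L, [20_000.0]),
                        rates, off, None, rtol=1e-11, atol=1e-10)
        kb, kf = rates["k_bnd"], rates["k_fwd"]
        eq = equilibrium_no_trafficking(
            kds={"K_la": kb / rates["k_1_rev"], "K_lb": kb / rates["k_2_rev"],
                 "K_lag": kf / rates["k_4_rev"], "K_lbg": kf / rates["k_5_rev"],
                 "K_lab_b": kf / rates["k_11_rev"], "K_labg_g": kf / rates["k_10_rev"]},
            totals={"a": 3000.0, "b": 700.0, "g": 3000.0}, ligand_conc=L)
        end = traj.state_at(-1)
        for label, key in [("IL2Ra", "a"), ("IL2Rb", "b"), ("gc", "g"),
                           ("IL2:IL2Ra", "la"), ("IL2:IL2Rb", "lb"),
                           ("IL2:IL2Ra.IL2Rb", "lab"), ("IL2:IL2Ra.gc", "lag"),
                           ("IL2:IL2Rb.gc", "lbg"), ("IL2:IL2Ra.IL2Rb.gc", "labg")]:
            assert end[f"surf/{label}"] == pytest.approx(eq[key], rel=1e-6, abs=1e-8)

    def test_equilibrium_independent_of_assembly_order(self, il2_network, rates):
        # same chain totals distributed differently over initial species
        off = TraffickingParams(k_endo=0, k_endo_active=0, k_rec=0, k_deg=0)
        from gcmodel.network import SystemState

        s1 = SystemState.zeros(il2_network)
        s1.surface[il2_network.species.index("IL2Ra")] = 1000.0
        s1.surface[il2_network.species.index("IL2Rb")] = 800.0
        s1.surface[il2_network.species.index("gc")] = 900.0

        s2 = SystemState.zeros(il2_network)
        s2.surface[il2_network.species.index("IL2:IL2Ra.IL2Rb.gc")] = 500.0
        s2.surface[il2_network.species.index("IL2Ra")] = 500.0
        s2.surface[il2_network.species.index("IL2Rb")] = 300.0
        s2.surface[il2_network.species.index("gc")] = 400.0
        # state 2 pre-binds 500 of each chain with ligand; the clamped bath
        # absorbs the difference, so binding totals match at equilibrium
        protocol = StimulusProtocol.single_dose("IL2", 2.0, [50_000.0])
        t1 = simulate(s1, protocol, rates, off, None, rtol=1e-11, atol=1e-10)
        t2 = simulate(s2, protocol, rates, off, None, rtol=1e-11, atol=1e-10)
        np.testing.assert_allclose(t1.states[-1][:9], t2.states[-1][:9],
                                   rtol=1e-5, atol=1e-7)


class TestReadouts:
    def test_active_signal_zero_without_ligand(self, il2_network, rates, treg, traffic):
        ss = steady_state(il2_network, treg, traffic)
        traj = simulate(ss, StimulusProtocol.single_dose("IL2", 0.0, [0.0, 60.0]),
                        rates, traffic, treg.synthesis(traffic))
        assert active_signal(traj, "IL2").max() == 0.0

    def test_active_signal_equals_labeled_sum(self, rates, traffic, treg):
        net = build_network(("IL2", "IL15", "IL4", "IL7", "IL9", "IL21"))
        prof = CellProfile("rich", receptor_surface={
            "IL2Ra": 3000, "IL2Rb": 700, "gc": 3000, "IL15Ra": 100,
            "IL4Ra": 500, "IL7Ra": 1000, "IL9R": 200, "IL21Ra": 150})
        ss = steady_state(net, prof, traffic)
        protocol = StimulusProtocol(events=[("IL2", 0.5, 0.0), ("IL4", 0.1, 0.0)],
                                    t_grid=np.array([30.0]))
        traj = simulate(ss, protocol, rates, traffic, prof.synthesis(traffic))
        end = traj.state_at(-1)
        manual = (end["surf/IL2:IL2Rb.gc"] + end["surf/IL2:IL2Ra.IL2Rb.gc"]
                  + traffic.phi * (end["endo/IL2:IL2Rb.gc"] + end["endo/IL2:IL2Ra.IL2Rb.gc"]))
        assert active_signal(traj, "IL2")[-1] == pytest.approx(manual, rel=1e-12)
        il4 = end["surf/IL4:IL4Ra.gc"] + traffic.phi * end["endo/IL4:IL4Ra.gc"]
        assert active_signal(traj, "IL4")[-1] == pytest.approx(il4, rel=1e-12)

    def test_pstat_scaling(self):
        np.testing.assert_allclose(pstat(np.array([10.0, 20.0]), 0.5), [5.0, 10.0])
        np.testing.assert_allclose(pstat(np.array([1.0]), 1.0), [1.0])
        with pytest.raises(ValueError):
            pstat(np.array([1.0]), 0.0)

    def test_surface_fraction_baseline_and_dose_ordering(self, il2_network, rates, treg, traffic):
        ss = steady_state(il2_network, treg, traffic)
        synth = treg.synthesis(traffic)
        times = np.linspace(0, 120, 7)
        fractions = {}
        for dose in (0.0, 0.001, 1.0):
            traj = simulate(ss, StimulusProtocol.single_dose("IL2", dose, times),
                            rates, traffic, synth)
            fractions[dose] = surface_fraction(traj, "IL2Rb")
        assert fractions[0.0][0] == pytest.approx(100.0)
        np.testing.assert_allclose(fractions[0.0], 100.0, atol=1e-4)
        # depletion is faster at the higher dose (active complexes internalize faster)
        assert fractions[1.0][-1] < fractions[0.001][-1] < 100.0 + 1e-9

    def test_surface_fraction_unknown_receptor(self, il2_network, rates, treg, traffic):
        ss = steady_state(il2_network, treg, traffic)
        traj = simulate(ss, StimulusProtocol.single_dose("IL2", 0.0, [0.0, 10.0]),
                        rates, traffic, treg.synthesis(traffic))
        with pytest.raises(ValueError):
            surface_fraction(traj, "IL7Ra")


class TestCrossInhibition:
    def test_zero_pretreatment_no_inhibition(self, rates, traffic, thelper):
        inh = cross_inhibition(thelper, "IL7", [0.0], "IL4", 0.00625, rates, traffic)
        assert abs(inh[0]) < 1e-6

    def test_self_inhibition_bounded(self, rates, traffic, thelper):
        inh = cross_inhibition(thelper, "IL4", [50.0], "IL4", 0.00625, rates, traffic)
        assert inh[0] <= 100.0

    def test_il7_inhibits_il4_more_than_reverse(self, rates, traffic, thelper):
        # tighter IL7.IL7Ra.γc dimerization -> stronger γc competition
        pre = [1.0, 10.0]
        il7_on_il4 = cross_inhibition(thelper, "IL7", pre, "IL4", 0.00625, rates, traffic)
        il4_on_il7 = cross_inhibition(thelper, "IL4", pre, "IL7", 0.002, rates, traffic)
        assert np.all(il7_on_il4 > il4_on_il7)


class TestDoseResponseGrid:
    def test_singleton_grid_matches_direct_simulation(self, il2_network, rates, traffic, treg):
        grid = dose_response_grid([treg], ["IL2"], [0.1], [60.0], rates, traffic,
                                  scale=2.0, rtol=1e-9)
        ss = steady_state(il2_network, treg, traffic)
        traj = simulate(ss, StimulusProtocol.single_dose("IL2", 0.1, [60.0]),
                        rates, traffic, treg.synthesis(traffic), rtol=1e-9)
        direct = pstat(active_signal(traj, "IL2"), 2.0)[-1]
        assert grid.shape == (1, 1, 1)
        assert float(grid[0, 0, 0]) == pytest.approx(direct, rel=1e-8)

    def test_monotone_in_concentration(self, rates, traffic, treg):
        doses = np.logspace(-3, 0, 5)
        grid = dose_response_grid([treg], ["IL2"], doses, [30.0], rates, traffic)
        resp = grid.values[0, :, 0]
        assert np.all(np.diff(resp) > 0)

    def test_grid_shape_and_labels(self, rates, traffic, treg, nk):
        grid = dose_response_grid([treg, nk], ["IL2", "IL7"],
                                  {"IL2": [0.01, 0.1, 1.0], "IL7": [0.01, 0.1]},
                                  [0.0, 30.0, 60.0], rates, traffic)
        assert grid.shape == (2, 5, 3)
        assert list(grid.coords["cell"].values) == ["Treg", "NK"]
        assert float(grid.sel(time=0.0).max()) == 0.0
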