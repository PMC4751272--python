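import numpy as np
import pytest
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from cablenet.experiments import detect_spikes
from cablenet.membrane import TABLE_NETWORK_SPEC, hh_rates, hh_steady_state
from cablenet.morphology import (BASAL, SOMA, NetworkGeometry, NeuronGraph,
                                 make_fixture)
from cablenet.netgen import ConnectivityMatrix, create_interconnecting_synapses
from cablenet.solver import (CableSimulation, LinearSystem, SimulationConfig,
                             SimulationDiverged, build_mesh,
                             cuthill_mckee_order, estimate_time_step,
                             has_one_superdiagonal_structure,
                             partitioned_solve, simulate)
from cablenet.synapses import ActivationPattern, SynapseSet, \
    distribute_primary, sample_pattern


def _random_tree(n, seed):
    rng = np.random.default_rng(seed)
    parents = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    pos = rng.normal(size=(n, 3)) * 50
    regions = np.array([SOMA] + [BASAL] * (n - 1), dtype=object)
    return NeuronGraph(pos, np.ones(n), regions, np.array(parents))


class TestMesh:
    def test_uniform_cable_axial_conductance(self):
        # a = 1 µm, edge 10 µm, r_c = 1.5 Ωm → G = π a² / (r_c L)
        g = make_fixture("ball_and_stick", n_seg=10, length_um=100.0,
                         radius_um=1.0, soma_radius_um=1.0)
        mesh = build_mesh(g, r_c=1.5)
        np.testing.assert_allclose(mesh.G, 2.0944e-7, rtol=1e-4)
        np.testing.assert_allclose(
            mesh.G, np.pi * (1e-6) ** 2 / (1.5 * 10e-6), rtol=1e-12)

    def test_tapered_edge_conductance(self):
        pos = np.array([[0, 0, 0], [10.0, 0, 0]])
        g = NeuronGraph(pos, np.array([1.0, 2.0]),
                        np.array([SOMA, BASAL], dtype=object),
                        np.array([-1, 0]))
        mesh = build_mesh(g, r_c=1.5)
        assert mesh.G[0] == pytest.approx(3.351e-7, rel=1e-3)

    def test_interior_control_volume_length(self):
        g = make_fixture("ball_and_stick", n_seg=10, length_um=100.0)
        mesh = build_mesh(g)
        # interior vertex: two half-edges of 10 µm
        assert mesh.length[5] == pytest.approx(10e-6)
        # chain end: one half-edge
        assert mesh.length[10] == pytest.approx(5e-6)

    def test_capacitance_follows_area(self):
        g = make_fixture("ball_and_stick", n_seg=4, length_um=40.0,
                         radius_um=2.0)
        mesh = build_mesh(g, c_m=1e-2)
        np.testing.assert_allclose(mesh.capacitance, 1e-2 * mesh.area)
        assert np.all(mesh.area > 0)
        assert np.all(mesh.capacitance > 0)

    def test_zero_length_edge_rejected(self):
        pos = np.array([[0, 0, 0], [0, 0, 0]])
        g = NeuronGraph(pos, np.ones(2), np.array([SOMA, BASAL], dtype=object),
                        np.array([-1, 0]))
        with pytest.raises(ValueError, match="zero-length"):
            build_mesh(g)


class TestOrdering:
    def test_path_graph_permutation_is_valid(self):
        g = make_fixture("ball_and_stick", n_seg=10, length_um=100.0)
        mesh = build_mesh(g)
        perm = cuthill_mckee_order(mesh)
        assert sorted(perm) == list(range(11))
        A = mesh.axial_laplacian()[perm, :][:, perm]
        assert has_one_superdiagonal_structure(A)

    def test_random_tree_one_superdiagonal_property(self):
        mesh = build_mesh(_random_tree(200, seed=5))
        perm = cuthill_mckee_order(mesh)
        A = (mesh.axial_laplacian()
             + sp.diags(mesh.capacitance / 1e-5))[perm, :][:, perm]
        assert has_one_superdiagonal_structure(A)

    def test_disjoint_cells_ordered_independently(self):
        net = NetworkGeometry(cells=[
            make_fixture("ball_and_stick", n_seg=5, length_um=50.0),
            make_fixture("ball_and_stick", n_seg=5, length_um=50.0)])
        mesh = build_mesh(net)
        perm = cuthill_mckee_order(mesh)
        # each component occupies a contiguous run of the new order
        cell_of = mesh.cell_index[perm]
        switches = np.sum(np.diff(cell_of) != 0)
        assert switches == 1
        A = mesh.axial_laplacian()[perm, :][:, perm]
        assert has_one_superdiagonal_structure(A)


class TestTimeStepEstimate:
    def test_no_membrane_flux_gives_dt_max(self, ball_and_stick):
        mesh = build_mesh(ball_and_stick)
        assert estimate_time_step(mesh, dt_max=1e-4) == 1e-4

    def test_passive_patch_bound(self, ball_and_stick):
        # g_l = 1 S/m², c_m = 1e-2 F/m² → C/G = 1e-2 s per unit area
        mesh = build_mesh(ball_and_stick, c_m=1e-2)
        dens = np.ones(mesh.n_vertices)
        dt = estimate_time_step(mesh, membrane_conductance_density=dens,
                                dt_max=1.0, safety=0.5)
        assert dt == pytest.approx(0.5 * 1e-2)

    def test_step_shrinks_with_conductance(self, ball_and_stick):
        mesh = build_mesh(ball_and_stick)
        lo = estimate_time_step(mesh, membrane_conductance_density=np.full(
            mesh.n_vertices, 10.0), dt_max=1.0)
        hi = estimate_time_step(mesh, membrane_conductance_density=np.full(
            mesh.n_vertices, 1000.0), dt_max=1.0)
        assert hi < lo

    def test_step_shrinks_during_action_potential(self, stick_with_axon):
        # a spiking simulation must use smaller steps than rest
        sets = [sample_pattern(
            distribute_primary(stick_with_axon, 150, seed=0, g_max=1.2),
            ActivationPattern(2.0, 0.0, 0.4, 0.0), seed=0)]
        cfg = SimulationConfig(geometry=stick_with_axon, synapses=sets[0],
                               duration=0.008)
        sim = CableSimulation(cfg)
        res = sim.run(0.008)
        assert detect_spikes(res.times, res.probe_trace(0)).size >= 1
        assert min(res.dt_history) < max(res.dt_history) / 8

    def test_invalid_safety_rejected(self, ball_and_stick):
        mesh = build_mesh(ball_and_stick)
        with pytest.raises(ValueError):
            estimate_time_step(mesh, safety=0.0)


class TestStep:
    def test_uniform_potential_without_mechanisms_is_steady(
            self, ball_and_stick, fluxless_spec):
        cfg = SimulationConfig(geometry=ball_and_stick, spec=fluxless_spec,
                               duration=0.01, V_init=0.042)
        res = simulate(cfg)
        np.testing.assert_allclose(res.final_V, 0.042, atol=1e-15)

    def test_total_charge_conserved_on_sealed_passive_cable(
            self, ball_and_stick, fluxless_spec):
        cfg = SimulationConfig(geometry=ball_and_stick, spec=fluxless_spec,
                               duration=0.0)
        sim = CableSimulation(cfg)
        rng = np.random.default_rng(0)
        sim.V = rng.uniform(-0.08, 0.02, size=sim.V.shape)
        q0 = float(np.sum(sim.mesh.capacitance * sim.V))
        for _ in range(200):
            sim.step(1e-5)
        q1 = float(np.sum(sim.mesh.capacitance * sim.V))
        assert q1 == pytest.approx(q0, rel=1e-12)

    def test_lu_solve_residual_small(self, binary_tree):
        mesh = build_mesh(binary_tree)
        A = (mesh.axial_laplacian()
             + sp.diags(mesh.capacitance / 1e-5)).tocsr()
        rng = np.random.default_rng(3)
        b = rng.normal(size=mesh.n_vertices) * 1e-12
        x = LinearSystem(A, b).solve()
        assert (np.linalg.norm(A @ x - b) / np.linalg.norm(b)) < 1e-10

    def test_sealed_cable_steady_state_matches_cosh_solution(
            self, passive_spec):
        errors = {}
        for n in (50, 200):
            cell = make_fixture("ball_and_stick", n_seg=n, length_um=1000.0,
                                radius_um=1.0, soma_radius_um=1.0)
            I = 1e-10
            cfg = SimulationConfig(
                geometry=cell, spec=passive_spec, duration=0.06,
                dt_max=1e-3, stimuli=[(0, 0.0, 1.0, I)], V_init=0.0,
                probes=list(range(cell.n_vertices)))
            res = simulate(cfg)
            lam = np.sqrt(1e-6 / (2 * 1.5 * 5.0))
            x = np.linspace(0, 1000e-6, n + 1)
            V_an = (I * 1.5 * lam / (np.pi * 1e-12)
                    * np.cosh((1000e-6 - x) / lam) / np.sinh(1000e-6 / lam))
            errors[n] = float(np.max(np.abs(res.final_V - V_an))
                              / np.max(V_an))
        assert errors[200] < 0.01
        assert errors[200] < errors[50]

    def test_single_compartment_hh_matches_ode_oracle_spike_for_spike(self):
        # isopotential two-vertex patch with somatic channel densities
        cell = make_fixture("ball_and_stick", n_seg=1, length_um=1.0,
                            radius_um=10.0, soma_radius_um=10.0,
                            dendrite_region=SOMA)
        mesh = build_mesh(cell)
        i_inj = 2.0  # A/m², suprathreshold step
        stim = [(v, 0.005, 0.05, i_inj * mesh.area[v]) for v in (0, 1)]
        cfg = SimulationConfig(geometry=cell, spec=TABLE_NETWORK_SPEC,
                               duration=0.05, dt_max=5e-6, stimuli=stim,
                               probes=[0])
        res = simulate(cfg)
        spikes_fv = detect_spikes(res.times, res.probe_trace(0))

        spec, p = TABLE_NETWORK_SPEC, TABLE_NETWORK_SPEC.regions["soma"]
        E_l = spec.leak_reversal("soma")

        def rhs(t, y):
            V, n, m, h = y
            a = hh_rates(V * 1e3, -65.0)
            i_hh = spec.c_T * (p.g_K * n ** 4 * (V - spec.E_K)
                               + p.g_Na * m ** 3 * h * (V - spec.E_Na))
            i_l = spec.c_T * p.g_l * (V - E_l)
            inj = i_inj if 0.005 <= t < 0.05 else 0.0
            return [(-(i_hh + i_l) + inj) / 1e-2,
                    spec.c_T * 1e3 * (a[0] * (1 - n) - a[1] * n),
                    spec.c_T * 1e3 * (a[2] * (1 - m) - a[3] * m),
                    spec.c_T * 1e3 * (a[4] * (1 - h) - a[5] * h)]

        n0, m0, h0 = hh_steady_state(-65.0)
        sol = solve_ivp(rhs, (0, 0.05), [-0.065, n0, m0, h0],
                        method="LSODA", rtol=1e-8, atol=1e-10,
                        dense_output=True, max_step=1e-4)
        tt = np.linspace(0, 0.05, 5001)
        spikes_ode = detect_spikes(tt, sol.sol(tt)[0])
        assert len(spikes_fv) == len(spikes_ode)
        assert len(spikes_fv) >= 3  # repetitive firing
        np.testing.assert_allclose(spikes_fv, spikes_ode, atol=5e-4)

    def test_violating_cfl_bound_is_detected_not_silent(self, stick_with_axon):
        cfg = SimulationConfig(geometry=stick_with_axon, duration=0.005)
        sim = CableSimulation(cfg)
        dt = sim.estimate_dt()
        with pytest.raises(SimulationDiverged, match="CFL"):
            for _ in range(2000):
                sim.step(dt * 50)


class TestPartitionedSolve:
    def _system(self, mesh, dt, seed=0):
        A = (mesh.axial_laplacian()
             + sp.diags(mesh.capacitance / dt)).tocsr()
        b = np.random.default_rng(seed).normal(size=mesh.n_vertices) * 1e-12
        return LinearSystem(A, b)

    def test_uncut_cells_converge_in_exactly_one_iteration(self):
        net = NetworkGeometry(cells=[
            make_fixture("ball_and_stick", n_seg=30, length_um=300.0),
            make_fixture("ball_and_stick", n_seg=30, length_um=300.0)])
        mesh = build_mesh(net)
        sys_ = self._system(mesh, 5e-6)
        x_mono = LinearSystem(sys_.A, sys_.b).solve()
        x, it = partitioned_solve(sys_, [np.arange(31), np.arange(31, 62)],
                                  reduction_factor=1e-10)
        assert it == 1
        np.testing.assert_allclose(x, x_mono, rtol=1e-9)

    def test_cut_cable_matches_monolithic_solution(self):
        mesh = build_mesh(make_fixture("ball_and_stick", n_seg=40,
                                       length_um=400.0))
        sys_ = self._system(mesh, 5e-6)
        x_mono = LinearSystem(sys_.A, sys_.b).solve()
        for blocks in ([np.arange(20), np.arange(20, 41)],
                       [np.arange(12), np.arange(12, 30), np.arange(30, 41)]):
            x, it = partitioned_solve(sys_, blocks, reduction_factor=1e-8)
            assert it <= 15
            assert (np.linalg.norm(x - x_mono)
                    / np.linalg.norm(x_mono)) < 1e-6

    def test_degenerate_reduction_factor_returns_x0(self):
        mesh = build_mesh(make_fixture("ball_and_stick", n_seg=10,
                                       length_um=100.0))
        sys_ = self._system(mesh, 1e-5)
        x0 = np.full(11, 0.5)
        x, it = partitioned_solve(sys_, [np.arange(6), np.arange(6, 11)],
                                  x0=x0, reduction_factor=1.0)
        assert it == 0
        np.testing.assert_array_equal(x, x0)

    def test_invalid_partitions_rejected(self):
        mesh = build_mesh(make_fixture("ball_and_stick", n_seg=10,
                                       length_um=100.0))
        sys_ = self._system(mesh, 1e-5)
        with pytest.raises(ValueError, match="disjoint"):
            partitioned_solve(sys_, [np.arange(6), np.arange(5, 11)])
        with pytest.raises(ValueError, match="cover"):
            partitioned_solve(sys_, [np.arange(6)])


class TestSimulate:
    def test_zero_duration_returns_initial_state_only(self, ball_and_stick):
        cfg = SimulationConfig(geometry=ball_and_stick, duration=0.0)
        res = simulate(cfg)
        assert len(res.times) == 1
        np.testing.assert_allclose(res.V[0], -0.065)

    def test_calibrated_rest_is_stable(self, stick_with_axon):
        cfg = SimulationConfig(geometry=stick_with_axon,
                               spec=TABLE_NETWORK_SPEC, duration=0.02)
        res = simulate(cfg)
        assert np.max(np.abs(res.V - (-0.065))) < 1e-4  # within 0.1 mV

    def test_synaptic_transmission_crosses_cells_with_one_step_lag(self):
        # presynaptic barrage -> spike -> interconnecting synapse ->
        # postsynaptic depolarization
        net = make_fixture("two_cell", gap_um=2.0, n_seg=10, length_um=80.0,
                           axon_n_seg=10, axon_length_um=80.0)
        conn = ConnectivityMatrix({"generic": {"generic": 1.0}})
        inter = create_interconnecting_synapses(net, 3.0, conn=conn)
        assert len(inter) >= 1
        drive = sample_pattern(
            distribute_primary(net.cells[0], 120, seed=0, g_max=1.2),
            ActivationPattern(2.0, 0.0, 0.4, 0.0), seed=1)
        allsyn = SynapseSet(list(drive) + list(inter))
        cfg = SimulationConfig(geometry=net, synapses=allsyn, duration=0.015)
        res = simulate(cfg)
        pre_trace = res.probe_trace(0)
        post_trace = res.probe_trace(1)
        assert detect_spikes(res.times, pre_trace).size >= 1
        assert len(res.events) >= 1  # synapse activated by the crossing
        t_act = res.events[0][2]
        after = post_trace[res.times > t_act + 1e-3]
        assert np.max(after) > -0.064  # visible depolarization
        # causality: no postsynaptic response before the activation
        before = post_trace[res.times < t_act]
        assert np.max(np.abs(before - (-0.065))) < 1e-4
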