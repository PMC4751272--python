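import json

import numpy as np
import pytest

from cablenet.io import network_to_dict, save_network, load_network
from cablenet.morphology import APICAL, AXON, BASAL, SOMA, make_fixture
from cablenet.netgen import (DEFAULT_CONNECTIVITY, L23, L4, L5A, L5B,
                             ConnectivityMatrix, ForbiddenPairError,
                             LayerSpec, NetgenConfig,
                             create_interconnecting_synapses,
                             generate_network, place_thalamic_inputs,
                             segment_segment_distance, synaptic_conductance)
from cablenet.synapses import INTERCONNECTING


def _small_config(seed=0, counts=(3, 3, 2, 2)):
    return NetgenConfig(
        layers=[LayerSpec(L23, counts[0], (150.0, 400.0)),
                LayerSpec(L4, counts[1], (400.0, 600.0)),
                LayerSpec(L5A, counts[2], (600.0, 800.0)),
                LayerSpec(L5B, counts[3], (800.0, 1000.0))],
        box_xy=(250.0, 250.0), seed=seed)


class TestConnectivity:
    def test_reference_base_conductances(self):
        assert DEFAULT_CONNECTIVITY.base_conductance(L5A, L5A) == 2.0
        assert DEFAULT_CONNECTIVITY.base_conductance(L4, L4) == 1.6
        assert DEFAULT_CONNECTIVITY.base_conductance(L23, L5B) == 0.3

    def test_forbidden_pair_raises_not_zero(self):
        assert not DEFAULT_CONNECTIVITY.allowed(L5B, L23)
        with pytest.raises(ForbiddenPairError):
            DEFAULT_CONNECTIVITY.base_conductance(L5B, L23)

    def test_nonpositive_conductance_rejected(self):
        with pytest.raises(ValueError):
            ConnectivityMatrix({L23: {L23: 0.0}})


class TestSynapticConductance:
    def test_soma_adjacent_synapse_keeps_base(self):
        assert synaptic_conductance(1.0, 0.0) == 1.0

    def test_distance_scaling_reference(self):
        assert synaptic_conductance(1.0, 100.0) == pytest.approx(1.1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synaptic_conductance(-1.0, 10.0)
        with pytest.raises(ValueError):
            synaptic_conductance(1.0, -5.0)


class TestSegmentDistance:
    def test_parallel_segments(self):
        d, s, u = segment_segment_distance([[0, 0, 0]], [[1, 0, 0]],
                                           [[0, 0, 2]], [[1, 0, 2]])
        assert d[0] == pytest.approx(2.0)

    def test_crossing_segments(self):
        d, s, u = segment_segment_distance([[-1, 0, 0]], [[1, 0, 0]],
                                           [[0, -1, 1]], [[0, 1, 1]])
        assert d[0] == pytest.approx(1.0)
        assert s[0] == pytest.approx(0.5)
        assert u[0] == pytest.approx(0.5)

    def test_endpoint_clamping(self):
        d, s, u = segment_segment_distance([[0, 0, 0]], [[1, 0, 0]],
                                           [[3, 0, 0]], [[4, 0, 0]])
        assert d[0] == pytest.approx(2.0)
        assert s[0] == pytest.approx(1.0)
        assert u[0] == pytest.approx(0.0)

    def test_matches_brute_force_point_sampling(self, rng):
        P0, P1 = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        Q0, Q1 = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        d, _, _ = segment_segment_distance(P0, P1, Q0, Q1)
        t = np.linspace(0, 1, 201)
        for i in range(20):
            pts_p = P0[i] + t[:, None] * (P1[i] - P0[i])
            pts_q = Q0[i] + t[:, None] * (Q1[i] - Q0[i])
            brute = np.min(np.linalg.norm(
                pts_p[:, None, :] - pts_q[None, :, :], axis=2))
            assert d[i] <= brute + 1e-9
            assert d[i] >= brute - 0.01  # sampling resolution bound


class TestGenerateNetwork:
    def test_ten_cell_network_with_type_region_subsets(self):
        net = generate_network(_small_config())
        assert net.n_cells == 10
        labels = net.subset_labels()
        # every cell type contributes axon, soma and dendrite subsets
        for ct in (L23, L4, L5A, L5B):
            assert f"{ct}/{SOMA}" in labels
            assert f"{ct}/{AXON}" in labels
            assert (f"{ct}/{BASAL}" in labels or f"{ct}/{APICAL}" in labels)

    def test_somata_inside_their_layer_slabs(self):
        cfg = _small_config(seed=3)
        net = generate_network(cfg)
        i = 0
        for layer in cfg.layers:
            for _ in range(layer.count):
                soma_z = net.cells[i].positions[net.cells[i].root][2]
                assert layer.depth_range[0] <= soma_z <= layer.depth_range[1]
                i += 1

    def test_empty_config_gives_empty_network(self):
        cfg = NetgenConfig(layers=[LayerSpec(L23, 0, (0.0, 100.0))])
        net = generate_network(cfg)
        assert net.n_cells == 0

    def test_same_seed_gives_byte_identical_export(self, tmp_path):
        a = generate_network(_small_config(seed=11))
        b = generate_network(_small_config(seed=11))
        pa, pb = tmp_path / "a.json", tmp_path / "b.json"
        save_network(pa, a)
        save_network(pb, b)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        a = generate_network(_small_config(seed=1))
        b = generate_network(_small_config(seed=2))
        assert not np.allclose(a.cells[0].positions, b.cells[0].positions)

    def test_overfull_box_rejected(self):
        cfg = NetgenConfig(layers=[LayerSpec(L23, 200, (0.0, 30.0))],
                           box_xy=(30.0, 30.0), min_separation=15.0)
        with pytest.raises(ValueError, match="box too small"):
            generate_network(cfg)


class TestDistanceRule:
    def _two_cell(self, gap):
        return make_fixture("two_cell", gap_um=gap, cell_pre_type=L4,
                            cell_post_type=L23)

    def test_threshold_below_gap_creates_nothing(self):
        net = self._two_cell(2.0)
        assert len(create_interconnecting_synapses(net, 1.0)) == 0

    def test_threshold_above_gap_creates_synapses_on_allowed_pair(self):
        net = self._two_cell(2.0)
        syn = create_interconnecting_synapses(net, 3.0)
        assert len(syn) >= 1
        for r in syn:
            assert r.kind == INTERCONNECTING
            assert DEFAULT_CONNECTIVITY.allowed(L4, L23)
            assert r.pre_cell == 0 and r.cell == 1

    def test_matches_brute_force_pair_enumeration(self):
        net = self._two_cell(2.0)
        d_thr = 4.0
        syn = create_interconnecting_synapses(net, d_thr)
        # brute force: enumerate all axon/dendrite edge pairs
        count = 0
        pre, post = net.cells
        ax_edges = [(p, c) for p, c in pre.edges if pre.regions[c] == AXON]
        de_edges = [(p, c) for p, c in post.edges
                    if str(post.regions[c]).startswith("dendrite")]
        for ap, ac in ax_edges:
            for dp, dc in de_edges:
                d, _, _ = segment_segment_distance(
                    [pre.positions[ap]], [pre.positions[ac]],
                    [post.positions[dp]], [post.positions[dc]])
                if d[0] < d_thr:
                    count += 1
        assert len(syn) == count

    def test_forbidden_pair_never_connected(self):
        net = make_fixture("two_cell", gap_um=1.0, cell_pre_type=L5B,
                           cell_post_type=L23)  # L5B->L23 is forbidden
        assert len(create_interconnecting_synapses(net, 5.0)) == 0

    def test_count_nondecreasing_in_threshold(self):
        net = generate_network(_small_config(seed=5))
        counts = [len(create_interconnecting_synapses(net, d))
                  for d in (1.0, 2.0, 4.0)]
        assert counts == sorted(counts)

    def test_presynaptic_side_is_axon_postsynaptic_is_dendrite(self):
        net = generate_network(_small_config(seed=6))
        syn = create_interconnecting_synapses(net, 4.0)
        for r in syn:
            pre_cell = net.cells[r.pre_cell]
            post_cell = net.cells[r.cell]
            assert pre_cell.regions[r.pre_vertex] in (AXON, SOMA)
            assert str(post_cell.regions[r.edge]).startswith("dendrite")

    def test_conductance_grows_with_distance_to_soma(self):
        net = generate_network(_small_config(seed=7))
        syn = create_interconnecting_synapses(net, 4.0)
        if len(syn) < 2:
            pytest.skip("too few synapses in this geometry")
        for r in syn:
            base = DEFAULT_CONNECTIVITY.base_conductance(
                net.cells[r.pre_cell].cell_type, net.cells[r.cell].cell_type)
            assert r.g_max >= base


class TestThalamicInputs:
    def test_counts_follow_poisson_means(self):
        net = generate_network(_small_config(seed=1, counts=(0, 10, 0, 0)))
        totals = [len(place_thalamic_inputs(net, seed=s)) for s in range(60)]
        mean = np.mean(totals)
        # 10 L4 cells × mean 30 = 300 expected; 3 SE over 60 draws
        assert abs(mean - 300.0) < 3 * np.sqrt(300.0 / 60) + 3

    def test_network_without_target_types_gives_empty_set(self):
        net = generate_network(_small_config(seed=1, counts=(3, 0, 2, 0)))
        assert len(place_thalamic_inputs(net, seed=0)) == 0

    def test_every_synapse_sits_on_its_own_cells_dendrite(self):
        net = generate_network(_small_config(seed=2))
        syn = place_thalamic_inputs(net, seed=4)
        assert len(syn) > 0
        for r in syn:
            cell = net.cells[r.cell]
            assert cell.cell_type in (L4, L5B)
            assert str(cell.regions[r.edge]).startswith("dendrite")


class TestExchangeFormat:
    def test_round_trip_network_with_synapses(self, tmp_path):
        net = generate_network(_small_config(seed=8))
        syn = create_interconnecting_synapses(net, 4.0)
        syn.extend(place_thalamic_inputs(net, seed=8))
        p = tmp_path / "net.json"
        save_network(p, net, syn)
        net2, syn2 = load_network(p)
        assert net2.n_cells == net.n_cells
        assert len(syn2) == len(syn)
        np.testing.assert_allclose(net2.cells[0].positions,
                                   net.cells[0].positions)
        assert [r.kind for r in syn2] == [r.kind for r in syn]

    def test_schema_header_fields(self):
        net = generate_network(_small_config(seed=8))
        doc = network_to_dict(net)
        assert doc["format"] == "cablenet-network"
        assert doc["version"] == 1

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"format": "something-else"}))
        with pytest.raises(ValueError):
            load_network(p)
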