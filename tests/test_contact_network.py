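"""Contact-network construction, Fiedler bipartition and the 2:1 chain trace."""

import numpy as np
import networkx as nx
import pytest

from conftest import brute_force_ratio_cuts, make_network, ratio_cut_value
from trimertrace.errors import ValidationError
from trimertrace import contact_network as cn
from trimertrace.structure_io import Frame
from trimertrace.synthetic import TrimerGeometrySpec, generate_trimer_ensemble


def _ca_frame(coords):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Frame(
        index=0,
        chain_ids=np.array(["A"] * n, dtype="U4"),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["ALA"] * n, dtype="U3"),
        ca_coords=coords,
    )


class TestBuildNetwork:
    @pytest.mark.parametrize(
        "distance, linked",
        [(5.0, True), (3.8, False), (8.5, False), (4.0, True), (8.0, True)],
    )
    def test_noncovalent_band(self, distance, linked):
        """A link exists iff the C-alpha distance falls in the 4-8 A band;
        consecutive-backbone spacing (~3.8 A) is excluded by the lower cutoff."""
        frame = _ca_frame([[0, 0, 0], [distance, 0, 0]])
        net = cn.build_contact_network(frame)
        assert bool(net.adjacency[0, 1]) is linked

    def test_invalid_cutoffs(self):
        frame = _ca_frame([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        with pytest.raises(ValidationError):
            cn.build_contact_network(frame, cutoff_low=8, cutoff_high=4)

    def test_laplacian_invariants_on_synthetic_frame(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        net = cn.build_contact_network(ensemble.frames[0])
        a = net.adjacency
        assert np.array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)
        lap = net.laplacian
        assert np.allclose(lap.sum(axis=1), 0.0)
        part = cn.fiedler_partition(net)
        assert part.algebraic_connectivity >= -1e-10


class TestFiedlerPartition:
    def test_path_graph_splits_in_halves(self):
        a = np.zeros((4, 4), dtype=int)
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = 1
        part = cn.fiedler_partition(make_network(a))
        assert part.labels[0] == part.labels[1]
        assert part.labels[2] == part.labels[3]
        assert part.labels[0] != part.labels[2]
        # exhaustive minimum ratio-cut agrees exactly
        assert ratio_cut_value(a, part.labels) == pytest.approx(
            brute_force_ratio_cuts(a)[0]
        )

    def test_joined_triangles_split_at_bridge(self):
        a = np.zeros((6, 6), dtype=int)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
            a[i, j] = a[j, i] = 1
        part = cn.fiedler_partition(make_network(a))
        assert len(set(part.labels[:3])) == 1
        assert len(set(part.labels[3:])) == 1
        assert part.labels[0] != part.labels[3]
        assert ratio_cut_value(a, part.labels) == pytest.approx(
            brute_force_ratio_cuts(a)[0]
        )

    def test_disconnected_graph_separates_components(self):
        a = np.zeros((6, 6), dtype=int)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            a[i, j] = a[j, i] = 1
        part = cn.fiedler_partition(make_network(a))
        assert part.algebraic_connectivity == pytest.approx(0.0, abs=1e-10)
        assert not part.connected
        assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1
        assert part.labels[0] != part.labels[3]

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValidationError):
            cn.fiedler_partition(make_network(np.zeros((2, 2), dtype=int)))

    def test_near_optimal_on_random_connected_graphs(self):
        """Sign-based spectral cuts stay within a small factor of the exhaustive
        ratio-cut optimum on random connected graphs (sign rounding carries no
        exact guarantee; the worked examples above are the exact cases)."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(4, 11))
            while True:
                g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
                if nx.is_connected(g):
                    break
            a = nx.to_numpy_array(g).astype(int)
            part = cn.fiedler_partition(make_network(a))
            worst = max(
                worst, ratio_cut_value(a, part.labels) / brute_force_ratio_cuts(a)[0]
            )
        assert worst <= 4.0

    def test_permutation_equivariance(self, planted_ensemble):
        """Permuting residue order permutes the labels identically."""
        ensemble, _ = planted_ensemble
        frame = ensemble.frames[0]
        rng = np.random.default_rng(5)
        perm = rng.permutation(frame.n_residues)
        permuted = Frame(
            index=0,
            chain_ids=frame.chain_ids[perm],
            res_ids=frame.res_ids[perm],
            res_names=frame.res_names[perm],
            ca_coords=frame.ca_coords[perm],
        )
        base, _ = cn.cluster_frame(frame)
        shuffled, _ = cn.cluster_frame(permuted)
        assert base.paired_chains == shuffled.paired_chains
        assert base.purity == pytest.approx(shuffled.purity)


class TestChainClustering:
    def test_planted_pair_recovered(self, planted_ensemble):
        ensemble, truth = planted_ensemble
        clustering, _ = cn.cluster_frame(ensemble.frames[0])
        assert clustering.paired_chains == truth[0] == frozenset("AC")
        assert 0.5 <= clustering.purity <= 1.0

    def test_symmetric_trimer_reports_purity_without_asserting_pair(
        self, symmetric_ensemble
    ):
        ensemble, _ = symmetric_ensemble
        clustering, _ = cn.cluster_frame(ensemble.frames[0])
        assert 0.0 <= clustering.purity <= 1.0
        assert clustering.paired_chains | {clustering.lone_chain} == {"A", "B", "C"}

    def test_no_interchain_edges_flagged_disconnected(self):
        # three far-apart chains: intra-chain contacts only
        coords, chains = [], []
        rng = np.random.default_rng(6)
        for k, c in enumerate("ABC"):
            blob = rng.normal(size=(10, 3)) * 3 + np.array([200.0 * k, 0, 0])
            coords.append(blob)
            chains += [c] * 10
        frame = Frame(
            index=0,
            chain_ids=np.array(chains, dtype="U4"),
            res_ids=np.tile(np.arange(1, 11), 3),
            res_names=np.array(["ALA"] * 30, dtype="U3"),
            ca_coords=np.concatenate(coords),
        )
        clustering, part = cn.cluster_frame(frame)
        assert part.algebraic_connectivity == pytest.approx(0.0, abs=1e-10)
        assert clustering.disconnected_interface
        assert clustering.low_confidence

    def test_non_trimer_rejected(self):
        frame = _ca_frame([[0, 0, 0], [5, 0, 0], [0, 5, 0], [5, 5, 0]])
        net = cn.build_contact_network(frame)
        part = cn.fiedler_partition(net)
        with pytest.raises(ValidationError):
            cn.assign_chain_clusters(part, net)


class TestClusterTrace:
    def test_single_frame_trace(self, symmetric_ensemble):
        ensemble, _ = symmetric_ensemble
        trace = cn.cluster_trace(ensemble)
        assert len(trace) == 1
        assert trace.switch_events == []
        assert sum(trace.occupancy.values()) == pytest.approx(1.0)

    def test_scheduled_switch_detected_once_at_boundary(self):
        spec = TrimerGeometrySpec(
            n_frames=100,
            approach_delta=-6.0,
            noise_sigma=0.3,
            pair_schedule=((0, ("A", "C")), (50, ("A", "B"))),
            seed=0,
        )
        ensemble, truth = generate_trimer_ensemble(spec)
        trace = cn.cluster_trace(ensemble)
        assert len(trace.switch_events) == 1
        assert abs(trace.switch_events[0] - 50) <= 2
        assert trace.clusterings[0].paired_chains == frozenset("AC")
        assert trace.clusterings[-1].paired_chains == frozenset("AB")

    def test_symmetric_null_has_no_dominant_pairing(self):
        """Over seeds, no chain pair occupies more than 60% of frames on average."""
        max_occ = []
        for seed in range(20):
            spec = TrimerGeometrySpec(n_frames=15, noise_sigma=0.3, seed=seed)
            ensemble, _ = generate_trimer_ensemble(spec)
            trace = cn.cluster_trace(ensemble)
            max_occ.append(max(trace.occupancy.values()))
        assert np.mean(max_occ) <= 0.6
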