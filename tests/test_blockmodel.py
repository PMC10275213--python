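import numpy as np
import pytest
import scipy.sparse as sp

from sbmcircuit.binarize import BinaryEnsemble
from sbmcircuit.blockmodel import (
    BlockProbabilityMatrix,
    Circuit,
    estimate_block_probabilities,
    floor_to_circuit,
    restricted_block_probabilities,
    top_fraction_edges,
)

from _util import block_labels, direct_sbm_ensemble, partition_from_labels, planted_block_probabilities


def single_graph_ensemble(dense, retained=None):
    A = sp.csr_matrix(np.asarray(dense))
    n = A.shape[0]
    retained = np.arange(n) if retained is None else np.asarray(retained)
    return BinaryEnsemble(graphs=[A], retained=[retained], n=n)


class TestEstimateBlockProbabilities:
    def test_hand_computed_proportion(self):
        # classes {0,1} and {2,3}; 2 of the 4 possible 1->2 edges present
        dense = np.zeros((4, 4))
        dense[0, 2] = 1
        dense[1, 3] = 1
        partition = partition_from_labels([1, 1, 2, 2])
        bpm = estimate_block_probabilities(partition, single_graph_ensemble(dense))
        assert bpm.p_hat[0, 1] == pytest.approx(0.5)
        assert bpm.p_hat[1, 0] == 0.0

    def test_within_class_denominator_excludes_self_pairs(self):
        # class {0,1}: one of the two ordered pairs realized -> 0.5
        dense = np.zeros((3, 3))
        dense[0, 1] = 1
        dense[2, 0] = 1
        partition = partition_from_labels([1, 1, 2])
        bpm = estimate_block_probabilities(partition, single_graph_ensemble(dense))
        assert bpm.p_hat[0, 0] == pytest.approx(0.5)

    def test_no_edges_gives_zero(self):
        partition = partition_from_labels([1, 1, 2, 2])
        bpm = estimate_block_probabilities(partition, single_graph_ensemble(np.zeros((4, 4))))
        assert np.all(bpm.p_hat == 0.0)

    def test_trimmed_neurons_excluded_from_denominators(self):
        # neuron 3 trimmed from the only graph: class 2 has 1 retained neuron
        dense = np.zeros((3, 3))
        dense[0, 2] = 1
        dense[1, 2] = 1
        ensemble = BinaryEnsemble(
            graphs=[sp.csr_matrix(dense)], retained=[np.array([0, 1, 2])], n=4
        )
        # neuron 3 exists in the partition but not in the graph
        partition = partition_from_labels([1, 1, 2, 2])
        bpm = estimate_block_probabilities(partition, ensemble)
        assert bpm.p_hat[0, 1] == pytest.approx(1.0)  # 2 of 2 retained pairs

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        dense = (rng.random((10, 10)) < 0.5).astype(int)
        np.fill_diagonal(dense, 0)
        partition = partition_from_labels(block_labels(10, 2))
        bpm = estimate_block_probabilities(partition, single_graph_ensemble(dense))
        assert np.all(bpm.p_hat >= 0.0) and np.all(bpm.p_hat <= 1.0)

    def test_planted_recovery_within_3se(self):
        truth = block_labels(600, 3)
        P = planted_block_probabilities(3, 0.25, 0.05)
        G = 20
        ensemble = direct_sbm_ensemble(truth, P, G=G, seed=1)
        partition = partition_from_labels(truth)
        bpm = estimate_block_probabilities(partition, ensemble)
        sizes = partition.class_sizes
        for i in range(3):
            for j in range(3):
                pairs = sizes[i] * sizes[j] - (sizes[i] if i == j else 0)
                se = np.sqrt(P[i, j] * (1 - P[i, j]) / (pairs * G))
                assert abs(bpm.p_hat[i, j] - P[i, j]) <= 3 * se

    def test_empty_partition_rejected(self):
        partition = partition_from_labels([0, 0, 0])
        partition.kappa = 0
        with pytest.raises(ValueError):
            estimate_block_probabilities(partition, single_graph_ensemble(np.zeros((3, 3))))


class TestRestricted:
    def test_full_mask_equals_unrestricted(self):
        rng = np.random.default_rng(2)
        dense = (rng.random((12, 12)) < 0.4).astype(int)
        np.fill_diagonal(dense, 0)
        partition = partition_from_labels(block_labels(12, 3))
        ensemble = single_graph_ensemble(dense)
        full = estimate_block_probabilities(partition, ensemble)
        restricted = restricted_block_probabilities(partition, ensemble, np.ones(12, bool))
        assert np.allclose(full.p_hat, restricted.p_hat)

    def test_excluded_class_zeroed(self):
        rng = np.random.default_rng(3)
        dense = (rng.random((9, 9)) < 0.6).astype(int)
        np.fill_diagonal(dense, 0)
        partition = partition_from_labels(block_labels(9, 3))
        mask = partition.labels != 2
        bpm = restricted_block_probabilities(partition, single_graph_ensemble(dense), mask)
        assert np.all(bpm.p_hat[1, :] == 0.0)
        assert np.all(bpm.p_hat[:, 1] == 0.0)

    def test_empty_mask_warns(self):
        partition = partition_from_labels([1, 1, 2, 2])
        bpm = restricted_block_probabilities(
            partition, single_graph_ensemble(np.zeros((4, 4))), np.zeros(4, bool)
        )
        assert bpm.warning is not None
        assert np.all(bpm.p_hat == 0.0)

    def test_marked_subpopulation_recovered(self):
        # only population-A neurons carry cross-block edges
        n, G = 400, 10
        truth = block_labels(n, 2)
        pop_a = np.zeros(n, bool)
        pop_a[::2] = True
        p_cross = 0.3
        rng = np.random.default_rng(4)
        graphs = []
        for _ in range(G):
            dense = np.zeros((n, n), dtype=np.int8)
            a_idx = np.nonzero(pop_a & (truth == 1))[0]
            b_idx = np.nonzero(pop_a & (truth == 2))[0]
            block = rng.random((a_idx.size, b_idx.size)) < p_cross
            dense[np.ix_(a_idx, b_idx)] = block
            graphs.append(sp.csr_matrix(dense))
        ensemble = BinaryEnsemble(graphs=graphs, retained=[np.arange(n)] * G, n=n)
        partition = partition_from_labels(truth)
        bpm = restricted_block_probabilities(partition, ensemble, pop_a)
        pairs = (pop_a & (truth == 1)).sum() * (pop_a & (truth == 2)).sum()
        se = np.sqrt(p_cross * (1 - p_cross) / (pairs * G))
        assert abs(bpm.p_hat[0, 1] - p_cross) <= 3 * se


class TestFloorToCircuit:
    def bpm(self, p, sizes=None):
        p = np.asarray(p, dtype=float)
        sizes = np.full(p.shape[0], 10) if sizes is None else np.asarray(sizes)
        return BlockProbabilityMatrix(p_hat=p, class_sizes=sizes, kappa=p.shape[0])

    def test_stray_edge_removed_with_threshold(self):
        p = np.zeros((3, 3))
        p[0, 1] = 0.5
        p[1, 2] = 0.5
        p[0, 2] = 0.001
        circuit = floor_to_circuit(self.bpm(p))
        assert circuit.floor_threshold == pytest.approx(0.001)
        assert circuit.p[0, 2] == 0.0
        assert circuit.p[0, 1] == 0.5 and circuit.p[1, 2] == 0.5

    def test_single_incident_edge_survives(self):
        p = np.zeros((3, 3))
        p[0, 1] = 0.5
        p[1, 2] = 0.5
        p[2, 0] = 1e-9  # class 2's only outgoing, but it has an incoming
        circuit = floor_to_circuit(self.bpm(p))
        # removing 2->0 keeps class 2 covered via 1->2; but then 0 retains 0->1
        assert circuit.p[2, 0] == 0.0
        # every class still has an incident edge
        incident = (circuit.p.sum(0) + circuit.p.sum(1)) > 0
        assert incident.all()

    def test_uniform_complete_circuit_stops_before_isolation(self):
        p = np.full((3, 3), 0.2)
        np.fill_diagonal(p, 0.0)
        circuit = floor_to_circuit(self.bpm(p))
        incident = (circuit.p.sum(0) + circuit.p.sum(1)) > 0
        assert incident.all()
        assert circuit.n_edges >= 2  # cannot floor below coverage

    def test_never_isolates_and_threshold_reproduces(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random((4, 4)) * (rng.random((4, 4)) < 0.7)
            np.fill_diagonal(p, 0.0)
            if not p.any() or np.any((p.sum(0) + p.sum(1)) == 0):
                continue
            circuit = floor_to_circuit(self.bpm(p))
            incident = (circuit.p.sum(0) + circuit.p.sum(1)) > 0
            assert incident.all()
            # distinct random values: survivors are exactly entries > threshold
            expected = np.where(p > circuit.floor_threshold, p, 0.0)
            assert np.allclose(circuit.p, expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            floor_to_circuit(self.bpm(np.zeros((2, 2))))


class TestTopFractionEdges:
    def circuit(self, p):
        p = np.asarray(p, dtype=float)
        return Circuit(p=p, class_sizes=np.full(p.shape[0], 5))

    def test_fraction_one_unchanged(self):
        p = np.zeros((3, 3))
        p[0, 1], p[1, 2] = 0.5, 0.3
        out = top_fraction_edges(self.circuit(p), 1.0)
        assert np.allclose(out.p, p)

    def test_top_fifth_of_ten_distinct(self):
        p = np.zeros((4, 4))
        weights = np.linspace(0.1, 1.0, 10)
        slots = [(i, j) for i in range(4) for j in range(4) if i != j][:10]
        for (i, j), w in zip(slots, weights):
            p[i, j] = w
        out = top_fraction_edges(self.circuit(p), 0.2)
        assert out.n_edges == 2
        assert out.p.max() == pytest.approx(1.0)
        assert sorted(out.p[out.p > 0].tolist()) == pytest.approx([0.9, 1.0])

    def test_ties_at_cutoff_all_kept(self):
        p = np.zeros((3, 3))
        p[0, 1] = p[1, 2] = p[2, 0] = 0.4  # three tied edges
        p[0, 2] = 0.9
        out = top_fraction_edges(self.circuit(p), 0.5)  # ceil(0.5*4)=2 -> tie at 0.4
        assert out.n_edges == 4

    def test_isolated_nodes_flagged(self):
        p = np.zeros((3, 3))
        p[0, 1] = 1.0
        p[1, 2] = 0.1
        out = top_fraction_edges(self.circuit(p), 0.34)
        assert 2 in out.isolated_flagged

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            top_fraction_edges(self.circuit(np.zeros((2, 2))), 0.0)
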