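import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from agglomnet.block_model import (
    BlockCharacteristics,
    BlockPartition,
    block_characteristics,
    block_table,
    classify_role,
    concor,
    flow_matrix_from_margins,
    inter_block_matrix,
    network_from_block_counts,
)
from agglomnet.gravity_network import SpatialNetwork
from agglomnet.synthetic_data import SyntheticSpec, generate_planted_network

from oracles import random_digraph

# Published 2018 reference block table: sizes, intra ties, off-block
# sent/received, and the resulting role labels.
REF_SIZES = [8, 7, 7, 9]
REF_INTRA = [17, 22, 15, 19]
REF_SENT = [44, 43, 37, 22]
REF_RECEIVED = [29, 38, 44, 35]
REF_ROLES = ["net_spillover", "bidirectional_spillover", "mediator", "net_beneficial"]


@pytest.fixture(scope="module")
def reference_network():
    flows = flow_matrix_from_margins(REF_SENT, REF_RECEIVED, REF_SIZES)
    return network_from_block_counts(REF_SIZES, REF_INTRA, flows)


def two_cliques(k=4):
    n = 2 * k
    a = np.zeros((n, n), dtype=int)
    a[:k, :k] = 1
    a[k:, k:] = 1
    np.fill_diagonal(a, 0)
    return a


class TestConcor:
    def test_two_cliques_depth1(self):
        part = concor(two_cliques(), depth=1)
        labels = part.assignment
        assert adjusted_rand_score([0] * 4 + [1] * 4, labels) == 1.0

    def test_depth2_at_most_four_blocks(self, rng):
        a = random_digraph(rng, 31, 0.3)
        part = concor(a, depth=2)
        assert part.n_blocks <= 4
        assert np.all(part.assignment >= 1)

    def test_planted_four_blocks_recovered(self):
        spec = SyntheticSpec(seed=3, block_plant=(8, 7, 7, 9))
        net, labels = generate_planted_network(spec)
        part = concor(net, depth=2, tolerance=0.2)
        assert adjusted_rand_score(labels, part.assignment) > 0.9

    def test_too_few_nodes(self):
        with pytest.raises(ValueError, match="at least 4"):
            concor(np.zeros((3, 3), dtype=int))

    def test_bad_depth(self):
        with pytest.raises(ValueError, match="depth"):
            concor(two_cliques(), depth=0)

    def test_every_region_assigned(self, rng):
        a = random_digraph(rng, 12, 0.2)
        part = concor(a, depth=2)
        assert part.assignment.shape == (12,)
        assert np.all(part.assignment >= 1)

    def test_isolates_assigned_deterministically(self):
        a = two_cliques()
        n = a.shape[0]
        b = np.zeros((n + 1, n + 1), dtype=int)
        b[:n, :n] = a
        part1 = concor(b, depth=1)
        part2 = concor(b, depth=1)
        np.testing.assert_array_equal(part1.assignment, part2.assignment)
        # isolate has no ties anywhere: lowest block id
        assert part1.assignment[n] == 1

    def test_label_permutation_equivariance(self, rng):
        a = random_digraph(rng, 10, 0.35)
        base = concor(a, depth=2).assignment
        perm = rng.permutation(10)
        permuted = concor(a[np.ix_(perm, perm)], depth=2).assignment
        assert adjusted_rand_score(base[perm], permuted) == 1.0


class TestBlockCharacteristics:
    def test_reference_counts_reproduced(self, reference_network):
        net, part = reference_network
        chars = block_characteristics(net, part)
        assert [b.intra_ties for b in chars] == REF_INTRA
        assert [b.out_ties for b in chars] == REF_SENT
        assert [b.in_ties for b in chars] == REF_RECEIVED

    def test_expected_proportion_eight_of_31(self, reference_network):
        net, part = reference_network
        chars = block_characteristics(net, part)
        assert chars[0].expected_internal_pct == pytest.approx(100 * 7 / 30)
        assert round(chars[0].expected_internal_pct, 2) == 23.33

    def test_actual_proportion_19_intra_22_off(self, reference_network):
        net, part = reference_network
        chars = block_characteristics(net, part)
        assert chars[3].actual_internal_pct == pytest.approx(100 * 19 / 41)
        assert round(chars[3].actual_internal_pct, 2) == 46.34

    def test_single_block_partition(self):
        a = two_cliques()
        ids = [f"r{i}" for i in range(8)]
        part = BlockPartition(np.ones(8, dtype=int), ids, depth=1, tolerance=0.2)
        chars = block_characteristics(SpatialNetwork(a, ids), part)
        assert len(chars) == 1
        assert chars[0].actual_internal_pct == 100.0
        assert chars[0].out_ties == 0 and chars[0].in_ties == 0

    def test_conservation(self, rng):
        for _ in range(20):
            a = random_digraph(rng, 12, 0.3)
            labels = rng.integers(1, 4, size=12)
            labels[:3] = [1, 2, 3]  # ensure non-empty
            part = BlockPartition(labels, [f"r{i}" for i in range(12)], 2, 0.2)
            chars = block_characteristics(a, part)
            assert sum(b.out_ties for b in chars) == sum(b.in_ties for b in chars)
            assert sum(b.intra_ties + b.out_ties for b in chars) == a.sum()

    def test_inter_block_matrix_consistent(self, reference_network):
        net, part = reference_network
        M = inter_block_matrix(net, part)
        np.testing.assert_array_equal(np.diag(M), REF_INTRA)
        chars = block_characteristics(net, part)
        off = M - np.diag(np.diag(M))
        np.testing.assert_array_equal(off.sum(axis=1), [b.out_ties for b in chars])
        np.testing.assert_array_equal(off.sum(axis=0), [b.in_ties for b in chars])


class TestClassifyRole:
    def test_reference_roles(self, reference_network):
        net, part = reference_network
        chars = block_characteristics(net, part)
        assert [b.role for b in chars] == REF_ROLES

    def test_sender_dominant_sparse_is_net_spillover(self):
        b = BlockCharacteristics(1, 8, [], 17, 44, 29, 23.33, 27.87)
        assert classify_role(b) == "net_spillover"

    def test_receiver_dominant_dense_is_net_beneficial(self):
        b = BlockCharacteristics(4, 9, [], 19, 22, 35, 26.67, 46.34)
        assert classify_role(b) == "net_beneficial"

    def test_balanced_symmetric_dense_is_bidirectional(self):
        b = BlockCharacteristics(1, 4, [], 10, 5, 5, 10.0, 50.0)
        assert classify_role(b) == "bidirectional_spillover"

    def test_balanced_sparse_is_mediator(self):
        b = BlockCharacteristics(1, 4, [], 1, 10, 10, 30.0, 9.1)
        assert classify_role(b) == "mediator"

    def test_block_table_shape(self, reference_network):
        net, part = reference_network
        tbl = block_table(block_characteristics(net, part))
        assert list(tbl.columns) == [
            "size",
            "intra_ties",
            "received_off_block",
            "sent_off_block",
            "expected_internal_pct",
            "actual_internal_pct",
            "role",
        ]
        assert len(tbl) == 4


class TestFixtures:
    def test_flow_matrix_margins(self):
        F = flow_matrix_from_margins(REF_SENT, REF_RECEIVED, REF_SIZES)
        np.testing.assert_array_equal(F.sum(axis=1), REF_SENT)
        np.testing.assert_array_equal(F.sum(axis=0), REF_RECEIVED)
        np.testing.assert_array_equal(np.diag(F), 0)

    def test_flow_matrix_infeasible(self):
        with pytest.raises(ValueError, match="total sent"):
            flow_matrix_from_margins([5, 5], [4, 5], [3, 3])

    def test_network_from_counts_too_many_ties(self):
        with pytest.raises(ValueError, match="not enough dyads"):
            network_from_block_counts([2, 2], [5, 0], np.zeros((2, 2), dtype=int))
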