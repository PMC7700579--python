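"""CONCOR blockmodel, block tie tabulation, and the four-role typology.

CONCOR (convergence of iterated correlations) repeatedly replaces a
node-profile correlation matrix by the correlation matrix of its own rows
until every off-diagonal entry is (close to) +1 or -1, then splits nodes
by sign; recursing to a given depth yields up to 2^depth blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .gravity_network import SpatialNetwork

ROLES = ("net_spillover", "bidirectional_spillover", "mediator", "net_beneficial")


@dataclass
class BlockPartition:
    """Assignment of regions to blocks 1..B."""

    assignment: np.ndarray  # block id per region, 1-based
    region_ids: list[str]
    depth: int
    tolerance: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.shape != (len(self.region_ids),):
            raise ValueError("assignment length does not match region count")
        if self.assignment.min() < 1:
            raise ValueError("block ids are 1-based")

    @property
    def n_blocks(self) -> int:
        return len(np.unique(self.assignment))

    def members(self, block: int) -> list[str]:
        return [r for r, b in zip(self.region_ids, self.assignment) if b == block]


@dataclass
class BlockCharacteristics:
    """Per-block tie counts and the two internal-proportion statistics."""

    block: int
    size: int
    members: list[str]
    intra_ties: int
    out_ties: int   # directed ties sent to other blocks
    in_ties: int    # directed ties received from other blocks
    expected_internal_pct: float
    actual_internal_pct: float
    role: str | None = None


def _row_correlations(M: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows, robust to zero-variance rows.

    A zero-variance row correlates 1 with an identical row and 0 with
    everything else (deterministic stand-in for the undefined value).
    """
    M = np.asarray(M, dtype=float)
    k = M.shape[0]
    centered = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    C = np.zeros((k, k))
    ok = norms > 1e-12
    if ok.any():
        unit = np.zeros_like(centered)
        unit[ok] = centered[ok] / norms[ok, None]
        C = unit @ unit.T
    for i in np.where(~ok)[0]:
        for j in range(k):
            same = (not ok[j]) and np.allclose(M[i], M[j])
            C[i, j] = C[j, i] = 1.0 if same else 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def _pair_correlation(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx < 1e-12 or ny < 1e-12:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _profile_correlation(adjacency: np.ndarray) -> np.ndarray:
    """Structural-equivalence correlation between every pair of nodes.

    Each node's profile is its out-row concatenated with its in-column;
    for a pair (u, v) the positions belonging to u and v themselves are
    excluded on both sides, which keeps the measure invariant to node
    relabeling.  Zero-variance profiles correlate 1 with identical
    profiles and 0 otherwise.
    """
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    C = np.eye(n)
    for u in range(n):
        for v in range(u + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[u, v]] = False
            x = np.concatenate([A[u, keep], A[keep, u]])
            y = np.concatenate([A[v, keep], A[keep, v]])
            C[u, v] = C[v, u] = _pair_correlation(x, y)
    return C


def _concor_split(
    C_init: np.ndarray, idx: list[int], tolerance: float, max_iter: int
) -> tuple[list[int], list[int]]:
    """One CONCOR split of the node subset ``idx``; either side may be empty."""
    C = C_init[np.ix_(idx, idx)]
    for _ in range(max_iter):
        off = ~np.eye(C.shape[0], dtype=bool)
        if C.shape[0] < 2 or np.all(1.0 - np.abs(C[off]) <= tolerance):
            break
        C = _row_correlations(C)
    pos = C[0, :] >= 0
    left = [idx[i] for i in range(len(idx)) if pos[i]]
    right = [idx[i] for i in range(len(idx)) if not pos[i]]
    return left, right


def concor(
    net: SpatialNetwork | np.ndarray,
    depth: int = 2,
    tolerance: float = 0.2,
    max_iter: int = 100,
) -> BlockPartition:
    """Recursive CONCOR partition of a directed network.

    Splits recurse to ``depth`` levels (at most 2^depth blocks).  Groups
    of size 1, and groups whose converged correlations are all of one
    sign, are not split further.  Isolated nodes (empty profiles) are
    attached afterwards to the block with which they share most ties,
    ties broken toward the lowest block id.
    """
    adjacency = net.adjacency if isinstance(net, SpatialNetwork) else np.asarray(net)
    region_ids = (
        net.region_ids
        if isinstance(net, SpatialNetwork)
        else [f"r{i}" for i in range(adjacency.shape[0])]
    )
    n = adjacency.shape[0]
    if n < 4:
        raise ValueError("CONCOR needs at least 4 nodes")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    degree = adjacency.sum(axis=0) + adjacency.sum(axis=1)
    isolates = [i for i in range(n) if degree[i] == 0]
    active = [i for i in range(n) if degree[i] > 0]
    C_init = _profile_correlation(adjacency)

    groups: list[list[int]] = [active] if active else []
    for _ in range(depth):
        nxt: list[list[int]] = []
        for grp in groups:
            if len(grp) < 2:
                nxt.append(grp)
                continue
            left, right = _concor_split(C_init, grp, tolerance, max_iter)
            if not left or not right:
                nxt.append(grp)
            else:
                nxt.extend([left, right])
        groups = nxt

    assignment = np.zeros(n, dtype=int)
    for b, grp in enumerate(groups, start=1):
        for i in grp:
            assignment[i] = b
    for i in isolates:
        if groups:
            ties = np.array(
                [
                    sum(adjacency[i, j] + adjacency[j, i] for j in grp)
                    for grp in groups
                ]
            )
            assignment[i] = int(np.argmax(ties)) + 1  # argmax takes lowest id on ties
        else:
            assignment[i] = 1
    return BlockPartition(
        assignment=assignment,
        region_ids=region_ids,
        depth=depth,
        tolerance=tolerance,
    )


def block_characteristics(
    net: SpatialNetwork | np.ndarray,
    partition: BlockPartition,
    margin: float = 1.5,
) -> list[BlockCharacteristics]:
    """Tabulate per-block tie counts and internal-correlation proportions.

    expected internal % = (size - 1) / (t - 1); actual internal % =
    intra-block sent / total sent.  Each block is also classified into the
    four-role typology (see :func:`classify_role`).
    """
    adjacency = net.adjacency if isinstance(net, SpatialNetwork) else np.asarray(net)
    t = adjacency.shape[0]
    labels = partition.assignment
    out = []
    for b in sorted(np.unique(labels)):
        mask = labels == b
        size = int(mask.sum())
        intra = int(adjacency[np.ix_(mask, mask)].sum())
        sent = int(adjacency[np.ix_(mask, ~mask)].sum())
        received = int(adjacency[np.ix_(~mask, mask)].sum())
        expected = 100.0 * (size - 1) / (t - 1)
        total_sent = intra + sent
        actual = 100.0 * intra / total_sent if total_sent else 0.0
        bc = BlockCharacteristics(
            block=int(b),
            size=size,
            members=partition.members(int(b)),
            intra_ties=intra,
            out_ties=sent,
            in_ties=received,
            expected_internal_pct=expected,
            actual_internal_pct=actual,
        )
        bc.role = classify_role(bc, margin=margin)
        out.append(bc)
    return out


def classify_role(block: BlockCharacteristics, margin: float = 1.5) -> str:
    """Classify a block into the four-role spillover typology.

    A block is *internally dense* when its actual internal proportion is
    at least ``margin`` times the expected proportion.  Dense blocks are
    ``net_beneficial`` if they receive more external ties than they send,
    else ``bidirectional_spillover``; sparse blocks are ``net_spillover``
    if they send more than they receive, else ``mediator``.
    """
    dense = block.actual_internal_pct >= margin * block.expected_internal_pct
    if dense:
        return "net_beneficial" if block.in_ties > block.out_ties else "bidirectional_spillover"
    return "net_spillover" if block.out_ties > block.in_ties else "mediator"


def block_table(blocks: list[BlockCharacteristics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block": [b.block for b in blocks],
            "size": [b.size for b in blocks],
            "intra_ties": [b.intra_ties for b in blocks],
            "received_off_block": [b.in_ties for b in blocks],
            "sent_off_block": [b.out_ties for b in blocks],
            "expected_internal_pct": [b.expected_internal_pct for b in blocks],
            "actual_internal_pct": [b.actual_internal_pct for b in blocks],
            "role": [b.role for b in blocks],
        }
    ).set_index("block")


def inter_block_matrix(
    net: SpatialNetwork | np.ndarray, partition: BlockPartition
) -> np.ndarray:
    """Directed tie counts aggregated to block level (diagonal = intra)."""
    adjacency = net.adjacency if isinstance(net, SpatialNetwork) else np.asarray(net)
    blocks = sorted(np.unique(partition.assignment))
    B = len(blocks)
    M = np.zeros((B, B), dtype=int)
    for a_i, a in enumerate(blocks):
        for b_i, b in enumerate(blocks):
            src = partition.assignment == a
            dst = partition.assignment == b
            sub = adjacency[np.ix_(src, dst)]
            M[a_i, b_i] = int(sub.sum()) - (int(np.trace(sub)) if a == b else 0)
    return M


def flow_matrix_from_margins(
    sent: list[int], received: list[int], sizes: list[int]
) -> np.ndarray:
    """Find integer off-diagonal block flows matching row/column margins.

    Solves a small transportation problem (max-flow with integer
    capacities) so that row b sums to ``sent[b]``, column b sums to
    ``received[b]``, the diagonal is zero, and no cell exceeds the number
    of possible inter-block dyads.  Raises if the margins are infeasible.
    """
    B = len(sizes)
    if sum(sent) != sum(received):
        raise ValueError("total sent must equal total received")
    G = nx.DiGraph()
    for a in range(B):
        G.add_edge("S", f"row{a}", capacity=sent[a])
        G.add_edge(f"col{a}", "T", capacity=received[a])
        for b in range(B):
            if a != b:
                G.add_edge(f"row{a}", f"col{b}", capacity=sizes[a] * sizes[b])
    value, flow = nx.maximum_flow(G, "S", "T")
    if value != sum(sent):
        raise ValueError("infeasible block-flow margins")
    F = np.zeros((B, B), dtype=int)
    for a in range(B):
        for b in range(B):
            if a != b:
                F[a, b] = flow[f"row{a}"].get(f"col{b}", 0)
    return F


def network_from_block_counts(
    sizes: list[int],
    intra: list[int],
    flows: np.ndarray,
    region_ids: list[str] | None = None,
) -> tuple[SpatialNetwork, BlockPartition]:
    """Construct a concrete network realizing block-level tie counts.

    Within each block, the first ``intra[b]`` ordered off-diagonal dyads
    become ties; between blocks a and b, the first ``flows[a, b]`` dyads.
    Used to materialize published block tables as testable fixtures.
    """
    B = len(sizes)
    n = sum(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    adjacency = np.zeros((n, n), dtype=int)

    def fill(src: range, dst: range, count: int) -> None:
        placed = 0
        for u in src:
            for v in dst:
                if u == v:
                    continue
                if placed == count:
                    return
                adjacency[u, v] = 1
                placed += 1
        if placed < count:
            raise ValueError("not enough dyads to place requested ties")

    for b in range(B):
        fill(range(starts[b], starts[b + 1]), range(starts[b], starts[b + 1]), intra[b])
    for a in range(B):
        for b in range(B):
            if a != b:
                fill(
                    range(starts[a], starts[a + 1]),
                    range(starts[b], starts[b + 1]),
                    int(flows[a, b]),
                )

    ids = region_ids or [f"r{i:02d}" for i in range(n)]
    net = SpatialNetwork(adjacency=adjacency, region_ids=ids)
    assignment = np.concatenate(
        [np.full(sizes[b], b + 1, dtype=int) for b in range(B)]
    )
    partition = BlockPartition(
        assignment=assignment, region_ids=ids, depth=1, tolerance=0.0
    )
    return net, partition
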