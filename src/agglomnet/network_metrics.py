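"""Whole-network structure statistics and node centralities.

Density and efficiency use the unordered-pair tie count (a reciprocated
pair counts once) so that both stay within [0, 1] against the t(t-1)/2
denominator; the directed tie count is reported separately.  Betweenness
is computed on the directed graph; closeness on the symmetrized graph
with unreachable distances capped at the node count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .gravity_network import SpatialNetwork


@dataclass
class NetworkSummary:
    density: float
    level: float | None
    efficiency: float
    tie_count: int            # unordered connected pairs (s of the density formula)
    directed_tie_count: int
    node_count: int
    bidirectional_count: int  # alpha: reciprocated pairs
    unidirectional_count: int  # beta: one-way pairs
    out_centralization_pct: float
    in_centralization_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def _adj(net: SpatialNetwork | np.ndarray) -> np.ndarray:
    a = net.adjacency if isinstance(net, SpatialNetwork) else np.asarray(net)
    return a.astype(int)


def tie_counts(net: SpatialNetwork | np.ndarray) -> tuple[int, int, int, int]:
    """Return (connected_pairs, directed_ties, alpha, beta).

    alpha counts reciprocated unordered pairs, beta one-way pairs;
    connected_pairs = alpha + beta.
    """
    a = _adj(net)
    directed = int(a.sum())
    both = a & a.T
    alpha = int(np.triu(both, 1).sum())
    either = a | a.T
    pairs = int(np.triu(either, 1).sum())
    return pairs, directed, alpha, pairs - alpha


def density(net: SpatialNetwork | np.ndarray) -> float:
    """Share of realized unordered connected pairs: s / (t(t-1)/2)."""
    a = _adj(net)
    t = a.shape[0]
    if t < 2:
        raise ValueError("density needs at least 2 nodes")
    pairs, _, _, _ = tie_counts(a)
    return min(pairs / (t * (t - 1) / 2), 1.0)


def level(net: SpatialNetwork | np.ndarray) -> float | None:
    """Share of connected pairs that are unreciprocated: 1 - alpha/(alpha+beta).

    Returns None (undefined) on a network without ties.
    """
    pairs, _, alpha, beta = tie_counts(net)
    if pairs == 0:
        return None
    return beta / (alpha + beta)


def efficiency(net: SpatialNetwork | np.ndarray) -> float:
    """Redundancy-based looseness: 1 - (s-(t-1)) / (t(t-1)/2 - (t-1)).

    1 at the spanning-tree minimum of t-1 connected pairs, 0 when every
    pair is connected.  Values above 1 (fewer pairs than a spanning tree)
    are reported as computed.
    """
    a = _adj(net)
    t = a.shape[0]
    if t < 3:
        raise ValueError("efficiency needs at least 3 nodes")
    pairs, _, _, _ = tie_counts(a)
    return 1.0 - (pairs - (t - 1)) / (t * (t - 1) / 2 - (t - 1))


def degree_centrality(net: SpatialNetwork | np.ndarray) -> np.ndarray:
    """Per node: (out-degree + in-degree) / (2(L-1))."""
    a = _adj(net)
    L = a.shape[0]
    if L < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    return (a.sum(axis=1) + a.sum(axis=0)) / (2 * (L - 1))


def betweenness_centrality(
    net: SpatialNetwork | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Directed-geodesic betweenness; returns (raw, normalized).

    The geodesic-share sum runs over ordered (j, k) pairs and is halved
    for the raw score, so a star centre on a reciprocated L-star scores
    C(L-1, 2).  Normalized = raw * 2 / (L^2 - 3L + 2), in [0, 1].
    """
    a = _adj(net)
    L = a.shape[0]
    G = nx.from_numpy_array(a, create_using=nx.DiGraph)
    bc = nx.betweenness_centrality(G, normalized=False)
    ordered = np.array([bc[i] for i in range(L)], dtype=float)
    raw = ordered / 2.0
    if L >= 3:
        norm = ordered / ((L - 1) * (L - 2))
    else:
        norm = np.zeros(L)
    return raw, norm


def closeness_centrality(
    net: SpatialNetwork | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Closeness on the symmetrized graph; returns (raw, normalized).

    raw = 1 / sum_j d(q, j); normalized = (L-1) / sum_j d(q, j).
    Unreachable pairs contribute distance L (node count).
    """
    a = _adj(net)
    L = a.shape[0]
    if L < 2:
        raise ValueError("closeness needs at least 2 nodes")
    sym = a | a.T
    G = nx.from_numpy_array(sym, create_using=nx.Graph)
    raw = np.empty(L)
    norm = np.empty(L)
    for q in range(L):
        dist = nx.single_source_shortest_path_length(G, q)
        total = sum(dist.get(j, L) for j in range(L) if j != q)
        raw[q] = 1.0 / total
        norm[q] = (L - 1) / total
    return raw, norm


def _degree_centralization(deg: np.ndarray, L: int) -> float:
    """Freeman-style centralization of a degree vector, in percent."""
    if L < 2:
        return 0.0
    return 100.0 * float((deg.max() - deg).sum()) / ((L - 1) ** 2)


def network_share_summary(net: SpatialNetwork | np.ndarray) -> tuple[float, float]:
    """Descriptive (out, in) degree centralization of the network, percent.

    The aggregation behind published single-number out/in network shares
    is not standardized; this is one reasonable convention and is not
    claimed to reproduce any published figure.
    """
    a = _adj(net)
    L = a.shape[0]
    return (
        _degree_centralization(a.sum(axis=1).astype(float), L),
        _degree_centralization(a.sum(axis=0).astype(float), L),
    )


def summarize(net: SpatialNetwork | np.ndarray) -> NetworkSummary:
    a = _adj(net)
    pairs, directed, alpha, beta = tie_counts(a)
    out_c, in_c = network_share_summary(a)
    return NetworkSummary(
        density=density(a),
        level=level(a),
        efficiency=efficiency(a),
        tie_count=pairs,
        directed_tie_count=directed,
        node_count=a.shape[0],
        bidirectional_count=alpha,
        unidirectional_count=beta,
        out_centralization_pct=out_c,
        in_centralization_pct=in_c,
    )


def centrality_table(net: SpatialNetwork) -> pd.DataFrame:
    """Per-region centrality table (degree, betweenness, closeness)."""
    a = net.adjacency
    bet_raw, bet_norm = betweenness_centrality(a)
    clo_raw, clo_norm = closeness_centrality(a)
    return pd.DataFrame(
        {
            "region_id": net.region_ids,
            "out_degree": a.sum(axis=1),
            "in_degree": a.sum(axis=0),
            "degree_centrality": degree_centrality(a),
            "betweenness_raw": bet_raw,
            "betweenness_norm": bet_norm,
            "closeness_raw": clo_raw,
            "closeness_norm": clo_norm,
        }
    ).set_index("region_id")
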