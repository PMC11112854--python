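"""Protein-association network construction, statistics and clustering.

Edges carry a confidence score in [0, 1]; the network keeps edges at or
above a minimum confidence (default 0.400, the conventional medium-high
STRING cutoff) over a declared protein universe.  Descriptive statistics
follow the reporting convention edges-per-protein = edges / universe size.
Edge-count excess over chance is assessed with an explicit permutation
null (uniform random subsets of a background proteome network), and the
network is partitioned by confidence-weighted greedy modularity
maximisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import LikError, ParameterError


def build_network(
    edges: pd.DataFrame,
    node_universe: list[str] | None = None,
    min_confidence: float = 0.4,
    inclusive: bool = True,
) -> nx.Graph:
    """Filter a (a, b, confidence) frame into an undirected weighted graph.

    Edges below the cutoff are dropped (``inclusive=True`` keeps an edge at
    exactly the cutoff).  When a universe is given, edges touching nodes
    outside it are dropped and every universe protein is present as a node,
    isolated ones included.
    """
    g = nx.Graph()
    if node_universe is not None:
        g.add_nodes_from(node_universe)
        allowed = set(node_universe)
    for _, a, b, conf in edges[["a", "b", "confidence"]].itertuples():
        if a == b:
            continue
        keep = conf >= min_confidence if inclusive else conf > min_confidence
        if not keep:
            continue
        if node_universe is not None and (a not in allowed or b not in allowed):
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    return g


def network_stats(net: nx.Graph, total_proteins: int) -> dict[str, float]:
    """Edge count, edges per protein (1-decimal reporting convention),
    connected-node count and mean degree over connected nodes."""
    if total_proteins <= 0:
        raise ParameterError("total_proteins must be positive")
    n_edges = net.number_of_edges()
    degrees = [d for _, d in net.degree()]
    n_connected = sum(1 for d in degrees if d >= 1)
    return {
        "n_edges": n_edges,
        "edges_per_protein": round(n_edges / total_proteins, 1),
        "n_connected": n_connected,
        "mean_degree": (2 * n_edges / n_connected) if n_connected else 0.0,
    }


@dataclass(frozen=True)
class EdgeNullResult:
    observed_edges: int
    expected_edges: float
    p_value: float
    n_permutations: int
    seed: int


def permutation_edge_null(
    universe_network: nx.Graph,
    subset: list[str] | None = None,
    observed_edges: int | None = None,
    subset_size: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> EdgeNullResult:
    """Null distribution of induced-edge counts for random protein subsets.

    Draws ``n_perm`` uniform subsets without replacement from the universe
    network, each the size of the candidate ``subset`` (or the explicit
    ``subset_size``), counts the edges each induces, and reports the null
    mean and the add-one upper-tail p-value
    (1 + #{null >= observed}) / (n_perm + 1).  The observed count comes
    from ``subset`` (its induced edges) or from ``observed_edges``.
    """
    if subset is not None:
        missing = [n for n in subset if n not in universe_network]
        if missing:
            raise ParameterError(
                f"{len(missing)} subset node(s) absent from the universe")
        subset_size = len(set(subset))
        observed_edges = universe_network.subgraph(subset).number_of_edges()
    if subset_size is None or observed_edges is None:
        raise ParameterError("provide subset, or subset_size and observed_edges")
    nodes = np.array(sorted(universe_network.nodes()))
    if subset_size > nodes.size:
        raise ParameterError("subset_size exceeds the universe")
    idx = {n: i for i, n in enumerate(nodes)}
    edge_arr = np.array(
        [[idx[a], idx[b]] for a, b in universe_network.edges()], dtype=np.int64
    ).reshape(-1, 2)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=np.int64)
    member = np.zeros(nodes.size, dtype=bool)
    for i in range(n_perm):
        pick = rng.choice(nodes.size, size=subset_size, replace=False)
        member[:] = False
        member[pick] = True
        if edge_arr.size:
            counts[i] = np.count_nonzero(member[edge_arr[:, 0]] & member[edge_arr[:, 1]])
        else:
            counts[i] = 0
    p = (1 + int((counts >= observed_edges).sum())) / (n_perm + 1)
    return EdgeNullResult(
        observed_edges=int(observed_edges),
        expected_edges=float(counts.mean()),
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class CommunityPartition:
    """Dense 1-based cluster labels over the non-isolated node set."""

    assignment: dict[str, int]
    modularity: float

    @property
    def n_clusters(self) -> int:
        return max(self.assignment.values(), default=0)

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.assignment.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["node", "cluster"])


def detect_communities(net: nx.Graph, seed: int = 0) -> CommunityPartition:
    """Confidence-weighted greedy modularity clustering of the non-isolated
    subgraph.  The greedy merge order is deterministic given the node set,
    so the result is reproducible; clusters are numbered 1..k by
    decreasing size (ties by smallest member id).
    """
    core = net.subgraph([n for n, d in net.degree() if d >= 1])
    if core.number_of_edges() == 0:
        raise LikError("network has no edges; skip clustering")
    comms = nx.community.greedy_modularity_communities(core, weight="confidence")
    comms = sorted(
        (sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    assignment = {n: i for i, c in enumerate(comms, start=1) for n in c}
    q = nx.community.modularity(
        core, [set(c) for c in comms], weight="confidence")
    return CommunityPartition(assignment=assignment, modularity=q)


def cluster_degree_stats(net: nx.Graph, partition: CommunityPartition) -> dict[int, float]:
    """Mean within-cluster degree per cluster: for each member node, the
    number of its edges that stay inside its own cluster, averaged."""
    totals: dict[int, list[int]] = {}
    for node, cluster in partition.assignment.items():
        within = sum(
            1 for nb in net.neighbors(node)
            if partition.assignment.get(nb) == cluster)
        totals.setdefault(cluster, []).append(within)
    return {c: float(np.mean(v)) for c, v in sorted(totals.items())}
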