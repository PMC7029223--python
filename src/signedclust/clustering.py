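"""Cluster assignment from the scoring matrix.

Rows of the scoring matrix are treated as node features and grouped by
agglomerative clustering (Ward's minimum-variance linkage on Euclidean
distances).  The number of clusters is chosen by maximizing the sparsity
score, an edge-sign bookkeeping statistic in [−1, 1] that rewards positive
intracluster and negative intercluster edges.  Small clusters — typically
an artifact of high-scoring central nodes — are dissolved, the retained
submatrix re-clustered, and the removed nodes reattached by average
shortest-path weight products.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import networkx as nx
import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .graph_io import SignedGraph
from .matrix_core import ScoringMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "ClusteringParams",
    "sparsity_score",
    "agglomerate",
    "select_assignment",
    "reassign_small",
]


@dataclass
class ClusterAssignment:
    """Node-to-cluster map with per-node weak flags.

    Cluster ids are integers ``0..k−1`` assigned by decreasing cluster
    size, ties broken by lexicographically smallest member, so output is
    stable across runs.  ``sparsity`` is the assignment's sparsity score on
    the graph it was computed from.
    """

    membership: Dict[str, int]
    weak: Dict[str, bool]
    k: int
    sparsity: float

    def cluster_members(self) -> Dict[int, set]:
        out: Dict[int, set] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return out


@dataclass
class ClusteringParams:
    """min/max cluster-number search range and the small-cluster threshold.

    ``minsize`` is a fraction of the node count; clusters smaller than
    ``minsize × |V|`` are dissolved and their nodes reattached.  Linkage is
    fixed to Ward on Euclidean distances.
    """

    min_clusters: int = 2
    max_clusters: int = 4
    minsize: float = 0.1

    def __post_init__(self):
        if not (2 <= self.min_clusters <= self.max_clusters):
            raise ValueError("need 2 <= min_clusters <= max_clusters")
        if not (0 <= self.minsize < 0.5):
            raise ValueError("minsize must be in [0, 0.5)")


def sparsity_score(g: SignedGraph, membership: Mapping[str, int]) -> float:
    """Sparsity score of a cluster assignment.

    With C the set of intracluster edges and N all edges,

        s = (|e(w<0) ∉ C| + |e(w>0) ∈ C| − |e(w<0) ∈ C| − |e(w>0) ∉ C|) / |N|

    so s = 1 when every positive edge is inside a cluster and every
    negative edge crosses clusters, and s = −1 in the mirrored worst case.
    """
    n_edges = g.n_edges
    if n_edges == 0:
        raise ValueError("sparsity score is undefined on an edgeless graph")
    score = 0
    for u, v, w in g.edges():
        internal = membership[u] == membership[v]
        if w > 0:
            score += 1 if internal else -1
        else:
            score += -1 if internal else 1
    return score / n_edges


def agglomerate(m: ScoringMatrix, k: int) -> Dict[str, int]:
    """Ward agglomerative clustering of scoring-matrix rows into k groups."""
    n = len(m.nodes)
    if k > n:
        raise ValueError(f"k={k} exceeds node count {n}")
    if k == n:
        labels = np.arange(n)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        labels = model.fit_predict(m.values)
    return dict(zip(m.nodes, (int(x) for x in labels)))


def _relabel(membership: Mapping[str, int]) -> Dict[str, int]:
    """Renumber cluster ids by decreasing size, then smallest member."""
    groups: Dict[int, list] = {}
    for node, cid in membership.items():
        groups.setdefault(cid, []).append(node)
    order = sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c])))
    remap = {old: new for new, old in enumerate(order)}
    return {node: remap[cid] for node, cid in membership.items()}


def select_assignment(
    g: SignedGraph,
    m: ScoringMatrix,
    params: Optional[ClusteringParams] = None,
) -> ClusterAssignment:
    """Choose the cluster number maximizing the sparsity score.

    Every k in ``[min_clusters, max_clusters]`` is evaluated; ties break
    toward smaller k.  Small clusters are then dissolved and reattached by
    :func:`reassign_small`.  If the graph has no negative edges a log
    message flags that the score cannot reach 1 with more than one cluster
    (sign information is what the method exploits).
    """
    params = params or ClusteringParams()
    if not any(w < 0 for _, _, w in g.edges()):
        logger.warning(
            "graph has no negative edges: every multi-cluster assignment "
            "cuts positive edges and the sparsity score cannot reach 1"
        )
    best = None
    upper = min(params.max_clusters, g.n_nodes)
    for k in range(params.min_clusters, upper + 1):
        membership = agglomerate(m, k)
        s = sparsity_score(g, membership)
        if best is None or s > best[0]:
            best = (s, k, membership)
    if best is None:
        raise ValueError("empty cluster-number search range")
    s, k, membership = best
    membership = _relabel(membership)
    assignment = ClusterAssignment(
        membership=membership,
        weak={n: False for n in membership},
        k=len(set(membership.values())),
        sparsity=s,
    )
    return reassign_small(g, m, assignment, params.minsize, params)


# -- small-cluster dissolution ---------------------------------------------


def _mean_path_product(nxg: nx.Graph, v: str, u: str) -> float:
    """Mean over all fewest-hop paths v→u of the product of edge weights.

    Unreachable pairs contribute 0 (no path evidence).
    """
    try:
        paths = nx.all_shortest_paths(nxg, v, u)
        products = []
        for path in paths:
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= nxg[a][b]["weight"]
            products.append(prod)
    except nx.NetworkXNoPath:
        return 0.0
    return float(np.mean(products)) if products else 0.0


def reassign_small(
    g: SignedGraph,
    m: ScoringMatrix,
    assignment: ClusterAssignment,
    minsize: float,
    params: Optional[ClusteringParams] = None,
) -> ClusterAssignment:
    """Dissolve clusters below ``minsize × |V|`` and reattach their nodes.

    Rows/columns of the scoring matrix belonging to small clusters are
    removed, the remaining submatrix is re-clustered with the same
    cluster-number selection, and each removed node is assigned to the
    retained cluster maximizing the mean (over cluster members, over all
    fewest-hop paths) edge-weight product from the node to the member.

    If every cluster is small the original assignment is returned with a
    warning.
    """
    params = params or ClusteringParams()
    threshold = minsize * g.n_nodes
    members = assignment.cluster_members()
    small = {cid for cid, nodes in members.items() if len(nodes) < threshold}
    if not small:
        return assignment
    if len(small) == len(members):
        logger.warning("every cluster is below minsize; keeping assignment")
        return assignment
    removed = sorted(n for cid in small for n in members[cid])
    retained = [n for n in m.nodes if n not in set(removed)]
    logger.info(
        "dissolving %d small cluster(s) covering %d node(s)",
        len(small), len(removed),
    )

    idx = [m.nodes.index(n) for n in retained]
    sub_values = m.values[np.ix_(idx, idx)]
    sub_matrix = ScoringMatrix(sub_values, tuple(retained), m.iterations, m.converged)
    sub_graph = g.induced_subgraph(retained)

    best = None
    upper = min(params.max_clusters, len(retained))
    lo = min(params.min_clusters, len(retained))
    for k in range(lo, upper + 1):
        membership = agglomerate(sub_matrix, k)
        try:
            s = sparsity_score(sub_graph, membership)
        except ValueError:  # edgeless core
            s = float("-inf")
        if best is None or s > best[0]:
            best = (s, membership)
    membership = dict(best[1])

    nxg = g.to_networkx()
    groups: Dict[int, set] = {}
    for node, cid in membership.items():
        groups.setdefault(cid, set()).add(node)
    for v in removed:
        scores = {}
        for cid, nodes in groups.items():
            vals = [_mean_path_product(nxg, v, u) for u in nodes]
            scores[cid] = float(np.mean(vals)) if vals else 0.0
        membership[v] = max(sorted(scores), key=lambda c: scores[c])

    membership = _relabel(membership)
    return ClusterAssignment(
        membership=membership,
        weak={n: False for n in membership},
        k=len(set(membership.values())),
        sparsity=sparsity_score(g, membership),
    )
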