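"""Cluster-assignment robustness under degree-preserving rewiring.

Association networks inferred from abundance data carry high edge error
rates, so a cluster assignment is only as useful as it is stable.  A
fraction of the network is repositioned by weight-carrying double-edge
swaps (degree sequence identical, weights travel with their edges), the
full pipeline is re-run, and stability is summarized as percentile
confidence intervals of Jaccard similarities — cluster-wise (each original
cluster against its best-matching rewired cluster) and node-wise (each
node's co-member set against its rewired co-member set).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .clustering import ClusteringParams
from .graph_io import SignedGraph
from .matrix_core import DiffusionParams
from .pipeline import cluster_signed_network

logger = logging.getLogger(__name__)

__all__ = ["RobustnessReport", "rewire", "cluster_robustness", "jaccard"]


@dataclass
class RobustnessReport:
    """Percentile Jaccard confidence intervals over rewired replicates."""

    per_cluster: Dict[int, Tuple[float, float]]
    per_node: Dict[str, Tuple[float, float]]
    n_replicates: int
    rewire_fraction: float
    ci_level: float


def jaccard(a: set, b: set) -> float:
    """Jaccard similarity; two empty sets count as identical (1)."""
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 1.0


def rewire(g: SignedGraph, fraction: float, seed: int = 0) -> SignedGraph:
    """Degree-preserving partial rewiring by double-edge swaps.

    Approximately ``fraction × |E|`` edges are repositioned: each swap
    replaces edges (u, v) and (x, y) by (u, x) and (v, y), with each weight
    traveling with the edge endpoint it keeps (u keeps w(u,v), y keeps
    w(x,y)).  The per-node degree sequence is exactly preserved; swaps that
    would create self-loops or multi-edges are rejected.  If the swap
    budget cannot be met within a bounded number of attempts the achieved
    fraction is logged and the partial result returned.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    edges = list(g.edges())
    if len(edges) < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    # each successful swap repositions two edges; a fraction too small to
    # afford one swap leaves the graph identical
    n_swaps = int(fraction * len(edges) / 2)
    edge_set = {(u, v) for u, v, _ in edges}
    done = 0
    attempts = 0
    max_attempts = 200 * n_swaps
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.choice(len(edges), size=2, replace=False)
        u, v, w1 = edges[i]
        x, y, w2 = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed: (u, x) and (v, y)
        if u == x or v == y:
            continue
        new1 = (min(u, x), max(u, x))
        new2 = (min(v, y), max(v, y))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((min(u, v), max(u, v)))
        edge_set.discard((min(x, y), max(x, y)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (new1[0], new1[1], w1)
        edges[j] = (new2[0], new2[1], w2)
        done += 1
    if done < n_swaps:
        logger.warning(
            "rewired %d/%d swaps (achieved fraction %.3f of the requested %.3f)",
            done, n_swaps, 2 * done / len(edges), fraction,
        )
    return SignedGraph(edges, nodes=g.nodes)


def cluster_robustness(
    g: SignedGraph,
    diffusion: Optional[DiffusionParams] = None,
    clustering: Optional[ClusteringParams] = None,
    n_replicates: int = 100,
    fraction: float = 0.1,
    ci_level: float = 95.0,
    seed: int = 0,
    exclude_weak: bool = False,
) -> RobustnessReport:
    """Jaccard-stability confidence intervals over rewired replicates.

    For each replicate the graph is partially rewired and re-clustered.
    Cluster-wise: each original cluster records the maximum Jaccard
    similarity against the replicate's clusters (original → replicate
    direction only).  Node-wise: each node records the Jaccard similarity
    between its original co-member set and its replicate co-member set;
    wide node intervals mean the node drifts between dissimilar clusters.
    Intervals are percentile intervals at ``ci_level``.  Replicates whose
    clustering fails are dropped and counted.

    With ``exclude_weak`` weakly assigned nodes are removed from co-member
    sets before comparison.
    """
    diffusion = diffusion or DiffusionParams()
    clustering = clustering or ClusteringParams()

    base = cluster_signed_network(g, diffusion, clustering)
    orig_clusters = base.assignment.cluster_members()
    orig_weak = {n for n, f in base.assignment.weak.items() if f}

    def comember_sets(assignment):
        weak_nodes = {n for n, f in assignment.weak.items() if f}
        members = assignment.cluster_members()
        out = {}
        for cid, nodes in members.items():
            usable = nodes - weak_nodes if exclude_weak else nodes
            for n in nodes:
                out[n] = usable - {n}
        return out

    orig_comembers = comember_sets(base.assignment)

    cluster_scores: Dict[int, list] = {cid: [] for cid in orig_clusters}
    node_scores: Dict[str, list] = {n: [] for n in g.nodes}
    rng = np.random.default_rng(seed)
    dropped = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        try:
            rewired = rewire(g, fraction, seed=rep_seed)
            rep_diffusion = DiffusionParams(
                epsilon=diffusion.epsilon,
                max_iterations=diffusion.max_iterations,
                n_subsets=diffusion.n_subsets,
                subset_fraction=diffusion.subset_fraction,
                ratio=diffusion.ratio,
                seed=rep_seed,
            )
            rep = cluster_signed_network(
                rewired, rep_diffusion, clustering, flag_weak_nodes=exclude_weak
            )
        except Exception as exc:  # noqa: BLE001 - replicate failure is data
            logger.warning("replicate dropped: %s", exc)
            dropped += 1
            continue
        rep_clusters = rep.assignment.cluster_members()
        for cid, nodes in orig_clusters.items():
            best = max(jaccard(nodes, other) for other in rep_clusters.values())
            cluster_scores[cid].append(best)
        rep_comembers = comember_sets(rep.assignment)
        for n in g.nodes:
            node_scores[n].append(jaccard(orig_comembers[n], rep_comembers[n]))
    if dropped:
        logger.warning("%d of %d replicates dropped", dropped, n_replicates)
    successful = n_replicates - dropped
    if successful == 0:
        raise RuntimeError("every rewiring replicate failed to cluster")

    lo_q = (100.0 - ci_level) / 2.0
    hi_q = 100.0 - lo_q

    def ci(values):
        lo, hi = np.percentile(values, [lo_q, hi_q])
        return float(lo), float(hi)

    return RobustnessReport(
        per_cluster={cid: ci(v) for cid, v in cluster_scores.items()},
        per_node={n: ci(v) for n, v in node_scores.items()},
        n_replicates=successful,
        rewire_fraction=fraction,
        ci_level=ci_level,
    )
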