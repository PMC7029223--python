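"""Weak-assignment detection via mean edge products to oscillators.

Oscillator nodes (found from the flip-flop regime of unbalanced graphs)
serve as reference points: for a node v and oscillator t, the mean edge
product P(v, t) averages, over all fewest-hop paths from v to t, the
product of the scaled edge weights along the path.  A node sharing a
cluster with an oscillator is *weakly assigned* when that evidence
conflicts with its label (P not positive) or is too thin (|P| below the
``edgescale`` threshold).  Weak flags annotate nodes — they never remove
them from the membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Set

import networkx as nx
import numpy as np

from .clustering import ClusterAssignment
from .graph_io import SignedGraph

logger = logging.getLogger(__name__)

__all__ = ["WeakParams", "mean_edge_product", "flag_weak"]


@dataclass
class WeakParams:
    """Threshold on |P| below which path evidence counts as weak.

    The default ``edgescale`` of 0.8 suits binarized (±1) networks, where
    every path product has magnitude 1 unless paths cancel; 0.3 is a
    documented alternative better suited to raw correlation weights.  With
    ``all_oscillators`` the magnitude criterion is also evaluated against
    oscillators outside the node's cluster (off by default).
    """

    edgescale: float = 0.8
    all_oscillators: bool = False

    def __post_init__(self):
        if not (0 <= self.edgescale <= 1):
            raise ValueError("edgescale must be in [0, 1]")


def mean_edge_product(g: SignedGraph, v: str, t: str) -> float:
    """Mean edge product P(v, t) over all fewest-hop paths from v to t.

    Each path contributes the product of its edge weights scaled by the
    graph-wide maximum absolute weight; P is the mean of those products and
    lies in [−1, 1] once weights are scaled.  A disconnected pair yields 0
    with a warning (no path evidence either way).
    """
    v, t = str(v), str(t)
    if v == t:
        raise ValueError("mean edge product needs two distinct nodes")
    nxg = g._g
    scale = max(abs(w) for _, _, w in g.edges())
    try:
        products = []
        for path in nx.all_shortest_paths(nxg, v, t):
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= nxg[a][b]["weight"] / scale
            products.append(prod)
    except nx.NetworkXNoPath:
        logger.warning("nodes %r and %r are disconnected; P set to 0", v, t)
        return 0.0
    return float(np.mean(products))


def flag_weak(
    g: SignedGraph,
    assignment: ClusterAssignment,
    oscillators: Iterable[str],
    edgescale: Optional[float] = None,
    params: Optional[WeakParams] = None,
) -> Set[str]:
    """Flag weakly assigned nodes and record the flags in ``assignment``.

    A node v is flagged when, for any oscillator t in the same cluster,
    (i) P(v, t) ≤ 0 — the shortest-path evidence conflicts with sharing
    t's cluster — or (ii) |P(v, t)| < edgescale — the evidence is weaker
    than the threshold.  Higher edgescale therefore flags a superset of
    nodes.  With no oscillators (balanced graphs) the result is empty, with
    a warning.

    Returns the set of flagged nodes; ``assignment.weak`` is updated in
    place.
    """
    params = params or WeakParams()
    if edgescale is None:
        edgescale = params.edgescale
    if not (0 <= edgescale <= 1):
        raise ValueError("edgescale must be in [0, 1]")
    oscillators = {str(t) for t in oscillators}
    if not oscillators:
        logger.warning("no oscillators given; no weak assignments to flag")
        return set()

    flagged: Set[str] = set()
    for v, cid in assignment.membership.items():
        same = [t for t in oscillators if t != v and assignment.membership.get(t) == cid]
        pool = same if not params.all_oscillators else [t for t in oscillators if t != v]
        for t in same:
            if mean_edge_product(g, v, t) <= 0:
                flagged.add(v)
                break
        else:
            for t in pool:
                if abs(mean_edge_product(g, v, t)) < edgescale:
                    flagged.add(v)
                    break
    for n in assignment.weak:
        assignment.weak[n] = n in flagged
    logger.info("%d node(s) weakly assigned", len(flagged))
    return flagged
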