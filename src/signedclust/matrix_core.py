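"""Sign-preserving score-matrix diffusion.

The scoring matrix is the object the clustering operates on: starting from
the weighted adjacency matrix, repeated rounds of squaring (network flow
along paths of length two), max-absolute-value normalization and an
elementwise inflation ``x -> x + 1/x`` drive every nonzero entry toward −1
or +1 while retaining the sign structure of the input.  Unlike Markov
clustering, no column-stochastic normalization is applied, so signs are
never destroyed.

Whether the iteration converges is governed by structural balance: a signed
graph is balanced when every cycle has a positive product of edge-weight
signs, equivalently (Harary) when its nodes admit a two-coloring with
positive edges inside colors and negative edges between them.  On balanced
graphs the diffusion converges to a ±1 block pattern; on unbalanced graphs
it enters a flip-flop equilibrium, which is handled by a subset-consensus
strategy (:func:`score_unbalanced`) and exploited to find *oscillator*
nodes (:func:`detect_oscillators`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import networkx as nx
import numpy as np

from .graph_io import SignedGraph, SignedNetworkError

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringMatrix",
    "DiffusionParams",
    "DegenerateMatrixError",
    "normalize_max_abs",
    "is_balanced",
    "converge_balanced",
    "detect_oscillators",
    "score_unbalanced",
]

#: Magnitudes below this are treated as exact zeros between diffusion steps.
#: During flip-flop iterations most entries decay toward zero; without a
#: floor the inflation 1/x overflows on denormals.
ZERO_FLOOR = 1e-12

#: Oscillator detection: fraction of the ±1 limit an extreme must reach.
OSCILLATOR_TOL = 0.01


class DegenerateMatrixError(SignedNetworkError):
    """The scoring matrix collapsed to all zeros (diffusion degenerated)."""


@dataclass
class ScoringMatrix:
    """Dense symmetric node-by-node score matrix in [−1, 1].

    ``values`` is indexed by ``nodes`` (the graph's sorted node order);
    ``iterations`` counts diffusion rounds and ``converged`` records whether
    the mean absolute change fell below threshold.
    """

    values: np.ndarray
    nodes: tuple
    iterations: int = 0
    converged: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.nodes)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} nodes"
            )


@dataclass
class DiffusionParams:
    """Tunable parameters of the diffusion.

    epsilon:
        Convergence threshold, in percent: iteration stops when 100× the
        mean absolute entry change drops to ``epsilon`` or below.
    max_iterations:
        Hard cap on diffusion rounds (also the flip-flop budget for
        oscillator detection).
    n_subsets:
        Number of edge subsets drawn for the unbalanced-graph consensus.
    subset_fraction:
        Fraction of edges per subset.
    ratio:
        Fraction of subsets that must agree on an entry's sign for it to
        enter the consensus matrix.
    seed:
        Governs all subset sampling.
    """

    epsilon: float = 2.0
    max_iterations: int = 100
    n_subsets: int = 100
    subset_fraction: float = 0.8
    ratio: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 < self.subset_fraction <= 1):
            raise ValueError("subset_fraction must be in (0, 1]")
        if not (0 < self.ratio <= 1):
            raise ValueError("ratio must be in (0, 1]")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")


# -- normalization ---------------------------------------------------------


def _normalize(values: np.ndarray) -> np.ndarray:
    mx = np.max(np.abs(values))
    if not np.isfinite(mx) or mx == 0.0:
        raise DegenerateMatrixError(
            "scoring matrix is all-zero (or non-finite); the diffusion "
            "degenerated — this typically indicates unsuitable input"
        )
    return values / mx


def normalize_max_abs(m: Union[np.ndarray, ScoringMatrix]):
    """Divide every entry by the maximum absolute entry.

    Signs are unchanged and the result has max |entry| = 1.  Raises
    :class:`DegenerateMatrixError` on an all-zero matrix.
    """
    if isinstance(m, ScoringMatrix):
        return ScoringMatrix(
            _normalize(m.values), m.nodes, m.iterations, m.converged
        )
    return _normalize(np.asarray(m, dtype=float))


# -- structural balance ----------------------------------------------------


def is_balanced(g: SignedGraph):
    """Test structural balance via sign-parity two-coloring.

    A signed graph is balanced iff the product of edge-weight signs around
    every cycle is positive; equivalently the nodes split into two groups
    with positive edges within groups and negative edges between them.  The
    test runs a BFS per connected component, coloring across negative edges
    and keeping color across positive edges.

    Returns
    -------
    (balanced, witness)
        ``witness`` is a ``node -> {0, 1}`` two-coloring when balanced, or a
        node list of one cycle with negative sign product when not.
    """
    color: dict = {}
    parent: dict = {}
    for start in g.nodes:
        if start in color:
            continue
        color[start] = 0
        parent[start] = None
        queue = [start]
        nxg = g  # alias
        while queue:
            u = queue.pop(0)
            for _, v, w in _incident(nxg, u):
                expected = color[u] ^ (1 if w < 0 else 0)
                if v not in color:
                    color[v] = expected
                    parent[v] = u
                    queue.append(v)
                elif color[v] != expected:
                    return False, _witness_cycle(parent, u, v)
    return True, color


def _incident(g: SignedGraph, u: str):
    nxg = g._g  # internal access: hot loop
    for v in nxg[u]:
        yield u, v, nxg[u][v]["weight"]


def _witness_cycle(parent: dict, u: str, v: str) -> list:
    """Cycle through the conflicting non-tree edge (u, v) in the BFS tree."""
    anc_u = [u]
    x = u
    while parent[x] is not None:
        x = parent[x]
        anc_u.append(x)
    seen = {n: i for i, n in enumerate(anc_u)}
    path_v = [v]
    y = v
    while y not in seen:
        y = parent[y]
        path_v.append(y)
    lca_idx = seen[y]
    return anc_u[: lca_idx + 1] + list(reversed(path_v[:-1]))


def cycle_sign_product(g: SignedGraph, cycle: list) -> float:
    """Product of edge-weight signs around ``cycle`` (closed implicitly)."""
    prod = 1.0
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        prod *= math.copysign(1.0, g.weight(a, b))
    return prod


# -- diffusion -------------------------------------------------------------


def _diffusion_step(values: np.ndarray) -> np.ndarray:
    """One round: square, normalize, inflate nonzero entries, normalize.

    The inflation ``x -> x + 1/x`` is applied only to nonzero entries
    (zeros are filled in by the squaring); entries whose magnitude has
    decayed below :data:`ZERO_FLOOR` are snapped to zero first so the
    reciprocal cannot overflow.
    """
    values = values @ values
    values = _normalize(values)
    values = values.copy()
    values[np.abs(values) < ZERO_FLOOR] = 0.0
    nz = values != 0
    values[nz] = values[nz] + 1.0 / values[nz]
    return _normalize(values)


def converge_balanced(g: SignedGraph, params: Optional[DiffusionParams] = None) -> ScoringMatrix:
    """Run the diffusion to convergence on a balanced graph.

    Starting from the weighted adjacency matrix (zero diagonal), rounds of
    square → normalize → elementwise ``x + 1/x`` on nonzero entries →
    normalize are repeated until 100× the mean absolute change over nonzero
    entries is at most ``params.epsilon``, or ``params.max_iterations`` is
    reached (in which case ``converged`` is False and a warning is logged —
    usually a sign the graph was not balanced after all).

    On balanced input the signs of nonzero entries never conflict with the
    adjacency-matrix signs, and entries converge to ±1 in the block pattern
    of the underlying two-coloring.
    """
    params = params or DiffusionParams()
    prev = g.adjacency()
    if not np.any(prev):
        raise DegenerateMatrixError("graph has no edges; nothing to diffuse")
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        cur = _diffusion_step(prev)
        nz = cur != 0
        b = int(nz.sum())
        err = float(np.abs(cur - prev)[nz].sum() / b) if b else 0.0
        prev = cur
        if 100.0 * err <= params.epsilon:
            return ScoringMatrix(cur, g.nodes, iterations, converged=True)
    logger.warning(
        "diffusion did not converge in %d iterations (graph may be "
        "unbalanced)", params.max_iterations,
    )
    return ScoringMatrix(prev, g.nodes, iterations, converged=False)


def detect_oscillators(
    g: SignedGraph,
    params: Optional[DiffusionParams] = None,
    tol: float = OSCILLATOR_TOL,
) -> set:
    """Find oscillator nodes of an unbalanced graph.

    During flip-flop iterations the matrix limits −1 and +1 are approached
    by only a few entries.  A node is an oscillator when, over the course of
    ``params.max_iterations`` flip-flop rounds (no convergence stop), its
    diagonal entry reaches at least ``1 − tol`` and some entry in its row
    reaches at most ``−(1 − tol)``.  Oscillators act as reference points for
    the weak-assignment test.

    Balanced input has no flip-flop regime (every diagonal approaches +1);
    an empty set is returned with a warning.
    """
    params = params or DiffusionParams()
    balanced, _ = is_balanced(g)
    if balanced:
        logger.warning("graph is balanced: no oscillators exist")
        return set()
    values = g.adjacency()
    n = values.shape[0]
    diag_max = np.full(n, -np.inf)
    row_min = np.full(n, np.inf)
    for _ in range(params.max_iterations):
        values = _diffusion_step(values)
        np.maximum(diag_max, np.diagonal(values), out=diag_max)
        np.minimum(row_min, values.min(axis=1), out=row_min)
    hit = (diag_max >= 1.0 - tol) & (row_min <= -(1.0 - tol))
    return {g.nodes[i] for i in np.nonzero(hit)[0]}


# -- unbalanced graphs: subset consensus -----------------------------------


def _one_pass_matrix(values: np.ndarray) -> np.ndarray:
    """Exactly one diffusion round (any more would start flip-flopping)."""
    return _diffusion_step(values)


def _balanced_component_scores(sub: SignedGraph, params: DiffusionParams) -> np.ndarray:
    """Run the convergent diffusion on each balanced component of ``sub``.

    Returns an n×n matrix with each balanced component's converged scores
    embedded at its nodes' rows/columns and zeros elsewhere (unbalanced
    components contribute nothing).
    """
    n = sub.n_nodes
    out = np.zeros((n, n))
    nxg = sub.to_networkx()
    for comp in nx.connected_components(nxg):
        if len(comp) < 2:
            continue
        comp_graph = sub.induced_subgraph(comp)
        balanced, _ = is_balanced(comp_graph)
        if not balanced:
            continue
        scores = converge_balanced(comp_graph, params)
        idx = np.array([sub.node_index[nd] for nd in comp_graph.nodes])
        out[np.ix_(idx, idx)] = scores.values
    return out


def score_unbalanced(g: SignedGraph, params: Optional[DiffusionParams] = None) -> ScoringMatrix:
    """Build a consensus scoring matrix for an unbalanced graph.

    ``n_subsets`` edge subsets of size ``ceil(subset_fraction × |E|)`` are
    drawn uniformly without replacement.  For each subset, balanced
    connected components get the full convergent diffusion; the whole
    subset matrix gets exactly one diffusion round (more would flip-flop);
    the two are summed and normalized.  An entry enters the consensus sum
    only when at least ``ratio`` of the subsets agree on its sign; the
    result is normalized to [−1, 1].

    Subsets whose matrices degenerate to all zeros are discarded (with a
    warning); if every subset degenerates a
    :class:`DegenerateMatrixError` is raised.
    """
    params = params or DiffusionParams()
    edges = list(g.edges())
    if not edges:
        raise DegenerateMatrixError("graph has no edges; nothing to score")
    rng = np.random.default_rng(params.seed)
    n_sample = max(1, math.ceil(params.subset_fraction * len(edges)))
    matrices = []
    for _ in range(params.n_subsets):
        idx = rng.choice(len(edges), size=n_sample, replace=False)
        sub = g.subgraph_from_edges([edges[i] for i in sorted(idx)])
        try:
            balanced_scores = _balanced_component_scores(sub, params)
            values = _one_pass_matrix(sub.adjacency())
            values = _normalize(values + balanced_scores)
        except DegenerateMatrixError:
            logger.warning("discarding degenerate subset")
            continue
        matrices.append(values)
    if not matrices:
        raise DegenerateMatrixError("all subsets degenerated to zero matrices")
    k_eff = len(matrices)
    if k_eff < params.n_subsets:
        logger.warning(
            "%d of %d subsets discarded", params.n_subsets - k_eff, params.n_subsets
        )
    stack = np.stack(matrices)
    pos = (stack > 0).sum(axis=0)
    neg = (stack < 0).sum(axis=0)
    stable = (pos / k_eff >= params.ratio) | (neg / k_eff >= params.ratio)
    combined = np.where(stable, stack.sum(axis=0), 0.0)
    if not np.any(combined):
        raise DegenerateMatrixError(
            "no entry was sign-stable across subsets; try a lower ratio"
        )
    return ScoringMatrix(_normalize(combined), g.nodes, iterations=1, converged=True)


def score_graph(g: SignedGraph, params: Optional[DiffusionParams] = None) -> tuple:
    """Route a graph to the appropriate scoring strategy.

    Balanced graphs get the convergent diffusion; unbalanced graphs get the
    subset consensus.  Returns ``(ScoringMatrix, balanced_flag)``.
    """
    params = params or DiffusionParams()
    balanced, _ = is_balanced(g)
    if balanced:
        return converge_balanced(g, params), True
    return score_unbalanced(g, params), False
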