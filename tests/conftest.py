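"""Shared fixtures: toy graphs and random-graph builders.

The two-triangle toys mirror the classic balanced/unbalanced examples of
signed-graph theory: two all-positive triangles joined by negative bridges
form a balanced two-cluster graph; flipping one within-triangle edge
negative breaks balance and produces the flip-flop regime.
"""

import numpy as np
import pytest

from signedclust import SignedGraph


def two_triangle_graph(bridge_weight=-1.0, triangle_weight=1.0, flip=None):
    """Two triangles {a,b,c} and {d,e,f} joined by bridges (c,d) and (a,f)."""
    edges = {
        ("a", "b"): triangle_weight,
        ("b", "c"): triangle_weight,
        ("a", "c"): triangle_weight,
        ("d", "e"): triangle_weight,
        ("e", "f"): triangle_weight,
        ("d", "f"): triangle_weight,
        ("c", "d"): bridge_weight,
        ("a", "f"): bridge_weight,
    }
    if flip:
        edges[flip] = -edges[flip]
    return SignedGraph([(u, v, w) for (u, v), w in edges.items()])


@pytest.fixture
def balanced_toy():
    """Two +1 triangles joined by two −1 edges: balanced, two clusters."""
    return two_triangle_graph()


@pytest.fixture
def unbalanced_toy():
    """Balanced toy with the within-triangle edge (a, b) flipped negative."""
    return two_triangle_graph(flip=("a", "b"))


def planted_two_block(n_per_block=7, p_within=0.8, p_between=0.5, seed=0):
    """Balanced planted-partition graph: positive within blocks, negative
    between, random weight magnitudes; a spanning path per block plus one
    bridge guarantees connectivity."""
    rng = np.random.default_rng(seed)
    left = [f"L{i}" for i in range(n_per_block)]
    right = [f"R{i}" for i in range(n_per_block)]
    edges = []
    for block in (left, right):
        for a, b in zip(block, block[1:]):  # spanning path
            edges.append((a, b, rng.uniform(0.3, 1.0)))
        for i in range(len(block)):
            for j in range(i + 2, len(block)):
                if rng.random() < p_within:
                    edges.append((block[i], block[j], rng.uniform(0.3, 1.0)))
    edges.append((left[0], right[0], -rng.uniform(0.3, 1.0)))
    for u in left:
        for v in right:
            if (u, v) != (left[0], right[0]) and rng.random() < p_between:
                edges.append((u, v, -rng.uniform(0.3, 1.0)))
    g = SignedGraph(edges)
    truth = {n: 0 for n in left} | {n: 1 for n in right}
    return g, truth


def random_signed_graph(seed, max_nodes=12, p=None):
    """Random signed graph for oracle-agreement tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    p = p if p is not None else float(rng.uniform(0.25, 0.6))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 1.0))
                edges.append((f"n{i:02d}", f"n{j:02d}", w))
    if not edges:
        edges = [("n00", "n01", 1.0)]
    return SignedGraph(edges)


def random_balanced_graph(seed, max_nodes=12):
    """Random balanced graph: random bipartition, signs follow crossing."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_nodes + 1))
    side = rng.integers(0, 2, size=n)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                sign = -1.0 if side[i] != side[j] else 1.0
                edges.append((f"n{i:02d}", f"n{j:02d}", sign * float(rng.uniform(0.2, 1.0))))
    if not edges:
        edges = [("n00", "n01", 1.0)]
    return SignedGraph(edges)
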