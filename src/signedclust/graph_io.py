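"""Readers and writers for signed weighted networks.

The clustering algorithm consumes undirected networks whose edge weights
carry meaningful signs (co-occurrence vs mutual exclusion).  Three
interchange formats are supported: GraphML, Cytoscape JSON (``.cyjs``) and a
plain three-column edge-list TSV (``source  target  weight``).  All readers
funnel into :class:`SignedGraph`, which enforces the invariants the
downstream matrix algebra relies on: no self-loops, no zero weights, and a
deterministic (sorted) node ordering so matrix indices are reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignedGraph",
    "SignedNetworkError",
    "NetworkFormatError",
    "NetworkDataError",
    "read_network",
    "write_network",
    "binarize_weights",
    "write_results",
]


class SignedNetworkError(Exception):
    """Base class for errors raised while handling signed networks."""


class NetworkFormatError(SignedNetworkError):
    """The input file does not parse in the named dialect."""


class NetworkDataError(SignedNetworkError):
    """The parsed data violates a signed-graph invariant (e.g. conflicting
    duplicate edges)."""


class SignedGraph:
    """Undirected weighted graph with signed, nonzero edge weights.

    Nodes are string identifiers kept in sorted order; ``adjacency()``
    returns the dense weighted adjacency matrix in that order, which is what
    the diffusion operates on.

    Parameters
    ----------
    edges:
        Iterable of ``(u, v, weight)`` triples.  Zero-weight edges are
        dropped with a warning; self-loops are dropped with a warning;
        duplicate pairs with equal weight are merged silently, while
        duplicates with unequal weights raise :class:`NetworkDataError`
        (silently averaging could flip a sign).
    node_attrs:
        Optional mapping ``node -> {key: value}`` of node annotations.
    nodes:
        Optional extra node identifiers (to keep isolated nodes).
    """

    def __init__(
        self,
        edges: Iterable[tuple],
        node_attrs: Optional[Mapping[str, Mapping]] = None,
        nodes: Optional[Iterable[str]] = None,
    ):
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(str(n) for n in nodes)
        for item in edges:
            u, v, w = item[0], item[1], item[2]
            u, v = str(u), str(v)
            try:
                w = float(w)
            except (TypeError, ValueError) as exc:
                raise NetworkFormatError(
                    f"edge ({u}, {v}) has non-numeric weight {w!r}"
                ) from exc
            if not math.isfinite(w):
                raise NetworkDataError(f"edge ({u}, {v}) has non-finite weight {w}")
            if u == v:
                logger.warning("dropping self-loop on node %r", u)
                continue
            if w == 0.0:
                logger.warning("dropping zero-weight edge (%r, %r)", u, v)
                continue
            if g.has_edge(u, v):
                existing = g[u][v]["weight"]
                if existing != w:
                    raise NetworkDataError(
                        f"conflicting duplicate edge ({u}, {v}): "
                        f"weights {existing} and {w}"
                    )
                continue
            g.add_edge(u, v, weight=w)
        if node_attrs:
            for n, attrs in node_attrs.items():
                n = str(n)
                if n not in g:
                    g.add_node(n)
                g.nodes[n].update(attrs)
        self._g = g
        self._nodes = tuple(sorted(g.nodes))
        self._index = {n: i for i, n in enumerate(self._nodes)}

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple:
        """Node identifiers in sorted (matrix) order."""
        return self._nodes

    @property
    def node_index(self) -> dict:
        """Mapping node identifier -> row/column index."""
        return self._index

    def edges(self) -> Iterator[tuple]:
        """Yield ``(u, v, weight)`` with u < v, in sorted order."""
        for u, v, data in sorted(self._g.edges(data=True)):
            if u > v:
                u, v = v, u
            yield u, v, data["weight"]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return self._g[str(u)][str(v)]["weight"]

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(str(u), str(v))

    def node_attrs(self, n: str) -> dict:
        return dict(self._g.nodes[str(n)])

    def to_networkx(self) -> nx.Graph:
        """Copy of the underlying :class:`networkx.Graph`."""
        return self._g.copy()

    def adjacency(self) -> np.ndarray:
        """Dense weighted adjacency matrix in sorted node order."""
        return nx.to_numpy_array(self._g, nodelist=self._nodes, weight="weight")

    def subgraph_from_edges(self, edge_subset: Iterable[tuple]) -> "SignedGraph":
        """Graph over the *same* node set containing only ``edge_subset``.

        Keeping the full node set means subset adjacency matrices stay
        index-aligned with the parent graph; nodes isolated in the subset
        contribute zero rows.
        """
        return SignedGraph(edge_subset, nodes=self._nodes)

    def induced_subgraph(self, keep: Iterable[str]) -> "SignedGraph":
        keep = {str(n) for n in keep}
        edges = [(u, v, w) for u, v, w in self.edges() if u in keep and v in keep]
        return SignedGraph(edges, nodes=keep)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignedGraph):
            return NotImplemented
        if self._nodes != other._nodes:
            return False
        mine, theirs = list(self.edges()), list(other.edges())
        if len(mine) != len(theirs):
            return False
        return all(
            a[:2] == b[:2] and abs(a[2] - b[2]) <= 1e-9 for a, b in zip(mine, theirs)
        )

    def __repr__(self) -> str:
        return f"SignedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# -- reading ---------------------------------------------------------------

_EXTENSIONS = {
    ".graphml": "graphml",
    ".xml": "graphml",
    ".cyjs": "cyjs",
    ".json": "cyjs",
    ".tsv": "edgelist-tsv",
    ".txt": "edgelist-tsv",
    ".edgelist": "edgelist-tsv",
}


def _detect_format(path: Path) -> str:
    fmt = _EXTENSIONS.get(path.suffix.lower())
    if fmt is None:
        raise NetworkFormatError(
            f"cannot infer format from extension {path.suffix!r}; "
            "pass format explicitly"
        )
    return fmt


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _edges_from_nx(g: nx.Graph) -> list:
    """Extract weighted edges from a networkx graph, collapsing direction.

    Directed inputs are collapsed to undirected; reciprocal edges with
    unequal weights raise :class:`NetworkDataError` rather than being
    averaged (averaging could flip a sign).
    """
    edges = []
    for u, v, data in g.edges(data=True):
        if "weight" not in data:
            raise NetworkFormatError(
                f"edge ({u}, {v}) is missing the numeric 'weight' attribute"
            )
        edges.append((u, v, data["weight"]))
    return edges


def read_network(path, format: str = "auto") -> SignedGraph:
    """Read a signed weighted network from ``path``.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``graphml``, ``cyjs``, ``edgelist-tsv`` or ``auto``
        (extension-based detection).

    Returns
    -------
    SignedGraph
        With zero-weight edges dropped (logged) and directed input collapsed
        to undirected; conflicting duplicate edges are a
        :class:`NetworkDataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)

    if format == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:
            raise NetworkFormatError(f"{path}: not valid GraphML: {exc}") from exc
        return SignedGraph(
            _edges_from_nx(g),
            node_attrs={n: dict(d) for n, d in g.nodes(data=True)},
            nodes=g.nodes,
        )

    if format == "cyjs":
        try:
            with open(path) as fh:
                payload = json.load(fh)
            g = nx.cytoscape_graph(payload)
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise NetworkFormatError(f"{path}: not valid Cytoscape JSON: {exc}") from exc
        attrs = {}
        for n, d in g.nodes(data=True):
            attrs[n] = {k: v for k, v in d.items() if k not in ("id", "value", "name")}
        return SignedGraph(_edges_from_nx(g), node_attrs=attrs, nodes=g.nodes)

    if format == "edgelist-tsv":
        return _read_edgelist(path)

    raise NetworkFormatError(f"unknown format {format!r}")


def _read_edgelist(path: Path) -> SignedGraph:
    """Tab-separated edge list: source, target, weight.

    Comment lines start with ``#``; an optional single header line is
    detected by a non-numeric third field.
    """
    edges = []
    with open(path) as fh:
        first_data_line = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-separated exports
                fields = line.split()
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            if first_data_line and not _is_number(fields[2]):
                first_data_line = False  # header
                continue
            first_data_line = False
            if not _is_number(fields[2]):
                raise NetworkFormatError(
                    f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                )
            edges.append((fields[0], fields[1], float(fields[2])))
    if not edges:
        raise NetworkFormatError(f"{path}: no edges found")
    # conflicting duplicates are caught by SignedGraph itself
    return SignedGraph(edges)


# -- transformation --------------------------------------------------------


def binarize_weights(g: SignedGraph) -> SignedGraph:
    """Replace every edge weight by its sign (−1 or +1); topology unchanged.

    Useful when the magnitudes produced by a network-inference tool are not
    comparable but the inferred signs are.
    """
    edges = [(u, v, math.copysign(1.0, w)) for u, v, w in g.edges()]
    attrs = {n: g.node_attrs(n) for n in g.nodes}
    return SignedGraph(edges, node_attrs=attrs, nodes=g.nodes)


# -- writing ---------------------------------------------------------------


def _to_nx_with_attrs(g: SignedGraph, extra: Optional[Mapping[str, Mapping]] = None):
    out = nx.Graph()
    for n in g.nodes:
        attrs = {
            k: v for k, v in g.node_attrs(n).items() if isinstance(v, (str, int, float, bool))
        }
        if extra and n in extra:
            attrs.update(extra[n])
        out.add_node(n, **attrs)
    for u, v, w in g.edges():
        out.add_edge(u, v, weight=float(w))
    return out


def write_network(g: SignedGraph, path, format: str = "auto") -> None:
    """Write a plain signed network in GraphML, Cytoscape JSON or TSV."""
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "graphml":
        nx.write_graphml(_to_nx_with_attrs(g), path)
    elif format == "cyjs":
        with open(path, "w") as fh:
            json.dump(nx.cytoscape_data(_to_nx_with_attrs(g)), fh, indent=1)
    elif format == "edgelist-tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in g.edges():
                fh.write(f"{u}\t{v}\t{w!r}\n")
    else:
        raise NetworkFormatError(f"unknown format {format!r}")


def write_results(g: SignedGraph, assignment, robustness=None, path=None,
                  format: str = "graphml") -> list:
    """Write the clustered network plus a TSV results table.

    The network file carries per-node attributes ``cluster`` (integer id)
    and ``assignment`` (``"strong"`` or ``"weak"``), and, when a robustness
    report is given, the node-wise Jaccard confidence bounds
    ``robustness_lower`` / ``robustness_upper``.  A TSV twin listing node,
    cluster, weak flag and CI bounds is always written next to the network
    file; with ``format="tsv"`` only the table is written.

    Returns the list of paths written.
    """
    if path is None:
        raise ValueError("path is required")
    path = Path(path)
    missing = [n for n in assignment.membership if n not in g.node_index]
    if missing:
        raise NetworkDataError(
            f"assignment names nodes absent from the graph: {missing[:5]}"
        )
    uncovered = [n for n in g.nodes if n not in assignment.membership]
    if uncovered:
        raise NetworkDataError(
            f"assignment does not cover graph nodes: {uncovered[:5]}"
        )

    extra = {}
    for n in g.nodes:
        attrs = {
            "cluster": int(assignment.membership[n]),
            "assignment": "weak" if assignment.weak.get(n, False) else "strong",
        }
        if robustness is not None and n in robustness.per_node:
            lo, hi = robustness.per_node[n]
            attrs["robustness_lower"] = float(lo)
            attrs["robustness_upper"] = float(hi)
        extra[n] = attrs

    written = []
    table_path = path if format == "tsv" else path.with_suffix(path.suffix + ".tsv")
    rows = []
    for n in g.nodes:
        row = {
            "node": n,
            "cluster": extra[n]["cluster"],
            "assignment": extra[n]["assignment"],
        }
        if robustness is not None:
            lo, hi = robustness.per_node.get(n, (float("nan"), float("nan")))
            row["robustness_lower"], row["robustness_upper"] = lo, hi
        rows.append(row)
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    written.append(table_path)

    if format == "graphml":
        nx.write_graphml(_to_nx_with_attrs(g, extra), path)
        written.insert(0, path)
    elif format == "cyjs":
        with open(path, "w") as fh:
            json.dump(nx.cytoscape_data(_to_nx_with_attrs(g, extra)), fh, indent=1)
        written.insert(0, path)
    elif format != "tsv":
        raise NetworkFormatError(f"unknown results format {format!r}")
    return written
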