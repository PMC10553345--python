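"""Simple undirected graphs and the four-measure evaluation profile.

Every system compared by this package — fired-neuron subgraphs of a trained
network, cumulative topic co-occurrence networks, random-graph draws and
connectome maps — is reduced to the same currency: a simple undirected
unweighted graph, profiled by four averages:

* **average degree** ``2|E|/|V|`` — edge volume relative to node count;
* **average PageRank** — mean stationary importance mass; equals ``1/|V|``
  by normalization, and is reported because its *trajectory* (across growth
  steps) tracks network size;
* **average clustering** — mean of the local clustering coefficient
  ``2·Tri(v) / (deg(v)·(deg(v)−1))``;
* **average triangles** — mean per-node triangle *membership* count
  (each triangle contributes to three nodes, so this is ``3T/|V|`` for
  ``T`` distinct triangles), a proxy for local completeness.

Directed or weighted inputs are symmetrized and deduplicated before they
reach this module; isolated nodes stay in ``|V|`` for every average.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Graph",
    "GraphError",
    "EmptyGraphError",
    "PageRankConvergenceWarning",
    "MeasureVector",
    "Trajectory",
    "average_degree",
    "pagerank_vector",
    "average_pagerank",
    "node_triangle_counts",
    "average_triangles",
    "node_clustering",
    "average_clustering",
    "edge_probability",
    "measure_vector",
    "read_edgelist",
    "write_edgelist",
    "measure_report",
    "pearson",
]

Node = Hashable


class GraphError(ValueError):
    """Invalid graph input or operation."""


class EmptyGraphError(GraphError):
    """Operation requires at least one node."""


class PageRankConvergenceWarning(UserWarning):
    """Power iteration hit max_iter before reaching tolerance."""


class Graph:
    """A simple undirected unweighted graph over opaque hashable node ids.

    Internally nodes are kept in first-seen order and edges as an (m, 2)
    integer index array with ``i < j``; this keeps the container cheap
    enough for multi-million-edge connectome-scale draws while presenting
    set semantics at the API.
    """

    __slots__ = ("_ids", "_index", "_eidx", "_adj", "_deg")

    def __init__(self, node_ids: Sequence[Node], edge_index: np.ndarray):
        # Trusted constructor: edge_index must be canonical (unique rows,
        # first column < second, indices valid). Use from_edges otherwise.
        self._ids: List[Node] = list(node_ids)
        self._index: Dict[Node, int] = {v: i for i, v in enumerate(self._ids)}
        if len(self._index) != len(self._ids):
            raise GraphError("duplicate node ids")
        eidx = np.asarray(edge_index, dtype=np.int64).reshape(-1, 2)
        if eidx.size and (eidx.min() < 0 or eidx.max() >= len(self._ids)):
            raise GraphError("edge endpoint outside node set")
        self._eidx = eidx
        self._adj: Optional[sp.csr_matrix] = None
        self._deg: Optional[np.ndarray] = None

    # ------------------------------------------------------------------ build

    @classmethod
    def from_edges(
        cls, edges: Iterable[Tuple[Node, Node]], nodes: Iterable[Node] = ()
    ) -> "Graph":
        """Build from an iterable of (u, v) pairs plus optional extra nodes.

        Symmetrizes and deduplicates (an undirected pair is stored once)
        and silently drops self-loops, matching the preprocessing applied
        to directed connectome and layer graphs.
        """
        ids: List[Node] = []
        index: Dict[Node, int] = {}

        def ix(v: Node) -> int:
            i = index.get(v)
            if i is None:
                i = len(ids)
                index[v] = i
                ids.append(v)
            return i

        for v in nodes:
            ix(v)
        pairs: List[Tuple[int, int]] = []
        for u, v in edges:
            iu, iv = ix(u), ix(v)
            if iu == iv:
                continue
            pairs.append((iu, iv) if iu < iv else (iv, iu))
        if pairs:
            eidx = np.unique(np.asarray(pairs, dtype=np.int64), axis=0)
        else:
            eidx = np.empty((0, 2), dtype=np.int64)
        return cls(ids, eidx)

    @classmethod
    def from_index_edges(cls, n: int, edge_index: np.ndarray) -> "Graph":
        """Build an integer-labelled graph (nodes 0..n-1) from a canonical
        index array. Fast path for the random-graph generators."""
        return cls(range(n), edge_index)

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        return cls.from_edges(g.edges(), nodes=g.nodes())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._ids)
        g.add_edges_from(self.edges())
        return g

    # ------------------------------------------------------------------ views

    @property
    def n_nodes(self) -> int:
        return len(self._ids)

    @property
    def n_edges(self) -> int:
        return int(self._eidx.shape[0])

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._ids)

    @property
    def node_list(self) -> List[Node]:
        """Nodes in deterministic (first-seen) order."""
        return list(self._ids)

    def edges(self) -> Iterator[Tuple[Node, Node]]:
        for i, j in self._eidx:
            yield (self._ids[i], self._ids[j])

    def edge_set(self) -> frozenset:
        return frozenset(frozenset(e) for e in self.edges())

    def has_edge(self, u: Node, v: Node) -> bool:
        iu, iv = self._index.get(u), self._index.get(v)
        if iu is None or iv is None or iu == iv:
            return False
        if self._eidx.size == 0:
            return False
        return self.adjacency()[iu, iv] != 0

    def __contains__(self, v: Node) -> bool:
        return v in self._index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # ----------------------------------------------------------- linear algebra

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric CSR adjacency with unit weights (cached)."""
        if self._adj is None:
            n = self.n_nodes
            if self._eidx.size:
                i, j = self._eidx[:, 0], self._eidx[:, 1]
                data = np.ones(2 * len(i), dtype=np.float64)
                rows = np.concatenate([i, j])
                cols = np.concatenate([j, i])
                self._adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
            else:
                self._adj = sp.csr_matrix((n, n), dtype=np.float64)
        return self._adj

    def degree_array(self) -> np.ndarray:
        if self._deg is None:
            deg = np.zeros(self.n_nodes, dtype=np.int64)
            if self._eidx.size:
                np.add.at(deg, self._eidx[:, 0], 1)
                np.add.at(deg, self._eidx[:, 1], 1)
            self._deg = deg
        return self._deg

    def degrees(self) -> Dict[Node, int]:
        return dict(zip(self._ids, self.degree_array().tolist()))


# ---------------------------------------------------------------------- types


@dataclass(frozen=True)
class MeasureVector:
    """The four-measure profile of one graph, with the optional task-side
    quantities (cohesion, accuracy) used for trained-network snapshots."""

    avg_degree: float
    avg_pagerank: float
    avg_clustering: float
    avg_triangles: float
    cohesion: Optional[float] = None
    accuracy: Optional[float] = None

    NAMES = ("avg_degree", "avg_pagerank", "avg_clustering", "avg_triangles")

    def as_dict(self, include_optional: bool = True) -> Dict[str, float]:
        d = {k: getattr(self, k) for k in self.NAMES}
        if include_optional:
            if self.cohesion is not None:
                d["cohesion"] = self.cohesion
            if self.accuracy is not None:
                d["accuracy"] = self.accuracy
        return d

    @staticmethod
    def mean(vectors: Sequence["MeasureVector"]) -> "MeasureVector":
        """Component-wise mean; optional fields averaged over the vectors
        that carry them."""
        if not vectors:
            raise ValueError("cannot average zero measure vectors")

        def _opt(name: str) -> Optional[float]:
            vals = [getattr(v, name) for v in vectors if getattr(v, name) is not None]
            return float(np.mean(vals)) if vals else None

        return MeasureVector(
            avg_degree=float(np.mean([v.avg_degree for v in vectors])),
            avg_pagerank=float(np.mean([v.avg_pagerank for v in vectors])),
            avg_clustering=float(np.mean([v.avg_clustering for v in vectors])),
            avg_triangles=float(np.mean([v.avg_triangles for v in vectors])),
            cohesion=_opt("cohesion"),
            accuracy=_opt("accuracy"),
        )


@dataclass
class Trajectory:
    """An ordered sequence of measure profiles over an ordinal axis
    (training epochs, calendar years, or growth iterations).

    Stored as a tidy DataFrame whose first column is the axis; the four
    measures are always present, extra columns (accuracy, cohesion,
    n_nodes, n_edges, ...) are carried through when supplied.
    """

    index_name: str
    frame: pd.DataFrame

    @classmethod
    def from_measures(
        cls,
        index_name: str,
        indices: Sequence,
        vectors: Sequence[MeasureVector],
        extras: Optional[Mapping[str, Sequence]] = None,
    ) -> "Trajectory":
        if len(indices) != len(vectors):
            raise ValueError("indices and vectors length mismatch")
        data: Dict[str, list] = {index_name: list(indices)}
        for name in MeasureVector.NAMES:
            data[name] = [getattr(v, name) for v in vectors]
        for opt in ("cohesion", "accuracy"):
            vals = [getattr(v, opt) for v in vectors]
            if any(x is not None for x in vals):
                data[opt] = vals
        for name, col in (extras or {}).items():
            data[name] = list(col)
        return cls(index_name, pd.DataFrame(data))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> List[str]:
        return [c for c in self.frame.columns if c != self.index_name]

    def series(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise KeyError(f"trajectory has no series {name!r}")
        return self.frame[name].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, index_name: Optional[str] = None) -> "Trajectory":
        frame = pd.read_csv(path)
        return cls(index_name or frame.columns[0], frame)


# ------------------------------------------------------------------- measures


def average_degree(g: Graph) -> float:
    """``2|E|/|V|``; raises :class:`EmptyGraphError` on an empty node set."""
    if g.n_nodes == 0:
        raise EmptyGraphError("average_degree undefined on an empty graph")
    return 2.0 * g.n_edges / g.n_nodes


def pagerank_vector(
    g: Graph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> Dict[Node, float]:
    """Damped PageRank by sparse power iteration.

    Teleportation and dangling mass are spread uniformly; on an undirected
    graph the out-degree equals the degree.  Masses sum to one.  If the
    L1 change is still above ``tol`` after ``max_iter`` sweeps a
    :class:`PageRankConvergenceWarning` is issued (result still returned).
    """
    n = g.n_nodes
    if n == 0:
        raise EmptyGraphError("pagerank undefined on an empty graph")
    deg = g.degree_array().astype(np.float64)
    A = g.adjacency()
    dangling = deg == 0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    x = np.full(n, 1.0 / n)
    converged = False
    for _ in range(max_iter):
        spread = x[dangling].sum() / n
        x_new = (1.0 - damping) / n + damping * (A @ (x * inv_deg) + spread)
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        warnings.warn(
            f"PageRank power iteration did not reach tol={tol} in {max_iter} iterations",
            PageRankConvergenceWarning,
            stacklevel=2,
        )
    return dict(zip(g.node_list, x.tolist()))


def average_pagerank(g: Graph, **kwargs) -> float:
    """Mean PageRank mass; equals ``1/|V|`` by normalization, computed
    (not assigned) so the normalization invariant is exercised."""
    pr = pagerank_vector(g, **kwargs)
    return float(np.mean(list(pr.values())))


def _triangle_array(g: Graph, flops_budget: float = 2e7) -> np.ndarray:
    """Per-node triangle membership via blocked sparse products.

    ``(A_B @ A) ∘ A_B`` counts, for each edge (v, w) with v in the row
    block, the common neighbours of v and w; the row sum is twice the
    number of triangles through v.  Blocking keeps the intermediate
    product's fill around ``flops_budget`` entries so connectome-scale
    graphs (n ≈ 2·10^4, |E| ≈ 3·10^6) fit comfortably in memory.
    """
    n = g.n_nodes
    if n == 0 or g.n_edges == 0:
        return np.zeros(n, dtype=np.int64)
    A = g.adjacency()
    mean_deg = max(1.0, 2.0 * g.n_edges / n)
    block = int(max(16, min(n, flops_budget / (mean_deg * mean_deg))))
    tri = np.zeros(n, dtype=np.float64)
    for start in range(0, n, block):
        stop = min(n, start + block)
        B = A[start:stop]
        paths = (B @ A).multiply(B)
        tri[start:stop] = np.asarray(paths.sum(axis=1)).ravel() / 2.0
    return np.rint(tri).astype(np.int64)


def node_triangle_counts(g: Graph) -> Dict[Node, int]:
    """Number of distinct triangles (3-cycles) each node belongs to."""
    return dict(zip(g.node_list, _triangle_array(g).tolist()))


def average_triangles(g: Graph) -> float:
    """Mean per-node triangle membership (= 3T/|V| for T total triangles)."""
    if g.n_nodes == 0:
        raise EmptyGraphError("average_triangles undefined on an empty graph")
    return float(_triangle_array(g).mean())


def _clustering_array(g: Graph) -> np.ndarray:
    deg = g.degree_array().astype(np.float64)
    tri = _triangle_array(g).astype(np.float64)
    denom = deg * (deg - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return c


def node_clustering(g: Graph, v: Node) -> float:
    """Local clustering coefficient; 0 by convention when deg(v) < 2."""
    if v not in g:
        raise GraphError(f"node {v!r} not in graph")
    idx = g.node_list.index(v)
    return float(_clustering_array(g)[idx])


def average_clustering(g: Graph) -> float:
    """Mean local clustering over *all* nodes (deg<2 nodes contribute 0)."""
    if g.n_nodes == 0:
        raise EmptyGraphError("average_clustering undefined on an empty graph")
    return float(_clustering_array(g).mean())


def edge_probability(g: Graph) -> float:
    """Edge-completion ratio p = 2|E| / (|V|·(|V|−1)): the G(n,p) density
    matched to this graph."""
    if g.n_nodes < 2:
        raise GraphError("edge_probability requires at least 2 nodes")
    return 2.0 * g.n_edges / (g.n_nodes * (g.n_nodes - 1))


def measure_vector(g: Graph) -> MeasureVector:
    """Bundle the four measures of one graph.

    Triangle counts are computed once and reused for clustering, so the
    bundle costs a single sparse pass even at connectome scale.
    """
    if g.n_nodes == 0:
        raise EmptyGraphError("measure_vector undefined on an empty graph")
    deg = g.degree_array().astype(np.float64)
    tri = _triangle_array(g).astype(np.float64)
    denom = deg * (deg - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        clus = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return MeasureVector(
        avg_degree=2.0 * g.n_edges / g.n_nodes,
        avg_pagerank=average_pagerank(g),
        avg_clustering=float(clus.mean()),
        avg_triangles=float(tri.mean()),
    )


# ------------------------------------------------------------------------ I/O


def read_edgelist(path, comment: str = "#", skip_header: bool = False) -> Graph:
    """Read a two-column whitespace/tab-separated edge list; ids are strings."""
    edges: List[Tuple[str, str]] = []
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or (comment and line.startswith(comment)):
                continue
            if first and skip_header:
                first = False
                continue
            first = False
            parts = line.split()
            if len(parts) < 2:
                raise GraphError(f"{path}:{lineno}: expected two columns, got {line!r}")
            edges.append((parts[0], parts[1]))
    return Graph.from_edges(edges)


def write_edgelist(g: Graph, path, header: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("source\ttarget\n")
        for u, v in g.edges():
            fh.write(f"{u}\t{v}\n")


def measure_report(g: Graph) -> Dict[str, float]:
    """JSON-serializable profile of one graph."""
    mv = measure_vector(g)
    rep = {"n_nodes": g.n_nodes, "n_edges": g.n_edges}
    if g.n_nodes >= 2:
        rep["edge_probability"] = edge_probability(g)
    rep.update(mv.as_dict())
    return rep


def write_report(g: Graph, path) -> None:
    with open(path, "w") as fh:
        json.dump(measure_report(g), fh, indent=2)
        fh.write("\n")


# -------------------------------------------------------------------- helpers


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of two equal-length series (nan if degenerate)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson requires two equal-length series of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
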