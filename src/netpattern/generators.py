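"""Random-graph models and the growth experiment.

Four classical models serve as artificial baselines: Barabási–Albert
preferential attachment G(n,e), the two Erdős–Rényi variants G(n,p) and
G(n,m), and the random d-regular graph G(n,d).  The growth experiment
regenerates each model at increasing sizes (default: 20 iterations of
200 nodes, 20 replicate draws averaged per size) and profiles every step,
yielding the trajectory whose trend direction is compared against the
trained-network, topic-network and connectome trajectories.

BA / G(n,m) / regular delegate to networkx; G(n,p) is a vectorized
index sampler so connectome-matched draws at n ≈ 2·10^4 (millions of
edges) stay fast and memory-light.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .graph_core import Graph, MeasureVector, Trajectory, measure_vector

__all__ = [
    "GrowthConfig",
    "ba_graph",
    "er_gnp",
    "er_gnm",
    "random_regular",
    "growth_experiment",
    "derive_seed",
]

MODELS = ("ba", "gnp", "gnm", "regular")


def derive_seed(*keys: int) -> int:
    """Deterministic child seed below 2**31 from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def ba_graph(n: int, e: int, seed: int) -> Graph:
    """Barabási–Albert scale-free graph: a seed star on e+1 nodes, then each
    new node attaches to e distinct existing nodes with degree-proportional
    probability.  |E| = e·(n−e) by construction."""
    if not 1 <= e < n:
        raise ValueError(f"ba_graph requires 1 <= e < n, got e={e}, n={n}")
    g = nx.barabasi_albert_graph(n, e, seed=seed)
    return Graph.from_networkx(g)


def _pair_from_index(k: np.ndarray, n: int) -> np.ndarray:
    """Invert the row-major upper-triangle linearization: indices k in
    [0, C(n,2)) -> pairs (i, j) with i < j."""
    k = k.astype(np.int64)
    # float solve of i*(2n-i-1)/2 <= k, then exact integer correction
    i = np.floor((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8.0 * k)) / 2).astype(np.int64)
    i = np.clip(i, 0, n - 2)
    for _ in range(3):
        start = i * (2 * n - i - 1) // 2
        too_high = start > k
        i = np.where(too_high, i - 1, i)
        start = i * (2 * n - i - 1) // 2
        too_low = k - start >= (n - 1 - i)
        i = np.where(too_low, i + 1, i)
    start = i * (2 * n - i - 1) // 2
    j = k - start + i + 1
    return np.column_stack([i, j])


def er_gnp(n: int, p: float, seed: int) -> Graph:
    """Erdős–Rényi G(n,p): each of the C(n,2) unordered pairs is an edge
    independently with probability p."""
    if n < 1:
        raise ValueError("er_gnp requires n >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("er_gnp requires 0 <= p <= 1")
    rng = np.random.default_rng(seed)
    total = n * (n - 1) // 2
    if total == 0 or p == 0.0:
        return Graph.from_index_edges(n, np.empty((0, 2), dtype=np.int64))
    if p == 1.0:
        k = np.arange(total, dtype=np.int64)
        return Graph.from_index_edges(n, _pair_from_index(k, n))
    m = int(rng.binomial(total, p))
    # Rejection sampling of m distinct pair indices: oversample with
    # replacement, deduplicate, top up; uniform over m-subsets after the
    # final shuffle-and-truncate.
    chosen = np.empty(0, dtype=np.int64)
    while chosen.size < m:
        need = m - chosen.size
        draw = rng.integers(0, total, size=int(need * 1.05) + 16, dtype=np.int64)
        chosen = np.unique(np.concatenate([chosen, draw]))
    if chosen.size > m:
        chosen = rng.permutation(chosen)[:m]
        chosen.sort()
    return Graph.from_index_edges(n, _pair_from_index(chosen, n))


def er_gnm(n: int, m: int, seed: int) -> Graph:
    """Erdős–Rényi G(n,m): exactly m edges, uniform over labeled edge sets."""
    total = n * (n - 1) // 2
    if not 0 <= m <= total:
        raise ValueError(f"er_gnm requires 0 <= m <= C(n,2)={total}, got {m}")
    g = nx.gnm_random_graph(n, m, seed=seed)
    return Graph.from_networkx(g)


def random_regular(n: int, d: int, seed: int) -> Graph:
    """Random d-regular graph (pairing model with restarts); requires
    3 <= d < n and n·d even."""
    if not 3 <= d < n:
        raise ValueError(f"random_regular requires 3 <= d < n, got d={d}, n={n}")
    if (n * d) % 2 != 0:
        raise ValueError(f"random_regular requires n*d even, got n={n}, d={d}")
    g = nx.random_regular_graph(d, n, seed=seed)
    return Graph.from_networkx(g)


@dataclass
class GrowthConfig:
    """Configuration of the incremental-size experiment.

    Defaults are the baseline study conditions: 20 iterations of 200 nodes
    (final size 4000), 20 replicate draws per size, p = 0.015 for G(n,p)
    and e = m_per_node = d = 20 for the fixed-budget models.  G(n,m) and
    the regular model keep a fixed *per-node* edge budget during growth
    (m_k = m_per_node·n_k), so their average degree stays static while
    only G(n,p)'s degree scales with size.
    """

    model: str
    step_nodes: int = 200
    iterations: int = 20
    reps: int = 20
    p: float = 0.015
    e: int = 20
    m_per_node: int = 20
    d: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.iterations < 1 or self.step_nodes < 1 or self.reps < 1:
            raise ValueError("iterations, step_nodes and reps must all be >= 1")


def _generate(cfg: GrowthConfig, n: int, seed: int) -> Graph:
    if cfg.model == "ba":
        return ba_graph(n, cfg.e, seed)
    if cfg.model == "gnp":
        return er_gnp(n, cfg.p, seed)
    if cfg.model == "gnm":
        return er_gnm(n, cfg.m_per_node * n, seed)
    return random_regular(n, cfg.d, seed)


def growth_experiment(cfg: GrowthConfig) -> Trajectory:
    """Regenerate the model at n_k = k·step_nodes for k = 1..iterations,
    profile each draw, and average the profile over ``reps`` replicates.

    Returns a trajectory indexed by iteration, with mean node and edge
    counts carried as extra columns.
    """
    indices, vectors = [], []
    n_nodes_col, n_edges_col = [], []
    for k in range(1, cfg.iterations + 1):
        n_k = k * cfg.step_nodes
        draws = []
        edge_counts = []
        for r in range(cfg.reps):
            g = _generate(cfg, n_k, derive_seed(cfg.seed, k, r))
            draws.append(measure_vector(g))
            edge_counts.append(g.n_edges)
        indices.append(k)
        vectors.append(MeasureVector.mean(draws))
        n_nodes_col.append(n_k)
        n_edges_col.append(float(np.mean(edge_counts)))
    return Trajectory.from_measures(
        "iteration", indices, vectors,
        extras={"n_nodes": n_nodes_col, "n_edges": n_edges_col},
    )
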