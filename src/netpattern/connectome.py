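"""Connectome profiles, matched Erdős–Rényi nulls and the animal p-sweep.

A connectome is reduced to a simple undirected unweighted graph (synapse
multiplicities, direction and synapse types are discarded), profiled with
the four measures, and compared against G(n, p) draws matched to its node
count and edge-completion ratio p = 2|E|/(|V|(|V|−1)).

The roundworm wiring-table dialect carries (neuron1, neuron2, type, count)
rows; Receiving / Receiving-Poly rows (types R, Rp) duplicate the Send
rows of the same synapses and are dropped by default.

Because only two full animal connectomes are openly available, intermediate
nervous systems are *projected*: for a roster of animals with estimated
neuron counts (200 to 18,000 neurons), G(n, p) graphs are generated on a
grid of ten p values spanning the fruit-fly density (0.012164) to the worm
density (0.061134).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .generators import derive_seed, er_gnp
from .graph_core import (
    Graph,
    GraphError,
    MeasureVector,
    Trajectory,
    edge_probability,
    measure_vector,
)

__all__ = [
    "ConnectomeSpec",
    "DEFAULT_ANIMALS",
    "WORM_P",
    "FRUITFLY_P",
    "read_connectome",
    "matched_null",
    "comparison_table",
    "p_grid",
    "projection_sweep",
    "fixed_p_trajectory",
    "density_matched_trajectory",
]

logger = logging.getLogger(__name__)

#: Edge-completion ratios of the two fully mapped connectomes.
WORM_P = 0.061134
FRUITFLY_P = 0.012164

#: Animals with estimated neuron counts spanning the worm-to-fruit-fly range.
DEFAULT_ANIMALS: List[Tuple[str, int]] = [
    ("rotifer", 200),
    ("sea_squirt_larva", 231),
    ("roundworm", 302),
    ("jellyfish", 5600),
    ("fairy_wasp", 7400),
    ("medicinal_leech", 10000),
    ("pond_snail", 11000),
    ("sea_slug", 18000),
]

KNOWN_TYPES = {"S", "Sp", "R", "Rp", "EJ", "NMJ"}
DEFAULT_EXCLUDE = frozenset({"R", "Rp"})


@dataclass
class ConnectomeSpec:
    """A named nervous system: neuron count, optional mapped edges, and the
    derived edge-completion ratio when edges are present."""

    name: str
    n_neurons: int
    graph: Optional[Graph] = None
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("a connectome needs at least 2 neurons")
        if self.graph is not None and self.p is None:
            self.p = edge_probability(self.graph)


def read_connectome(
    path,
    dialect: str = "edgelist",
    exclude_types: Iterable[str] = DEFAULT_EXCLUDE,
    name: Optional[str] = None,
) -> ConnectomeSpec:
    """Read a connectome file and collapse it to a simple undirected graph.

    ``dialect='edgelist'`` reads bare two-column pairs.
    ``dialect='wormatlas'`` reads tab/whitespace-separated
    (neuron1, neuron2, type, count) rows, dropping rows whose synapse type
    is in ``exclude_types`` (default {R, Rp}: receiving rows duplicating
    send rows).  Unknown type tokens are kept with a logged warning;
    malformed rows raise with their line number.
    """
    exclude = set(exclude_types)
    edges: List[Tuple[str, str]] = []
    unknown: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if dialect == "edgelist":
                if len(parts) < 2:
                    raise GraphError(f"{path}:{lineno}: expected 2 columns, got {line!r}")
                edges.append((parts[0], parts[1]))
            elif dialect == "wormatlas":
                if len(parts) < 4:
                    # a header row is tolerated once at the top
                    if lineno == 1:
                        continue
                    raise GraphError(f"{path}:{lineno}: expected 4 columns, got {line!r}")
                n1, n2, typ, count = parts[0], parts[1], parts[2], parts[3]
                if lineno == 1 and not count.lstrip("-").isdigit():
                    continue  # header row
                if typ in exclude:
                    continue
                if typ not in KNOWN_TYPES:
                    unknown[typ] = unknown.get(typ, 0) + 1
                edges.append((n1, n2))
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    for typ, cnt in unknown.items():
        logger.warning("unknown synapse type %r on %d rows (kept)", typ, cnt)
    g = Graph.from_edges(edges)
    return ConnectomeSpec(name or str(path), g.n_nodes, graph=g)


def matched_null(spec: ConnectomeSpec, seed: int) -> Graph:
    """G(n, p) draw matched to the spec's neuron count and density."""
    if spec.p is None:
        raise ValueError("spec has no density p (no edges given)")
    return er_gnp(spec.n_neurons, spec.p, seed)


def comparison_table(specs: Sequence[ConnectomeSpec], seeds: Sequence[int] = (0,)) -> pd.DataFrame:
    """Real-vs-generated profile table.

    One row per mapped connectome plus one row per matched null (measures
    averaged over ``seeds``; realized synapse count averaged likewise).
    """
    rows = []
    for spec in specs:
        if spec.graph is not None:
            mv = measure_vector(spec.graph)
            rows.append(
                {"name": spec.name, "kind": "real", "n_neurons": spec.graph.n_nodes,
                 "n_synapses": spec.graph.n_edges, **mv.as_dict(include_optional=False)}
            )
        if spec.p is not None:
            draws, m_edges = [], []
            for s in seeds:
                g = matched_null(spec, derive_seed(s, spec.n_neurons))
                draws.append(measure_vector(g))
                m_edges.append(g.n_edges)
            mv = MeasureVector.mean(draws)
            rows.append(
                {"name": f"generated_{spec.name}", "kind": "generated",
                 "n_neurons": spec.n_neurons, "n_synapses": float(np.mean(m_edges)),
                 **mv.as_dict(include_optional=False)}
            )
    return pd.DataFrame(rows)


def p_grid(p_low: float = FRUITFLY_P, p_high: float = WORM_P, n_p: int = 10) -> np.ndarray:
    """Ten densities uniformly spaced from the fruit-fly p to the worm p,
    inclusive of both endpoints."""
    return np.linspace(p_low, p_high, n_p)


def projection_sweep(
    animals: Optional[Sequence[Tuple[str, int]]] = None,
    p_low: float = FRUITFLY_P,
    p_high: float = WORM_P,
    n_p: int = 10,
    seeds: Sequence[int] = (0,),
    max_n: Optional[int] = None,
) -> pd.DataFrame:
    """Profile G(n, p) draws for every (animal, p, seed) combination.

    ``max_n`` caps the roster for desk-scale runs (the full sweep at
    n = 18,000 × p ≈ 0.061 generates ~10M edges).  Returns a tidy frame
    with one row per draw: animal, n, p-index, p, seed, realized synapse
    count and the four measures.
    """
    roster = list(animals if animals is not None else DEFAULT_ANIMALS)
    if max_n is not None:
        roster = [(a, n) for a, n in roster if n <= max_n]
    grid = p_grid(p_low, p_high, n_p)
    rows = []
    for name, n in roster:
        for k, p in enumerate(grid, start=1):
            for s in seeds:
                g = er_gnp(n, float(p), derive_seed(s, n, k))
                mv = measure_vector(g)
                rows.append(
                    {"animal": name, "n_neurons": n, "p_index": k, "p": float(p),
                     "seed": s, "n_synapses": g.n_edges,
                     **mv.as_dict(include_optional=False)}
                )
    return pd.DataFrame(rows)


def _trajectory_from_rows(frame: pd.DataFrame) -> Trajectory:
    grouped = frame.groupby("n_neurons", sort=True).mean(numeric_only=True)
    vectors = [
        MeasureVector(r.avg_degree, r.avg_pagerank, r.avg_clustering, r.avg_triangles)
        for r in grouped.itertuples()
    ]
    return Trajectory.from_measures(
        "n_neurons", list(grouped.index), vectors,
        extras={"p": grouped["p"].tolist(), "n_edges": grouped["n_synapses"].tolist()},
    )


def fixed_p_trajectory(
    p: float = WORM_P,
    animals: Optional[Sequence[Tuple[str, int]]] = None,
    seeds: Sequence[int] = (0,),
    max_n: Optional[int] = None,
) -> Trajectory:
    """Per-animal profile series at one fixed density, ordered by neuron
    count and averaged over seeds: the fixed-p reading of the animal row."""
    frame = projection_sweep(animals, p_low=p, p_high=p, n_p=1, seeds=seeds, max_n=max_n)
    return _trajectory_from_rows(frame)


def density_matched_trajectory(
    animals: Optional[Sequence[Tuple[str, int]]] = None,
    p_low: float = FRUITFLY_P,
    p_high: float = WORM_P,
    n_p: int = 10,
    seeds: Sequence[int] = (0,),
    max_n: Optional[int] = None,
) -> Trajectory:
    """Diagonal reading of the sweep: the k-th animal (ascending neuron
    count) paired with the k-th *descending* density, emulating the drop
    in synaptic density from worm to fruit fly as brains grow."""
    roster = list(animals if animals is not None else DEFAULT_ANIMALS)
    if max_n is not None:
        roster = [(a, n) for a, n in roster if n <= max_n]
    roster = sorted(roster, key=lambda an: an[1])
    desc = p_grid(p_low, p_high, n_p)[::-1]
    if len(roster) > len(desc):
        raise ValueError("more animals than grid densities")
    rows = []
    for k, (name, n) in enumerate(roster):
        p = float(desc[k])
        for s in seeds:
            g = er_gnp(n, p, derive_seed(s, n, 1000 + k))
            mv = measure_vector(g)
            rows.append(
                {"animal": name, "n_neurons": n, "p_index": k + 1, "p": p,
                 "seed": s, "n_synapses": g.n_edges,
                 **mv.as_dict(include_optional=False)}
            )
    return _trajectory_from_rows(pd.DataFrame(rows))
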