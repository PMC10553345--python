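"""Cumulative topic co-occurrence networks from publication streams.

Each publication is a (year, topic-set) record; topics co-occurring in one
publication form a clique.  The network for year *y* is the union of the
cliques of every record with year ≤ y — a cumulative stack in which past
research activity is never removed, so node and edge sets grow
monotonically.  Profiling each yearly snapshot yields the topic-network
maturity trajectory (degree and triangles rising, PageRank and clustering
falling as a field accretes around key topics).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .graph_core import Graph, Trajectory, measure_vector, pearson

__all__ = [
    "PublicationRecord",
    "read_records",
    "write_records",
    "cumulative_networks",
    "yearly_trajectory",
    "growth_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PublicationRecord:
    """One publication: its year and its (non-empty) topic set."""

    year: int
    topics: frozenset

    def __post_init__(self) -> None:
        if not self.topics:
            raise ValueError("publication record needs at least one topic")


def read_records(path, topic_delim: str = ";", max_year: int | None = 2020) -> List[PublicationRecord]:
    """Read `year,topic1;topic2;...` CSV rows.

    Rows with an empty topic list are rejected (skipped with a logged
    count); rows beyond ``max_year`` are dropped when a cap is given.
    """
    records: List[PublicationRecord] = []
    rejected = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() == "year":
                continue
            year = int(row[0])
            if max_year is not None and year > max_year:
                continue
            topics = frozenset(t.strip() for t in row[1].split(topic_delim) if t.strip())
            if not topics:
                rejected += 1
                continue
            records.append(PublicationRecord(year, topics))
    if rejected:
        logger.warning("rejected %d records with empty topic sets", rejected)
    return records


def write_records(records: Iterable[PublicationRecord], path, topic_delim: str = ";") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "topics"])
        for rec in records:
            writer.writerow([rec.year, topic_delim.join(sorted(rec.topics))])


def cumulative_networks(records: Sequence[PublicationRecord]) -> Dict[int, Graph]:
    """Cumulative co-occurrence graph for every year present in the stream.

    The graph at year y is the clique-union over all records with
    year ≤ y; node and edge sets are non-decreasing in y.
    """
    if not records:
        raise ValueError("no publication records supplied")
    by_year: Dict[int, List[PublicationRecord]] = {}
    for rec in records:
        by_year.setdefault(rec.year, []).append(rec)
    nodes: List[str] = []
    seen: Set[str] = set()
    edges: List[Tuple[str, str]] = []
    edge_seen: Set[Tuple[str, str]] = set()
    nets: Dict[int, Graph] = {}
    for year in sorted(by_year):
        for rec in by_year[year]:
            topics = sorted(rec.topics)
            for t in topics:
                if t not in seen:
                    seen.add(t)
                    nodes.append(t)
            for i in range(len(topics)):
                for j in range(i + 1, len(topics)):
                    e = (topics[i], topics[j])
                    if e not in edge_seen:
                        edge_seen.add(e)
                        edges.append(e)
        nets[year] = Graph.from_edges(list(edges), nodes=list(nodes))
    return nets


def yearly_trajectory(nets: Dict[int, Graph]) -> Trajectory:
    """Profile each yearly snapshot on a contiguous year axis.

    Years with no records inherit the previous year's graph (explicit
    carry-forward), so trajectories from sparse streams stay comparable.
    """
    if not nets:
        raise ValueError("no yearly networks supplied")
    years = sorted(nets)
    indices, vectors, n_nodes, n_edges = [], [], [], []
    current = None
    for year in range(years[0], years[-1] + 1):
        current = nets.get(year, current)
        indices.append(year)
        vectors.append(measure_vector(current))
        n_nodes.append(current.n_nodes)
        n_edges.append(current.n_edges)
    return Trajectory.from_measures(
        "year", indices, vectors, extras={"n_nodes": n_nodes, "n_edges": n_edges}
    )


def growth_correlation(traj: Trajectory) -> float:
    """Pearson correlation between yearly node and edge counts."""
    return pearson(traj.series("n_nodes"), traj.series("n_edges"))
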