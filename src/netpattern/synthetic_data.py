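"""Seeded synthetic inputs with the statistical structure each stage assumes.

Three generators stand in for external corpora so every pipeline runs and
tests without downloads:

* **images** — a 10-class grayscale problem in the handwritten-digit
  layout (28×28, flat rows in [0,1], or a reduced 8×8 profile): one fixed
  random prototype per class plus clipped Gaussian pixel noise.  This is a
  learnable 784-dimensional classification task, not a visual imitation.
* **publications** — a yearly stream of (year, topic-set) records with
  linear vocabulary growth and preferential topic reuse, reproducing the
  qualitative bibliometric shape of near-linear node growth with
  super-linear edge growth in the cumulative co-occurrence network.
* **toy connectome** — a wiring table in the worm dialect with planted
  edges and synthetic Send/Receive/junction type tokens, so the reader's
  type filtering is testable against a known ground truth.

All generators are seed-deterministic and emit exactly the dialects the
corresponding readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph_core import Graph
from .generators import er_gnp, derive_seed
from .topic_net import PublicationRecord

__all__ = [
    "SynthImageConfig",
    "SynthDataset",
    "make_images",
    "save_dataset",
    "load_dataset",
    "desk_image_profile",
    "SynthPubConfig",
    "make_publications",
    "make_toy_connectome",
]


# ------------------------------------------------------------------- images


@dataclass(frozen=True)
class SynthImageConfig:
    """Prototype-plus-noise image generator settings.

    Defaults mirror the handwritten-digit corpus layout: 10 classes of
    28×28 grayscale images, 60,000 training and 10,000 test rows.  The
    separability invariant (min pairwise prototype distance > 4·noise_sd)
    guarantees a nearest-prototype learner — and a fortiori the trained
    classifier — can separate the classes.
    """

    n_classes: int = 10
    side: int = 28
    n_train: int = 60000
    n_test: int = 10000
    noise_sd: float = 0.1
    seed: int = 0


def desk_image_profile(seed: int = 0) -> SynthImageConfig:
    """Reduced 8×8 profile used by the test-scale pipelines.

    The noise level is set so the classifier stays in the
    rising-accuracy regime (high-90s held-out accuracy, loss still
    shrinking) across a full 100-epoch run, mirroring how the
    handwritten-digit corpus behaves, rather than saturating to zero
    loss within a few epochs.
    """
    return SynthImageConfig(side=8, n_train=4000, n_test=800, noise_sd=0.5, seed=seed)


@dataclass
class SynthDataset:
    """Flat image rows in [0,1] with integer labels, split train/test."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    side: int
    prototypes: np.ndarray

    @property
    def n_features(self) -> int:
        return self.side * self.side


def make_images(cfg: SynthImageConfig) -> SynthDataset:
    """Sample class prototypes and noisy examples, stratified and shuffled.

    Each class prototype is a fixed uniform-random point in [0,1]^(side²);
    examples add N(0, noise_sd) pixel noise and clip back to [0,1].
    Raises if the prototypes violate the separability invariant (only
    possible at extreme noise_sd for the default dimensions).
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.side * cfg.side
    protos = rng.random((cfg.n_classes, d))
    dists = np.sqrt(((protos[:, None, :] - protos[None, :, :]) ** 2).sum(-1))
    min_dist = dists[np.triu_indices(cfg.n_classes, k=1)].min()
    if min_dist <= 4 * cfg.noise_sd:
        raise ValueError(
            f"prototypes not separable: min pairwise distance {min_dist:.3f} "
            f"<= 4*noise_sd = {4 * cfg.noise_sd:.3f}"
        )

    def sample(n: int) -> Tuple[np.ndarray, np.ndarray]:
        # stratified: class c gets n//k (+1 for the first n%k classes)
        counts = np.full(cfg.n_classes, n // cfg.n_classes)
        counts[: n % cfg.n_classes] += 1
        y = np.repeat(np.arange(cfg.n_classes), counts)
        X = protos[y] + rng.normal(0.0, cfg.noise_sd, size=(n, d))
        np.clip(X, 0.0, 1.0, out=X)
        order = rng.permutation(n)
        return X[order], y[order]

    X_train, y_train = sample(cfg.n_train)
    X_test, y_test = sample(cfg.n_test)
    return SynthDataset(X_train, y_train, X_test, y_test, cfg.side, protos)


def save_dataset(data: SynthDataset, out_dir) -> None:
    """Write the on-disk layout the trained-network CLI consumes:
    ``images`` / ``labels`` CSV pairs per split plus a sidecar with the
    image side length."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "train_images.csv", data.X_train, fmt="%.5f", delimiter=",")
    np.savetxt(out / "train_labels.csv", data.y_train, fmt="%d")
    np.savetxt(out / "test_images.csv", data.X_test, fmt="%.5f", delimiter=",")
    np.savetxt(out / "test_labels.csv", data.y_test, fmt="%d")
    (out / "meta.txt").write_text(f"side={data.side}\n")


def load_dataset(in_dir) -> SynthDataset:
    src = Path(in_dir)
    X_train = np.loadtxt(src / "train_images.csv", delimiter=",", ndmin=2)
    y_train = np.loadtxt(src / "train_labels.csv", dtype=int, ndmin=1)
    X_test = np.loadtxt(src / "test_images.csv", delimiter=",", ndmin=2)
    y_test = np.loadtxt(src / "test_labels.csv", dtype=int, ndmin=1)
    side = int(np.sqrt(X_train.shape[1]))
    meta = src / "meta.txt"
    if meta.exists():
        for line in meta.read_text().splitlines():
            if line.startswith("side="):
                side = int(line.split("=", 1)[1])
    return SynthDataset(X_train, y_train, X_test, y_test, side, np.empty((0, X_train.shape[1])))


# ------------------------------------------------------------- publications


@dataclass(frozen=True)
class SynthPubConfig:
    """Publication-stream generator settings.

    The stream emulates the canonical bibliometric growth shapes of a
    maturing research field: yearly publication volume grows
    exponentially at ``pub_growth`` (the literature's multi-decade
    doubling), a constant expected number of brand-new topics enters
    each year (``new_topics_per_year``, keeping cumulative vocabulary
    near-linear in time while edges grow super-linearly), each
    publication lists a Poisson-distributed number of topics around
    ``mean_topics`` (never fewer than 2, so every record contributes
    co-occurrence edges), and topics are drawn with probability
    proportional to (attractiveness + past use count)^``reuse_bias``
    — Price-style preferential reuse with initial attractiveness.
    The sublinear default bias spreads reuse beyond a closed hub core,
    so a topic's partners diversify faster than they interconnect and
    the mean clustering declines as the network matures, while degree
    and triangles rise.
    """

    year_start: int = 1971
    year_end: int = 2020
    pubs_per_year: int = 60
    pub_growth: float = 1.05
    mean_topics: float = 4.0
    new_topics_per_year: int = 30
    attractiveness: float = 3.0
    reuse_bias: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_topics < 2:
            raise ValueError("publications need >= 2 topics on average to contribute edges")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        if self.pub_growth <= 0:
            raise ValueError("pub_growth must be positive")


def make_publications(cfg: SynthPubConfig) -> List[PublicationRecord]:
    """Generate the preferential-reuse publication stream."""
    rng = np.random.default_rng(cfg.seed)
    counts: List[float] = []  # past use count per topic; topic id = index
    records: List[PublicationRecord] = []
    for yi, year in enumerate(range(cfg.year_start, cfg.year_end + 1)):
        n_pubs = max(1, int(round(cfg.pubs_per_year * cfg.pub_growth**yi)))
        n_new = rng.poisson(cfg.new_topics_per_year)
        counts.extend([0.0] * max(n_new, 2 if not counts else 0))
        for _ in range(n_pubs):
            vocab = len(counts)
            k = min(max(2, rng.poisson(cfg.mean_topics)), vocab)
            weights = (cfg.attractiveness + np.asarray(counts)) ** cfg.reuse_bias
            chosen = rng.choice(vocab, size=k, replace=False, p=weights / weights.sum())
            for t in chosen:
                counts[t] += 1.0
            records.append(PublicationRecord(year, frozenset(f"t{t}" for t in chosen)))
    return records


# --------------------------------------------------------------- connectome

SEND_TYPES = ("S", "Sp", "EJ", "NMJ")


def make_toy_connectome(
    n: int,
    p: float,
    path,
    directed_fraction: float = 0.5,
    type_mix: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> Graph:
    """Write a worm-dialect wiring table with a planted edge set.

    Every planted edge gets one Send-side row (type sampled from
    ``type_mix`` over {S, Sp, EJ, NMJ}); a ``directed_fraction`` of edges
    additionally get the duplicate Receiving row (type R or Rp) that the
    reader must drop.  Returns the planted graph, so round-trips can
    assert exact recovery after type filtering.
    """
    rng = np.random.default_rng(seed)
    mix = type_mix or {"S": 0.4, "Sp": 0.3, "EJ": 0.2, "NMJ": 0.1}
    types = list(mix)
    probs = np.asarray([mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    planted = er_gnp(n, p, derive_seed(seed, n))
    neuron = [f"N{i:03d}" for i in range(n)]
    lines = ["Neuron1\tNeuron2\tType\tNbr"]
    for u, v in planted.edges():
        typ = types[int(rng.choice(len(types), p=probs))]
        count = int(rng.integers(1, 6))
        lines.append(f"{neuron[u]}\t{neuron[v]}\t{typ}\t{count}")
        if rng.random() < directed_fraction:
            rtyp = "Rp" if typ == "Sp" else "R"
            lines.append(f"{neuron[v]}\t{neuron[u]}\t{rtyp}\t{count}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Graph.from_edges(((neuron[u], neuron[v]) for u, v in planted.edges()))
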