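"""Multilayer perceptron training and fired-neuron pattern graphs.

A feed-forward classifier (default 784–80–40–20–10: sigmoid hidden layers,
softmax output) is trained with mini-batch Adam on sparse categorical
cross-entropy.  At epoch checkpoints, each evaluation input induces a
*fired pattern*: the set of neurons whose output strictly exceeds the
activation threshold 0.5 (input neurons participate with their normalized
pixel intensity as output).  The graph on the fired set — by default every
fired pair lying in *different* layers is an edge — is profiled with the
four measures, and *cohesion* relates the fired subgraph to the wider
above-background (output > 0.1) subgraph:

    cohesion = |edges among fired| / |edges among active|

The per-checkpoint accuracy plus averaged profile forms the epoch
trajectory whose trend directions (degree and triangles falling as the
classifier matures) are the trained-network row of the comparison summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph_core import (
    EmptyGraphError,
    Graph,
    MeasureVector,
    Trajectory,
    measure_vector,
    pearson,
)

__all__ = [
    "Hyper",
    "MLP",
    "AdamState",
    "adam_step",
    "train_epoch",
    "forward_outputs",
    "FiredPattern",
    "fired_pattern",
    "cohesion",
    "default_checkpoints",
    "epoch_sweep",
    "trajectory_correlation",
]

EDGE_MODES = ("adjacent", "cross", "all")


@dataclass(frozen=True)
class Hyper:
    """Adam + batching hyperparameters (library-default values of the era)."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch: int = 32


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class MLP:
    """Sigmoid-hidden, softmax-output feed-forward network."""

    sizes: List[int]
    W: List[np.ndarray]
    b: List[np.ndarray]

    @classmethod
    def init(cls, sizes: Sequence[int] = (784, 80, 40, 20, 10), seed: int = 0) -> "MLP":
        """Glorot-uniform weights, zero biases."""
        rng = np.random.default_rng(seed)
        sizes = list(sizes)
        W, b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            b.append(np.zeros(fan_out))
        return cls(sizes, W, b)

    @property
    def n_layers(self) -> int:
        """Number of neuron layers including input and output."""
        return len(self.sizes)

    def forward(self, X: np.ndarray) -> List[np.ndarray]:
        """Per-layer activations [input, hidden..., softmax output]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.sizes[0]:
            raise ValueError(
                f"input width {X.shape[1]} does not match input layer {self.sizes[0]}"
            )
        acts = [X]
        h = X
        last = len(self.W) - 1
        for li, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = _softmax(z) if li == last else _sigmoid(z)
            acts.append(h)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Sparse categorical cross-entropy (mean over inputs)."""
        proba = self.predict_proba(X)
        y = np.asarray(y, dtype=int)
        return float(-np.log(np.clip(proba[np.arange(len(y)), y], 1e-300, None)).mean())

    def gradients(self, X: np.ndarray, y: np.ndarray) -> Tuple[List[np.ndarray], List[np.ndarray]]:
        """Backprop gradients of the mean cross-entropy w.r.t. W and b."""
        acts = self.forward(X)
        y = np.asarray(y, dtype=int)
        n = len(y)
        delta = acts[-1].copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        gW: List[np.ndarray] = [np.empty(0)] * len(self.W)
        gb: List[np.ndarray] = [np.empty(0)] * len(self.b)
        for li in range(len(self.W) - 1, -1, -1):
            gW[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                h = acts[li]
                delta = (delta @ self.W[li].T) * h * (1.0 - h)
        return gW, gb


@dataclass
class AdamState:
    """First/second-moment accumulators and step counter."""

    m: List[np.ndarray]
    v: List[np.ndarray]
    t: int = 0

    @classmethod
    def for_model(cls, model: MLP) -> "AdamState":
        params = model.W + model.b
        return cls(
            m=[np.zeros_like(p) for p in params],
            v=[np.zeros_like(p) for p in params],
        )


def adam_step(
    params: List[np.ndarray],
    grads: List[np.ndarray],
    state: AdamState,
    hyper: Hyper,
) -> None:
    """One in-place Adam update with bias-corrected moments."""
    state.t += 1
    b1, b2 = hyper.beta1, hyper.beta2
    corr1 = 1.0 - b1**state.t
    corr2 = 1.0 - b2**state.t
    for p, g, m, v in zip(params, grads, state.m, state.v):
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * g * g
        p -= hyper.lr * (m / corr1) / (np.sqrt(v / corr2) + hyper.eps)


def train_epoch(
    model: MLP,
    X: np.ndarray,
    y: np.ndarray,
    hyper: Hyper,
    state: AdamState,
    rng: np.random.Generator,
) -> float:
    """One full shuffled mini-batch pass; returns the mean batch loss."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != model.sizes[0] or len(X) != len(y):
        raise ValueError("dataset shape does not match the model input layer")
    order = rng.permutation(len(X))
    losses = []
    for start in range(0, len(X), hyper.batch):
        idx = order[start : start + hyper.batch]
        losses.append(model.loss(X[idx], y[idx]))
        gW, gb = model.gradients(X[idx], y[idx])
        adam_step(model.W + model.b, gW + gb, state, hyper)
    return float(np.mean(losses))


# ----------------------------------------------------------- pattern graphs


def neuron_id(layer: int, index: int) -> str:
    """Stable opaque id for neuron ``index`` of layer ``layer``."""
    return f"L{layer}.{index}"


def forward_outputs(model: MLP, x: np.ndarray) -> Dict[str, float]:
    """Output value of every neuron for one input: input neurons report the
    pixel intensity, hidden neurons their sigmoid, output neurons their
    softmax probability."""
    acts = model.forward(np.atleast_2d(x))
    out: Dict[str, float] = {}
    for li, layer_act in enumerate(acts):
        for i, val in enumerate(layer_act[0]):
            out[neuron_id(li, i)] = float(val)
    return out


@dataclass
class FiredPattern:
    """Per-input activation subgraphs at the two thresholds.

    ``fired`` holds neurons with output strictly above 0.5, ``active`` the
    superset above 0.1; the two graphs apply the same edge rule to each set.
    """

    fired: frozenset
    active: frozenset
    pattern_graph: Graph
    active_graph: Graph
    edge_mode: str
    layer_sizes: List[int]
    fired_per_layer: List[int]
    active_per_layer: List[int]


def _layer_pair_edges(
    ids_per_layer: List[np.ndarray], edge_mode: str
) -> np.ndarray:
    """All edges induced by the edge rule on the given per-layer id arrays
    (global integer ids)."""
    blocks = []
    L = len(ids_per_layer)
    for a in range(L):
        ia = ids_per_layer[a]
        if ia.size == 0:
            continue
        if edge_mode == "all" and ia.size > 1:
            tri = np.triu_indices(ia.size, k=1)
            blocks.append(np.column_stack([ia[tri[0]], ia[tri[1]]]))
        bs = range(a + 1, min(a + 2, L)) if edge_mode == "adjacent" else range(a + 1, L)
        for b in bs:
            ib = ids_per_layer[b]
            if ib.size == 0:
                continue
            blocks.append(
                np.column_stack([np.repeat(ia, ib.size), np.tile(ib, ia.size)])
            )
    if not blocks:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(blocks).astype(np.int64)


def fired_pattern(
    model: MLP,
    x: np.ndarray,
    edge_mode: str = "cross",
    activation_threshold: float = 0.5,
    graph_threshold: float = 0.1,
) -> FiredPattern:
    """Extract the fired (> 0.5, strict) and active (> 0.1, strict) neuron
    subgraphs for one input.

    ``edge_mode`` controls the edge universe on a neuron set:
    ``adjacent`` links pairs in consecutive layers only, ``cross``
    (default) links every pair lying in different layers, ``all`` links
    every pair.  The default must be ``cross`` for triangle trajectories
    to be non-degenerate (a layered adjacent-only graph is multipartite
    and triangle-free).
    """
    if edge_mode not in EDGE_MODES:
        raise ValueError(f"edge_mode must be one of {EDGE_MODES}, got {edge_mode!r}")
    acts = model.forward(np.atleast_2d(x))
    offsets = np.concatenate([[0], np.cumsum(model.sizes)])

    def build(threshold: float) -> Tuple[List[np.ndarray], List[str]]:
        per_layer, labels = [], []
        for li, layer_act in enumerate(acts):
            local = np.flatnonzero(layer_act[0] > threshold)
            per_layer.append(local + offsets[li])
            labels.extend(neuron_id(li, int(i)) for i in local)
        return per_layer, labels

    fired_ids, fired_labels = build(activation_threshold)
    active_ids, active_labels = build(graph_threshold)
    id_to_label = dict(
        zip(np.concatenate(active_ids).tolist() if active_labels else [], active_labels)
    )

    def graph_of(ids_per_layer: List[np.ndarray], labels: List[str]) -> Graph:
        eidx = _layer_pair_edges(ids_per_layer, edge_mode)
        edges = ((id_to_label[int(u)], id_to_label[int(v)]) for u, v in eidx)
        return Graph.from_edges(edges, nodes=labels)

    return FiredPattern(
        fired=frozenset(fired_labels),
        active=frozenset(active_labels),
        pattern_graph=graph_of(fired_ids, fired_labels),
        active_graph=graph_of(active_ids, active_labels),
        edge_mode=edge_mode,
        layer_sizes=list(model.sizes),
        fired_per_layer=[int(a.size) for a in fired_ids],
        active_per_layer=[int(a.size) for a in active_ids],
    )


def cohesion(p: FiredPattern, denominator: str = "both") -> float:
    """Ratio of fired-subgraph edges to above-background edges.

    ``denominator='both'`` (default) counts pairs with *both* endpoints
    active, which keeps the ratio in [0, 1] since fired ⊆ active;
    ``'either'`` counts pairs with at least one active endpoint drawn from
    the full neuron universe.  Returns 0 when the denominator is empty.
    """
    num = p.pattern_graph.n_edges
    if denominator == "both":
        den = p.active_graph.n_edges
    elif denominator == "either":
        den = 0
        L = len(p.layer_sizes)
        for a in range(L):
            bs = range(a + 1, min(a + 2, L)) if p.edge_mode == "adjacent" else range(a + 1, L)
            for b in bs:
                na, nb = p.layer_sizes[a], p.layer_sizes[b]
                aa, ab = p.active_per_layer[a], p.active_per_layer[b]
                den += na * ab + aa * nb - aa * ab
            if p.edge_mode == "all":
                na, aa = p.layer_sizes[a], p.active_per_layer[a]
                den += aa * (aa - 1) // 2 + aa * (na - aa)
    else:
        raise ValueError("denominator must be 'both' or 'either'")
    return num / den if den > 0 else 0.0


# ------------------------------------------------------------------- sweeps


def default_checkpoints(epochs: int = 100) -> List[int]:
    """Epochs 1..10, then every 10th up to ``epochs`` (19 entries at 100)."""
    cps = [e for e in range(1, 11) if e <= epochs]
    cps += [e for e in range(20, epochs + 1, 10)]
    return cps


_ZERO = MeasureVector(0.0, 0.0, 0.0, 0.0)


def epoch_sweep(
    data,
    hyper: Optional[Hyper] = None,
    eval_n: int = 100,
    seed: int = 0,
    epochs: int = 100,
    hidden: Sequence[int] = (80, 40, 20),
    checkpoints: Optional[Sequence[int]] = None,
    edge_mode: str = "cross",
    n_classes: int = 10,
) -> Trajectory:
    """Train for ``epochs`` epochs and profile fired patterns at checkpoints.

    ``data`` is any object with X_train/y_train/X_test/y_test arrays
    (rows flat in [0,1], labels 0..n_classes-1).  At each checkpoint the
    held-out accuracy is recorded and the four measures plus cohesion of
    the fired pattern are averaged over the first ``eval_n`` held-out
    inputs (an empty fired set contributes an all-zero profile).
    """
    hyper = hyper or Hyper()
    checkpoints = sorted(checkpoints) if checkpoints is not None else default_checkpoints(epochs)
    if checkpoints and checkpoints[-1] > epochs:
        raise ValueError("checkpoint beyond final epoch")
    sizes = [np.asarray(data.X_train).shape[1], *hidden, n_classes]
    model = MLP.init(sizes, seed=seed)
    state = AdamState.for_model(model)
    rng = np.random.default_rng(derive_seed_local(seed))
    X_eval = np.asarray(data.X_test, dtype=float)[:eval_n]
    indices, vectors = [], []
    losses = []
    cps = set(checkpoints)
    for epoch in range(1, epochs + 1):
        loss = train_epoch(model, data.X_train, data.y_train, hyper, state, rng)
        if epoch not in cps:
            continue
        acc = model.accuracy(data.X_test, data.y_test)
        per_input = []
        for x in X_eval:
            pat = fired_pattern(model, x, edge_mode=edge_mode)
            if pat.pattern_graph.n_nodes == 0:
                mv = _ZERO
            else:
                mv = measure_vector(pat.pattern_graph)
            per_input.append(
                MeasureVector(
                    mv.avg_degree, mv.avg_pagerank, mv.avg_clustering,
                    mv.avg_triangles, cohesion=cohesion(pat),
                )
            )
        mean = MeasureVector.mean(per_input)
        vectors.append(
            MeasureVector(
                mean.avg_degree, mean.avg_pagerank, mean.avg_clustering,
                mean.avg_triangles, cohesion=mean.cohesion, accuracy=acc,
            )
        )
        indices.append(epoch)
        losses.append(loss)
    return Trajectory.from_measures("epoch", indices, vectors, extras={"loss": losses})


def derive_seed_local(seed: int) -> int:
    return int(np.random.SeedSequence([seed, 0xA5]).generate_state(1)[0] % (2**31))


def trajectory_correlation(t: Trajectory, a: str, b: str) -> float:
    """Pearson correlation of two named per-checkpoint series."""
    return pearson(t.series(a), t.series(b))
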