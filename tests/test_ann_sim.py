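"""Classifier training, fired-pattern extraction and epoch sweeps."""

import numpy as np
import pytest

from netpattern import ann_sim
from netpattern.ann_sim import (
    AdamState,
    FiredPattern,
    Hyper,
    MLP,
    adam_step,
    cohesion,
    default_checkpoints,
    epoch_sweep,
    fired_pattern,
    forward_outputs,
    train_epoch,
    trajectory_correlation,
)
from netpattern.graph_core import Trajectory


def zero_model(sizes=(4, 3, 2)):
    m = MLP.init(sizes, seed=0)
    for W in m.W:
        W[:] = 0.0
    for b in m.b:
        b[:] = 0.0
    return m


class TestAdam:
    def test_single_step_matches_hand_computation(self):
        # one parameter, gradient g: m=(1-b1)g, v=(1-b2)g^2, bias-corrected
        # update = lr * g / (|g| + eps)
        hyper = Hyper(lr=0.1)
        p = np.array([2.0])
        g = np.array([3.0])
        state = AdamState(m=[np.zeros(1)], v=[np.zeros(1)])
        adam_step([p], [g], state, hyper)
        expected = 2.0 - 0.1 * 3.0 / (3.0 + hyper.eps)
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_exactly_zero_gradient_leaves_weights_unchanged(self):
        # saturated softmax: logit gap so large the probabilities are exact
        # one-hot in float64, so the gradient is exactly zero
        m = MLP(sizes=[2, 2], W=[np.array([[500.0, -500.0], [-500.0, 500.0]])],
                b=[np.zeros(2)])
        X = np.array([[1.0, 0.0]])
        y = np.array([0])
        W_before = m.W[0].copy()
        state = AdamState.for_model(m)
        gW, gb = m.gradients(X, y)
        assert np.all(gW[0] == 0.0) and np.all(gb[0] == 0.0)
        adam_step(m.W + m.b, gW + gb, state, Hyper())
        assert np.array_equal(m.W[0], W_before)


class TestForward:
    def test_zero_model_hidden_outputs_are_half(self):
        out = forward_outputs(zero_model(), np.array([0.2, 0.9, 0.0, 0.5]))
        hidden = [v for k, v in out.items() if k.startswith("L1.")]
        assert hidden == [0.5, 0.5, 0.5]
        probs = [v for k, v in out.items() if k.startswith("L2.")]
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_hand_set_toy_weights(self):
        # 2-2-2 net with hand-chosen weights; sigmoid values computed by hand
        m = MLP(sizes=[2, 2, 2],
                W=[np.array([[1.0, -1.0], [2.0, 0.5]]), np.eye(2)],
                b=[np.array([0.5, 0.0]), np.zeros(2)])
        x = np.array([1.0, 0.5])
        out = forward_outputs(m, x)
        # z1 = [1*1 + 2*0.5 + 0.5, -1*1 + 0.5*0.5 + 0] = [2.5, -0.75]
        assert out["L1.0"] == pytest.approx(1 / (1 + np.exp(-2.5)), abs=1e-12)
        assert out["L1.1"] == pytest.approx(1 / (1 + np.exp(0.75)), abs=1e-12)
        assert out["L0.0"] == 1.0 and out["L0.1"] == 0.5

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            zero_model().forward(np.ones((1, 7)))


class TestFiredPattern:
    def test_zero_model_no_hidden_fires(self):
        # hidden outputs are exactly 0.5 and the threshold is strict
        pat = fired_pattern(zero_model(), np.array([0.9, 0.9, 0.9, 0.9]))
        assert not any(v.startswith("L1.") for v in pat.fired)
        assert all(v.startswith("L0.") for v in pat.fired)

    def test_fired_subset_of_active_across_random_models(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            m = MLP.init([6, 5, 4, 3], seed=trial)
            for W in m.W:
                W += rng.normal(0, 1.0, W.shape)
            x = rng.random(6)
            pat = fired_pattern(m, x)
            assert pat.fired <= pat.active
            assert pat.pattern_graph.nodes == pat.fired

    def test_cross_layer_edges_hand_enumerated(self):
        # toy where every neuron fires: inputs 0.9/0.6, hidden both >0.5,
        # outputs 0.8/0.2 -> fired = 2 inputs + 2 hidden + 1 output
        m = MLP(sizes=[2, 2, 2],
                W=[np.full((2, 2), 2.0), np.array([[2.0, 0.0], [2.0, 0.0]])],
                b=[np.zeros(2), np.zeros(2)])
        x = np.array([0.9, 0.6])
        out = forward_outputs(m, x)
        assert out["L2.0"] > 0.5 > out["L2.1"]
        pat = fired_pattern(m, x, edge_mode="cross")
        assert len(pat.fired) == 5
        # cross-layer pairs: 2*2 (in-hid) + 2*1 (in-out) + 2*1 (hid-out) = 8
        assert pat.pattern_graph.n_edges == 8

    def test_adjacent_mode_is_triangle_free_cross_is_not(self):
        m = MLP(sizes=[2, 2, 2],
                W=[np.full((2, 2), 2.0), np.array([[2.0, 0.0], [2.0, 0.0]])],
                b=[np.zeros(2), np.zeros(2)])
        x = np.array([0.9, 0.6])
        from netpattern.graph_core import average_triangles

        adj = fired_pattern(m, x, edge_mode="adjacent").pattern_graph
        cross = fired_pattern(m, x, edge_mode="cross").pattern_graph
        assert average_triangles(adj) == 0.0
        assert average_triangles(cross) > 0.0

    def test_unknown_edge_mode(self):
        with pytest.raises(ValueError):
            fired_pattern(zero_model(), np.zeros(4), edge_mode="bogus")


class TestCohesion:
    def _pattern(self, fired_layers, active_layers, sizes):
        """Build a FiredPattern directly from per-layer id lists."""
        from netpattern.ann_sim import _layer_pair_edges, neuron_id
        from netpattern.graph_core import Graph

        def graph(layers):
            offsets = np.concatenate([[0], np.cumsum(sizes)])
            ids = [np.asarray(l, dtype=np.int64) + offsets[i] for i, l in enumerate(layers)]
            labels = [neuron_id(i, j) for i, l in enumerate(layers) for j in l]
            lab = {int(v): neuron_id(i, j)
                   for i, l in enumerate(layers) for j, v in zip(l, np.asarray(l) + offsets[i])}
            eidx = _layer_pair_edges(ids, "cross")
            return Graph.from_edges(((lab[int(u)], lab[int(v)]) for u, v in eidx), nodes=labels)

        return FiredPattern(
            fired=frozenset(graph(fired_layers).node_list),
            active=frozenset(graph(active_layers).node_list),
            pattern_graph=graph(fired_layers),
            active_graph=graph(active_layers),
            edge_mode="cross",
            layer_sizes=list(sizes),
            fired_per_layer=[len(l) for l in fired_layers],
            active_per_layer=[len(l) for l in active_layers],
        )

    def test_active_equals_fired_gives_one(self):
        p = self._pattern([[0], [0, 1], [0]], [[0], [0, 1], [0]], [2, 2, 2])
        assert cohesion(p) == 1.0

    def test_empty_fired_gives_zero(self):
        p = self._pattern([[], [], []], [[0], [0], [0]], [2, 2, 2])
        assert cohesion(p) == 0.0

    def test_one_active_only_neuron_hand_ratio(self):
        # fired: 1 input + 1 hidden; active adds a second hidden neuron
        p = self._pattern([[0], [0], []], [[0], [0, 1], []], [2, 2, 2])
        # fired cross edges: 1; active cross edges: input-h0, input-h1 = 2
        assert cohesion(p) == pytest.approx(0.5)

    def test_either_denominator_counts_full_universe(self):
        p = self._pattern([[0], [0], []], [[0], [0, 1], []], [2, 2, 2])
        # layer pairs (0,1),(0,2),(1,2): pairs with >=1 active endpoint:
        # (0,1): 2*2+1*2-1*2=4; (0,2): 0+1*2-0=2; (1,2): 0+2*2-0=4 -> 10
        assert cohesion(p, denominator="either") == pytest.approx(1 / 10)

    def test_bounds_on_random_models(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            m = MLP.init([5, 4, 3], seed=trial)
            for W in m.W:
                W += rng.normal(0, 1.5, W.shape)
            c = cohesion(fired_pattern(m, rng.random(5)))
            assert 0.0 <= c <= 1.0


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        from netpattern.synthetic_data import SynthImageConfig, make_images

        data = make_images(SynthImageConfig(side=8, n_train=300, n_test=60, noise_sd=0.1, seed=4))
        model = MLP.init([64, 20, 10], seed=0)
        state = AdamState.for_model(model)
        rng = np.random.default_rng(0)
        losses = [train_epoch(model, data.X_train, data.y_train, Hyper(), state, rng)
                  for _ in range(12)]
        assert losses[-1] < losses[0]
        assert model.accuracy(data.X_train, data.y_train) > 0.8

    def test_dataset_shape_validation(self):
        model = MLP.init([4, 3, 2], seed=0)
        with pytest.raises(ValueError):
            train_epoch(model, np.ones((5, 3)), np.zeros(5, dtype=int),
                        Hyper(), AdamState.for_model(model), np.random.default_rng(0))


class TestEpochSweep:
    def test_default_checkpoint_schedule(self):
        cps = default_checkpoints(100)
        assert cps == list(range(1, 11)) + list(range(20, 101, 10))
        assert len(cps) == 19

    def test_sweep_records_checkpoints_and_optional_columns(self, desk_dataset):
        traj = epoch_sweep(desk_dataset, eval_n=10, seed=0, epochs=3,
                           hidden=(12, 8), checkpoints=[1, 3])
        assert list(traj.series("epoch")) == [1, 3]
        for col in ("accuracy", "cohesion", "avg_degree", "avg_triangles"):
            assert col in traj.frame.columns

    def test_checkpoint_beyond_epochs_rejected(self, desk_dataset):
        with pytest.raises(ValueError):
            epoch_sweep(desk_dataset, epochs=2, checkpoints=[5])


class TestTrajectoryCorrelation:
    def _traj(self, a, b):
        import pandas as pd

        return Trajectory("i", pd.DataFrame({"i": range(len(a)), "a": a, "b": b}))

    def test_self_negation_and_hand_value(self):
        t = self._traj([1.0, 2.0, 4.0], [-1.0, -2.0, -4.0])
        assert trajectory_correlation(t, "a", "a") == pytest.approx(1.0)
        assert trajectory_correlation(t, "a", "b") == pytest.approx(-1.0)
        # closed form for ([1,2,4],[1,3,2]): r = 3/sqrt(84)
        t2 = self._traj([1.0, 2.0, 4.0], [1.0, 3.0, 2.0])
        assert trajectory_correlation(t2, "a", "b") == pytest.approx(3 / np.sqrt(84))
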