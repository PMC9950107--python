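import numpy as np
import pytest
from scipy.special import expit

from hinlpi.hin2vec import (
    ModelParams,
    TrainConfig,
    f01,
    forward_prob,
    init_params,
    node_embeddings,
    sgd_step,
    train,
    tuple_log_objective,
)
from hinlpi.io_formats import read_embeddings, write_embeddings
from hinlpi.metapath import (
    RelationSet,
    TrainingTuple,
    enumerate_relations,
    random_walks,
    walks_to_tuples,
)


def tiny_params(n_nodes=3, n_rel=2, d=4, seed=0):
    rng = np.random.default_rng(seed)
    rels = RelationSet(tuple(("L",) * (i + 2) for i in range(n_rel)))
    return ModelParams(
        rng.standard_normal((n_nodes, d)),
        rng.standard_normal((n_nodes, d)),
        rng.standard_normal((n_rel, d)),
        [f"v{i}" for i in range(n_nodes)],
        rels,
    )


class TestF01:
    def test_zero_maps_to_half(self):
        assert np.allclose(f01(np.zeros(5)), 0.5)

    def test_range_open_unit_interval(self):
        # within float64 resolution of the sigmoid (|v| < ~36)
        v = np.array([-30.0, -1.0, 0.3, 30.0])
        out = f01(v)
        assert np.all((out > 0) & (out < 1))

    def test_reflection_identity(self):
        v = np.linspace(-5, 5, 11)
        assert np.allclose(f01(v) + f01(-v), 1.0)


class TestForwardProb:
    def test_zero_source_gives_half(self):
        p = tiny_params()
        p.WM[0] = 0.0
        assert forward_prob(p, "v0", "v1", 0) == pytest.approx(0.5)

    def test_hand_evaluated_d1(self):
        rels = RelationSet((("L", "L"),))
        p = ModelParams(
            np.array([[2.0]]), np.array([[1.0]]), np.array([[0.0]]),
            ["a"], rels,
        )
        # sigmoid(2 * 1 * sigmoid(0)) = sigmoid(1)
        assert forward_prob(p, "a", "a", 0) == pytest.approx(expit(1.0), abs=1e-12)

    def test_output_in_open_interval(self):
        p = tiny_params(seed=3)
        for r in range(2):
            assert 0 < forward_prob(p, "v0", "v2", r) < 1

    def test_bad_relation_index(self):
        with pytest.raises(IndexError):
            forward_prob(tiny_params(), "v0", "v1", 9)

    def test_invariant_under_coordinate_permutation(self):
        p = tiny_params(seed=5)
        perm = np.array([2, 0, 3, 1])
        q = ModelParams(
            p.WM[:, perm], p.WN[:, perm], p.WR[:, perm],
            list(p.node_ids), p.relation_set,
        )
        assert forward_prob(p, "v0", "v1", 1) == pytest.approx(
            forward_prob(q, "v0", "v1", 1)
        )


class TestTupleLogObjective:
    def test_half_probability_positive(self):
        p = tiny_params()
        p.WM[0] = 0.0
        t = TrainingTuple("v0", "v1", (1, 0), 1)
        assert tuple_log_objective(p, t) == pytest.approx(np.log(0.5))

    def test_always_non_positive(self):
        p = tiny_params(seed=9)
        for label in (0, 1):
            t = TrainingTuple("v0", "v2", (0, 1), label)
            assert tuple_log_objective(p, t) <= 0

    def test_multi_hot_additivity(self):
        p = tiny_params(seed=2)
        both = TrainingTuple("v0", "v1", (1, 1), 1)
        first = TrainingTuple("v0", "v1", (1, 0), 1)
        second = TrainingTuple("v0", "v1", (0, 1), 1)
        assert tuple_log_objective(p, both) == pytest.approx(
            tuple_log_objective(p, first) + tuple_log_objective(p, second)
        )

    def test_saturation_clipped_finite(self):
        rels = RelationSet((("L", "L"),))
        p = ModelParams(
            np.array([[1e4]]), np.array([[1e4]]), np.array([[1e4]]),
            ["a"], rels,
        )
        t = TrainingTuple("a", "a", (1,), 0)
        assert np.isfinite(tuple_log_objective(p, t))


def numerical_gradient(params, tup, row_getter, row_setter, h=1e-6):
    row = row_getter(params).copy()
    grad = np.zeros_like(row)
    for k in range(len(row)):
        for sign in (+1, -1):
            bumped = row.copy()
            bumped[k] += sign * h
            row_setter(params, bumped)
            val = tuple_log_objective(params, tup)
            grad[k] += sign * val / (2 * h)
        row_setter(params, row)
    return grad


class TestSgdStep:
    @pytest.mark.parametrize("seed", range(100))
    def test_analytic_matches_numerical_gradient(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(1, 9))
        n_rel = int(rng.integers(1, 4))
        p = tiny_params(n_nodes=4, n_rel=n_rel, d=d, seed=seed)
        m, n = "v0", f"v{rng.integers(1, 4)}"
        label = int(rng.integers(0, 2))
        if label == 1 and n_rel > 1:
            y = tuple(int(b) for b in rng.integers(0, 2, n_rel))
            if not any(y):
                y = (1,) + (0,) * (n_rel - 1)
        else:
            r = int(rng.integers(n_rel))
            y = tuple(1 if i == r else 0 for i in range(n_rel))
        tup = TrainingTuple(m, n, y, label)
        mi, ni = p.node_index[m], p.node_index[n]

        before = p.copy()
        lr = 0.37
        sgd_step(p, tup, lr)
        analytic_m = (p.WM[mi] - before.WM[mi]) / lr
        analytic_n = (p.WN[ni] - before.WN[ni]) / lr

        num_m = numerical_gradient(
            before.copy(), tup,
            lambda q: q.WM[mi], lambda q, v: q.WM.__setitem__(mi, v),
        )
        num_n = numerical_gradient(
            before.copy(), tup,
            lambda q: q.WN[ni], lambda q, v: q.WN.__setitem__(ni, v),
        )
        assert np.allclose(analytic_m, num_m, rtol=1e-6, atol=1e-9)
        assert np.allclose(analytic_n, num_n, rtol=1e-6, atol=1e-9)
        for r in tup.relation_indices:
            analytic_r = (p.WR[r] - before.WR[r]) / lr
            num_r = numerical_gradient(
                before.copy(), tup,
                lambda q: q.WR[r], lambda q, v: q.WR.__setitem__(r, v),
            )
            assert np.allclose(analytic_r, num_r, rtol=1e-6, atol=1e-9)

    def test_untouched_rows_bit_identical(self):
        p = tiny_params(n_nodes=4, seed=1)
        before = p.copy()
        sgd_step(p, TrainingTuple("v0", "v1", (1, 0), 1), 0.1)
        assert np.array_equal(p.WM[2:], before.WM[2:])
        assert np.array_equal(p.WN[0], before.WN[0])
        assert np.array_equal(p.WN[2:], before.WN[2:])
        assert np.array_equal(p.WR[1], before.WR[1])

    def test_repeated_ascent_drives_probability_up(self):
        rng = np.random.default_rng(0)
        rels = RelationSet((("L", "L"),))
        p = ModelParams(
            rng.uniform(-0.125, 0.125, (2, 4)),
            rng.uniform(-0.125, 0.125, (2, 4)),
            rng.uniform(-0.125, 0.125, (1, 4)),
            ["a", "b"], rels,
        )
        tup = TrainingTuple("a", "b", (1,), 1)
        probs = []
        for _ in range(500):
            probs.append(forward_prob(p, "a", "b", 0))
            sgd_step(p, tup, 0.5)
        assert forward_prob(p, "a", "b", 0) > 0.99
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


class TestTrain:
    def toy_tuples(self, toy_net, toy_relations):
        walks = random_walks(toy_net, 5, 20, seed=0)
        return walks_to_tuples(walks, toy_net, toy_relations, 2, 2, seed=0)

    def test_deterministic_under_seed(self, toy_net, toy_relations):
        tuples = self.toy_tuples(toy_net, toy_relations)
        cfg = TrainConfig(d=8, epochs=2, seed=11)
        p1, t1 = train(toy_net, toy_relations, tuples, cfg)
        p2, t2 = train(toy_net, toy_relations, tuples, cfg)
        assert np.array_equal(p1.WM, p2.WM)
        assert np.array_equal(p1.WN, p2.WN)
        assert np.array_equal(p1.WR, p2.WR)
        assert t1 == t2

    def test_objective_improves_over_epochs(self, toy_net, toy_relations):
        tuples = self.toy_tuples(toy_net, toy_relations)
        _, trace = train(toy_net, toy_relations, tuples, TrainConfig(d=8, epochs=5))
        assert trace[-1] >= trace[0]
        assert all(v <= 0 for v in trace)

    def test_empty_tuples_rejected(self, toy_net, toy_relations):
        with pytest.raises(ValueError):
            train(toy_net, toy_relations, [], TrainConfig())

    def test_two_community_separation(self):
        from conftest import build_network

        # two L-communities bridged weakly; embeddings should cluster
        types = {f"A{i}": "L" for i in range(4)}
        types.update({f"B{i}": "L" for i in range(4)})
        edges = [
            (a, b)
            for grp in ("A", "B")
            for i, a in enumerate(f"{grp}{k}" for k in range(4))
            for b in [f"{grp}{j}" for j in range(i + 1, 4)]
        ]
        edges.append(("A0", "B0"))
        net = build_network(types, edges)
        from hinlpi.metapath import enumerate_relations

        rels = enumerate_relations(("L",), 2, net.present_edge_types())
        walks = random_walks(net, 20, 30, seed=0)
        tuples = walks_to_tuples(walks, net, rels, 2, 3, seed=0)
        params, _ = train(net, rels, tuples, TrainConfig(d=2, epochs=3, seed=0))
        emb = node_embeddings(params)

        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

        ids = emb.ids
        within, between = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                sim = cos(emb.vector(a), emb.vector(b))
                (within if a[0] == b[0] else between).append(sim)
        assert np.mean(within) > np.mean(between)


class TestNodeEmbeddings:
    def test_size_and_roundtrip(self, toy_net, toy_relations, tmp_path):
        cfg = TrainConfig(d=4, epochs=1)
        params = init_params(toy_net.nodes(), toy_relations, cfg)
        emb = node_embeddings(params)
        assert len(emb) == toy_net.num_nodes
        write_embeddings(emb, tmp_path / "e.txt")
        assert read_embeddings(tmp_path / "e.txt") == emb

    def test_pure_read(self, toy_net, toy_relations):
        params = init_params(toy_net.nodes(), toy_relations, TrainConfig(d=4))
        e1 = node_embeddings(params)
        e2 = node_embeddings(params)
        assert e1 == e2

    def test_export_switches(self, toy_net, toy_relations):
        params = init_params(toy_net.nodes(), toy_relations, TrainConfig(d=4))
        wm = node_embeddings(params, "WM")
        wn = node_embeddings(params, "WN")
        mean = node_embeddings(params, "mean")
        assert np.allclose((wm.vectors + wn.vectors) / 2, mean.vectors)
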