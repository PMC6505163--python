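import math

import numpy as np
import pytest

from gpmix import (
    NetworkConfig,
    NetworkWeights,
    PhenotypeTable,
    PredictionBundle,
    TraitSpec,
    compute_total_loss,
    encode_targets,
    forward_pass,
    predict_traits,
    standardize_continuous,
    train_network,
)
from gpmix.errors import ValidationError
from gpmix.network import initialize_weights

MIXED_SPECS = [
    TraitSpec("cont", "continuous"),
    TraitSpec("bin", "binary"),
    TraitSpec("ord", "ordinal", 3),
]


def make_table(cont, bin_, ord_):
    n = len(cont)
    return PhenotypeTable(
        [f"L{i}" for i in range(n)],
        ["E1"] * n,
        {
            "cont": np.asarray(cont, dtype=float),
            "bin": np.asarray(bin_, dtype=float),
            "ord": np.asarray(ord_, dtype=float),
        },
        MIXED_SPECS,
    )


class TestEncodeTargets:
    def test_binary_labels_to_zero_one(self):
        table = make_table([0, 0, 0], [1, 2, 2], [1, 1, 1])
        targets = encode_targets(table, MIXED_SPECS)
        np.testing.assert_array_equal(targets["bin"], [0.0, 1.0, 1.0])

    def test_ordinal_label_to_indicator(self):
        table = make_table([0], [1], [2])
        targets = encode_targets(table, MIXED_SPECS)
        np.testing.assert_array_equal(targets["ord"], [[0.0, 1.0, 0.0]])

    def test_continuous_passes_through(self):
        table = make_table([1.5, -2.0], [1, 1], [1, 3])
        targets = encode_targets(table, MIXED_SPECS)
        np.testing.assert_array_equal(targets["cont"], [1.5, -2.0])

    def test_missing_value_rejected(self):
        table = make_table([np.nan], [1], [1])
        with pytest.raises(ValidationError, match="cont"):
            encode_targets(table, MIXED_SPECS)


class TestStandardizeContinuous:
    def test_train_standardization(self):
        std, mean, sd = standardize_continuous(np.array([1.0, 3.0]))
        assert (mean, sd) == (2.0, pytest.approx(math.sqrt(2)))
        np.testing.assert_allclose(std, [-math.sqrt(2) / 2, math.sqrt(2) / 2])
        assert std.mean() == pytest.approx(0.0)
        assert std.std(ddof=1) == pytest.approx(1.0)

    def test_apply_to_new_values_uses_train_stats(self):
        std, _, _ = standardize_continuous(np.array([1.0, 3.0]), np.array([4.0]))
        assert std[0] == pytest.approx(1.41421356, abs=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            standardize_continuous(np.array([5.0, 5.0, 5.0]))


def hand_weights():
    """3 inputs -> 2 hidden units -> three heads, fixed hand-set weights."""
    W1 = np.array([[0.5, -1.0], [1.0, 0.25], [-0.5, 0.75]])
    b1 = np.array([0.1, -0.2])
    heads = {
        "cont": (np.array([[1.0], [-0.5]]), np.array([0.05])),
        "bin": (np.array([[0.3], [0.8]]), np.array([-0.1])),
        "ord": (
            np.array([[0.2, -0.4, 0.6], [-0.3, 0.5, 0.1]]),
            np.array([0.0, 0.1, -0.1]),
        ),
    }
    return NetworkWeights([(W1, b1)], heads)


def oracle_forward(X, weights, specs):
    """Straight-line nested-sum forward pass (scalar loops, no linear algebra)."""
    outs = {s.name: [] for s in specs}
    for row in X:
        hidden_in = weights.hidden[0]
        V = []
        for j in range(hidden_in[0].shape[1]):
            h = sum(hidden_in[0][p, j] * row[p] for p in range(len(row)))
            h += hidden_in[1][j]
            V.append(max(h, 0.0))
        for s in specs:
            W, b = weights.heads[s.name]
            nets = []
            for t in range(W.shape[1]):
                nets.append(sum(W[k, t] * V[k] for k in range(len(V))) + b[t])
            if s.kind == "continuous":
                outs[s.name].append(max(nets[0], 0.0))
            elif s.kind == "binary":
                outs[s.name].append(1.0 / (1.0 + math.exp(-nets[0])))
            else:
                exps = [math.exp(v) for v in nets]
                total = sum(exps)
                outs[s.name].append([e / total for e in exps])
    return {k: np.array(v) for k, v in outs.items()}


class TestForwardPass:
    def test_relu_zeroes_negatives(self):
        weights = NetworkWeights(
            [(np.eye(2), np.zeros(2))],
            {"cont": (np.eye(2)[:, :1], np.zeros(1)),
             "bin": (np.zeros((2, 1)), np.zeros(1)),
             "ord": (np.zeros((2, 3)), np.zeros(3))},
        )
        bundle = forward_pass(np.array([[1.0, -1.0]]), weights, MIXED_SPECS)
        # hidden output is [1, 0]; identity head column picks the first unit
        assert bundle.outputs["cont"][0] == 1.0

    def test_sigmoid_at_zero_is_half(self):
        weights = hand_weights()
        weights.heads["bin"] = (np.zeros((2, 1)), np.zeros(1))
        bundle = forward_pass(np.array([[0.3, 0.7, -0.2]]), weights, MIXED_SPECS)
        assert bundle.outputs["bin"][0] == pytest.approx(0.5, abs=1e-15)

    def test_softmax_uniform_for_equal_logits(self):
        weights = hand_weights()
        weights.heads["ord"] = (np.zeros((2, 3)), np.zeros(3))
        bundle = forward_pass(np.array([[0.3, 0.7, -0.2]]), weights, MIXED_SPECS)
        np.testing.assert_allclose(bundle.outputs["ord"][0], [1 / 3] * 3, atol=1e-15)

    def test_matches_nested_sum_oracle(self):
        rng = np.random.default_rng(77)
        X = rng.normal(size=(5, 3))
        weights = hand_weights()
        bundle = forward_pass(X, weights, MIXED_SPECS)
        oracle = oracle_forward(X, weights, MIXED_SPECS)
        for name in oracle:
            np.testing.assert_allclose(bundle.outputs[name], oracle[name], atol=1e-10)

    def test_deterministic_without_dropout(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 3))
        weights = hand_weights()
        a = forward_pass(X, weights, MIXED_SPECS)
        b = forward_pass(X, weights, MIXED_SPECS)
        for name in a.outputs:
            np.testing.assert_array_equal(a.outputs[name], b.outputs[name])

    def test_probability_invariants(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 3)) * 3
        bundle = forward_pass(X, hand_weights(), MIXED_SPECS)
        bundle.validate(MIXED_SPECS)
        assert np.abs(bundle.outputs["ord"].sum(axis=1) - 1.0).max() < 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="features"):
            forward_pass(np.zeros((2, 5)), hand_weights(), MIXED_SPECS)


class TestTotalLoss:
    def test_perfect_continuous_is_zero(self):
        preds = PredictionBundle({"cont": np.array([1.0, 2.0])})
        specs = [TraitSpec("cont", "continuous")]
        assert compute_total_loss(preds, {"cont": np.array([1.0, 2.0])}, specs) == 0.0

    def test_perfect_ordinal_is_tiny(self):
        target = np.array([[0.0, 1.0, 0.0]])
        preds = PredictionBundle({"ord": target.copy()})
        specs = [TraitSpec("ord", "ordinal", 3)]
        assert compute_total_loss(preds, {"ord": target}, specs) <= 1e-6

    def test_hand_summed_mixed_loss(self):
        specs = [TraitSpec("cont", "continuous"), TraitSpec("bin", "binary")]
        preds = PredictionBundle(
            {"cont": np.array([2.0, 1.0]), "bin": np.array([0.5, 0.5])}
        )
        targets = {"cont": np.array([1.0, 2.0]), "bin": np.array([0.0, 1.0])}
        total = compute_total_loss(preds, targets, specs)
        assert total == pytest.approx(1.0 + math.log(2.0), abs=1e-9)


class TestTraining:
    def test_zero_epochs_returns_initialization_bit_for_bit(self):
        config = NetworkConfig(units=4, epochs=0, seed=9)
        X = np.random.default_rng(0).normal(size=(6, 3))
        table = make_table([0.1] * 6, [1, 2] * 3, [1, 2, 3] * 2)
        targets = encode_targets(table, MIXED_SPECS)
        init = initialize_weights(3, MIXED_SPECS, config)
        weights, trace = train_network(X, targets, config, MIXED_SPECS)
        assert trace["train"] == []
        for (W1, b1), (W2, b2) in zip(init.hidden, weights.hidden):
            np.testing.assert_array_equal(W1, W2)
            np.testing.assert_array_equal(b1, b2)
        for name in init.heads:
            np.testing.assert_array_equal(init.heads[name][0], weights.heads[name][0])

    def test_separable_binary_toy_improves(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 0.3, size=(10, 2)), rng.normal(2, 0.3, size=(10, 2))])
        specs = [TraitSpec("bin", "binary")]
        targets = {"bin": np.array([0.0] * 10 + [1.0] * 10)}
        config = NetworkConfig(units=8, epochs=200, dropout_rate=0.0, seed=1)
        _, trace = train_network(X, targets, config, specs)
        assert trace["train"][-1] < trace["train"][0]
        assert len(trace["train"]) == 200

    def test_continuous_toy_memorizes(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 3))
        y = np.abs(rng.normal(size=8))  # ReLU head needs non-negative targets
        specs = [TraitSpec("cont", "continuous")]
        config = NetworkConfig(units=32, epochs=500, dropout_rate=0.0,
                               learning_rate=0.01, seed=2)
        _, trace = train_network(X, {"cont": y}, config, specs)
        assert trace["train"][-1] < 0.01

    def test_seeded_training_is_reproducible(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 3))
        table = make_table(rng.normal(size=12), [1, 2] * 6, [1, 2, 3] * 4)
        targets = encode_targets(table, MIXED_SPECS)
        config = NetworkConfig(units=6, epochs=20, dropout_rate=0.3, seed=42)
        _, trace_a = train_network(X, targets, config, MIXED_SPECS)
        _, trace_b = train_network(X, targets, config, MIXED_SPECS)
        assert trace_a["train"] == trace_b["train"]

    def test_exploding_loss_reports_learning_rate(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 2)) * 1e200
        specs = [TraitSpec("cont", "continuous")]
        targets = {"cont": rng.normal(size=8) * 1e200}
        config = NetworkConfig(units=4, epochs=3, dropout_rate=0.0, seed=0)
        with pytest.raises(ValidationError, match="learning rate"):
            train_network(X, targets, config, specs)


class TestPredictTraits:
    def test_decoding_rules(self):
        weights = hand_weights()
        rng = np.random.default_rng(10)
        X = rng.normal(size=(4, 3))
        bundle, decoded = predict_traits(
            X, weights, MIXED_SPECS, standardization={"cont": (2.0, math.sqrt(2))}
        )
        # ordinal decodes by arg-max
        np.testing.assert_array_equal(
            decoded["ord"], bundle.outputs["ord"].argmax(axis=1) + 1
        )
        # binary threshold at 0.5 maps to upper category
        np.testing.assert_array_equal(
            decoded["bin"], np.where(bundle.outputs["bin"] >= 0.5, 2, 1)
        )

    def test_binary_exact_half_goes_to_category_two(self):
        weights = hand_weights()
        weights.heads["bin"] = (np.zeros((2, 1)), np.zeros(1))
        _, decoded = predict_traits(
            np.zeros((1, 3)), weights, MIXED_SPECS,
            standardization={"cont": (0.0, 1.0)},
        )
        assert decoded["bin"][0] == 2

    def test_ordinal_tie_goes_to_lowest_category(self):
        specs = [TraitSpec("ord", "ordinal", 3)]
        weights = NetworkWeights(
            [(np.zeros((2, 2)), np.zeros(2))],
            {"ord": (np.zeros((2, 3)), np.zeros(3))},
        )
        _, decoded = predict_traits(np.zeros((1, 2)), weights, specs)
        assert decoded["ord"][0] == 1

    def test_destandardization_inverts_the_worked_example(self):
        specs = [TraitSpec("cont", "continuous")]
        weights = NetworkWeights(
            [(np.zeros((1, 1)), np.array([1.41421356]))],
            {"cont": (np.ones((1, 1)), np.zeros(1))},
        )
        _, decoded = predict_traits(
            np.zeros((1, 1)), weights, specs,
            standardization={"cont": (2.0, math.sqrt(2.0))},
        )
        assert decoded["cont"][0] == pytest.approx(4.0, abs=1e-6)

    def test_missing_stats_rejected(self):
        specs = [TraitSpec("cont", "continuous")]
        weights = NetworkWeights(
            [(np.zeros((1, 1)), np.zeros(1))], {"cont": (np.ones((1, 1)), np.zeros(1))}
        )
        with pytest.raises(ValidationError, match="standardization"):
            predict_traits(np.zeros((1, 1)), weights, specs)


class TestArchitecture:
    def test_udl_is_single_trait_special_case(self):
        """A one-trait multi-output network equals the univariate network."""
        config = NetworkConfig(units=16, seed=0)
        spec = TraitSpec("cont", "continuous")
        multi = initialize_weights(10, [spec], config)
        uni = initialize_weights(10, [spec], config)
        assert multi.n_parameters == uni.n_parameters
        assert multi.n_parameters == (10 * 16 + 16) + (16 * 1 + 1)
        np.testing.assert_array_equal(multi.heads["cont"][0], uni.heads["cont"][0])

    def test_weight_shapes_chain(self):
        config = NetworkConfig(n_hidden_layers=3, units=7, seed=1)
        weights = initialize_weights(5, MIXED_SPECS, config)
        shapes = [W.shape for W, _ in weights.hidden]
        assert shapes == [(5, 7), (7, 7), (7, 7)]
        assert weights.heads["ord"][0].shape == (7, 3)

    def test_save_load_round_trip_is_bit_identical(self, tmp_path):
        config = NetworkConfig(units=5, seed=3)
        weights = initialize_weights(4, MIXED_SPECS, config)
        path = tmp_path / "weights.npz"
        weights.save(path)
        loaded = NetworkWeights.load(path)
        X = np.random.default_rng(1).normal(size=(6, 4))
        a = forward_pass(X, weights, MIXED_SPECS)
        b = forward_pass(X, loaded, MIXED_SPECS)
        for name in a.outputs:
            np.testing.assert_array_equal(a.outputs[name], b.outputs[name])
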