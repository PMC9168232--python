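import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from joingcla.network import (
    AdamState,
    LayerShapes,
    ModelParameters,
    attention_fuse,
    class_weights,
    encoder_linear,
    gcn_propagate,
    loss_and_gradients,
    model_forward,
    normalize_adjacency,
    omics_head,
    output_probabilities,
    self_attention_fuse,
    weighted_cross_entropy,
)

from oracles import (
    attention_loop,
    gcn_loop,
    linear_relu_loop,
    omics_head_loop,
    self_attention_loop,
    weighted_ce_loop,
)


@pytest.fixture
def small_problem(rng):
    """A 6-scan, 3-omics problem with all operators pre-normalized."""
    p, j, n = 6, 5, 3
    shapes = LayerShapes(4, 4, 4, 2)
    xc = rng.standard_normal((p, j))
    graphs = []
    for _ in range(n + 1):
        a = np.abs(rng.standard_normal((p, p)))
        graphs.append((a + a.T) / 2)
    params = ModelParameters.initialize(j, n, np.random.default_rng(7), shapes)
    return {
        "xc": xc,
        "psg_op": normalize_adjacency(graphs[0]),
        "pog_ops": [normalize_adjacency(g) for g in graphs[1:]],
        "params": params,
        "labels": np.array([0, 1, 0, 1, 1, 0]),
        "shapes": shapes,
    }


class TestEncoderLinear:
    def test_identity_weights_pass_nonnegative_input(self, rng):
        x = np.abs(rng.standard_normal((3, 4)))
        np.testing.assert_array_equal(
            encoder_linear(x, np.eye(4), np.zeros(4)), x
        )

    def test_rectifier_floor(self):
        x = -np.ones((2, 3))
        out = encoder_linear(x, np.eye(3), np.zeros(3))
        np.testing.assert_array_equal(out, np.zeros((2, 3)))

    def test_matches_elementwise_loop(self, rng):
        x = rng.standard_normal((3, 4))
        w = rng.standard_normal((4, 5))
        b = rng.standard_normal(5)
        np.testing.assert_allclose(
            encoder_linear(x, w, b), linear_relu_loop(x, w, b), atol=1e-12
        )

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            encoder_linear(rng.standard_normal((3, 4)),
                           rng.standard_normal((5, 2)), np.zeros(2))


class TestGcnPropagate:
    def test_graphless_limit_is_plain_linear(self, rng):
        h = rng.standard_normal((4, 3))
        w = rng.standard_normal((3, 2))
        out = gcn_propagate(h, np.zeros((4, 4)), w, activation=False)
        np.testing.assert_allclose(out, h @ w, atol=1e-12)

    def test_two_node_hand_computation(self):
        # A = [[0,1],[1,0]]: A+I is all-ones, degrees 2, so propagation
        # averages the two node values: (1+3)/2 = 2 for both
        out = gcn_propagate(
            np.array([[1.0], [3.0]]),
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.array([[1.0]]),
            activation=False,
        )
        np.testing.assert_allclose(out, [[2.0], [2.0]])

    @pytest.mark.parametrize("activation", [True, False])
    def test_matches_dense_loop_oracle(self, rng, activation):
        a = np.abs(rng.standard_normal((5, 5)))
        a = (a + a.T) / 2
        h = rng.standard_normal((5, 3))
        w = rng.standard_normal((3, 4))
        np.testing.assert_allclose(
            gcn_propagate(h, a, w, activation=activation),
            gcn_loop(h, a, w, activation),
            atol=1e-9,
        )

    def test_rejects_negative_weights(self, rng):
        a = -np.ones((3, 3))
        with pytest.raises(ValueError):
            gcn_propagate(rng.standard_normal((3, 2)), a,
                          rng.standard_normal((2, 2)))


class TestOmicsHead:
    def test_nonpositive_input_zero_bias_gives_zero(self, rng):
        h3 = -np.abs(rng.standard_normal((4, 3)))
        out = omics_head(h3, rng.standard_normal((3, 2)), np.zeros(2))
        np.testing.assert_array_equal(out, np.zeros((4, 2)))

    def test_identity_path_for_nonnegative_input(self, rng):
        h3 = np.abs(rng.standard_normal((4, 3)))
        np.testing.assert_array_equal(
            omics_head(h3, np.eye(3), np.zeros(3)), h3
        )

    def test_matches_two_stage_loop(self, rng):
        h3 = rng.standard_normal((5, 4))
        w4 = rng.standard_normal((4, 2))
        b4 = rng.standard_normal(2)
        np.testing.assert_allclose(
            omics_head(h3, w4, b4), omics_head_loop(h3, w4, b4), atol=1e-12
        )

    def test_output_nonnegative(self, rng):
        out = omics_head(rng.standard_normal((6, 5)),
                         rng.standard_normal((5, 3)), rng.standard_normal(3))
        assert (out >= 0).all()


class TestAttentionFuse:
    def test_identical_networks_give_uniform_weights(self, rng):
        h3 = rng.standard_normal((4, 3))
        h4 = np.abs(rng.standard_normal((4, 2)))
        w3c = rng.standard_normal((3, 1))
        w4c = rng.standard_normal((2, 1))
        h5, scores = attention_fuse([h3, h3], [h4, h4], w3c, w4c)
        np.testing.assert_allclose(scores, 0.5)
        np.testing.assert_allclose(h5, (h4 @ w4c) * np.ones((1, 2)), atol=1e-12)

    def test_dominant_key_saturates_softmax(self, rng):
        h3s = [rng.standard_normal((2, 3)) for _ in range(3)]
        h4s = [np.abs(rng.standard_normal((2, 2))) + 0.5 for _ in range(3)]
        w3c = rng.standard_normal((3, 1))
        w4c = rng.standard_normal((2, 1))
        h3s[1] = h3s[1] + 1e6 * np.sign(w3c).ravel()  # key_1 -> +inf
        _, scores = attention_fuse(h3s, h4s, w3c, w4c)
        np.testing.assert_allclose(scores[:, :, 1], 1.0, atol=1e-6)

    def test_matches_scalar_loop_oracle(self, rng):
        h3s = [rng.standard_normal((2, 2)) for _ in range(2)]
        h4s = [np.abs(rng.standard_normal((2, 2))) for _ in range(2)]
        w3c = rng.standard_normal((2, 1))
        w4c = rng.standard_normal((2, 1))
        h5, scores = attention_fuse(h3s, h4s, w3c, w4c)
        h5_ref, scores_ref = attention_loop(h3s, h4s, w3c, w4c)
        np.testing.assert_allclose(h5, h5_ref, atol=1e-9)
        np.testing.assert_allclose(scores, scores_ref, atol=1e-9)

    def test_rows_are_distributions(self, rng):
        h3s = [rng.standard_normal((5, 3)) for _ in range(4)]
        h4s = [rng.standard_normal((5, 2)) for _ in range(4)]
        _, scores = attention_fuse(h3s, h4s, rng.standard_normal((3, 1)),
                                   rng.standard_normal((2, 1)))
        np.testing.assert_allclose(scores.sum(axis=2), 1.0, atol=1e-9)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_fewer_than_two_networks_rejected(self, rng):
        h3 = [rng.standard_normal((2, 2))]
        h4 = [rng.standard_normal((2, 2))]
        with pytest.raises(ValueError, match="reduced"):
            attention_fuse(h3, h4, np.ones((2, 1)), np.ones((2, 1)))


class TestSelfAttentionFuse:
    def test_identical_networks_return_shared_logits(self, rng):
        h4 = rng.standard_normal((4, 3))
        out, _ = self_attention_fuse([h4, h4, h4])
        np.testing.assert_allclose(out, h4, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        h4s = [rng.standard_normal((3, 2)) for _ in range(2)]
        out, _ = self_attention_fuse(h4s)
        np.testing.assert_allclose(out, self_attention_loop(h4s), atol=1e-9)

    def test_permutation_of_networks_invariant(self, rng):
        h4s = [rng.standard_normal((3, 2)) for _ in range(3)]
        a, _ = self_attention_fuse(h4s)
        b, _ = self_attention_fuse([h4s[2], h4s[0], h4s[1]])
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestOutputProbabilities:
    @pytest.mark.parametrize(
        "logits, expected",
        [([0.0, 0.0], [0.5, 0.5]), ([np.log(2), 0.0], [2 / 3, 1 / 3])],
    )
    def test_closed_forms(self, logits, expected):
        np.testing.assert_allclose(
            output_probabilities(np.array([logits]))[0], expected, atol=1e-12
        )

    @given(arrays(float, (4, 3), elements=st.floats(-50, 50)))
    def test_rows_normalize(self, logits):
        probs = output_probabilities(logits)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()


class TestClassWeights:
    def test_balanced_classes(self):
        np.testing.assert_allclose(class_weights([0, 1, 0, 1]), [0.5, 0.5])

    def test_paired_cohort_counts(self):
        # 351 majority / 25 minority: w_major = 1 - 351/376, w_minor = 1 - 25/376
        labels = np.array([1] * 351 + [0] * 25)
        w = class_weights(labels)
        assert w[1] == pytest.approx(1 - 351 / 376)
        assert w[1] == pytest.approx(0.0665, abs=5e-4)
        assert w[0] == pytest.approx(0.9335, abs=5e-4)

    @given(st.integers(1, 50), st.integers(1, 50))
    def test_binary_weights_sum_to_one(self, a, b):
        labels = np.array([0] * a + [1] * b)
        assert class_weights(labels).sum() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestWeightedCrossEntropy:
    def test_perfect_predictions_zero_limit(self):
        loss = weighted_cross_entropy([1.0, 0.0, 1.0], [1, 0, 1], [0.5, 0.5])
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_half_weights_halve_standard_bce(self, rng):
        y = rng.uniform(0.05, 0.95, 10)
        labels = rng.integers(0, 2, 10)
        bce = -(labels * np.log(y) + (1 - labels) * np.log(1 - y)).mean()
        got = weighted_cross_entropy(y, labels, [0.5, 0.5])
        assert got == pytest.approx(0.5 * bce)

    def test_matches_per_sample_loop(self, rng):
        y = rng.uniform(0.01, 0.99, 12)
        labels = rng.integers(0, 2, 12)
        w = [0.9335, 0.0665]
        assert weighted_cross_entropy(y, labels, w) == pytest.approx(
            weighted_ce_loop(y, labels, w)
        )

    def test_nonnegative(self, rng):
        y = rng.uniform(0, 1, 20)
        labels = rng.integers(0, 2, 20)
        assert weighted_cross_entropy(y, labels, [0.3, 0.7]) >= 0.0


class TestModelForward:
    def test_reduced_architectures_bypass_attention(self, small_problem):
        sp = small_problem
        for n in (0, 1):
            params = ModelParameters.initialize(
                sp["xc"].shape[1], n, np.random.default_rng(3), sp["shapes"]
            )
            trace = model_forward(sp["xc"], sp["psg_op"], sp["pog_ops"][:n], params)
            assert trace.attention_scores is None
            np.testing.assert_allclose(
                trace.class_probabilities.sum(axis=1), 1.0, atol=1e-12
            )

    def test_single_omics_softmaxes_head_logits(self, small_problem):
        sp = small_problem
        params = ModelParameters.initialize(
            sp["xc"].shape[1], 1, np.random.default_rng(3), sp["shapes"]
        )
        trace = model_forward(sp["xc"], sp["psg_op"], sp["pog_ops"][:1], params)
        np.testing.assert_allclose(trace.H5, trace.H4[0])

    def test_eval_forward_bitwise_reproducible(self, small_problem):
        sp = small_problem
        a = model_forward(sp["xc"], sp["psg_op"], sp["pog_ops"], sp["params"])
        b = model_forward(sp["xc"], sp["psg_op"], sp["pog_ops"], sp["params"])
        np.testing.assert_array_equal(
            a.class_probabilities, b.class_probabilities
        )

    def test_permutation_equivariance(self, small_problem, rng):
        sp = small_problem
        perm = rng.permutation(6)
        a = model_forward(sp["xc"], sp["psg_op"], sp["pog_ops"], sp["params"])
        pm = np.ix_(perm, perm)
        b = model_forward(
            sp["xc"][perm],
            sp["psg_op"][pm],
            [g[pm] for g in sp["pog_ops"]],
            sp["params"],
        )
        np.testing.assert_allclose(b.H5, a.H5[perm], atol=1e-9)

    def test_graphless_limit_equals_mlp(self, small_problem):
        # zero adjacency everywhere: the normalized operators become the
        # identity and the model collapses to a per-sample feed-forward net
        sp = small_problem
        p = sp["xc"].shape[0]
        eye_op = normalize_adjacency(np.zeros((p, p)))
        trace = model_forward(sp["xc"], eye_op, [eye_op] * 3, sp["params"])
        params = sp["params"]
        h1 = np.maximum(sp["xc"] @ params["W1"] + params["b1"], 0)
        h2 = np.maximum(h1 @ params["W2"], 0)
        h3s = [h2 @ params[f"W3_{n}"] for n in range(3)]
        h4s = [
            np.maximum(np.maximum(h3, 0) @ params[f"W4_{n}"] + params[f"b4_{n}"], 0)
            for n, h3 in enumerate(h3s)
        ]
        h5, _ = attention_fuse(h3s, h4s, params["W3c"], params["W4c"])
        np.testing.assert_allclose(trace.H5, h5, atol=1e-9)

    def test_dropout_off_at_evaluation(self, small_problem):
        sp = small_problem
        a = model_forward(sp["xc"], sp["psg_op"], sp["pog_ops"], sp["params"],
                          dropout_rate=0.5, training=False)
        b = model_forward(sp["xc"], sp["psg_op"], sp["pog_ops"], sp["params"])
        np.testing.assert_array_equal(a.H5, b.H5)


class TestGradients:
    @pytest.mark.parametrize(
        "variant, n_omics",
        [("joingcla", 0), ("joingcla", 1), ("joingcla", 3),
         ("self_attention", 3)],
    )
    def test_gradients_match_central_differences(self, small_problem, variant,
                                                 n_omics):
        sp = small_problem
        params = ModelParameters.initialize(
            sp["xc"].shape[1], n_omics, np.random.default_rng(11),
            sp["shapes"], variant,
        )
        ops = sp["pog_ops"][:n_omics]
        labels = sp["labels"]
        mask = np.array([True, True, True, True, False, True])
        w = class_weights(labels[mask])

        def loss_at(p):
            tr = model_forward(sp["xc"], sp["psg_op"], ops, p)
            return loss_and_gradients(
                tr, sp["xc"], sp["psg_op"], ops, p, labels, mask, w
            )[0]

        trace = model_forward(sp["xc"], sp["psg_op"], ops, params)
        _, grads = loss_and_gradients(
            trace, sp["xc"], sp["psg_op"], ops, params, labels, mask, w
        )
        eps = 1e-6
        for key in params.keys():
            numeric = np.zeros_like(grads[key])
            it = np.nditer(numeric, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                p2 = params.copy()
                p2[key][i] += eps
                up = loss_at(p2)
                p2[key][i] -= 2 * eps
                down = loss_at(p2)
                numeric[i] = (up - down) / (2 * eps)
            np.testing.assert_allclose(grads[key], numeric, atol=1e-7,
                                       err_msg=f"{variant}/{n_omics}/{key}")

    def test_sample_multiplicity_equals_materialized_duplicates(
        self, small_problem
    ):
        # doubling a sample's loss multiplicity must equal feeding the loss
        # its term twice: compare against an explicit two-mask average
        sp = small_problem
        params = sp["params"]
        labels = sp["labels"]
        mask = np.ones(6, dtype=bool)
        mult = np.array([2.0, 1, 1, 1, 1, 1])
        trace = model_forward(sp["xc"], sp["psg_op"], sp["pog_ops"], params)
        loss_m, _ = loss_and_gradients(
            trace, sp["xc"], sp["psg_op"], sp["pog_ops"], params, labels,
            mask, None, sample_multiplicity=mult,
        )
        probs = trace.class_probabilities
        ce = -np.log(probs[np.arange(6), labels])
        expected = 0.5 * (mult * ce).sum() / mult.sum()
        assert loss_m == pytest.approx(expected)


class TestAdam:
    def test_zero_learning_rate_is_noop(self, small_problem, rng):
        sp = small_problem
        params = sp["params"].copy()
        opt = AdamState(params, learning_rate=0.0)
        grads = {k: rng.standard_normal(params[k].shape) for k in params.keys()}
        before = {k: params[k].copy() for k in params.keys()}
        opt.step(params, grads)
        for k in params.keys():
            np.testing.assert_array_equal(params[k], before[k])

    def test_step_moves_against_gradient_sign(self, small_problem):
        sp = small_problem
        params = sp["params"].copy()
        opt = AdamState(params, learning_rate=0.01)
        grads = {k: np.ones_like(params[k]) for k in params.keys()}
        before = {k: params[k].copy() for k in params.keys()}
        opt.step(params, grads)
        for k in params.keys():
            assert (params[k] < before[k]).all()
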