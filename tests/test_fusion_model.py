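"""Fusion architecture: channel stacking, attention gate, forward contracts."""

import numpy as np
import pytest

from gazefusion import (AttentionGateParams, FixationHeatmap, GazeFusionClassifier,
                        attention_gate, build_image_only_model, colorize,
                        predict_probs, stack_multimodal)
from gazefusion.nn import sigmoid


def make_heatmap(density):
    return FixationHeatmap(density=density, rgb=colorize(density))


def random_gate_params(rng, in_ch=4, hidden=3, per_channel=False, scale=0.5):
    out_ch = in_ch if per_channel else 1
    return AttentionGateParams(
        W1=rng.normal(0, scale, (hidden, in_ch, 1, 1)),
        b1=rng.normal(0, scale, hidden),
        W2=rng.normal(0, scale, (out_ch, hidden, 1, 1)),
        b2=rng.normal(0, scale, out_ch),
    )


def gate_oracle(x, p):
    """Per-pixel conv1x1 -> ReLU -> conv1x1 -> sigmoid -> multiply loop."""
    c, h, w = x.shape
    out = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            hid = np.maximum(p.W1[:, :, 0, 0] @ x[:, i, j] + p.b1, 0.0)
            s = p.W2[:, :, 0, 0] @ hid + p.b2
            a = 1.0 / (1.0 + np.exp(-s))
            out[:, i, j] = x[:, i, j] * (a if a.size > 1 else a[0])
    return out


class TestStackMultimodal:
    def test_zero_heatmap_keeps_image_in_channel_0(self, rng):
        img = rng.random((32, 32))
        hm = make_heatmap(np.zeros((32, 32)))
        hm.rgb = np.zeros((32, 32, 3))
        out = stack_multimodal(img, hm)
        np.testing.assert_array_equal(out[0], img)
        assert not out[1:].any()

    def test_224_input_gives_4x224x224(self, rng):
        img = rng.random((224, 224))
        out = stack_multimodal(img, make_heatmap(rng.random((224, 224))))
        assert out.shape == (4, 224, 224)

    def test_shape_mismatch_error_names_both_shapes(self, rng):
        hm = make_heatmap(np.zeros((112, 112)))
        with pytest.raises(ValueError, match=r"(?s)224.*112"):
            stack_multimodal(np.zeros((224, 224)), hm)


class TestAttentionGate:
    def test_zero_score_conv_halves_input(self, rng):
        x = rng.random((4, 6, 6))
        p = random_gate_params(rng)
        p = AttentionGateParams(W1=p.W1, b1=p.b1, W2=np.zeros_like(p.W2),
                                b2=np.zeros_like(p.b2))
        np.testing.assert_array_equal(attention_gate(x, p), 0.5 * x)

    def test_saturated_bias_passes_input_through(self, rng):
        x = rng.random((4, 6, 6))
        p = random_gate_params(rng)
        p = AttentionGateParams(W1=p.W1, b1=p.b1, W2=np.zeros_like(p.W2),
                                b2=np.full_like(p.b2, 20.0))
        np.testing.assert_allclose(attention_gate(x, p), x, atol=1e-8)

    @pytest.mark.parametrize("per_channel", [False, True])
    def test_matches_per_pixel_composition_oracle(self, rng, per_channel):
        x = rng.random((4, 8, 8))
        p = random_gate_params(rng, per_channel=per_channel)
        np.testing.assert_allclose(attention_gate(x, p), gate_oracle(x, p), atol=1e-6)

    def test_scores_bounded_and_output_dominated_by_input(self, rng):
        for _ in range(5):
            x = rng.normal(0, 3, (4, 5, 5))
            p = random_gate_params(rng, scale=2.0)
            out = attention_gate(x, p)
            assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_channel_mismatch_raises(self, rng):
        p = random_gate_params(rng, in_ch=4)
        with pytest.raises(ValueError, match="channels"):
            attention_gate(rng.random((3, 4, 4)), p)


class TestPredictProbs:
    def test_zero_logit_gives_half(self):
        probs, labels = predict_probs(np.array([0.0]), threshold=0.5)
        assert probs[0] == 0.5
        assert labels[0] == 1  # >= threshold

    def test_saturated_logits_threshold_correctly(self):
        probs, labels = predict_probs(np.array([10.0, -10.0]), threshold=0.5)
        np.testing.assert_array_equal(labels, [1, 0])

    def test_sigmoid_symmetry_identity(self, rng):
        x = rng.normal(0, 5, 1000)
        np.testing.assert_allclose(sigmoid(x) + sigmoid(-x), 1.0, atol=1e-12)


class TestForwardContracts:
    def test_eval_forward_is_deterministic(self, tiny_fitted, small_arrays):
        X, _ = small_arrays
        a = tiny_fitted.decision_function(X[:4])
        b = tiny_fitted.decision_function(X[:4])
        np.testing.assert_array_equal(a, b)

    def test_tiny_backbone_emits_six_logits_on_32px_input(self, tiny_fitted):
        x = np.random.default_rng(0).random((2, 4, 32, 32))
        logits = tiny_fitted.decision_function(x)
        assert logits.shape == (2, 6)
        assert np.all(np.isfinite(logits))

    def test_channel_count_mismatch_raises(self, tiny_fitted):
        with pytest.raises(ValueError, match="channel"):
            tiny_fitted.decision_function(np.zeros((1, 1, 32, 32)))

    def test_predict_proba_in_unit_interval(self, tiny_fitted, small_arrays):
        X, _ = small_arrays
        p = tiny_fitted.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))

    def test_gate_scores_bounded_on_fitted_model(self, tiny_fitted, small_arrays):
        X, _ = small_arrays
        a = tiny_fitted.attention_map(X[:4])
        assert np.all((a >= 0) & (a <= 1))

    def test_gradient_flow_reaches_every_parameter(self, small_arrays):
        from gazefusion.nn import bce_with_logits

        X, y = small_arrays
        clf = GazeFusionClassifier(backbone="tiny2", epochs=0, random_state=1)
        clf.fit(X, y)
        net = clf.network_
        logits = net.forward(X[:8], train=False)
        _, d = bce_with_logits(logits, y[:8].astype(float))
        net.backward(d)
        for name, _, g in net.iter_params():
            assert np.any(g != 0), f"zero gradient for {name}"


class TestImageOnlyBaseline:
    def test_has_strictly_fewer_parameters_than_fusion(self, small_phantom):
        from gazefusion import stack_dataset

        X4, y = stack_dataset(small_phantom)
        X1, _ = stack_dataset(small_phantom, include_gaze=False)
        fusion = GazeFusionClassifier(epochs=0, random_state=0).fit(X4, y)
        image_only = build_image_only_model(epochs=0, random_state=0).fit(X1, y)
        assert image_only.n_parameters() < fusion.n_parameters()

    def test_identical_seed_gives_identical_initialization(self, small_phantom):
        from gazefusion import stack_dataset

        X, y = stack_dataset(small_phantom, include_gaze=False)
        a = build_image_only_model(epochs=0, random_state=5).fit(X, y)
        b = build_image_only_model(epochs=0, random_state=5).fit(X, y)
        for (na, pa, _), (nb, pb, _) in zip(a.network_.iter_params(),
                                            b.network_.iter_params()):
            assert na == nb
            np.testing.assert_array_equal(pa, pb)


class TestDualBranchBaseline:
    def test_trains_and_predicts(self, small_arrays):
        X, y = small_arrays
        clf = GazeFusionClassifier(backbone="tiny2", shared_backbone=False,
                                   epochs=1, learning_rate=1e-3, batch_size=8,
                                   random_state=0)
        clf.fit(X, y)
        assert clf.predict_proba(X[:3]).shape == (3, 6)
        assert clf.feature_dim_ == 32  # concatenated branch features

    def test_rejects_single_channel_input(self, small_phantom):
        from gazefusion import stack_dataset

        X, y = stack_dataset(small_phantom, include_gaze=False)
        clf = GazeFusionClassifier(shared_backbone=False, epochs=0)
        with pytest.raises(ValueError, match="4-channel"):
            clf.fit(X, y)


def test_sklearn_clone_and_get_params_roundtrip():
    from sklearn.base import clone

    clf = GazeFusionClassifier(backbone="tiny2", epochs=3, learning_rate=1e-4)
    cloned = clone(clf)
    assert cloned.get_params() == clf.get_params()
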