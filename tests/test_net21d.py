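"""Architecture construction, shape arithmetic, inference, and gradients."""

import time

import numpy as np
import pytest

from neoseg import (
    ArchitectureConfig,
    MultiModalVolume,
    ShapeError,
    build_conv21d_pair,
    build_model,
    level_shape,
    load_model,
    predict,
    save_model,
    softmax,
)
from neoseg.metrics import hybrid_loss, hybrid_loss_logit_grad

DEFAULT = ArchitectureConfig()


def conv_param_oracle(kernel, cin, cout):
    kd, kh, kw = kernel
    return kd * kh * kw * cin * cout + cout


class TestConvPair:
    @pytest.mark.parametrize("cin,filters", [(6, 65), (2, 16), (3, 7)])
    def test_parameter_count_matches_closed_form(self, cin, filters):
        pair = build_conv21d_pair(cin, filters)
        expected = conv_param_oracle((1, 3, 3), cin, filters) + conv_param_oracle(
            (3, 1, 1), filters, filters
        )
        assert pair.parameter_count == expected

    def test_reference_pair_has_16315_parameters(self):
        # 1*3*3*6*65 + 65 = 3575 and 3*1*1*65*65 + 65 = 12740
        assert build_conv21d_pair(6, 65).parameter_count == 16315

    def test_same_padding_preserves_extents(self, rng):
        pair = build_conv21d_pair(2, 4)
        out = pair(rng.random((8, 16, 16, 2)).astype(np.float32))
        assert out.shape == (8, 16, 16, 4)

    def test_zero_weights_give_zero_output(self, rng):
        pair = build_conv21d_pair(2, 4)
        for conv in pair.layers:
            conv.W[...] = 0
            conv.b[...] = 0
        out = pair(rng.random((4, 8, 8, 2)).astype(np.float32))
        assert not out.any()

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(Exception):
            build_conv21d_pair(0, 4)


class TestBuildModel:
    def test_seeded_builds_are_bitwise_identical(self, tiny_arch):
        w1 = build_model(tiny_arch, seed=42).get_weights()
        w2 = build_model(tiny_arch, seed=42).get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))
        w3 = build_model(tiny_arch, seed=43).get_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(w1, w3))

    def test_top_encoder_carries_65_filters(self):
        model = build_model(DEFAULT, seed=0)
        for conv in model.encoders[0].pair1.layers + model.encoders[0].pair2.layers:
            assert conv.filters == 65

    def test_classifier_is_1x1x1_softmax_with_4_channels(self):
        model = build_model(DEFAULT, seed=0)
        row = model.layer_table()[-1]
        assert row["layer"] == "Conv3D"
        assert row["kernel"] == (1, 1, 1)
        assert row["filters"] == 4
        assert row["activation"] == "softmax"

    def test_layer_audit_matches_reference_table(self):
        """Row-for-row audit of the default network against the published
        layer listing: kernels, strides, filter counts, activations."""
        def conv(f, kernel):
            return ("Conv3D", f, kernel, (1, 1, 1), "elu", None)

        def rows_for_body(f):
            return [conv(f, (1, 3, 3)), conv(f, (3, 1, 1)),
                    ("BN", None, None, None, None, None),
                    ("Dropout", None, None, None, None, 0.2),
                    conv(f, (1, 3, 3)), conv(f, (3, 1, 1)),
                    ("BN", None, None, None, None, None)]

        expected = []
        for f in (65, 32, 16, 8):
            expected += rows_for_body(f)
            expected += [("MPool3D", None, None, (2, 2, 2), None, None)]
        expected += rows_for_body(4)  # bridge: encoder body without pooling
        for f in (8, 16, 32, 65):
            expected += [("ConvT3d", f, (2, 2, 2), (2, 2, 2), "elu", None),
                         ("Concatenate", None, None, None, None, None)]
            expected += rows_for_body(f)
        expected += [("Conv3D", 4, (1, 1, 1), (1, 1, 1), "softmax", None)]

        table = build_model(DEFAULT, seed=0).layer_table()
        got = [(r["layer"], r["filters"], r["kernel"], r["strides"], r["activation"], r["dropout"])
               for r in table]
        assert got == expected


class TestLevelShape:
    @pytest.mark.parametrize(
        "extents,level,expected",
        [
            ((112, 192, 144), 1, (56, 96, 72)),
            ((112, 192, 144), 2, (28, 48, 36)),
            ((112, 192, 144), 3, (14, 24, 18)),
            ((112, 192, 144), 4, (7, 12, 9)),
            ((16, 32, 32), 2, (4, 8, 8)),
        ],
    )
    def test_halving_sequence(self, extents, level, expected):
        assert level_shape(DEFAULT, extents, level) == expected

    def test_non_divisible_raises(self):
        with pytest.raises(ShapeError):
            level_shape(DEFAULT, (112, 192, 100), 4)

    def test_scaling_equivariance(self, rng):
        for _ in range(20):
            e = tuple(int(v) * 16 for v in rng.integers(1, 6, 3))
            k = int(rng.integers(0, 5))
            doubled = level_shape(DEFAULT, tuple(2 * x for x in e), k)
            assert doubled == tuple(2 * x for x in level_shape(DEFAULT, e, k))


class TestForwardAndPredict:
    def test_trace_matches_actual_forward_shapes(self, scaled_arch, rng):
        model = build_model(scaled_arch, seed=3)
        x = rng.random((32, 48, 32, 2)).astype(np.float32)
        log = {}
        model.forward(x, shape_log=log)
        assert log == model.trace_shapes((32, 48, 32))

    def test_scaled_forward_under_five_seconds(self, scaled_arch, rng):
        model = build_model(scaled_arch, seed=3)
        x = rng.random((32, 48, 32, 2)).astype(np.float32)
        start = time.perf_counter()
        model.forward(x)
        assert time.perf_counter() - start < 5.0

    def test_probabilities_sum_to_one_and_inference_deterministic(self, tiny_arch, rng):
        model = build_model(tiny_arch, seed=0)
        mm = MultiModalVolume(rng.random((16, 16, 16, 2)), channel_labels=["T1", "T2"])
        pv1, lv1 = predict(model, mm)
        pv2, lv2 = predict(model, mm)
        np.testing.assert_allclose(pv1.probs.sum(axis=3), 1.0, atol=1e-5)
        np.testing.assert_array_equal(pv1.probs, pv2.probs)
        np.testing.assert_array_equal(lv1.labels, lv2.labels)

    def test_uniform_probabilities_break_ties_to_lowest_class(self, tiny_arch, rng):
        model = build_model(tiny_arch, seed=0)
        model.classifier.W[...] = 0
        model.classifier.b[...] = 0
        mm = MultiModalVolume(rng.random((16, 16, 16, 2)), channel_labels=["T1", "T2"])
        pv, lv = predict(model, mm)
        np.testing.assert_allclose(pv.probs, 0.25, atol=1e-12)
        assert (lv.labels == 0).all()

    def test_channel_mismatch_and_bad_extents(self, tiny_arch, rng):
        model = build_model(tiny_arch, seed=0)
        with pytest.raises(ShapeError):
            predict(model, MultiModalVolume(rng.random((16, 16, 16, 3)),
                                            channel_labels=["a", "b", "c"]))
        odd = MultiModalVolume(rng.random((15, 16, 16, 2)), channel_labels=["T1", "T2"])
        with pytest.raises(ShapeError):
            predict(model, odd)

    def test_padding_recovers_original_extents(self, tiny_arch, rng):
        model = build_model(tiny_arch, seed=0)
        odd = MultiModalVolume(rng.random((15, 20, 17, 2)), channel_labels=["T1", "T2"])
        pv, lv = predict(model, odd, pad=True)
        assert pv.probs.shape == (15, 20, 17, 4)
        assert lv.shape == (15, 20, 17)

    def test_checkpoint_round_trip(self, tiny_arch, rng, tmp_path):
        model = build_model(tiny_arch, seed=9)
        mm = MultiModalVolume(rng.random((16, 16, 16, 2)), channel_labels=["T1", "T2"])
        pv, _ = predict(model, mm)
        save_model(model, str(tmp_path / "ckpt"))
        back = load_model(str(tmp_path / "ckpt"))
        pv2, _ = predict(back, mm)
        np.testing.assert_array_equal(pv.probs, pv2.probs)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients of the full network (convs, BN, pooling,
        transpose convs, skip concatenation) against central differences."""
        cfg = ArchitectureConfig(filters_per_level=(3, 3, 2, 2), bridge_filters=2,
                                 in_channels=2, dropout_rate=0.0, dtype="float64")
        model = build_model(cfg, seed=7)
        x = rng.random((16, 16, 16, 2))
        y = rng.integers(0, 4, (16, 16, 16))

        def loss_value():
            return hybrid_loss(softmax(model.forward(x, training=True)), y)

        logits = model.forward(x, training=True)
        _, grad = hybrid_loss_logit_grad(softmax(logits), y)
        model.backward(grad)

        param_rng = np.random.default_rng(1)
        triples = model.trainables()
        picks = [triples[i] for i in param_rng.choice(len(triples), size=8, replace=False)]
        for lyr, p, g in picks:
            flat = getattr(lyr, p).ravel()
            grad_flat = getattr(lyr, g).ravel()
            i = int(param_rng.integers(flat.size))
            eps, old = 1e-6, flat[i]
            flat[i] = old + eps
            up = loss_value()
            flat[i] = old - eps
            down = loss_value()
            flat[i] = old
            numeric = (up - down) / (2 * eps)
            assert grad_flat[i] == pytest.approx(numeric, rel=5e-3, abs=1e-7)
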