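"""CNN: architecture analytics, backprop correctness, augmentation,
aggregation, Grad-CAM."""

import numpy as np
import pytest

from dfoct.cnn import (
    FULL_PROFILE,
    REDUCED_PROFILE,
    ArchitectureSpec,
    TrainConfig,
    aggregate_sample_percentile,
    augment_dataset,
    build_model,
    count_parameters,
    gradcam,
    receptive_fields,
    train_model,
    weighted_bce,
)


class TestArchitecture:
    def test_full_profile_feature_map_sizes(self):
        assert FULL_PROFILE.feature_map_size(1440, 1440) == (45, 45)
        assert REDUCED_PROFILE.feature_map_size(96, 96) == (12, 12)

    def test_incompatible_input_size_rejected(self):
        with pytest.raises(ValueError):
            REDUCED_PROFILE.feature_map_size(97, 96)

    def test_untrained_output_is_probability(self, rng):
        m = build_model(ArchitectureSpec(blocks=((1, 4), (1, 8)), head_width=16), seed=0)
        p = m.predict_proba(rng.standard_normal((2, 16, 16, 3)))
        assert np.all((p > 0) & (p < 1))

    def test_gap_head_accepts_multiple_input_sizes(self, rng):
        m = build_model(ArchitectureSpec(blocks=((1, 4),), head_width=8), seed=0)
        for size in (8, 16, 32):
            assert m.predict_proba(rng.standard_normal((1, size, size, 3))).shape == (1,)


class TestParameterCount:
    def test_single_conv_3_to_1(self):
        spec = ArchitectureSpec(blocks=((1, 1),), head_width=1)
        total, backbone, head = count_parameters(spec)
        assert backbone == 28  # 3*3*3*1 + 1

    def test_full_profile_head_is_526337(self):
        _, _, head = count_parameters(FULL_PROFILE)
        assert head == 512 * 1024 + 1024 + 1024 + 1 == 526_337

    def test_full_profile_total_rounds_to_15_million(self):
        total, _, _ = count_parameters(FULL_PROFILE)
        assert round(total / 1e6) == 15

    def test_analytic_count_matches_instantiated_arrays(self):
        for spec in (REDUCED_PROFILE, ArchitectureSpec(blocks=((2, 5), (1, 7)), head_width=11)):
            m = build_model(spec, seed=0)
            assert m.n_parameters() == count_parameters(spec)[0]


class TestReceptiveFields:
    def test_full_profile_matches_published_series(self):
        assert receptive_fields(FULL_PROFILE) == [6, 16, 44, 100, 212]

    def test_single_block_recurrence_by_hand(self):
        # one 3x3 conv (RF 3) then 2x2 pool -> RF 4
        assert receptive_fields(ArchitectureSpec(blocks=((1, 8),))) == [4]

    def test_brute_force_perturbation_oracle(self, rng):
        """Perturbing one input pixel affects exactly the feature-map cells
        whose receptive field covers it."""
        spec = ArchitectureSpec(blocks=((1, 4), (1, 4)), head_width=4)
        rf = receptive_fields(spec)[-1]
        m = build_model(spec, seed=1)
        x = rng.standard_normal((1, 16, 16, 3))
        m.forward_logits(x)
        base = m.layers[-2].out.copy()  # last conv activations before pool
        x2 = x.copy()
        x2[0, 8, 8, :] += 10.0
        m.forward_logits(x2)
        changed = np.any(m.layers[-2].out != base, axis=(0, 1))
        ys, xs = np.nonzero(changed)
        jump = 2  # one pooling layer before the last conv
        span_y = (ys.max() - ys.min()) * jump + 1
        assert span_y <= rf

    def test_custom_profile_recurrence(self):
        spec = ArchitectureSpec(blocks=((2, 4), (2, 4)))
        assert receptive_fields(spec) == [6, 16]


class TestAugmentation:
    def test_default_configuration_expands_sixfold(self, rng):
        imgs = [rng.random((8, 8, 3)) for _ in range(4)]
        out, labels = augment_dataset(imgs, ["a", "b", "c", "d"])
        assert len(out) == 24
        assert labels == [l for l in "abcd" for _ in range(6)]

    def test_identity_lut_no_flip_is_identity(self, rng):
        img = rng.random((8, 8, 3))
        out, _ = augment_dataset([img], [1], lut_specs=("identity",), flip_mode="none")
        np.testing.assert_array_equal(out[0], img)

    def test_flip_is_involution(self, rng):
        img = rng.random((8, 8, 3))
        out, _ = augment_dataset([img], [1], lut_specs=("identity",), flip_mode="horizontal")
        np.testing.assert_array_equal(out[1][:, ::-1], img)

    def test_unknown_lut_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_dataset([rng.random((4, 4))], [0], lut_specs=("gamma_burn",))


class TestTraining:
    def test_gradients_match_finite_differences(self, rng):
        spec = ArchitectureSpec(blocks=((1, 3), (1, 4)), head_width=5, in_channels=2)
        m = build_model(spec, seed=0)
        x = rng.standard_normal((2, 8, 8, 2))
        y = np.array([0, 1])
        w = TrainConfig().sample_weights(y)
        m.zero_grads()
        _, dz = weighted_bce(m.forward_logits(x), y, w)
        m.backward(dz)
        grads = [g.copy() for g in m.grads]
        for pi, p in enumerate(m.params):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, orig = 1e-6, p[idx]
            p[idx] = orig + eps
            lp = weighted_bce(m.forward_logits(x), y, w)[0]
            p[idx] = orig - eps
            lm = weighted_bce(m.forward_logits(x), y, w)[0]
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(grads[pi][idx], rel=1e-4, abs=1e-8)

    def test_class_weighted_loss_arithmetic(self):
        """One healthy error carries twice the loss of one tumoral error
        under weights 1.5 / 0.75."""
        cfg = TrainConfig()
        z = np.array([2.0])  # confident tumoral logit
        loss_healthy_error = weighted_bce(z, np.array([0]), cfg.sample_weights(np.array([0])))[0]
        loss_tumoral_error = weighted_bce(-z, np.array([1]), cfg.sample_weights(np.array([1])))[0]
        assert loss_healthy_error == pytest.approx(2.0 * loss_tumoral_error)

    def test_memorizes_separable_toy_set_and_stops_on_train_acc(self, rng):
        spec = ArchitectureSpec(blocks=((1, 4),), head_width=8)
        m = build_model(spec, seed=0)
        imgs = [np.full((8, 8, 3), v) for v in (0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0)]
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cfg = TrainConfig(lr=0.05, max_epochs=500, seed=0)
        hist = train_model(m, imgs, labels, imgs, labels, cfg)
        assert hist["train_acc"][-1] == 1.0
        assert hist["stopped_by"] == "train_acc"

    def test_patience_rule_fires_on_flat_validation(self, rng):
        spec = ArchitectureSpec(blocks=((1, 2),), head_width=4)
        m = build_model(spec, seed=0)
        imgs = [rng.random((4, 4, 3)) for _ in range(6)]
        labels = np.array([0, 1, 0, 1, 0, 1])
        # lr=0 freezes the model: validation loss never improves after epoch 0
        cfg = TrainConfig(lr=0.0, patience=5, max_epochs=100, seed=0)
        hist = train_model(m, imgs, labels, imgs[:2], labels[:2], cfg)
        assert hist["stopped_by"] == "patience"
        assert len(hist["train_loss"]) <= 7

    def test_single_class_training_rejected(self, rng):
        m = build_model(ArchitectureSpec(blocks=((1, 2),), head_width=4), seed=0)
        imgs = [rng.random((4, 4, 3))] * 4
        with pytest.raises(ValueError):
            train_model(m, imgs, np.zeros(4), imgs, np.zeros(4), TrainConfig(max_epochs=1))


class TestPercentileAggregation:
    def test_all_zero_probabilities_is_healthy(self):
        d = aggregate_sample_percentile(np.zeros(5), ["s"] * 5)[0]
        assert d.predicted == "healthy"

    def test_singleton_percentile_is_the_value(self):
        d = aggregate_sample_percentile(np.array([0.9]), ["s"])[0]
        assert d.score == pytest.approx(0.9) and d.predicted == "tumoral"

    def test_linear_interpolation_matches_sort_based_oracle(self):
        # nine 0.1 values and one 0.95: sorted index 0.9*(10-1)=8.1 ->
        # 0.1 + 0.1*(0.95-0.1) = 0.185
        p = np.array([0.1] * 9 + [0.95])
        srt = np.sort(p)
        pos = 0.9 * (len(p) - 1)
        lo, frac = int(pos), pos - int(pos)
        oracle = srt[lo] + frac * (srt[lo + 1] - srt[lo])
        d = aggregate_sample_percentile(p, ["s"] * 10)[0]
        assert d.score == pytest.approx(oracle) == pytest.approx(0.185)
        assert d.predicted == "healthy"

    def test_one_hot_tumor_roi_detected_via_90th_percentile(self):
        p = np.array([0.05] * 5 + [0.99])
        d = aggregate_sample_percentile(p, ["s"] * 6)[0]
        assert d.predicted == "tumoral"


class TestGradCam:
    def test_hand_weighted_single_channel_model(self, rng):
        """Output = mean of channel 0 of the last conv: the positive map is
        proportional to that channel's activation (analytic gradient)."""
        spec = ArchitectureSpec(blocks=((1, 4),), head_width=3)
        m = build_model(spec, seed=0)
        # head passes GAP(channel 0) straight through: fc unit 0 reads
        # channel 0 with weight 1, output reads fc unit 0 with weight 1
        m.fc_w[:] = 0.0
        m.fc_w[0, 0] = 1.0
        m.fc_b[:] = 0.0
        m.out_w[:] = 0.0
        m.out_w[0, 0] = 1.0
        m.out_b[:] = 0.0
        x = np.abs(rng.standard_normal((8, 8, 3)))
        amap = gradcam(m, x, target="positive", layers=("block1_conv1",))
        act0 = m.conv_layer("block1_conv1").out[0, 0]
        pooled = act0.reshape(4, 2, 4, 2).max(axis=(1, 3))
        # gradient w.r.t. channel 0 is constant 1/(H*W) through GAP; the map
        # is that constant times the activation, channel 0 only
        expected = np.maximum(m.conv_layer("block1_conv1").grad_out[0, 0].mean()
                              * act0, 0.0)
        np.testing.assert_allclose(amap.map, expected, atol=1e-12)
        assert np.all(amap.map >= 0)

    def test_zero_activations_give_zero_map(self):
        spec = ArchitectureSpec(blocks=((1, 2),), head_width=2)
        m = build_model(spec, seed=0)
        amap = gradcam(m, np.zeros((8, 8, 3)), target="positive")
        assert np.allclose(amap.map, 0.0)

    def test_unknown_layer_rejected(self, rng):
        m = build_model(ArchitectureSpec(blocks=((1, 2),), head_width=2), seed=0)
        with pytest.raises(KeyError):
            gradcam(m, np.zeros((8, 8, 3)), layers=("block9_conv9",))

    def test_two_layer_fusion_resolution(self, rng):
        spec = ArchitectureSpec(blocks=((1, 2), (1, 3)), head_width=4)
        m = build_model(spec, seed=0)
        amap = gradcam(m, rng.random((16, 16, 3)))
        # finest participating conv runs at 16 (block2 conv sees 8x8 after
        # one pool); block1 conv at 16x16 -> fused at 16x16
        assert amap.map.shape == (16, 16)
        assert len(amap.source_layers) == 2
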