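"""Segmentation networks: layer algebra, training behaviour, fallback."""

import warnings

import numpy as np
import pytest

from spinecurve import nn
from spinecurve.metrics import evaluate
from spinecurve.phantom import extract_chips
from spinecurve.segmentation import (
    DenseBlock,
    NetworkSpec,
    ResidualBlock,
    TrainingConfig,
    augment,
    build_network,
    classical_segment,
    conv_unit,
    crossvalidate,
    l2_loss,
    predict_mask,
    predict_proba,
    train,
)

TINY = dict(input_shape=(16, 8), depth=2, base_channels=2,
            growth_rate=2, dense_layers_per_block=2)


class TestConvUnit:
    def test_zero_filters_zero_bias_give_zero_preactivation(self, rng):
        cu = conv_unit(1, 3, rng)
        conv = cu.layers[0]
        conv.W.value[...] = 0
        conv.b.value[...] = 0
        x = rng.standard_normal((2, 1, 8, 8)).astype(np.float32)
        # after conv the map is exactly zero; ReLU and BN keep it zero
        assert np.allclose(cu.forward(x, train=False), 0.0)

    def test_negative_preactivation_rectified_to_zero(self, rng):
        cu = conv_unit(1, 2, rng)
        conv = cu.layers[0]
        conv.W.value[...] = 0
        conv.b.value[...] = -5.0  # all pre-activations negative
        x = rng.standard_normal((1, 1, 8, 8)).astype(np.float32)
        out_relu = cu.layers[1].forward(conv.forward(x))
        assert np.all(out_relu == 0.0)

    def test_box_kernel_on_constant_map_is_constant(self, rng):
        conv = nn.Conv2D(1, 1, 3, rng)
        conv.W.value[...] = 1.0 / 9.0
        conv.b.value[...] = 0
        x = np.full((1, 1, 6, 6), 4.0, dtype=np.float32)
        y = conv.forward(x)
        # same-padding averages fewer pixels at the border; interior exact
        assert np.allclose(y[0, 0, 1:-1, 1:-1], 4.0, atol=1e-5)


class TestResidualBlock:
    def test_zeroed_branch_is_exact_identity(self, rng):
        blk = ResidualBlock(3, 3, rng)
        for layer in blk.branch.layers:
            for p in layer.params():
                p.value[...] = 0
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        assert np.array_equal(blk.forward(x, train=False), x)

    def test_zero_input_passes_branch_only(self, rng):
        blk = ResidualBlock(3, 3, rng)
        x = np.zeros((1, 3, 8, 8), dtype=np.float32)
        y = blk.forward(x, train=False)
        branch = blk.branch.forward(x, train=False)
        assert np.allclose(y, branch)

    def test_output_minus_input_equals_branch(self, rng):
        blk = ResidualBlock(4, 4, rng)
        x = rng.standard_normal((2, 4, 8, 8)).astype(np.float32)
        y = blk.forward(x, train=False)
        branch = blk.branch.forward(x, train=False)
        assert np.allclose(y - x, branch, atol=1e-5)

    def test_channel_change_uses_projection(self, rng):
        blk = ResidualBlock(2, 5, rng)
        x = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
        assert blk.forward(x, train=False).shape == (1, 5, 8, 8)
        assert blk.project is not None


class TestDenseBlock:
    @pytest.mark.parametrize("layers,growth", [(4, 12), (1, 7), (3, 4)])
    def test_block_emits_l_times_k_channels(self, rng, layers, growth):
        blk = DenseBlock(2, 6, layers, growth, rng)
        # channels entering the transition = l * k
        assert blk.transition.in_ch == layers * growth

    def test_concatenation_width_grows_by_k_per_layer(self, rng):
        blk = DenseBlock(3, 6, layers=4, growth=5, rng=rng)
        x = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        blk.forward(x, train=False)
        # input widths seen by successive layers: in, in+k, in+2k, ...
        assert blk._n_feats[:4] == [3, 5, 5, 5]
        widths = [lay.layers[2].in_ch for lay in blk.layers]
        assert widths == [3 + 5 * j for j in range(4)]


class TestBuildNetwork:
    def test_bottleneck_is_input_over_2_pow_depth(self):
        spec = NetworkSpec(input_shape=(256, 128), depth=4, base_channels=2)
        assert (256 // 2**4, 128 // 2**4) == (16, 8)
        net = build_network(spec, seed=0)
        x = np.zeros((1, 1, 256, 128), dtype=np.float32)
        skips = []
        h = x
        for blk, pool in zip(net.enc, net.pools):
            h = pool.forward(blk.forward(h, train=False))
        assert h.shape[2:] == (16, 8)

    @pytest.mark.parametrize("variant", ["unet", "residual", "dense"])
    def test_probability_map_shape_and_range(self, variant, rng):
        net = build_network(NetworkSpec(variant=variant, **TINY), seed=0)
        x = rng.standard_normal((2, 1, 16, 8)).astype(np.float32)
        y = net.forward(x, train=False)
        assert y.shape == (2, 1, 16, 8)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkSpec(input_shape=(100, 50), depth=3)


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        x = np.ones((3, 4))
        assert l2_loss(x, x) == 0.0

    def test_all_zero_vs_all_one_is_one(self):
        assert l2_loss(np.zeros((5, 5)), np.ones((5, 5))) == 1.0

    def test_two_item_batch_averages(self):
        pred = np.array([0.0, 1.0])
        truth = np.array([1.0, 1.0])
        assert l2_loss(pred, truth) == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l2_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestTraining:
    def test_overfits_single_chip(self, phantom20):
        chip, mask = extract_chips(phantom20, chip_shape=(32, 16))[8]
        spec = NetworkSpec(input_shape=(32, 16), depth=2, base_channels=2)
        losses = []
        for seed in range(3):
            net = build_network(spec, seed=seed)
            cfg = TrainingConfig(epochs=20, seed=seed, batch_size=1)
            net, hist = train(net, [chip], [mask], cfg, augment_data=False)
            losses.append(hist["train_loss"])
        # training loss non-increasing over the last 5 epochs in >= 1 seed
        ok = sum(all(a >= b - 1e-9 for a, b in zip(l[-5:], l[-4:])) for l in losses)
        assert ok >= 1
        assert losses[0][-1] < losses[0][0]

    def test_augmentation_reaches_target_count(self, rng):
        chips = [rng.uniform(0, 255, (16, 8)) for _ in range(595)]
        masks = [rng.random((16, 8)) > 0.5 for _ in range(595)]
        out_c, out_m = augment(chips, masks, 1000, rng)
        assert len(out_c) == len(out_m) == 1000
        assert all(m.dtype == bool for m in out_m)
        # originals are preserved in front
        assert np.array_equal(out_c[0], chips[0].astype(np.float32))

    def test_validation_split_is_10_percent(self, phantom20):
        chip, mask = extract_chips(phantom20, chip_shape=(16, 8))[0]
        spec = NetworkSpec(input_shape=(16, 8), depth=2, base_channels=2)
        net = build_network(spec, seed=0)
        cfg = TrainingConfig(epochs=1, seed=0, augmentation_target=40,
                             validation_fraction=0.10)
        net, hist = train(net, [chip] * 4, [mask] * 4, cfg)
        assert len(hist["val_loss"]) == 1  # validation ran (4 = 10% of 40)

    def test_reproducible_for_fixed_seed(self, phantom20):
        chip, mask = extract_chips(phantom20, chip_shape=(16, 8))[3]
        spec = NetworkSpec(input_shape=(16, 8), depth=2, base_channels=2)
        outs = []
        for _ in range(2):
            net = build_network(spec, seed=5)
            cfg = TrainingConfig(epochs=2, seed=5, batch_size=2)
            net, _ = train(net, [chip] * 3, [mask] * 3, cfg, augment_data=False)
            outs.append(predict_proba(net, chip))
        assert np.array_equal(outs[0], outs[1])


class TestPredict:
    def test_threshold_boundary_is_strict_greater(self):
        tiny_spec = NetworkSpec(**TINY)

        class Fake:
            spec = tiny_spec

            def forward(self, x, train=False):
                out = np.full((1, 1, 16, 8), 0.49, dtype=np.float32)
                out[0, 0, 0, 0] = 0.51
                return out

        mask = predict_mask(Fake(), np.zeros((16, 8)), threshold=0.5)
        assert mask[0, 0] and mask.sum() == 1

    def test_wrong_chip_shape_rejected(self):
        net = build_network(NetworkSpec(**TINY), seed=0)
        with pytest.raises(ValueError, match="shape"):
            predict_mask(net, np.zeros((10, 10)))


class TestCrossValidate:
    def test_folds_partition_images(self, phantom20):
        pairs = extract_chips(phantom20, chip_shape=(16, 8))
        dataset = [[pairs[i]] for i in range(10)]
        spec = NetworkSpec(input_shape=(16, 8), depth=2, base_channels=2)
        cfg = TrainingConfig(epochs=1, folds=5, seed=0, augmentation_target=10)
        out = crossvalidate(dataset, spec, cfg)
        assert len(out["per_fold"]) == 5
        assert 0.0 <= out["mean"] <= 1.0

    def test_more_folds_than_images_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate([[(np.zeros((16, 8)), np.zeros((16, 8), bool))]],
                          NetworkSpec(input_shape=(16, 8), depth=2),
                          TrainingConfig(folds=5))


class TestClassicalSegment:
    def test_bimodal_chip_recovers_bright_region(self):
        chip = np.full((64, 32), 50.0)
        chip[16:48, 8:24] = 200.0
        mask = classical_segment(chip)
        assert mask[20:44, 10:22].all()
        assert not mask[:8].any()

    def test_constant_chip_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="flat chip"):
            mask = classical_segment(np.full((32, 16), 80.0))
        assert not mask.any()

    def test_phantom_chips_reach_dsc_085(self, phantom20):
        pairs = extract_chips(phantom20, chip_shape=(128, 64))
        dscs = [evaluate(m, classical_segment(c)).dsc for c, m in pairs]
        assert np.mean(dscs) >= 0.85
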