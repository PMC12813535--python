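import numpy as np
import pytest

from cytoseg import nnet
from cytoseg.synthgen import generate_dataset, small_cell_config
from cytoseg.unet import (LossConfig, TrainConfig, UNetConfig, build_unet,
                          combined_loss, make_weight_map, predict_probmap, train)

UNIT = LossConfig(w_ce=0.5, w_mse=0.5, class_weights=(1.0, 1.0), boundary_weight=1.0)


class TestArchitecture:
    def test_output_matches_input_size_and_classes(self):
        net = build_unet(UNetConfig(depth=2, base_channels=4, n_classes=3), seed=0)
        out = net.forward(np.random.default_rng(0).random((1, 3, 64, 64)))
        assert out.shape == (1, 3, 64, 64)

    def test_bottleneck_size_three_halvings(self):
        net = build_unet(UNetConfig(depth=3, base_channels=2), seed=0)
        x = np.random.default_rng(0).random((1, 3, 64, 64))
        for (c1, r1, c2, r2, dp), pool in zip(net.enc_convs, net.pools):
            x = pool.forward(dp.forward(r2.forward(c2.forward(r1.forward(c1.forward(x)))), False, None))
        assert x.shape[2:] == (8, 8)

    def test_odd_input_padded_and_cropped(self):
        net = build_unet(UNetConfig(depth=2, base_channels=4), seed=0)
        out = net.forward(np.random.default_rng(0).random((1, 3, 70, 70)))
        assert out.shape == (1, 2, 70, 70)

    def test_skip_connection_count_equals_depth(self):
        assert build_unet(UNetConfig(depth=3, base_channels=2), seed=0).n_skip_connections == 3

    def test_parameter_count_matches_hand_tally(self):
        # depth=1, base=4, n_classes=2, rgb input; two 3x3 convs per block,
        # 2x2 transposed-conv upsampling, 1x1 output conv
        tally = (
            (3 * 4 * 9 + 4)      # enc conv1 3->4
            + (4 * 4 * 9 + 4)    # enc conv2 4->4
            + (4 * 8 * 9 + 8)    # bottleneck conv1 4->8
            + (8 * 8 * 9 + 8)    # bottleneck conv2 8->8
            + (8 * 4 * 4 + 4)    # transposed conv 8->4, 2x2
            + (8 * 4 * 9 + 4)    # dec conv1 (4 skip + 4 up) -> 4
            + (4 * 4 * 9 + 4)    # dec conv2 4->4
            + (4 * 2 + 2)        # 1x1 output conv 4->2
        )
        net = build_unet(UNetConfig(depth=1, base_channels=4, n_classes=2), seed=0)
        assert net.n_params == tally

    def test_numerical_gradient_agreement(self, rng):
        net = build_unet(UNetConfig(depth=1, base_channels=3, dropout_p=0.0), seed=1)
        x = rng.random((1, 3, 8, 8))
        target = (rng.random((8, 8)) > 0.5).astype(np.int64)
        wmap = np.ones((8, 8))

        def loss_of():
            probs = nnet.softmax(net.forward(x), axis=1)
            return combined_loss(probs[0].transpose(1, 2, 0), target, wmap, UNIT)

        probs = nnet.softmax(net.forward(x), axis=1)
        _l, dp = combined_loss(probs[0].transpose(1, 2, 0), target, wmap, UNIT, return_grad=True)
        dlogits = nnet.softmax_backward(probs[0], dp.transpose(2, 0, 1), axis=0)[None]
        for p in net.params():
            p.grad[...] = 0
        net.backward(dlogits)
        for name in ("enc0.c1.w", "bott.c2.w", "up0.b", "out.w"):
            p = net.named_params()[name]
            idx = tuple(0 for _ in p.data.shape)
            old = p.data[idx]
            p.data[idx] = old + 1e-6
            lp = loss_of()
            p.data[idx] = old - 1e-6
            lm = loss_of()
            p.data[idx] = old
            num = (lp - lm) / 2e-6
            assert abs(num - p.grad[idx]) < 1e-6 * max(1.0, abs(num))


class TestCombinedLoss:
    def test_zero_at_perfect_one_hot(self):
        target = np.array([[0, 1], [1, 0]])
        probs = np.eye(2)[target].astype(float)
        assert combined_loss(probs, target, np.ones((2, 2)), UNIT) == 0.0

    def test_uniform_prediction_ce_is_ln2(self):
        cfg = LossConfig(w_ce=1.0, w_mse=0.0, class_weights=(1.0, 1.0), boundary_weight=1.0)
        probs = np.full((3, 3, 2), 0.5)
        target = np.zeros((3, 3), dtype=np.int64)
        assert abs(combined_loss(probs, target, np.ones((3, 3)), cfg) - np.log(2)) < 1e-12

    def test_equal_weights_average_the_two_terms(self, rng):
        probs = rng.dirichlet(np.ones(2), size=(4, 4))
        target = (rng.random((4, 4)) > 0.5).astype(np.int64)
        w = rng.uniform(0.5, 2.0, size=(4, 4))
        ce = combined_loss(probs, target, w, LossConfig(w_ce=1, w_mse=0, class_weights=(1, 1), boundary_weight=1))
        mse = combined_loss(probs, target, w, LossConfig(w_ce=0, w_mse=1, class_weights=(1, 1), boundary_weight=1))
        both = combined_loss(probs, target, w, LossConfig(w_ce=0.5, w_mse=0.5, class_weights=(1, 1), boundary_weight=1))
        assert abs(both - 0.5 * (ce + mse)) < 1e-12

    def test_weight_rescaling_invariance(self, rng):
        probs = rng.dirichlet(np.ones(2), size=(5, 5))
        target = (rng.random((5, 5)) > 0.5).astype(np.int64)
        w = rng.uniform(0.5, 2.0, size=(5, 5))
        assert abs(combined_loss(probs, target, w, UNIT)
                   - combined_loss(probs, target, 2 * w, UNIT)) < 1e-12

    def test_nonnegative_and_zero_only_at_target(self, rng):
        probs = rng.dirichlet(np.ones(2), size=(4, 4))
        target = (rng.random((4, 4)) > 0.5).astype(np.int64)
        loss = combined_loss(probs, target, np.ones((4, 4)), UNIT)
        assert loss > 0.0

    def test_invalid_inputs_rejected(self):
        probs = np.full((2, 2, 2), 0.5)
        target = np.zeros((2, 2), dtype=np.int64)
        with pytest.raises(ValueError):
            combined_loss(probs, target, np.zeros((2, 2)), UNIT)  # non-positive weights
        with pytest.raises(ValueError):
            combined_loss(probs, np.zeros((3, 3), np.int64), np.ones((2, 2)), UNIT)


class TestWeightMap:
    def test_identity_configuration_gives_ones(self):
        lab = np.zeros((6, 6), dtype=np.int64)
        lab[2:4, 2:4] = 1
        cfg = LossConfig(class_weights=(1.0, 1.0), boundary_weight=1.0)
        assert np.array_equal(make_weight_map(lab, cfg), np.ones((6, 6)))

    def test_single_pixel_instance_weights_its_neighborhood(self):
        lab = np.zeros((7, 7), dtype=np.int64)
        lab[3, 3] = 1
        cfg = LossConfig(class_weights=(1.0, 1.0), boundary_weight=3.0, boundary_radius=1)
        w = make_weight_map(lab, cfg)
        expected = np.ones((7, 7))
        expected[2:5, 2:5] = 3.0
        assert np.array_equal(w, expected)

    def test_all_background_constant(self):
        cfg = LossConfig(class_weights=(0.7, 1.3), boundary_weight=5.0)
        w = make_weight_map(np.zeros((5, 5), dtype=np.int64), cfg)
        assert np.all(w == 0.7)


class TestTrainingAndPrediction:
    def test_zero_epochs_is_noop(self, tiny_dataset):
        net = build_unet(UNetConfig(depth=1, base_channels=2), seed=0)
        before = [p.data.copy() for p in net.params()]
        ds = [(img.pixels, gt.nucleus_labels.labels) for img, gt in tiny_dataset[:1]]
        hist = train(net, ds, TrainConfig(epochs=0), LossConfig())
        assert hist == []
        for p, b in zip(net.params(), before):
            assert np.array_equal(p.data, b)

    def test_same_seed_same_history(self, tiny_dataset):
        ds = [(img.pixels, gt.nucleus_labels.labels) for img, gt in tiny_dataset]
        cfg = TrainConfig(learning_rate=0.05, epochs=2, batch_size=2, seed=3)
        h1 = train(build_unet(UNetConfig(depth=1, base_channels=2), 0), ds, cfg, LossConfig())
        h2 = train(build_unet(UNetConfig(depth=1, base_channels=2), 0), ds, cfg, LossConfig())
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        net = build_unet(UNetConfig(depth=1, base_channels=2), seed=0)
        with pytest.raises(ValueError):
            train(net, [], TrainConfig(), LossConfig())

    def test_overfits_single_image(self):
        # optimisation sanity: loss on one image collapses within 200 steps
        passed = 0
        for seed in (0, 1, 2):
            img, gt = generate_dataset(small_cell_config(64, seed=20 + seed), 1)[0]
            ds = [(img.pixels, gt.nucleus_labels.labels)]
            net = build_unet(UNetConfig(depth=2, base_channels=8, dropout_p=0.0), seed=seed)
            cfg = TrainConfig(learning_rate=0.3, epochs=200, batch_size=1,
                              l2_lambda=0.0, seed=seed, max_steps=200)
            hist = train(net, ds, cfg, LossConfig())
            if hist[-1] < 0.1 * hist[0]:
                passed += 1
        assert passed >= 2

    def test_probmap_contract_and_inference_determinism(self, tiny_dataset):
        net = build_unet(UNetConfig(depth=2, base_channels=4, dropout_p=0.5), seed=0)
        img = tiny_dataset[0][0]
        p1 = predict_probmap(net, img)
        p2 = predict_probmap(net, img)
        assert p1.shape == img.pixels.shape[:2] + (2,)
        assert np.allclose(p1.sum(axis=2), 1.0, atol=1e-5)
        assert np.array_equal(p1, p2)

    def test_checkpoint_round_trip(self, tmp_path, tiny_dataset):
        net = build_unet(UNetConfig(depth=1, base_channels=2), seed=0)
        net.save(tmp_path / "ck.npz")
        net2 = build_unet(UNetConfig(depth=1, base_channels=2), seed=99)
        net2.load(tmp_path / "ck.npz")
        img = tiny_dataset[0][0]
        assert np.array_equal(predict_probmap(net, img), predict_probmap(net2, img))
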