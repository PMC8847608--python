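import numpy as np
import pytest

from groomdet.labels import LabelTrack
from groomdet.models import (AMSGrad, ConfigError, EpochPlan, ModelConfig,
                             SamplingError, Sequential, argmax_labels, augment,
                             build_cnn3d, build_crnn, build_model, load_model,
                             predict_probs, rotate_stack, sample_epoch,
                             save_model, softmax, softmax_cross_entropy, train)
from groomdet.models.nn import (LSTM, Conv3D, Dense, Flatten, MaxPool3D, ReLU)
from groomdet.models.training import TrainedModel

SMALL_CNN = dict(arch="cnn3d", w=10, input_side=32, conv_widths=(8, 16, 32, 32, 64),
                 fc_widths=(64, 32, 3), double_blocks=(), dropout=0.0,
                 learning_rate=3e-4)

SMALL_CRNN = dict(arch="crnn", w=10, input_side=32, conv_widths=(8, 16, 16),
                  fc_widths=(32, 16, 8, 8, 3), lstm_units=(16, 16), dropout=0.2)


def tiny_cnn_config(**overrides):
    return ModelConfig(**{**SMALL_CNN, **overrides})


class TestModelConfig:
    def test_paper_defaults_cnn3d(self):
        cfg = ModelConfig(arch="cnn3d")
        assert cfg.w == 40 and cfg.dropout == 0.50 and cfg.learning_rate == 3e-5
        assert cfg.input_shape == (81, 128, 128, 1)

    def test_paper_defaults_crnn(self):
        cfg = ModelConfig(arch="crnn")
        assert cfg.w == 10 and cfg.dropout == 0.20 and cfg.learning_rate == 1e-4
        assert cfg.input_shape == (21, 128, 128, 1)
        assert len(cfg.fc_widths) == 5 and len(cfg.lstm_units) == 2

    @pytest.mark.parametrize("bad", [
        {"dropout": 1.0}, {"learning_rate": 0.0}, {"fc_widths": (64, 4)},
        {"arch": "vgg"},
    ])
    def test_validation(self, bad):
        with pytest.raises(ConfigError):
            ModelConfig(**{**SMALL_CNN, **bad})

    def test_json_round_trip(self):
        cfg = tiny_cnn_config(seed=5)
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestBuildCnn3d:
    def test_small_forward_shapes(self, rng):
        cfg = tiny_cnn_config()
        net = build_cnn3d(cfg)
        x = rng.integers(0, 2, (2,) + cfg.input_shape).astype(np.float32)
        out = net.forward(x)
        assert out.shape == (2, 3)

    def test_full_scale_config_structure(self):
        cfg = ModelConfig(arch="cnn3d")  # w=40, S=128
        net = build_cnn3d(cfg)
        convs = [l for l in net.layers if isinstance(l, Conv3D)]
        # blocks 3-5 have a second conv layer
        assert len(convs) == 8
        assert all(c.kernel == (3, 3, 3) for c in convs)
        denses = [l for l in net.layers if isinstance(l, Dense)]
        assert [d.b.value.size for d in denses] == [512, 256, 3]
        assert cfg.input_shape == (81, 128, 128, 1)

    def test_input_too_small(self):
        with pytest.raises(ConfigError, match="halvings"):
            build_cnn3d(tiny_cnn_config(input_side=16))

    def test_softmax_normalized(self, rng):
        net = build_cnn3d(tiny_cnn_config())
        x = rng.random((3,) + tiny_cnn_config().input_shape).astype(np.float32)
        probs = softmax(net.forward(x))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_matches_hand_computation(self):
        net = build_cnn3d(tiny_cnn_config())
        # conv blocks: 27*cin*cout + cout, single conv per block
        expected = 0
        cin = 1
        for cout in (8, 16, 32, 32, 64):
            expected += 27 * cin * cout + cout
            cin = cout
        # temporal 21->21->10->5->2->1, spatial 32->1  => flatten = 64
        expected += 64 * 64 + 64   # fc1
        expected += 64 * 32 + 32   # fc2
        expected += 32 * 3 + 3     # head
        assert net.n_params() == expected == 106931


class TestBuildCrnn:
    def test_accepts_grouped_input(self, rng):
        cfg = ModelConfig(**SMALL_CRNN)
        net = build_crnn(cfg)
        x = rng.integers(0, 2, (2, 21, 32, 32, 1)).astype(np.float32)
        out = net.forward(x)
        assert out.shape == (2, 3)
        assert np.allclose(softmax(out).sum(axis=1), 1.0, atol=1e-6)

    def test_structure(self):
        net = build_crnn(ModelConfig(**SMALL_CRNN))
        lstms = [l for l in net.layers if isinstance(l, LSTM)]
        denses = [l for l in net.layers if isinstance(l, Dense)]
        assert len(lstms) == 2 and lstms[0].return_sequences and not lstms[1].return_sequences
        assert len(denses) == 5 and denses[-1].b.value.size == 3

    def test_deterministic_under_seed(self, rng):
        cfg = ModelConfig(**SMALL_CRNN, seed=3)
        x = rng.random((2, 21, 32, 32, 1)).astype(np.float32)
        out1 = build_crnn(cfg).forward(x)
        out2 = build_crnn(ModelConfig(**SMALL_CRNN, seed=3)).forward(x)
        assert np.array_equal(out1, out2)


class TestSampleEpoch:
    def test_default_plan_counts(self, rng):
        pool = np.tile([0, 1, 2], 50)
        idx = sample_epoch(pool, EpochPlan(), rng)
        assert idx.size == 1600
        tallies = np.bincount(pool[idx], minlength=3)
        assert tuple(tallies) == (1000, 200, 400)

    def test_tiny_plan(self, rng):
        pool = np.array([0, 1, 2])
        idx = sample_epoch(pool, EpochPlan(n_not=1, n_face=1, n_body=1, batch_size=1), rng)
        assert sorted(pool[idx]) == [0, 1, 2]

    def test_tallies_exact_over_many_seeds(self):
        pool = np.array([0] * 7 + [1] * 2 + [2] * 3)
        plan = EpochPlan(n_not=13, n_face=5, n_body=9, batch_size=4)
        for seed in range(100):
            idx = sample_epoch(pool, plan, np.random.default_rng(seed))
            assert tuple(np.bincount(pool[idx], minlength=3)) == (13, 5, 9)

    def test_missing_class_named_in_error(self, rng):
        with pytest.raises(SamplingError, match="facial grooming"):
            sample_epoch(np.array([0, 0, 2]), EpochPlan(), rng)

    def test_invalid_plan(self):
        with pytest.raises(ValueError):
            EpochPlan(n_not=0)


class TestAugment:
    def stack(self, rng, depth=5, side=16):
        return rng.integers(0, 2, (depth, side, side)).astype(np.uint8)

    def test_rotation_zero_is_identity(self, rng):
        s = self.stack(rng)
        assert np.array_equal(rotate_stack(s, 0), s)

    def test_flip_is_involution(self, rng):
        s = self.stack(rng)
        assert np.array_equal(s[:, :, ::-1][:, :, ::-1], s)
        assert np.array_equal(s[:, ::-1, :][:, ::-1, :], s)

    def test_rotation_180_equals_double_rot90(self, rng):
        s = self.stack(rng)
        expected = np.rot90(np.rot90(s, axes=(1, 2)), axes=(1, 2))
        assert np.array_equal(rotate_stack(s, 9), expected)

    def test_preserves_binarity_depth_and_is_deterministic(self, rng):
        s = self.stack(rng, depth=7)
        out1 = augment(s, np.random.default_rng(42))
        out2 = augment(s, np.random.default_rng(42))
        assert out1.shape == s.shape
        assert set(np.unique(out1)) <= {0, 1}
        assert np.array_equal(out1, out2)


def separable_dataset(rng, n_per_class=6, depth=21, side=32):
    """Trivially separable stacks: motion in a class-specific quadrant."""
    stacks, labels = [], []
    for cls in (0, 1, 2):
        for _ in range(n_per_class):
            s = np.zeros((depth, side, side), dtype=np.uint8)
            if cls == 1:
                s[:, 2:8, 2:8] = rng.integers(0, 2, (depth, 6, 6))
            elif cls == 2:
                s[:, 20:30, 20:30] = rng.integers(0, 2, (depth, 10, 10))
            stacks.append(s)
            labels.append(cls)
    return stacks, np.array(labels)


class TestTrain:
    def test_one_epoch_loss_history(self, rng):
        cfg = tiny_cnn_config()
        stacks, labels = separable_dataset(rng, n_per_class=4)
        plan = EpochPlan(n_not=4, n_face=3, n_body=3, batch_size=5)
        trained = train(build_model(cfg), (stacks, labels), plan, cfg, epochs=1)
        assert len(trained.loss_history) == 1
        assert np.isfinite(trained.loss_history[0])

    def test_loss_decreases_on_separable_data(self, rng):
        cfg = tiny_cnn_config(seed=1, learning_rate=1e-3)
        stacks, labels = separable_dataset(rng)
        plan = EpochPlan(n_not=8, n_face=8, n_body=8, batch_size=8)
        trained = train(build_model(cfg), (stacks, labels), plan, cfg, epochs=10)
        assert trained.loss_history[-1] < trained.loss_history[0]

    def test_reproducible_under_seed(self, rng):
        stacks, labels = separable_dataset(rng, n_per_class=3)
        plan = EpochPlan(n_not=3, n_face=3, n_body=3, batch_size=3)
        losses = []
        for _ in range(2):
            cfg = tiny_cnn_config(seed=7)
            trained = train(build_model(cfg), (stacks, labels), plan, cfg, epochs=2)
            losses.append(trained.loss_history)
        assert losses[0] == losses[1]

    def test_empty_data_rejected(self):
        cfg = tiny_cnn_config()
        with pytest.raises(ValueError):
            train(build_model(cfg), ([], np.array([])), EpochPlan(), cfg, 1)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    cfg = tiny_cnn_config(seed=2, learning_rate=1e-3)
    stacks, labels = separable_dataset(rng)
    plan = EpochPlan(n_not=6, n_face=6, n_body=6, batch_size=6)
    return train(build_model(cfg), (stacks, labels), plan, cfg, epochs=3), stacks


class TestPredict:

    def test_probability_simplex(self, trained):
        model, stacks = trained
        probs = predict_probs(model, stacks)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_inputs_identical(self, trained):
        model, stacks = trained
        probs = predict_probs(model, [stacks[0], stacks[0]])
        assert np.array_equal(probs[0], probs[1])

    def test_batch_partition_invariance(self, trained):
        model, stacks = trained
        all_at_once = predict_probs(model, stacks, batch_size=64)
        one_by_one = np.vstack([predict_probs(model, [s], batch_size=1) for s in stacks])
        assert np.allclose(all_at_once, one_by_one, atol=1e-5)

    def test_checkpoint_round_trip(self, trained, tmp_path):
        model, stacks = trained
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.config == model.config
        assert np.allclose(predict_probs(loaded, stacks[:3]),
                           predict_probs(model, stacks[:3]))


class TestArgmaxLabels:
    def test_plain_max(self):
        assert argmax_labels(np.array([[0.1, 0.7, 0.2]])).values[0] == 1

    def test_tie_breaks_to_lowest_index(self):
        assert argmax_labels(np.array([[0.4, 0.4, 0.2]])).values[0] == 0
        assert argmax_labels(np.array([[0.2, 0.4, 0.4]])).values[0] == 1

    def test_matches_brute_force_scan(self, rng):
        probs = rng.random((1000, 3))
        got = argmax_labels(probs).values
        for row, g in zip(probs, got):
            best, best_i = -1.0, 0
            for i, v in enumerate(row):
                if v > best:
                    best, best_i = v, i
            assert g == best_i


class TestGradients:
    def test_finite_difference_check(self):
        rng = np.random.default_rng(0)
        net = Sequential([
            Conv3D(1, 3, (3, 3, 3), rng=rng), ReLU(), MaxPool3D((1, 2, 2)),
            Conv3D(3, 4, (3, 3, 3), rng=rng), ReLU(), MaxPool3D((2, 2, 2)),
            Flatten(), Dense(4 * 2 * 2 * 2, 6, rng=rng), ReLU(), Dense(6, 3, rng=rng),
        ])
        for p in net.params():
            p.value = p.value.astype(np.float64)
        x = rng.random((3, 5, 8, 8, 1))
        y = np.eye(3)[rng.integers(0, 3, 3)]
        loss, dl = softmax_cross_entropy(net.forward(x), y)
        net.zero_grad()
        net.backward(dl)
        eps = 1e-6
        for p in net.params():
            for _ in range(5):
                idx = tuple(int(rng.integers(0, s)) for s in p.value.shape)
                old = p.value[idx]
                p.value[idx] = old + eps
                l1, _ = softmax_cross_entropy(net.forward(x), y)
                p.value[idx] = old - eps
                l2, _ = softmax_cross_entropy(net.forward(x), y)
                p.value[idx] = old
                numeric = (l1 - l2) / (2 * eps)
                assert p.grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_lstm_finite_difference_check(self):
        rng = np.random.default_rng(1)
        net = Sequential([LSTM(6, 5, return_sequences=True, rng=rng),
                          LSTM(5, 4, rng=rng), Dense(4, 3, rng=rng)])
        for p in net.params():
            p.value = p.value.astype(np.float64)
        x = rng.random((2, 7, 6))
        y = np.eye(3)[rng.integers(0, 3, 2)]
        loss, dl = softmax_cross_entropy(net.forward(x), y)
        net.zero_grad()
        net.backward(dl)
        eps = 1e-6
        for p in net.params():
            for _ in range(5):
                idx = tuple(int(rng.integers(0, s)) for s in p.value.shape)
                old = p.value[idx]
                p.value[idx] = old + eps
                l1, _ = softmax_cross_entropy(net.forward(x), y)
                p.value[idx] = old - eps
                l2, _ = softmax_cross_entropy(net.forward(x), y)
                p.value[idx] = old
                numeric = (l1 - l2) / (2 * eps)
                assert p.grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestAMSGrad:
    def test_converges_on_quadratic(self):
        from groomdet.models.nn import Param

        p = Param("x", np.array([5.0, -3.0]))
        opt = AMSGrad([p], lr=0.1)
        for _ in range(500):
            p.grad = 2 * p.value
            opt.step()
        assert np.abs(p.value).max() < 1e-2
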