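"""Network construction, gradients, the training recipe and prediction."""

import numpy as np
import pytest

from emgfusion.model import (ArchitectureConfig, CNNLSTM, TrainConfig,
                             build_model, lr_at_epoch, parameter_count,
                             predict_label, train, _softmax)


def _layer_arithmetic(arch):
    """Independent parameter-count oracle from layer shapes alone."""
    K, total, cin = arch.kernel_size, 0, arch.input_channels
    for f in arch.conv_filters:
        total += cin * f * K + f + 2 * f
        cin = f
    nin = arch.conv_filters[-1]
    for units in arch.lstm_units:
        total += 4 * (nin + units + 1) * units
        nin = units
    return total + nin * arch.n_classes + arch.n_classes


class TestArchitecture:
    @pytest.mark.parametrize("arch", [
        ArchitectureConfig(n_classes=7),
        ArchitectureConfig(n_classes=2),
        ArchitectureConfig(conv_filters=(8, 16), kernel_size=3,
                           lstm_units=(10, 5), n_classes=4),
        ArchitectureConfig(n_classes=7, topology_variant="lstm_last"),
    ])
    def test_parameter_count_matches_layer_arithmetic(self, arch):
        assert parameter_count(arch) == _layer_arithmetic(arch)

    def test_final_layer_width_equals_n_classes(self):
        model = build_model(ArchitectureConfig(n_classes=7))
        assert model.params["fc_W"].shape[1] == 7
        assert model.params["fc_b"].shape == (7,)

    @pytest.mark.parametrize("kwargs", [
        {"n_classes": 1}, {"dropout_rates": (1.0, 0.2)},
        {"topology_variant": "bidirectional"}])
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            ArchitectureConfig(**kwargs)

    @pytest.mark.parametrize("variant", ["paper_literal", "lstm_last",
                                         "gap_after_lstm"])
    def test_probability_rows_sum_to_one(self, variant, rng):
        model = build_model(ArchitectureConfig(
            n_classes=5, topology_variant=variant), seed=1)
        X = rng.standard_normal((6, 100, 4)).astype(np.float32)
        probs = model.predict_proba(X)
        assert probs.shape == (6, 5)
        np.testing.assert_allclose(probs.sum(axis=1), np.ones(6), atol=1e-6)


class TestLRSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (1, 0.002), (100, 0.002), (101, 0.0002), (200, 0.0002),
        (201, 0.00002), (300, 0.00002)])
    def test_piecewise_decay(self, epoch, expected):
        assert lr_at_epoch(TrainConfig(), epoch) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("epoch", [0, 301])
    def test_epoch_out_of_range(self, epoch):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), epoch)


class TestGradients:
    @pytest.mark.parametrize("variant", ["paper_literal", "lstm_last",
                                         "gap_after_lstm"])
    def test_backward_matches_numeric_gradient(self, variant):
        arch = ArchitectureConfig(input_channels=3, conv_filters=(4, 5),
                                  kernel_size=3, lstm_units=(6, 4),
                                  dropout_rates=(0, 0), n_classes=3,
                                  topology_variant=variant)
        rng = np.random.default_rng(0)
        model = CNNLSTM(arch, rng)
        # float64 + randomized biases keep the check away from ReLU kinks
        model.params = {k: v.astype(np.float64)
                        + 0.01 * rng.standard_normal(v.shape)
                        for k, v in model.params.items()}
        X = rng.standard_normal((4, 12, 3))
        y = np.array([0, 1, 2, 1])

        def loss():
            logits, _ = model._forward(X, train=False)
            p = _softmax(logits)
            return -np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))

        logits, cache = model._forward(X, train=False)
        p = _softmax(logits)
        d = p.copy()
        d[np.arange(len(y)), y] -= 1
        d /= len(y)
        grads = model._backward(d, cache)
        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for name, param in model.params.items():
            flat = param.ravel()
            for i in check_rng.choice(flat.size, size=min(5, flat.size),
                                      replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert num == pytest.approx(ana, abs=1e-7, rel=1e-4), name


@pytest.fixture(scope="module")
def toy_data():
    """Two bandpower-pattern classes, linearly separable."""
    rng = np.random.default_rng(3)
    X, y = [], []
    for cls, gains in enumerate([(1.0, 0.1, 0.1, 0.1), (0.1, 0.1, 0.1, 1.0)]):
        for _ in range(40):
            X.append(rng.standard_normal((80, 4)) * np.asarray(gains))
            y.append(cls)
    return np.asarray(X, dtype=np.float32), np.asarray(y)


class TestTraining:
    def test_loss_decreases_and_fits(self, toy_data):
        X, y = toy_data
        arch = ArchitectureConfig(conv_filters=(8, 8), lstm_units=(8, 8),
                                  dropout_rates=(0, 0), n_classes=2)
        cfg = TrainConfig(max_epochs=15, seed=0, validation_fraction=0.0)
        model = build_model(arch, 0)
        _, log = train(model, X, y, cfg)
        smoothed = np.convolve(log.epoch_loss, np.ones(3) / 3, mode="valid")
        assert smoothed[-1] < smoothed[0]
        acc = np.mean(predict_label(model.predict_proba(X)) == y)
        assert acc > 0.9

    def test_log_follows_schedule_and_batch_arithmetic(self, toy_data):
        X, y = toy_data
        cfg = TrainConfig(max_epochs=4, seed=1, validation_fraction=0.1,
                          validation_period=2)
        arch = ArchitectureConfig(conv_filters=(4, 4), lstm_units=(4, 4),
                                  n_classes=2)
        model = build_model(arch, 1)
        _, log = train(model, X, y, cfg)
        assert log.epoch_lr == [lr_at_epoch(cfg, e) for e in range(1, 5)]
        n_train = len(X) - 2 * round(0.1 * 40)
        batches_per_epoch = int(np.ceil(n_train / cfg.batch_size))
        # validation ran at every validation_period-th iteration
        total_iters = 4 * batches_per_epoch
        assert len(log.val_checks) == total_iters // cfg.validation_period

    def test_reproducible_given_seed(self, toy_data):
        X, y = toy_data
        cfg = TrainConfig(max_epochs=2, seed=7)
        arch = ArchitectureConfig(conv_filters=(4, 4), lstm_units=(4, 4),
                                  n_classes=2)
        m1, _ = train(build_model(arch), X, y, cfg)
        m2, _ = train(build_model(arch), X, y, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_label_out_of_range_and_empty_set(self, toy_data):
        X, y = toy_data
        arch = ArchitectureConfig(n_classes=2)
        with pytest.raises(ValueError, match="labels"):
            train(build_model(arch), X, y + 1, TrainConfig(max_epochs=1))
        with pytest.raises(ValueError, match="empty"):
            train(build_model(arch), X[:0], y[:0], TrainConfig(max_epochs=1))


class TestPrediction:
    def test_permuting_inputs_permutes_outputs(self, rng):
        model = build_model(ArchitectureConfig(n_classes=3), seed=2)
        X = rng.standard_normal((8, 90, 4)).astype(np.float32)
        perm = rng.permutation(8)
        np.testing.assert_allclose(model.predict_proba(X)[perm],
                                   model.predict_proba(X[perm]), atol=1e-6)

    def test_deterministic_at_inference(self, rng):
        model = build_model(ArchitectureConfig(n_classes=3), seed=2)
        X = rng.standard_normal((4, 90, 4)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_proba(X),
                                      model.predict_proba(X))

    def test_shape_mismatch(self, rng):
        model = build_model(ArchitectureConfig(n_classes=3))
        with pytest.raises(ValueError):
            model.predict_proba(rng.standard_normal((4, 90, 3)))

    def test_predict_label_ties_and_oracle(self, rng):
        assert predict_label(np.array([[0.1, 0.7, 0.2]]))[0] == 1
        assert predict_label(np.array([[0.5, 0.5]]))[0] == 0
        scores = rng.random((50, 4))
        brute = [max(range(4), key=lambda k: (row[k], -k)) for row in scores]
        np.testing.assert_array_equal(predict_label(scores), brute)

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            predict_label(np.empty((0, 3)))


def test_save_load_roundtrip(tmp_path, rng):
    model = build_model(ArchitectureConfig(n_classes=4), seed=5)
    X = rng.standard_normal((3, 100, 4)).astype(np.float32)
    model.save(tmp_path / "model")
    again = CNNLSTM.load(tmp_path / "model")
    np.testing.assert_array_equal(model.predict_proba(X),
                                  again.predict_proba(X))
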