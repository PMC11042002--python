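"""Training loop: SGD-with-momentum semantics, early stopping, determinism."""

import numpy as np
import pytest

from diatomnet import archspec as A
from diatomnet import engine as E
from diatomnet import network as N
from diatomnet import training as T

from conftest import tiny_toy_spec


def _toy_data(n=12, num_classes=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 14, 12, 2)).astype(np.float32)
    y = rng.integers(0, num_classes, size=n)
    return X, y


class TestDeterminism:
    def test_same_seed_and_data_give_identical_logs(self):
        X, y = _toy_data()
        logs = []
        for _ in range(2):
            net = N.build_network(tiny_toy_spec(), seed=1)
            cfg = T.TrainConfig(learning_rate=1e-2, batch_size=4, max_epochs=4, seed=5)
            _, log = T.train_arrays(net, X[:8], y[:8], X[8:], y[8:], cfg)
            logs.append(log)
        assert logs[0].train_loss == logs[1].train_loss
        assert logs[0].val_loss == logs[1].val_loss
        assert logs[0].best_epoch == logs[1].best_epoch


class TestOptimizerSemantics:
    def test_momentum_zero_equals_plain_gradient_descent(self):
        """One zero-momentum update must equal w - lr * grad, with the gradient
        cross-checked against central finite differences (<=1e-4 relative)."""
        spec = tiny_toy_spec()
        net = N.build_network(spec, seed=4, dtype=np.float64)
        # keep pre-activations off the ReLU kink for clean finite differences
        rng = np.random.default_rng(0)
        for k, v in net.parameter_store().items():
            if k.endswith("b"):
                v[...] = rng.standard_normal(v.shape) * 0.1
        X, y = _toy_data(n=4, seed=2)
        xb = net._to_input_batch(X)

        before = net.copy_parameters()
        net.zero_grads()
        logits = net.forward_logits(xb, training=False)
        _, dl = E.softmax_cross_entropy(logits, y)
        net.backward_logits(dl)
        grads = {
            f"{lab}/{nm}": g.copy() for lab, obj in net.layers for nm, g in obj.grads.items()
        }

        # finite-difference spot check of the gradient used by the update
        def loss_at():
            return E.softmax_cross_entropy(net.forward_logits(xb, training=False), y)[0]

        eps = 1e-6
        rngp = np.random.default_rng(1)
        store = net.parameter_store()
        for key in ("c1/W", "i1/b2.W", "fc/W", "fc/b"):
            flat = store[key].ravel()
            for i in rngp.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_at()
                flat[i] = old - eps
                lm = loss_at()
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[key].ravel()[i]) <= 1e-4 * max(1.0, abs(fd))

        cfg = T.TrainConfig(learning_rate=1e-3, momentum=0.0, batch_size=4, max_epochs=1, seed=3, shuffle_each_epoch=False)
        net2 = N.build_network(spec, seed=4, dtype=np.float64)
        net2.load_parameters(before)
        T.train_arrays(net2, X, y, X, y, cfg)
        after = net2.parameter_store()
        for key, w0 in before.items():
            np.testing.assert_allclose(after[key], w0 - 1e-3 * grads[key], rtol=1e-10, atol=1e-12)

    def test_one_sample_overfit_loss_strictly_decreases(self):
        net = N.build_network(tiny_toy_spec(), seed=0, dtype=np.float64)
        X, y = _toy_data(n=1, seed=7)
        cfg = T.TrainConfig(learning_rate=5e-2, momentum=0.0, batch_size=1, max_epochs=5, seed=0)
        _, log = T.train_arrays(net, X, y, X, y, cfg)
        losses = log.train_loss
        assert len(losses) == 5
        assert all(b < a for a, b in zip(losses, losses[1:]))


class TestEarlyStopping:
    def test_stops_patience_epochs_after_best(self):
        net = N.build_network(tiny_toy_spec(), seed=0)
        X, y = _toy_data()
        # an impossible improvement threshold freezes the best epoch at 1
        cfg = T.TrainConfig(
            learning_rate=1e-5, batch_size=4, max_epochs=50, patience=2, min_delta=1e9, seed=0
        )
        _, log = T.train_arrays(net, X[:8], y[:8], X[8:], y[8:], cfg)
        assert log.best_epoch == 0 or log.best_epoch == 1
        assert log.stopped_epoch == 1 + cfg.patience

    def test_best_epoch_weights_are_restored(self):
        net = N.build_network(tiny_toy_spec(), seed=3)
        X, y = _toy_data(n=16, seed=9)
        cfg = T.TrainConfig(learning_rate=5e-2, batch_size=4, max_epochs=6, seed=1)
        net, log = T.train_arrays(net, X[:10], y[:10], X[10:], y[10:], cfg)
        xb = net._to_input_batch(X[10:])
        logits = net.forward_logits(xb, training=False)
        loss, _ = E.softmax_cross_entropy(logits, y[10:])
        assert loss == pytest.approx(log.val_loss[log.best_epoch - 1], abs=1e-6)

    def test_validation_accuracy_goal_stops_training(self):
        net = N.build_network(tiny_toy_spec(), seed=0)
        X, y = _toy_data()
        cfg = T.TrainConfig(learning_rate=1e-4, batch_size=4, max_epochs=30, seed=0, val_accuracy_goal=0.0)
        _, log = T.train_arrays(net, X[:8], y[:8], X[8:], y[8:], cfg)
        assert log.stopped_epoch == 1  # any accuracy satisfies a zero goal


class TestFailureModes:
    def test_non_finite_loss_aborts_with_location(self):
        net = N.build_network(tiny_toy_spec(), seed=0)
        X, y = _toy_data()
        cfg = T.TrainConfig(learning_rate=1e12, batch_size=4, max_epochs=10, seed=0)
        with pytest.raises(RuntimeError, match="epoch"):
            with np.errstate(all="ignore"):
                T.train_arrays(net, X[:8], y[:8], X[8:], y[8:], cfg)

    def test_empty_split_rejected(self):
        net = N.build_network(tiny_toy_spec(), seed=0)
        X, y = _toy_data()
        cfg = T.TrainConfig()
        with pytest.raises(ValueError, match="nonempty"):
            T.train_arrays(net, X[:0], y[:0], X, y, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            T.TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            T.TrainConfig(momentum=1.0)


class TestLogIO:
    def test_curve_file_round_trips_epoch_count(self, tmp_path):
        net = N.build_network(tiny_toy_spec(), seed=0)
        X, y = _toy_data()
        cfg = T.TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=3, seed=0)
        _, log = T.train_arrays(net, X[:8], y[:8], X[8:], y[8:], cfg)
        path = tmp_path / "curves.csv"
        log.write_csv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 3 + 1  # header + epochs + stop summary
        assert lines[-1].startswith("# stopped_epoch=3")
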