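"""Model zoo: architecture contracts, losses, training behavior."""

import numpy as np
import pytest

from mcrepeat.mc import MCConfig, aggregate, mc_forward
from mcrepeat.models import (
    ModelSpec,
    TrainConfig,
    bce_with_logits,
    build_model,
    coral_loss,
    cross_entropy,
    load_checkpoint,
    mse_loss,
    save_checkpoint,
    train,
)
from mcrepeat.scoring import HeadKind, encode_ordinal_label
from tests.conftest import train_tiny


class TestBuildModel:
    @pytest.mark.parametrize("kind, k, width", [
        ("binary", 2, 1), ("multiclass", 3, 3), ("ordinal", 5, 4), ("regression", 3, 1),
    ])
    def test_head_output_widths(self, kind, k, width):
        model = build_model(ModelSpec(head=HeadKind(kind, k), input_size=16))
        x = np.zeros((2, 1, 16, 16), dtype=np.float32)
        assert model.forward_logits(x).shape == (2, width)

    def test_ordinal_head_requires_k_of_three(self):
        with pytest.raises(ValueError):
            HeadKind("ordinal", 2)

    def test_no_dropout_variant_has_no_dropout_layers(self):
        plain = build_model(ModelSpec(head=HeadKind("multiclass", 3), dropout_rate=None))
        assert not plain.has_dropout
        mc = build_model(ModelSpec(head=HeadKind("multiclass", 3), dropout_rate=0.1))
        assert mc.has_dropout

    def test_zero_rate_model_is_deterministic_under_mc(self):
        model = build_model(ModelSpec(head=HeadKind("multiclass", 3),
                                      dropout_rate=0.0, input_size=16))
        img = np.random.default_rng(0).uniform(0, 1, (1, 16, 16)).astype(np.float32)
        preds = mc_forward(model, img, MCConfig(n_samples=6, seed=0))
        assert np.allclose(preds.draws, preds.draws[0], rtol=1e-6)

    def test_channel_dropout_zeroes_expected_fraction(self):
        from mcrepeat.nn import ChannelDropout

        rate = 0.3
        layer = ChannelDropout(rate)
        rng = np.random.default_rng(0)
        x = np.ones((100, 100, 2, 2), dtype=np.float32)
        zeroed = []
        for _ in range(10):
            out = layer.forward(x, stochastic=True, rng=rng)
            zeroed.append((out[:, :, 0, 0] == 0).mean())
        m = np.mean(zeroed)
        sigma = np.sqrt(rate * (1 - rate) / (100 * 100 * 10))
        assert abs(m - rate) < 4 * sigma + 1e-3

    def test_dropout_zeroes_whole_channels(self):
        from mcrepeat.nn import ChannelDropout

        layer = ChannelDropout(0.5)
        rng = np.random.default_rng(1)
        x = np.ones((4, 8, 5, 5), dtype=np.float32)
        out = layer.forward(x, stochastic=True, rng=rng)
        per_channel = out.reshape(4, 8, -1)
        # each channel is either fully zero or fully scaled
        assert all(len(np.unique(per_channel[b, c])) == 1
                   for b in range(4) for c in range(8))


class TestLosses:
    def test_coral_all_zero_logits_closed_form(self):
        k = 5
        logits = np.zeros((1, k - 1))
        target = encode_ordinal_label(2, k)[None]
        loss, _ = coral_loss(logits, target)
        assert loss == pytest.approx((k - 1) * np.log(2))

    def test_coral_confident_correct_logits_vanish(self):
        target = encode_ordinal_label(1, 3)[None]
        logits = np.array([[30.0, -30.0]])
        loss, _ = coral_loss(logits, target)
        assert loss == pytest.approx(0.0, abs=1e-10)

    def test_bce_matches_cross_entropy_on_binary(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(16, 1))
        y = rng.integers(0, 2, size=(16, 1)).astype(float)
        loss, _ = bce_with_logits(z, y)
        two_class = np.hstack([np.zeros_like(z), z])
        ce, _ = cross_entropy(two_class, y.ravel().astype(int))
        assert loss == pytest.approx(ce, rel=1e-9)

    def test_mse_value_and_gradient(self):
        loss, grad = mse_loss(np.array([[1.0], [3.0]]), np.array([0.0, 3.0]))
        assert loss == pytest.approx(0.5)
        np.testing.assert_allclose(grad, [[1.0], [0.0]])

    @pytest.mark.parametrize("loss_fn, make_target", [
        (cross_entropy, lambda rng: rng.integers(0, 3, 8)),
        (bce_with_logits, lambda rng: rng.integers(0, 2, (8, 1)).astype(float)),
    ])
    def test_gradients_match_finite_differences(self, loss_fn, make_target):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(8, 3)) if loss_fn is cross_entropy else rng.normal(size=(8, 1))
        t = make_target(rng)
        loss, grad = loss_fn(z, t)
        eps = 1e-6
        for idx in [(0, 0), (3, z.shape[1] - 1)]:
            zp = z.copy()
            zp[idx] += eps
            lp, _ = loss_fn(zp, t)
            assert grad[idx] == pytest.approx((lp - loss) / eps, rel=1e-3, abs=1e-6)


class TestTraining:
    def test_one_epoch_smoke_returns_finite_losses(self, tiny_dataset):
        model, hist = train_tiny(tiny_dataset, epochs=1)
        assert len(hist.train_loss) == 1
        assert np.isfinite(hist.train_loss[0]) and np.isfinite(hist.val_loss[0])

    def test_empty_validation_split_rejected(self, tiny_dataset):
        x, y, _ = tiny_dataset.split("train")
        model = build_model(ModelSpec(head=HeadKind("multiclass", 3), input_size=16))
        with pytest.raises(ValueError):
            train(model, x, y, x[:0], y[:0], TrainConfig(epochs=1))

    def test_fixed_seed_training_is_bitwise_reproducible(self, tiny_dataset):
        m1, h1 = train_tiny(tiny_dataset, epochs=2, seed=5)
        m2, h2 = train_tiny(tiny_dataset, epochs=2, seed=5)
        assert h1.train_loss == h2.train_loss
        for a, b in zip(m1.get_state(), m2.get_state()):
            np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("kind", ["binary", "multiclass", "ordinal", "regression"])
    @pytest.mark.parametrize("dropout", [0.1, None])
    def test_all_eight_variants_train_through_one_switch(self, tiny_dataset, kind, dropout):
        model, hist = train_tiny(tiny_dataset, kind=kind, dropout_rate=dropout, epochs=1)
        assert np.isfinite(hist.val_loss[-1])
        assert model.has_dropout == (dropout is not None)

    def test_multiclass_learns_above_chance(self, tiny_dataset):
        """The severity signal is learnable: held-out accuracy on the tiny
        benchmark clearly exceeds the 1/3 chance level."""
        model, _ = train_tiny(tiny_dataset, epochs=20, seed=1)
        x_te, y_te, _ = tiny_dataset.split("test")
        acc = (model.forward_logits(x_te).argmax(1) == y_te).mean()
        assert acc > 0.5

    def test_coral_outputs_are_rank_monotone_after_training(self, tiny_dataset):
        model, _ = train_tiny(tiny_dataset, kind="ordinal", epochs=5, seed=2)
        # shared weight vector: monotonicity holds iff biases are descending
        head_layer = model.net.layers[-1]
        assert np.all(np.diff(head_layer.b) <= 0)
        x_te, _, _ = tiny_dataset.split("test")
        q = model.predict(x_te)
        assert np.all(np.diff(q, axis=1) <= 1e-7)

    def test_scheduler_reduces_lr_on_plateau(self):
        from mcrepeat.nn import Adam, ReduceLROnPlateau

        opt = Adam([np.zeros(1)], lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=2)
        for loss in [1.0, 1.0, 1.0, 1.0]:
            sched.step(loss)
        assert opt.lr == pytest.approx(0.1)


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tiny_dataset, tmp_path):
        model, _ = train_tiny(tiny_dataset, epochs=1)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path, TrainConfig(epochs=1))
        loaded, cfg = load_checkpoint(path)
        assert cfg.epochs == 1
        x_te, _, _ = tiny_dataset.split("test")
        np.testing.assert_array_equal(model.forward_logits(x_te), loaded.forward_logits(x_te))

    def test_patient_level_split_discipline(self, tiny_dataset):
        man = tiny_dataset.manifest
        per_patient_splits = man.groupby("patient_id")["split"].nunique()
        assert (per_patient_splits == 1).all()
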