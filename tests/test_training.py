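"""Schedule exactness, pretraining mechanics, fine-tuning behaviour."""

import math

import numpy as np
import pytest

from ecgmae.model import (DecoderConfig, EncoderConfig, MAEModel, attach_head,
                          build_model, mae_loss)
from ecgmae.patching import make_mask_batch
from ecgmae.training import (FinetuneConfig, PretrainConfig, TrainState,
                             finetune, pretrain, scheduler_step)


def run_schedule(losses, lr0=1.0):
    """Feed a scripted loss sequence; returns per-epoch states."""
    state = TrainState(lr=lr0)
    states = []
    for loss in losses:
        state = scheduler_step(state, loss)
        states.append(state)
        if state.stop:
            break
    return states


class TestSchedulerStep:
    def test_single_halving_after_three_flat_epochs(self):
        states = run_schedule([1.0, 0.9, 0.95, 0.96, 0.97])
        assert [s.lr for s in states] == [1.0, 1.0, 1.0, 1.0, 0.5]
        assert states[-1].best_loss == 0.9
        assert not states[-1].stop

    def test_strictly_decreasing_never_halves_or_stops(self):
        losses = list(1.0 - 0.009 * np.arange(100))
        states = run_schedule(losses)
        assert len(states) == 100
        assert all(s.lr == 1.0 for s in states)
        assert not states[-1].stop
        assert states[-1].best_epoch == 100

    def test_stop_after_ten_non_improving_epochs(self):
        states = run_schedule([0.9] + [1.0] * 12)
        assert len(states) == 11  # stops on the 10th bad epoch
        assert states[-1].stop
        assert states[-1].best_loss == 0.9
        assert states[-1].best_epoch == 1
        # halvings at multiples of 3: epochs 4, 7, 10 of the run
        assert states[-1].lr == pytest.approx(1.0 / 8)

    def test_tie_is_a_non_improvement(self):
        states = run_schedule([0.5, 0.5, 0.5, 0.5])
        assert states[-1].since_improve == 3
        assert states[-1].lr == 0.5
        assert states[-1].best_epoch == 1

    def test_improvement_resets_counter(self):
        states = run_schedule([1.0, 1.1, 1.1, 0.5, 1.2, 1.2])
        assert states[3].since_improve == 0
        assert states[3].improved
        assert states[-1].since_improve == 2

    def test_counter_restarts_after_late_improvement(self):
        # 2 bad, improve, then 3 bad -> only one halving (after the last 3)
        states = run_schedule([1.0, 1.2, 1.2, 0.8, 0.9, 0.9, 0.9])
        assert states[-1].lr == 0.5
        assert states[-1].best_loss == 0.8


def _toy_data(rng, n=24, signal=3.0):
    """Patch stacks whose class signal is a mean shift in lead II."""
    labels = (np.arange(n) % 2).astype(float)
    stacks = rng.normal(size=(n, 240, 250)).astype(np.float32)
    stacks[labels == 1, 20:40, :] += signal
    return stacks, labels[:, None]


@pytest.fixture(scope="module")
def micro_mae():
    enc = EncoderConfig("m", embed_dim=32, depth=2, n_heads=2)
    dec = DecoderConfig(embed_dim=16, depth=1, n_heads=2)
    return MAEModel(enc, dec, seed=0)


class TestPretrain:
    def test_zero_epochs_leaves_model_unchanged(self, micro_mae, rng):
        stack = rng.normal(size=(4, 240, 250)).astype(np.float32)
        before = micro_mae.copy_values()
        history = pretrain(micro_mae, stack,
                           PretrainConfig(epochs=0, batch_size=2))
        assert history == []
        for b, p in zip(before, micro_mae.params()):
            np.testing.assert_array_equal(b, p.value)

    def test_same_seed_reproduces_history(self, rng):
        stack = rng.normal(size=(8, 240, 250)).astype(np.float32)
        cfg = PretrainConfig(epochs=2, batch_size=4, warmup_epochs=1, seed=5)
        hists = []
        for _ in range(2):
            enc = EncoderConfig("m", embed_dim=32, depth=1, n_heads=2)
            dec = DecoderConfig(embed_dim=16, depth=1, n_heads=2)
            hists.append(pretrain(MAEModel(enc, dec, seed=1), stack, cfg))
        assert hists[0] == hists[1]

    def test_repeated_steps_reduce_loss_on_fixed_batch(self, rng):
        """Gradient sanity: optimizing one batch drives its loss down."""
        enc = EncoderConfig("m", embed_dim=32, depth=1, n_heads=2)
        dec = DecoderConfig(embed_dim=16, depth=1, n_heads=2)
        model = MAEModel(enc, dec, seed=2)
        # smooth periodic records: masked patches are predictable from context
        t = np.arange(5000) / 500.0
        sigs = np.stack([
            np.outer(rng.normal(size=12), np.sin(2 * np.pi * f * t))
            for f in (1.0, 1.3, 1.7, 2.1)
        ])
        stack = sigs.reshape(4, 12, 20, 250).reshape(4, 240, 250)
        stack = stack.astype(np.float32)
        from ecgmae import nn

        params = model.params()
        opt = nn.AdamW(params, lr=1e-2, betas=(0.9, 0.95), weight_decay=0.05)
        vis = make_mask_batch(4, 0.75, "random", 0)
        maskb = np.ones((4, 240), dtype=bool)
        maskb[np.arange(4)[:, None], vis] = False
        losses = []
        for _ in range(50):
            pred = model.forward_batch(stack, vis)
            loss, grad = mae_loss(pred, stack, maskb, return_grad=True)
            opt.zero_grad()
            model.backward_batch(grad)
            nn.clip_grad_norm(params, 1.0)
            opt.step()
            losses.append(loss)
        assert losses[-1] < 0.85 * losses[0]

    def test_empty_record_set_rejected(self, micro_mae):
        with pytest.raises(ValueError):
            pretrain(micro_mae, np.empty((0, 240, 250), np.float32),
                     PretrainConfig(epochs=1))


class TestFinetune:
    def test_zero_epochs_returns_initial_weights(self, micro_mae, rng):
        clf = attach_head(micro_mae, 1, seed=0, copy=True)
        before = clf.copy_values()
        x, y = _toy_data(rng, n=8)
        clf, hist = finetune(clf, x, y, x, y,
                             FinetuneConfig(max_epochs=0))
        assert hist["val_loss"] == []
        for b, p in zip(before, clf.params()):
            np.testing.assert_array_equal(b, p.value)

    def test_single_class_warns_but_proceeds(self, micro_mae, rng):
        clf = attach_head(micro_mae, 1, seed=0, copy=True)
        x = rng.normal(size=(6, 240, 250)).astype(np.float32)
        y = np.ones((6, 1))
        with pytest.warns(UserWarning):
            _, hist = finetune(clf, x, y, x, y,
                               FinetuneConfig(max_epochs=1, batch_size=3))
        assert len(hist["val_loss"]) == 1

    def test_empty_training_set_rejected(self, micro_mae):
        clf = attach_head(micro_mae, 1, seed=0, copy=True)
        with pytest.raises(ValueError):
            finetune(clf, np.empty((0, 240, 250), np.float32),
                     np.empty((0, 1)), np.empty((0, 240, 250), np.float32),
                     np.empty((0, 1)), FinetuneConfig(max_epochs=1))

    def test_learns_a_strong_toy_signal(self, rng):
        from ecgmae.stats import auroc

        enc = EncoderConfig("m", embed_dim=32, depth=1, n_heads=2)
        dec = DecoderConfig(embed_dim=16, depth=1, n_heads=2)
        clf = attach_head(MAEModel(enc, dec, seed=3), 1, seed=3)
        xtr, ytr = _toy_data(rng, n=24)
        xva, yva = _toy_data(rng, n=12)
        xte, yte = _toy_data(rng, n=12)
        clf, hist = finetune(clf, xtr, ytr, xva, yva,
                             FinetuneConfig(batch_size=8, lr=1e-3,
                                            max_epochs=12, seed=0))
        scores = clf.predict_proba(xte)[:, 0]
        assert auroc(scores, yte[:, 0].astype(int)) >= 0.9

    def test_restores_best_epoch_weights(self, micro_mae, rng):
        clf = attach_head(micro_mae, 1, seed=1, copy=True)
        x, y = _toy_data(rng, n=8)
        clf, hist = finetune(clf, x, y, x, y,
                             FinetuneConfig(batch_size=4, lr=1e-3,
                                            max_epochs=6, seed=0))
        best = hist["best_epoch"]
        assert best >= 1
        assert min(hist["val_loss"]) == hist["val_loss"][best - 1]
        # returned classifier reproduces the best validation loss
        assert clf.bce_loss(x, y) == pytest.approx(min(hist["val_loss"]),
                                                   rel=1e-5)

    def test_grid_search_selects_lowest_val_loss_cell(self, micro_mae, rng):
        from ecgmae.training import finetune_grid

        x, y = _toy_data(rng, n=16)

        def factory():
            return attach_head(micro_mae, 1, seed=4, copy=True)

        clf, cfg, hist = finetune_grid(
            factory, x, y, x, y,
            batch_grid=(8,), lr_grid=(1e-3, 1e-7), max_epochs=2, seed=0)
        # the effectively-frozen 1e-7 cell cannot beat the learning cell
        assert cfg.lr == 1e-3
        assert min(hist["val_loss"]) <= 0.75

    def test_cls_pooling_head_runs(self, micro_mae, rng):
        clf = attach_head(micro_mae, 1, pool="cls", seed=0, copy=True)
        x, y = _toy_data(rng, n=4)
        p = clf.predict_proba(x)
        assert p.shape == (4, 1)
        assert np.isfinite(p).all()

    def test_paper_lr_scaling_rule(self):
        cfg = PretrainConfig(batch_size=256, base_lr=1.5e-4)
        assert cfg.lr == pytest.approx(1.5e-4)
        assert PretrainConfig(batch_size=512, base_lr=1.5e-4).lr == \
            pytest.approx(3e-4)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FinetuneConfig(stop_patience=2, plateau_patience=3)
        with pytest.raises(ValueError):
            FinetuneConfig(plateau_patience=0)
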