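"""Losses, inner-loop adaptation arithmetic, meta-gradient correctness on toy
quadratic task families, and trainer reductions/equivalences."""

import numpy as np
import pytest

from cryoice import autodiff as ad
from cryoice import meta as mt
from cryoice.meta import (MetaConfig, finetune_kshot, inner_adapt, meta_loss,
                          meta_step, meta_train, segmentation_loss,
                          train_supervised)
from cryoice.model import build_model
from cryoice.synthetic import make_task

from conftest import make_quad_task, make_quad_theta, quad_loss

RNG = np.random.default_rng(1)


class TestSegmentationLoss:
    def test_saturated_logits_near_zero_loss(self):
        mask = (RNG.uniform(size=(8, 8)) > 0.7).astype(float)
        logits = ad.Tensor(np.where(mask > 0, 50.0, -50.0))
        assert segmentation_loss(logits, ad.Tensor(mask), "bce").item() < 1e-3
        assert segmentation_loss(logits, ad.Tensor(mask), "dice").item() < 1e-3

    def test_zero_logits_bce_is_ln2(self):
        logits = ad.Tensor(np.zeros((10, 10)))
        mask = ad.Tensor((RNG.uniform(size=(10, 10)) > 0.5).astype(float))
        got = segmentation_loss(logits, mask, "bce").item()
        assert got == pytest.approx(np.log(2.0), rel=1e-12)

    def test_matches_independent_recomputation(self):
        logits = RNG.normal(size=(6, 6))
        y = (RNG.uniform(size=(6, 6)) > 0.6).astype(float)
        sig = 1.0 / (1.0 + np.exp(-logits))
        bce_ref = float(np.mean(-y * np.log(sig) - (1 - y) * np.log1p(-sig)))
        dice_ref = 1.0 - (2 * (sig * y).sum() + 1.0) / (sig.sum() + y.sum() + 1.0)
        lt, yt = ad.Tensor(logits), ad.Tensor(y)
        assert segmentation_loss(lt, yt, "bce").item() == pytest.approx(
            bce_ref, rel=1e-10)
        assert segmentation_loss(lt, yt, "dice").item() == pytest.approx(
            dice_ref, rel=1e-10)
        assert segmentation_loss(lt, yt, "bce_plus_dice").item() == pytest.approx(
            bce_ref + dice_ref, rel=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            segmentation_loss(ad.Tensor(np.zeros((4, 4))),
                              ad.Tensor(np.zeros((5, 5))), "bce")


class TestInnerAdapt:
    def test_zero_steps_is_identity(self):
        theta = make_quad_theta([0.0])
        cfg = MetaConfig(inner_steps=0)
        res = inner_adapt(theta, [np.array([3.0])], cfg, loss_fn=quad_loss)
        assert np.array_equal(res.phi.params["w"].data, theta.params["w"].data)
        assert len(res.support_loss_trace) == 1

    def test_one_step_quadratic_by_hand(self):
        """L(w) = (w-3)^2, w0 = 0, lr 0.1: w1 = 0 - 0.1*(-6) = 0.6."""
        theta = make_quad_theta([0.0])
        cfg = MetaConfig(inner_lr=0.1, inner_steps=1)
        res = inner_adapt(theta, [np.array([3.0])], cfg, loss_fn=quad_loss)
        assert res.phi.params["w"].data[0] == pytest.approx(0.6, rel=1e-12)

    def test_two_steps_quadratic_by_hand(self):
        """Iterating w <- w - 0.1*2*(w-3): 0 -> 0.6 -> 1.08."""
        theta = make_quad_theta([0.0])
        cfg = MetaConfig(inner_lr=0.1, inner_steps=2)
        res = inner_adapt(theta, [np.array([3.0])], cfg, loss_fn=quad_loss)
        assert res.phi.params["w"].data[0] == pytest.approx(1.08, rel=1e-12)
        assert len(res.support_loss_trace) == 3
        # trace records L at w = 0, 0.6, 1.08
        np.testing.assert_allclose(res.support_loss_trace,
                                   [9.0, 5.76, 3.6864], rtol=1e-12)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            inner_adapt(make_quad_theta([0.0]), [], MetaConfig(),
                        loss_fn=quad_loss)


class TestMetaStep:
    def _plain_query_step(self, theta, tasks, cfg):
        """Reference: one gradient step on the mean query loss (no adaptation),
        built with the same op sequence as the meta objective."""
        total = None
        for t in tasks:
            q = quad_loss(theta, t.query)
            total = q if total is None else total + q
        total = total * (1.0 / len(tasks))
        grads = ad.grad(total, [theta.params["w"]])
        return theta.params["w"].data - cfg.outer_lr * grads[0].data

    def test_zero_inner_steps_reduces_to_plain_gradient_step(self):
        theta = make_quad_theta([1.0, -2.0])
        tasks = [make_quad_task([0.0, 0.0], [3.0, 1.0]),
                 make_quad_task([1.0, 1.0], [-1.0, 2.0])]
        for second in (False, True):
            cfg = MetaConfig(inner_steps=0, outer_lr=0.05, second_order=second)
            new = meta_step(theta, tasks, cfg, loss_fn=quad_loss)
            ref = self._plain_query_step(theta, tasks, cfg)
            assert np.array_equal(new.params["w"].data, ref)

    def test_zero_inner_lr_equals_zero_steps(self):
        theta = make_quad_theta([1.0])
        tasks = [make_quad_task([0.0], [3.0])]
        a = meta_step(theta, tasks, MetaConfig(inner_steps=3, inner_lr=0.0,
                                               outer_lr=0.05,
                                               second_order=True),
                      loss_fn=quad_loss)
        b = meta_step(theta, tasks, MetaConfig(inner_steps=0, outer_lr=0.05,
                                               second_order=True),
                      loss_fn=quad_loss)
        assert np.array_equal(a.params["w"].data, b.params["w"].data)

    def test_first_and_second_order_differ_with_adaptation(self):
        theta = make_quad_theta([1.0, -1.0])
        tasks = [make_quad_task([0.5, 2.0], [3.0, 1.0])]
        kw = dict(inner_steps=2, inner_lr=0.1, outer_lr=0.1)
        fo = meta_step(theta, tasks, MetaConfig(second_order=False, **kw),
                       loss_fn=quad_loss)
        so = meta_step(theta, tasks, MetaConfig(second_order=True, **kw),
                       loss_fn=quad_loss)
        assert not np.allclose(fo.params["w"].data, so.params["w"].data)

    def test_second_order_meta_gradient_matches_finite_differences(self):
        """Exact MAML gradient on a 2-parameter quadratic family vs. central
        differences of the meta objective."""
        w0 = np.array([0.7, -1.3])
        tasks = [make_quad_task([0.5, 2.0], [3.0, 1.0]),
                 make_quad_task([-1.0, 0.0], [0.5, -2.0])]
        cfg = MetaConfig(inner_steps=3, inner_lr=0.08, second_order=True)

        theta = make_quad_theta(w0)
        loss = meta_loss(theta, tasks, cfg, loss_fn=quad_loss)
        (g,) = ad.grad(loss, [theta.params["w"]])

        def objective(w):
            th = make_quad_theta(w)
            return float(meta_loss(th, tasks, cfg, loss_fn=quad_loss).data)

        eps = 1e-6
        for i in range(2):
            wp, wm = w0.copy(), w0.copy()
            wp[i] += eps
            wm[i] -= eps
            num = (objective(wp) - objective(wm)) / (2 * eps)
            assert g.data[i] == pytest.approx(num, rel=1e-5)

    def test_first_order_drops_curvature_terms(self):
        """On quadratics, adapted φ = θ - lr·Σ∇L has dφ/dθ = (1-2lr)^s·I; the
        first-order gradient uses dφ/dθ = I instead. Check both analytically
        for a single 1-parameter task, one inner step."""
        w0, a, b, lr = 0.7, 0.5, 3.0, 0.1
        # phi = w - 2 lr (w - a); query loss (phi - b)^2
        phi = w0 - 2 * lr * (w0 - a)
        full = 2 * (phi - b) * (1 - 2 * lr)
        fomaml = 2 * (phi - b)
        cfg_kw = dict(inner_steps=1, inner_lr=lr)
        tasks = [make_quad_task([a], [b])]
        for second, expected in ((True, full), (False, fomaml)):
            theta = make_quad_theta([w0])
            loss = meta_loss(theta, tasks,
                             MetaConfig(second_order=second, **cfg_kw),
                             loss_fn=quad_loss)
            (g,) = ad.grad(loss, [theta.params["w"]])
            assert g.data[0] == pytest.approx(expected, rel=1e-12)


class TestTrainers:
    def test_zero_epochs_leaves_parameters_unchanged(self, tiny_theta,
                                                     small_task):
        out = train_supervised(small_task.support, tiny_theta, epochs=0,
                               lr=0.1, cfg=MetaConfig())
        assert all(np.array_equal(out.params[k].data,
                                  tiny_theta.params[k].data)
                   for k in out.params)

    def test_trajectory_equals_inner_adapt(self, tiny_theta, small_task):
        """Both are full-batch gradient descent: given the same data, lr and
        step count they must produce the same parameters."""
        cfg = MetaConfig(inner_steps=3, inner_lr=0.05)
        adapted = inner_adapt(tiny_theta, small_task.support, cfg).phi
        trained = train_supervised(small_task.support, tiny_theta, epochs=3,
                                   lr=0.05, cfg=cfg)
        for k in adapted.params:
            np.testing.assert_array_equal(adapted.params[k].data,
                                          trained.params[k].data)

    def test_loss_descends_with_small_lr(self, tiny_theta, small_task):
        log = []
        train_supervised(small_task.support, tiny_theta, epochs=5, lr=0.02,
                         cfg=MetaConfig(), log=log)
        losses = [e["loss"] for e in log]
        assert losses[-1] < losses[0]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_meta_train_zero_iterations_returns_theta0(self, tiny_theta):
        cfg = MetaConfig(meta_iterations=0)
        out = meta_train(lambda rng: None, tiny_theta, cfg)
        assert out is tiny_theta

    def test_meta_train_deterministic_from_seed(self, hex_dataset_cfg,
                                                tiny_theta):
        def sampler(rng):
            return make_task(hex_dataset_cfg, k_support=2, n_query=1,
                             seed=int(rng.integers(2 ** 31)))

        cfg = MetaConfig(meta_iterations=2, meta_batch_tasks=2, inner_steps=1,
                         seed=13)
        a = meta_train(sampler, tiny_theta, cfg)
        b = meta_train(sampler, tiny_theta, cfg)
        assert all(np.array_equal(a.params[k].data, b.params[k].data)
                   for k in a.params)


class TestFinetuneKshot:
    def test_k_bounds_enforced(self, tiny_theta, small_task):
        pair = small_task.support[0]
        with pytest.raises(ValueError, match=r"\[1, 10\]"):
            finetune_kshot(tiny_theta, [pair] * 11, small_task.query,
                           MetaConfig())
        with pytest.raises(ValueError, match=r"\[1, 10\]"):
            finetune_kshot(tiny_theta, [], small_task.query, MetaConfig())

    def test_best_epoch_selected_by_heldout_iou(self, monkeypatch, tiny_theta,
                                                small_task):
        """With per-epoch held-out IoUs [0.2, 0.6, 0.5] the epoch-2 snapshot
        wins (argmax, earliest on ties)."""
        snapshots = []

        def fake_train(dataset, theta0, epochs, lr, cfg, **kw):
            snap = theta0.copy()
            snapshots.append(snap)
            return snap

        ious = iter([0.2, 0.6, 0.5])
        monkeypatch.setattr(mt, "train_supervised", fake_train)
        monkeypatch.setattr(mt, "evaluate_pairs",
                            lambda *a, **k: (next(ious), 0.0))
        best = finetune_kshot(tiny_theta, small_task.support,
                              small_task.query, MetaConfig(), epochs=3)
        assert best is snapshots[1]

    def test_empty_heldout_falls_back_to_final_epoch(self, tiny_theta,
                                                     small_task, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            out = finetune_kshot(tiny_theta, small_task.support, [],
                                 MetaConfig(), epochs=1, lr=0.01)
        assert "held-out" in caplog.text
        assert any(not np.array_equal(out.params[k].data,
                                      tiny_theta.params[k].data)
                   for k in out.params)

    def test_finetuning_on_seen_image_does_no_harm(self, tiny_backbone,
                                                   hex_dataset_cfg):
        """Fine-tune on an image from the pre-training set: held-out IoU on
        that distribution must not drop below the pre-adaptation value."""
        from cryoice.meta import evaluate_pairs
        task = make_task(hex_dataset_cfg, k_support=2, n_query=2, seed=77)
        theta = build_model(tiny_backbone, 3)
        cfg = MetaConfig(seed=0)
        pre = train_supervised(task.support, theta, epochs=25, lr=0.05, cfg=cfg)
        iou_before, _ = evaluate_pairs(pre, task.query)
        tuned = finetune_kshot(pre, [task.support[0]], task.query, cfg,
                               epochs=5, lr=0.02)
        iou_after, _ = evaluate_pairs(tuned, task.query)
        assert iou_after >= iou_before - 1e-9
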