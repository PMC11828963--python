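"""Training loops: regular gradient descent, MAML, and k-shot fine-tuning.

Two learning strategies are implemented over the same functional model:

* the transfer baseline — plain (full- or mini-batch) gradient descent on a
  pooled labeled set, used both for pre-training and for the vanilla-transfer
  comparison; and
* model-agnostic meta-learning — bi-level optimization in which each task τ
  adapts the shared initialization θ on its support set with a few gradient
  steps (φ_τ), and θ is updated with the gradient of the mean *query* loss at
  the adapted parameters. With ``second_order=True`` that meta-gradient
  differentiates through the inner updates exactly (gradient-of-gradient);
  with ``second_order=False`` the inner gradients are treated as constants
  (first-order MAML), which keeps the identity path dφ/dθ = I but drops the
  curvature terms.

All loops are pure functions of (inputs, config, seed): given the same task
stream and seed they reproduce parameter trajectories bitwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io_formats import Micrograph, SegmentationMask
from .model import ModelParameters, forward, predict_mask
from .synthetic import Task

logger = logging.getLogger(__name__)

__all__ = [
    "MetaConfig", "AdaptationResult",
    "segmentation_loss", "inner_adapt", "meta_step", "meta_train",
    "train_supervised", "finetune_kshot", "evaluate_pairs",
]

K_SHOT_MIN, K_SHOT_MAX = 1, 10


@dataclass(frozen=True)
class MetaConfig:
    """Hyperparameters for both training strategies.

    inner_lr / inner_steps govern per-task adaptation on the support set;
    outer_lr / meta_batch_tasks / meta_iterations govern the meta-update.
    loss selects the segmentation objective; bce_plus_dice is the default
    because the foreground (crystalline ice) typically covers only a few
    percent of a lamella and plain BCE under-weights it.
    """

    inner_lr: float = 0.01
    inner_steps: int = 5
    outer_lr: float = 1e-3
    meta_batch_tasks: int = 4
    meta_iterations: int = 100
    second_order: bool = False
    loss: str = "bce_plus_dice"
    seed: int = 0

    def __post_init__(self):
        if self.inner_lr < 0 or self.outer_lr <= 0:
            raise ValueError("learning rates must be positive (inner_lr may be 0)")
        if self.inner_steps < 0 or self.meta_iterations < 0:
            raise ValueError("step counts must be >= 0")
        if self.meta_batch_tasks < 1:
            raise ValueError("meta_batch_tasks must be >= 1")
        if self.loss not in ("bce", "dice", "bce_plus_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class AdaptationResult:
    """Outcome of adapting θ on one support set."""

    phi: ModelParameters
    support_loss_trace: list[float]
    query_metrics: tuple[float, float] = (float("nan"), float("nan"))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_DICE_EPS = 1.0


def segmentation_loss(logits: Tensor, mask, kind: str = "bce_plus_dice") -> Tensor:
    """Segmentation objective on logits vs. a binary mask.

    bce: mean per-pixel binary cross-entropy with logits (overflow-safe).
    dice: 1 − (2·|soft ∩ gt| + ε) / (|soft| + |gt| + ε), soft = sigmoid(logits),
    ε = 1 so empty-vs-empty is well defined. bce_plus_dice is their sum.
    """
    if isinstance(mask, SegmentationMask):
        y = Tensor(mask.mask.astype(np.float64))
    elif isinstance(mask, Tensor):
        y = mask.detach()
    else:
        y = Tensor(np.asarray(mask, dtype=np.float64))
    if y.shape != logits.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs mask {y.shape}")
    total = None
    if kind in ("bce", "bce_plus_dice"):
        # log(1+e^l) - l*y  ==  -y log σ(l) - (1-y) log(1-σ(l))
        bce = ad.tmean(ad.softplus(logits) - logits * y)
        total = bce
    if kind in ("dice", "bce_plus_dice"):
        soft = ad.sigmoid(logits)
        inter = ad.tsum(soft * y)
        denom = ad.tsum(soft) + ad.tsum(y)
        dice = 1.0 - (2.0 * inter + _DICE_EPS) * ad.power(denom + _DICE_EPS, -1.0)
        total = dice if total is None else total + dice
    return total


def _batch_loss(params: ModelParameters,
                pairs: Sequence[tuple[Micrograph, SegmentationMask]],
                kind: str) -> Tensor:
    images = np.stack([m.image for m, _ in pairs])
    masks = np.stack([g.mask for _, g in pairs]).astype(np.float64)
    logits = forward(params, images)
    return segmentation_loss(logits, Tensor(masks), kind)


def evaluate_pairs(params: ModelParameters,
                   pairs: Sequence[tuple[Micrograph, SegmentationMask]],
                   threshold: float = 0.5) -> tuple[float, float]:
    """Mean IoU and F1 of thresholded predictions over (image, mask) pairs."""
    from .evaluation import f1, iou
    ious, f1s = [], []
    with ad.no_grad():
        for m, gt in pairs:
            logits = forward(params, m.image[None])
            pred = predict_mask(logits.data[0], threshold)
            ious.append(iou(pred, gt))
            f1s.append(f1(pred, gt))
    return float(np.mean(ious)), float(np.mean(f1s))


# ---------------------------------------------------------------------------
# inner loop (task adaptation)
# ---------------------------------------------------------------------------

def inner_adapt(theta: ModelParameters,
                support: Sequence[tuple[Micrograph, SegmentationMask]],
                cfg: MetaConfig,
                query: Sequence[tuple[Micrograph, SegmentationMask]] | None = None,
                loss_fn: Callable | None = None,
                _track_meta: bool = False) -> AdaptationResult:
    """Adapt θ on a support set with full-batch gradient descent.

    φ ← θ, then inner_steps times φ ← φ − inner_lr · ∇_φ L(φ; support).
    The loss trace has inner_steps + 1 entries (pre-adaptation loss first).
    When called inside the meta objective with second_order=True, φ stays
    differentiable with respect to θ; with second_order=False the per-step
    gradients are detached (first-order MAML) but the φ = θ − Σ lr·g chain is
    kept so the query gradient reaches θ through the identity path.
    """
    if not support:
        raise ValueError("support set must be non-empty")
    if loss_fn is None:
        loss_fn = lambda mp_, pairs_: _batch_loss(mp_, pairs_, cfg.loss)
    create_graph = _track_meta and cfg.second_order
    phi = dict(theta.params)
    trace: list[float] = []
    for step in range(cfg.inner_steps):
        mp = ModelParameters(phi, theta.config)
        loss = loss_fn(mp, support)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite support loss at inner step {step}: {loss.data}")
        trace.append(loss.item())
        grads = ad.grad(loss, list(phi.values()), create_graph=create_graph)
        if _track_meta:
            phi = {k: p - cfg.inner_lr * g
                   for (k, p), g in zip(phi.items(), grads)}
        else:
            phi = {k: Tensor(p.data - cfg.inner_lr * g.data, requires_grad=True)
                   for (k, p), g in zip(phi.items(), grads)}
    adapted = ModelParameters(phi, theta.config)
    final = loss_fn(adapted, support)
    if not np.isfinite(final.data):
        raise FloatingPointError("non-finite post-adaptation support loss")
    trace.append(final.item())
    metrics = evaluate_pairs(adapted, query) if query else (float("nan"),) * 2
    return AdaptationResult(phi=adapted, support_loss_trace=trace,
                            query_metrics=metrics)


# ---------------------------------------------------------------------------
# outer loop (meta-update)
# ---------------------------------------------------------------------------

def meta_loss(theta: ModelParameters, task_batch: Sequence[Task],
              cfg: MetaConfig, loss_fn: Callable | None = None) -> Tensor:
    """Mean query loss after per-task adaptation (the MAML objective)."""
    if not task_batch:
        raise ValueError("meta batch must contain at least one task")
    if loss_fn is None:
        loss_fn = lambda mp_, pairs_: _batch_loss(mp_, pairs_, cfg.loss)
    total = None
    for task in task_batch:
        res = inner_adapt(theta, task.support, cfg, loss_fn=loss_fn,
                          _track_meta=True)
        q = loss_fn(res.phi, task.query)
        total = q if total is None else total + q
    return total * (1.0 / len(task_batch))


def meta_step(theta: ModelParameters, task_batch: Sequence[Task],
              cfg: MetaConfig, loss_fn: Callable | None = None) -> ModelParameters:
    """One meta-update: θ ← θ − outer_lr · ∇_θ mean_τ L(adapt(θ; S_τ); Q_τ)."""
    names = list(theta.params)
    leaves = [theta.params[k] for k in names]
    loss = meta_loss(theta, task_batch, cfg, loss_fn=loss_fn)
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite meta-loss: {loss.data}")
    grads = ad.grad(loss, leaves, create_graph=False)
    new = {k: Tensor(p.data - cfg.outer_lr * g.data, requires_grad=True)
           for k, p, g in zip(names, leaves, grads)}
    return ModelParameters(new, theta.config)


def meta_train(task_sampler, theta0: ModelParameters,
               cfg: MetaConfig,
               log: list | None = None) -> ModelParameters:
    """Run cfg.meta_iterations meta-steps over freshly sampled task batches.

    task_sampler is either an iterator of Task or a callable
    ``(rng) -> Task``; batches of cfg.meta_batch_tasks are drawn per step.
    Reproducible from cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    theta = theta0

    def draw() -> Task:
        if callable(task_sampler):
            return task_sampler(rng)
        try:
            return next(task_sampler)
        except StopIteration as exc:
            raise RuntimeError("task sampler exhausted during meta-training") from exc

    for it in range(cfg.meta_iterations):
        batch = [draw() for _ in range(cfg.meta_batch_tasks)]
        theta = meta_step(theta, batch, cfg)
        if log is not None:
            with ad.no_grad():
                q = float(meta_loss(theta, batch, cfg).data)
            log.append({"iteration": it, "mean_query_loss": q})
            logger.info("meta-iter %d: mean query loss %.4f", it, q)
    return theta


# ---------------------------------------------------------------------------
# supervised training (Algorithm 1 / transfer baseline)
# ---------------------------------------------------------------------------

def train_supervised(dataset: Sequence[tuple[Micrograph, SegmentationMask]],
                     theta0: ModelParameters, epochs: int, lr: float,
                     cfg: MetaConfig, batch_size: int | None = None,
                     log: list | None = None) -> ModelParameters:
    """Regular gradient descent on the pooled labeled set.

    Full-batch by default (so its trajectory coincides with the inner loop's
    given the same data, lr and step count); mini-batches when batch_size is
    set, with a deterministic shuffle from cfg.seed.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    theta = ModelParameters(
        {k: Tensor(v.data.copy(), requires_grad=True)
         for k, v in theta0.params.items()}, theta0.config)
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    names = list(theta.params)
    for epoch in range(epochs):
        if batch_size is None:
            batches = [list(dataset)]
        else:
            order = rng.permutation(len(dataset))
            batches = [[dataset[i] for i in order[s:s + batch_size]]
                       for s in range(0, len(dataset), batch_size)]
        for batch in batches:
            loss = _batch_loss(theta, batch, cfg.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            grads = ad.grad(loss, [theta.params[k] for k in names])
            for k, g in zip(names, grads):
                theta.params[k] = Tensor(theta.params[k].data - lr * g.data,
                                         requires_grad=True)
            if log is not None:
                log.append({"epoch": epoch, "loss": float(loss.data)})
    return theta


def finetune_kshot(theta_pretrained: ModelParameters,
                   labeled: Sequence[tuple[Micrograph, SegmentationMask]],
                   heldout: Sequence[tuple[Micrograph, SegmentationMask]],
                   cfg: MetaConfig, epochs: int = 20,
                   lr: float | None = None,
                   log: list | None = None) -> ModelParameters:
    """k-shot fine-tuning with automatic best-model selection.

    Runs gradient descent from the pre-trained parameters on k labeled pairs
    (k restricted to the tool's 1–10 range), evaluates IoU on the held-out
    pairs after every epoch, and returns the snapshot with the highest
    held-out IoU; ties go to the earliest epoch (the less overfit snapshot).
    An empty held-out set falls back to the final epoch with a warning.
    """
    k = len(labeled)
    if not (K_SHOT_MIN <= k <= K_SHOT_MAX):
        raise ValueError(f"k must be in [{K_SHOT_MIN}, {K_SHOT_MAX}], got {k}")
    lr = cfg.inner_lr if lr is None else lr
    theta = theta_pretrained
    best: tuple[float, int, ModelParameters] | None = None
    for epoch in range(1, epochs + 1):
        theta = train_supervised(labeled, theta, epochs=1, lr=lr, cfg=cfg)
        if heldout:
            miou, _ = evaluate_pairs(theta, heldout)
            if log is not None:
                log.append({"epoch": epoch, "heldout_iou": miou})
            if best is None or miou > best[0]:
                best = (miou, epoch, theta)
    if not heldout:
        logger.warning("empty held-out set: returning final-epoch parameters")
        return theta
    return best[2]
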