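"""Seeded training loop with polynomial LR decay, JSON-lines logging,
and best/last checkpointing."""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import as_tensor
from .config import ModelConfig, TrainConfig
from .losses import hybrid_loss, softmax_probs
from .metrics import dsc_metric
from .network import DCFNet, build_model, save_checkpoint

__all__ = ["train_model", "predict_masks", "mean_dsc_on"]


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def predict_masks(model: DCFNet, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Argmax label masks for (N, S, S) or (N, C, S, S) images."""
    if images.ndim == 3:
        images = images[:, None]
    outs = []
    with ad.no_grad():
        for i in range(0, len(images), batch_size):
            logits = model(as_tensor(images[i:i + batch_size])).data
            outs.append(np.argmax(logits, axis=1))
    return np.concatenate(outs)


def mean_dsc_on(model: DCFNet, images: np.ndarray, masks: np.ndarray,
                num_classes: int, batch_size: int = 8) -> float:
    """Mean foreground Dice of the model's argmax predictions."""
    preds = predict_masks(model, images, batch_size)
    scores = [
        np.mean([dsc_metric(p, m, cls=c) for c in range(1, num_classes)])
        for p, m in zip(preds, masks)
    ]
    return float(np.mean(scores))


def train_model(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    images: np.ndarray,
    masks: np.ndarray,
    val_images: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
    out_dir=None,
    max_steps: int | None = None,
    eval_every: int = 1,
    augment_fn=None,
    resume_from=None,
    log=print,
):
    """Train a model on in-memory (N, S, S) images and masks.

    Returns ``(model, history)`` where ``history`` is a list of per-epoch
    dicts (loss, train/val Dice, lr). Fully seeded: identical configs and
    data give identical trajectories.
    """
    model_cfg.validate()
    train_cfg.validate()
    rng = np.random.default_rng(train_cfg.seed)
    model = build_model(model_cfg, seed=train_cfg.seed)
    start_epoch = 0
    history: list[dict] = []
    if resume_from is not None:
        from .network import load_checkpoint
        model, extra = load_checkpoint(resume_from)
        start_epoch = int(extra.get("epoch", 0))
        history = extra.get("history", [])
    params = list(model.parameters())
    if train_cfg.optimizer == "sgd_momentum":
        opt = nn.SGD(params, lr=train_cfg.lr, momentum=train_cfg.momentum,
                     weight_decay=train_cfg.weight_decay)
    else:
        opt = nn.Adam(params, lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)

    n = len(images)
    steps_per_epoch = max(1, (n + train_cfg.batch_size - 1) // train_cfg.batch_size)
    total_steps = (max_steps if max_steps is not None
                   else train_cfg.epochs * steps_per_epoch)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "train_config.json", "w") as fh:
            json.dump({"model": str(model_cfg), "train": asdict(train_cfg)}, fh, indent=2)
    logf = open(out_dir / "log.jsonl", "a") if out_dir is not None else None

    step = start_epoch * steps_per_epoch
    best_val = -np.inf
    t0 = time.time()
    try:
        for epoch in range(start_epoch, train_cfg.epochs):
            if step >= total_steps:
                break
            losses = []
            for idx in _batches(n, train_cfg.batch_size, rng):
                if step >= total_steps:
                    break
                xb = images[idx]
                yb = masks[idx]
                if augment_fn is not None:
                    aug = [augment_fn(x, y, int(rng.integers(0, 2 ** 31)))
                           for x, y in zip(xb, yb)]
                    xb = np.stack([a[0] for a in aug])
                    yb = np.stack([a[1] for a in aug])
                lr = nn.poly_lr(train_cfg.lr, step, total_steps, train_cfg.lr_power)
                opt.lr = lr
                logits = model(as_tensor(xb[:, None] if xb.ndim == 3 else xb))
                loss = hybrid_loss(softmax_probs(logits), yb, train_cfg.lam)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                step += 1
            row = {
                "epoch": epoch + 1,
                "step": step,
                "lr": lr,
                "loss": float(np.mean(losses)) if losses else float("nan"),
                "seconds": round(time.time() - t0, 2),
            }
            if (epoch + 1) % eval_every == 0:
                row["train_dsc"] = mean_dsc_on(model, images, masks, model_cfg.num_classes,
                                               train_cfg.batch_size)
                if val_images is not None:
                    row["val_dsc"] = mean_dsc_on(model, val_images, val_masks,
                                                 model_cfg.num_classes, train_cfg.batch_size)
            history.append(row)
            if log:
                log(json.dumps(row))
            if logf:
                logf.write(json.dumps(row) + "\n")
                logf.flush()
            if out_dir is not None:
                extra = {"epoch": epoch + 1, "history": history}
                save_checkpoint(out_dir / "last.npz", model, extra)
                score = row.get("val_dsc", row.get("train_dsc", -np.inf))
                if score >= best_val:
                    best_val = score
                    save_checkpoint(out_dir / "best.npz", model, extra)
    finally:
        if logf:
            logf.close()
    return model, history
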