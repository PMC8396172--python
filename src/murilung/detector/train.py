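"""Training loops for the four data strategies under K-fold cross validation.

Strategies: ``sim_only`` trains once on all simulated data and is evaluated
on every fold's test set; ``real_only`` trains one network per fold on real
data; ``combined`` adds the full simulated training set to each fold's real
training data; ``transfer`` initializes each fold's network from the
sim-only weights before retraining on real data.  The Adam learning rate
starts at ``lr0`` and decays by 10% every 100 epochs; validation soft-Dice
is monitored to catch overfitting.  One "epoch" is one optimizer step on a
freshly sampled batch of patches, matching patch-wise training practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import get_logger
from .data import FoldSplit, TrainConfig, make_folds, sample_patch
from .layers import soft_dice_loss_grad
from .vnet import NetworkSpec, VNet

__all__ = ["TrainedFold", "TrainResult", "train", "train_single"]

_log = get_logger("detector")


@dataclass
class TrainedFold:
    model: VNet
    history: dict
    fold_index: int
    test_ids: list = field(default_factory=list)


@dataclass
class TrainResult:
    strategy: str
    folds: list[TrainedFold]
    fold_split: FoldSplit | None


def _lr_at(cfg: TrainConfig, epoch: int) -> float:
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.lr_decay_every)


def train_single(
    spec: NetworkSpec,
    train_sets: list,
    cfg: TrainConfig,
    rng: np.random.Generator,
    *,
    val_sets: list | None = None,
    init_weights: list | None = None,
    epochs: int | None = None,
) -> tuple[VNet, dict]:
    """Train one network on (image, label) pairs; returns model + history.

    ``train_sets`` entries expose ``.image`` (HU ``CTVolume``) and
    ``.labels`` (``BinaryMask``); validation soft-Dice is recorded every 25
    epochs when ``val_sets`` is given.  Zero epochs returns the initial
    weights untouched (used by transfer-learning identity checks).
    """
    model = VNet(spec)
    if init_weights is not None:
        model.set_weights(init_weights)
    model.set_dropout_rng(rng)
    opt = model.make_optimizer(lr=cfg.lr0, beta1=cfg.beta1)
    n_epochs = cfg.epochs if epochs is None else epochs
    history: dict = {"loss": [], "val_dice": [], "lr": []}
    for epoch in range(n_epochs):
        opt.lr = _lr_at(cfg, epoch)
        xs, ys = [], []
        for _ in range(cfg.batch_size):
            entry = train_sets[rng.integers(len(train_sets))]
            p, l = sample_patch(entry.image, entry.labels, cfg, rng)
            xs.append(p)
            ys.append(l)
        x = np.stack(xs)[:, None]
        y = np.stack(ys)[:, None]
        model.zero_grads()
        pred = model.forward(x, training=True)
        loss, grad = soft_dice_loss_grad(pred, y)
        model.backward(grad)
        opt.step()
        history["loss"].append(loss)
        history["lr"].append(opt.lr)
        if val_sets and (epoch % 25 == 24 or epoch == n_epochs - 1):
            history["val_dice"].append((epoch, _validation_dice(model, val_sets, cfg, rng)))
    return model, history


def _validation_dice(model: VNet, val_sets: list, cfg: TrainConfig, rng) -> float:
    from .layers import soft_dice

    scores = []
    for entry in val_sets[:3]:
        p, l = sample_patch(entry.image, entry.labels, cfg, rng)
        pred = model.forward(p[None, None], training=False)
        scores.append(soft_dice(pred[0, 0], l))
    return float(np.mean(scores))


def train(
    datasets: dict,
    cfg: TrainConfig,
    spec: NetworkSpec,
    rng: np.random.Generator,
    *,
    epochs: int | None = None,
) -> TrainResult:
    """Run one training strategy end to end.

    ``datasets`` maps ``"sim"`` and/or ``"real"`` to lists of set objects
    with ``.image``, ``.labels`` and ``.set_id``; simulated entries flagged
    ``.is_validation`` are held out of simulated training.
    """
    sim = list(datasets.get("sim", []))
    real = list(datasets.get("real", []))
    sim_train = [s for s in sim if not getattr(s, "is_validation", False)]
    sim_val = [s for s in sim if getattr(s, "is_validation", False)]

    if cfg.strategy == "sim_only":
        if not sim_train:
            raise ValueError("sim_only strategy needs simulated data")
        model, hist = train_single(spec, sim_train, cfg, rng, val_sets=sim_val, epochs=epochs)
        folds = [TrainedFold(model, hist, 0, [getattr(s, "set_id", i) for i, s in enumerate(real)])]
        return TrainResult(cfg.strategy, folds, None)

    if not real:
        raise ValueError(f"{cfg.strategy} strategy needs real data")

    # pretrain before drawing folds so the sim-only stage consumes the same
    # random stream as a plain sim_only run (transfer with zero retraining
    # epochs then reproduces the sim_only weights exactly)
    sim_weights = None
    if cfg.strategy == "transfer":
        if not sim_train:
            raise ValueError("transfer strategy needs simulated data to pretrain on")
        base, _ = train_single(spec, sim_train, cfg, rng, val_sets=sim_val, epochs=epochs)
        sim_weights = base.get_weights()

    ids = [getattr(s, "set_id", i) for i, s in enumerate(real)]
    by_id = dict(zip(ids, real))
    split = make_folds(ids, cfg.k_folds, rng)

    folds = []
    for fi, fold in enumerate(split):
        train_list = [by_id[i] for i in fold["train"]]
        if cfg.strategy == "combined":
            train_list = train_list + sim_train
        fold_epochs = epochs
        if cfg.strategy == "transfer" and cfg.transfer_epochs is not None:
            fold_epochs = cfg.transfer_epochs
        model, hist = train_single(
            spec, train_list, cfg, rng,
            val_sets=sim_val or None,
            init_weights=sim_weights,
            epochs=fold_epochs,
        )
        folds.append(TrainedFold(model, hist, fi, fold["test"]))
        _log.info("fold %d/%d trained (%s)", fi + 1, cfg.k_folds, cfg.strategy)
    return TrainResult(cfg.strategy, folds, split)
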