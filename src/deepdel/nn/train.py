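"""Training loop: Adam, epoch shuffling, early stopping on validation AUC."""

from __future__ import annotations

import math

import numpy as np

from ..config import TrainingConfig
from .loss import masked_mean_loss
from .model import WindowClassifier


class Adam:
    def __init__(self, model: WindowClassifier, lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {qn: np.zeros_like(layer.params[k])
                  for qn, layer, k in model.parameters()}
        self.v = {qn: np.zeros_like(layer.params[k])
                  for qn, layer, k in model.parameters()}

    def step(self, clip_norm: float | None = 5.0) -> None:
        params = self.model.parameters()
        if clip_norm is not None:
            total = math.sqrt(sum(float((layer.grads[k] ** 2).sum())
                                  for _, layer, k in params if k in layer.grads))
            scale = clip_norm / total if total > clip_norm else 1.0
        else:
            scale = 1.0
        self.t += 1
        for qn, layer, k in params:
            g = layer.grads.get(k)
            if g is None:
                continue
            g = g * scale
            self.m[qn] = self.b1 * self.m[qn] + (1 - self.b1) * g
            self.v[qn] = self.b2 * self.v[qn] + (1 - self.b2) * g * g
            mhat = self.m[qn] / (1 - self.b1 ** self.t)
            vhat = self.v[qn] / (1 - self.b2 ** self.t)
            layer.params[k] -= (self.lr * mhat /
                                (np.sqrt(vhat) + self.eps)).astype(layer.params[k].dtype)


class EarlyStopping:
    """Keep the best-metric checkpoint; stop after ``patience`` epochs
    without improvement (strict improvement, higher is better)."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_metric = -np.inf
        self.best_epoch = 0
        self.best_state = None

    def update(self, epoch: int, metric: float, state) -> bool:
        """Record one epoch; returns True if training should stop."""
        if metric > self.best_metric:
            self.best_metric = metric
            self.best_epoch = epoch
            self.best_state = state
            return False
        return epoch - self.best_epoch >= self.patience


def _stack(batches):
    """RegionBatches -> (x (B,T,n,m) float32, labels (B,T), mask (B,T))."""
    x = np.stack([b.matrices for b in batches]).astype(np.float32)
    mask = np.stack([b.mask for b in batches])
    labels = np.stack([np.asarray(b.labels, dtype=np.float32)
                       for b in batches])
    return x, labels, mask


def evaluate_loss_and_scores(model, batches, loss_a):
    """Inference pass: (mean loss over unmasked windows, scores, labels)."""
    total, count = 0.0, 0
    scores, labels = [], []
    for b in batches:
        probs = model.forward(b.matrices[None].astype(np.float32))[0]
        lab = np.asarray(b.labels, dtype=np.float32)
        lsum, _ = masked_mean_loss(probs, lab, b.mask, loss_a)
        k = int(b.mask.sum())
        total += lsum * k
        count += k
        scores.append(probs[b.mask])
        labels.append(lab[b.mask])
    scores = np.concatenate(scores) if scores else np.empty(0)
    labels = np.concatenate(labels) if labels else np.empty(0)
    return (total / count if count else 0.0), scores, labels


def train(model: WindowClassifier, train_batches, val_batches=None,
          cfg: TrainingConfig | None = None, verbose: bool = False):
    """Fit the classifier; returns a history dict.

    ``train_batches``/``val_batches`` are RegionBatch objects that carry a
    ``labels`` array (set by the dataset builder).  Early stopping monitors
    window-level AUC on the validation set (mean training loss if no
    validation set, or a single-class one, is given); the best weights are
    checkpointed and restored.
    """
    from sklearn.metrics import roc_auc_score

    cfg = cfg or TrainingConfig()
    train_batches = list(train_batches)
    if not train_batches:
        raise ValueError("no training data")
    n_pos = sum(int(np.asarray(b.labels)[b.mask].sum()) for b in train_batches)
    if n_pos == 0:
        raise ValueError(
            "training set contains no positive windows; the classifier "
            "cannot learn a deletion signal from all-negative data")

    T = train_batches[0].mask.shape[0]
    samples_per_step = max(1, math.ceil(cfg.batch_size / T))
    rng = np.random.default_rng(cfg.shuffle_seed)

    opt = Adam(model, lr=cfg.learning_rate)
    history = {"epoch": [], "train_loss": [], "val_auc": [], "monitor": []}
    stopper = EarlyStopping(cfg.patience)
    stopper.best_state = model.get_weights()

    use_val_auc = False
    if val_batches:
        val_lab = np.concatenate([np.asarray(b.labels)[b.mask]
                                  for b in val_batches])
        use_val_auc = len(np.unique(val_lab)) == 2

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_batches))
        epoch_loss, epoch_windows = 0.0, 0
        for i0 in range(0, len(order), samples_per_step):
            group = [train_batches[i] for i in order[i0:i0 + samples_per_step]]
            x, labels, mask = _stack(group)
            probs = model.forward(x, train=True)
            loss, grad = masked_mean_loss(probs, labels, mask, cfg.loss_a)
            model.backward(grad)
            opt.step()
            k = int(mask.sum())
            epoch_loss += loss * k
            epoch_windows += k
        train_loss = epoch_loss / max(epoch_windows, 1)

        val_auc = float("nan")
        if use_val_auc:
            _, scores, labels = evaluate_loss_and_scores(model, val_batches,
                                                         cfg.loss_a)
            val_auc = float(roc_auc_score(labels, scores))
            metric = val_auc
        else:
            metric = -train_loss
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_auc"].append(val_auc)
        history["monitor"].append(metric)
        if verbose:
            print(f"epoch {epoch:3d}  loss {train_loss:.6f}  "
                  f"val_auc {val_auc:.4f}")

        if stopper.update(epoch, metric, model.get_weights()):
            break

    model.set_weights(stopper.best_state)
    history["best_epoch"] = stopper.best_epoch
    history["best_metric"] = float(stopper.best_metric)
    return history
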