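"""Training strategy: splitting, preprocessing, optimization, diagnostics.

The pipeline mirrors a standard small-dataset segmentation workflow: the
dataset is split once into 80% training (which internally carves out a
validation subset) and 20% held-out test images, images are resized and
intensity-scaled to [0, 1], and the network is optimized with Adam
(learning rate 0.001 by default) under a pixel-wise binary cross-entropy
loss. Validation loss drives both early stopping and
reduce-on-plateau learning-rate adjustment, and the best-validation-loss
weights are restored at the end. Per-epoch train/validation loss and
pixel-accuracy series are recorded for curve inspection and for the
overfit diagnosis rule: a model is flagged as overfit when the final
validation loss sits above the final training loss by more than a margin
while the validation-loss trend still rises as the training loss falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .model import UNet

__all__ = ["TrainConfig", "TrainingHistory", "SplitResult", "split_dataset",
           "prepare_pair", "train", "detect_overfit"]


@dataclass(frozen=True)
class TrainConfig:
    image_size: tuple = (256, 256)
    batch_size: int = 2
    epochs: int = 50
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    early_stop_patience: int = 10
    lr_reduce_factor: float = 0.5
    lr_reduce_patience: int = 5
    split_seed: int = 0
    init_seed: int = 0
    binarize_threshold: float = 0.5

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie strictly in (0, 1)")
        if not 0.0 < self.lr_reduce_factor < 1.0:
            raise ValueError("lr_reduce_factor must lie strictly in (0, 1)")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie strictly in (0, 1)")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    lr_schedule: list = field(default_factory=list)

    @property
    def stopped_epoch(self) -> int:
        return len(self.train_loss)

    def as_dict(self) -> dict:
        return {"train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
                "lr_schedule": self.lr_schedule,
                "stopped_epoch": self.stopped_epoch}


@dataclass(frozen=True)
class SplitResult:
    train_items: list
    val_items: list
    test_items: list


def split_dataset(items, test_fraction: float = 0.20,
                  validation_fraction: float = 0.20,
                  seed: int = 0) -> SplitResult:
    """Random train/validation/test partition of dataset identifiers.

    The test fraction is taken from the full set first (rounded to the
    nearest count, so 60 items at 0.20 give the 48/12 convention); the
    validation fraction is then taken from the remaining training pool.
    Test items never overlap the training or validation pools.
    """
    items = list(items)
    n = len(items)
    if n < 5:
        raise ValueError(f"need at least 5 items to split, got {n}; "
                         "add more images or merge datasets")
    if not 0.0 < test_fraction < 1.0 or not 0.0 < validation_fraction < 1.0:
        raise ValueError("fractions must lie strictly in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_test = max(1, round(n * test_fraction))
    n_val = max(1, round((n - n_test) * validation_fraction))
    test = [items[i] for i in order[:n_test]]
    val = [items[i] for i in order[n_test:n_test + n_val]]
    trn = [items[i] for i in order[n_test + n_val:]]
    if not trn:
        raise ValueError("split leaves no training items; reduce fractions")
    return SplitResult(train_items=trn, val_items=val, test_items=test)


def prepare_pair(image: np.ndarray, mask: np.ndarray,
                 target_size: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Resize and normalize one image/mask pair for the network.

    The image is resized with smooth (anti-aliased bilinear) interpolation
    and scaled into [0, 1]; the mask is resized with nearest-neighbour so
    it stays strictly binary {0, 1}.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError(f"mask must be binary; found values {vals[:10]}")
    mask = (mask > 0).astype(np.uint8)
    h, w = target_size
    if image.shape != (h, w):
        image = _sk_resize(image, (h, w), order=1, anti_aliasing=True,
                           preserve_range=True)
        mask = _sk_resize(mask, (h, w), order=0, anti_aliasing=False,
                          preserve_range=True).astype(np.uint8)
    lo, hi = float(image.min()), float(image.max())
    if hi > 1.0 or lo < 0.0:
        image = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    return image.astype(np.float32), mask


def _epoch_pass(model: UNet, pairs, batch_size, optimizer=None, rng=None):
    """One pass over ``pairs``; trains when an optimizer is given.

    Returns (mean loss, mean pixel accuracy) weighted by batch size.
    """
    idx = np.arange(len(pairs))
    if rng is not None:
        rng.shuffle(idx)
    total_loss = total_acc = total_n = 0
    for start in range(0, len(idx), batch_size):
        chunk = idx[start:start + batch_size]
        x = np.stack([pairs[i][0] for i in chunk])[:, None].astype(model.dtype)
        y = np.stack([pairs[i][1] for i in chunk])[:, None].astype(model.dtype)
        logits = model.forward(x)
        loss, dz = nn.bce_with_logits(logits, y)
        acc = float(np.mean((logits >= 0) == (y > 0.5)))
        if optimizer is not None:
            optimizer.zero_grad()
            model.backward(dz)
            optimizer.step()
        k = len(chunk)
        total_loss += loss * k
        total_acc += acc * k
        total_n += k
    return total_loss / total_n, total_acc / total_n


def train(model: UNet, dataset, split: SplitResult,
          config: TrainConfig) -> TrainingHistory:
    """Optimize ``model`` on the split's training items.

    ``dataset`` maps item identifiers to (image, mask) pairs (a mapping,
    or a sequence indexed by the identifiers). Pairs are resized to
    ``config.image_size`` on entry. Training minimizes pixel-wise binary
    cross-entropy with Adam; validation loss drives early stopping and
    learning-rate reduction; the best-validation-loss weights are restored
    into ``model`` before returning.
    """
    config.validate()
    ih, iw = config.image_size
    if (model.config.input_height, model.config.input_width) != (ih, iw):
        raise ValueError(
            f"model input {model.config.input_height}x{model.config.input_width} "
            f"does not match config.image_size {ih}x{iw}")
    if not split.train_items or not split.val_items:
        raise ValueError("train and validation partitions must be non-empty")

    def fetch(ids):
        return [prepare_pair(*dataset[i], (ih, iw)) for i in ids]

    train_pairs = fetch(split.train_items)
    val_pairs = fetch(split.val_items)

    optimizer = nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.init_seed)
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.get_state()
    stall_stop = stall_lr = 0
    for _epoch in range(config.epochs):
        tl, ta = _epoch_pass(model, train_pairs, config.batch_size,
                             optimizer=optimizer, rng=rng)
        vl, va = _epoch_pass(model, val_pairs, config.batch_size)
        history.train_loss.append(tl)
        history.train_accuracy.append(ta)
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
        history.lr_schedule.append(optimizer.lr)
        if vl < best_val - 1e-12:
            best_val = vl
            best_state = model.get_state()
            stall_stop = stall_lr = 0
        else:
            stall_stop += 1
            stall_lr += 1
        if stall_lr >= config.lr_reduce_patience:
            optimizer.lr *= config.lr_reduce_factor
            stall_lr = 0
        if stall_stop >= config.early_stop_patience:
            break
    model.set_state(best_state)
    return history


def _slope(y: np.ndarray) -> float:
    x = np.arange(len(y), dtype=np.float64)
    return float(np.polyfit(x, np.asarray(y, dtype=np.float64), 1)[0])


def detect_overfit(history: TrainingHistory, gap_margin: float = 0.1,
                   trend_window: int = 5) -> tuple[bool, str]:
    """Flag overfitting from the loss curves.

    Overfit iff (final val_loss - final train_loss) > gap_margin AND, over
    the last ``trend_window`` epochs, the least-squares slope of val_loss
    is positive while the train_loss slope is <= 0.
    """
    n = history.stopped_epoch
    if n < trend_window:
        raise ValueError(f"history has {n} epochs, shorter than "
                         f"trend_window={trend_window}")
    gap = history.val_loss[-1] - history.train_loss[-1]
    val_slope = _slope(history.val_loss[-trend_window:])
    train_slope = _slope(history.train_loss[-trend_window:])
    flag = gap > gap_margin and val_slope > 0 and train_slope <= 0
    text = (f"gap={gap:.4f} (margin {gap_margin}), val_slope={val_slope:+.5f}, "
            f"train_slope={train_slope:+.5f} over last {trend_window} epochs "
            f"-> {'OVERFIT' if flag else 'ok'}")
    return flag, text
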