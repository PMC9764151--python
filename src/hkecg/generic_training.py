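"""Generic (population-level) model training.

The study protocol is the default: subject-level 6:2:2 split, class-balanced
beats, Adam at 5e-5 with mini-batches of 1024, the rate halved whenever the
validation loss fails to reach a new minimum for 3 consecutive epochs, 50
epochs, and the epoch with minimal validation loss kept as the pretrained
checkpoint.  Desk-scale runs override batch size, rate and epoch count via
``TrainConfig`` without touching the protocol defaults.
"""

from __future__ import annotations

import copy
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, cross_entropy, softmax
from .errors import InvalidArgumentError, TrainingDivergedError
from .preprocess import Beat, Label, LabeledRecord
from .resnet1d import Checkpoint, NetworkSpec, ResNet1D, build_network

CLASS_INDEX = {Label.NORMO: 0, Label.HYPER: 1}


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 5e-5
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    max_epochs: int = 50
    batch_size: int = 1024
    split_ratio: tuple[int, int, int] = (6, 2, 2)
    balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise InvalidArgumentError("only the Adam optimizer is supported")
        if any(r <= 0 for r in self.split_ratio) or sum(self.split_ratio) != 10:
            raise InvalidArgumentError("split ratio must be positive and sum to 10")
        if self.plateau_patience < 1:
            raise InvalidArgumentError("plateau patience must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)


def split_dataset(records: list[LabeledRecord],
                  ratio: tuple[int, int, int] = (6, 2, 2), seed: int = 0
                  ) -> tuple[list[LabeledRecord], list[LabeledRecord],
                             list[LabeledRecord]]:
    """Subject-level train/validation/test split (no subject straddles two
    partitions); partition sizes follow the ratio by largest remainder."""
    if len(records) < 10:
        raise InvalidArgumentError("need at least 10 records to split")
    by_subject: dict[str, list[LabeledRecord]] = defaultdict(list)
    for r in records:
        by_subject[r.subject_id].append(r)
    subjects = sorted(by_subject)
    if len(subjects) < len(ratio):
        raise InvalidArgumentError("fewer subjects than partitions")
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n = len(subjects)
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    counts = [int(q) for q in quotas]
    remainders = sorted(range(len(ratio)),
                        key=lambda i: (quotas[i] - counts[i], -i), reverse=True)
    for i in range(n - sum(counts)):
        counts[remainders[i % len(ratio)]] += 1
    parts, start = [], 0
    for c in counts:
        part_subjects = subjects[start: start + c]
        parts.append([r for s in part_subjects for r in by_subject[s]])
        start += c
    return tuple(parts)


def balance_classes(beats: list[Beat], seed: int = 0) -> list[Beat]:
    """Equalize per-class beat counts by seeded downsampling of the majority."""
    groups: dict[Label, list[Beat]] = defaultdict(list)
    for b in beats:
        groups[b.label].append(b)
    if Label.HYPER not in groups or Label.NORMO not in groups:
        raise InvalidArgumentError("both classes must be present to balance")
    n = min(len(groups[Label.HYPER]), len(groups[Label.NORMO]))
    rng = np.random.default_rng(seed)
    out = []
    for label in (Label.NORMO, Label.HYPER):
        pool = groups[label]
        idx = rng.choice(len(pool), size=n, replace=False) \
            if len(pool) > n else np.arange(n)
        out.extend(pool[i] for i in sorted(idx))
    return out


class PlateauScheduler:
    """Halve the rate after ``patience`` consecutive epochs without a new
    validation-loss minimum; the stale counter resets on improvement and
    after each reduction."""

    def __init__(self, initial_lr: float, factor: float = 0.5, patience: int = 3):
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def step(self, loss: float) -> float:
        """Record one epoch's monitored loss; return the rate for the next
        epoch."""
        if loss < self.best:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr *= self.factor
                self.stale = 0
        return self.lr


def lr_schedule(losses: list[float], config: TrainConfig | None = None
                ) -> list[float]:
    """Learning rate in effect at each epoch 1..len(losses)+1 given the
    monitored loss history."""
    config = config or TrainConfig()
    sched = PlateauScheduler(config.learning_rate, config.plateau_factor,
                             config.plateau_patience)
    rates = [sched.lr]
    for loss in losses:
        rates.append(sched.step(loss))
    return rates


def beats_to_arrays(beats: list[Beat]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([b.samples for b in beats]).astype(np.float32)
    y = np.array([CLASS_INDEX[b.label] for b in beats], dtype=np.int64)
    return x, y


def evaluate_loss(model: ResNet1D, x: np.ndarray, y: np.ndarray,
                  batch_size: int = 512) -> tuple[float, float]:
    """(mean cross-entropy, accuracy) in evaluation mode."""
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i: i + batch_size], train=False)
        loss, _ = cross_entropy(logits, y[i: i + batch_size])
        losses.append(loss * len(logits))
        correct += int(np.sum(logits.argmax(axis=1) == y[i: i + batch_size]))
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_generic(train_beats: list[Beat], val_beats: list[Beat],
                  spec: NetworkSpec, config: TrainConfig | None = None
                  ) -> tuple[Checkpoint, TrainHistory]:
    """Train from random init; return the checkpoint of the epoch with the
    minimal validation loss plus the full training curve."""
    config = config or TrainConfig()
    if not train_beats or not val_beats:
        raise InvalidArgumentError("training and validation sets must be non-empty")
    if config.balance:
        train_beats = balance_classes(train_beats, seed=config.seed)
    x_train, y_train = beats_to_arrays(train_beats)
    x_val, y_val = beats_to_arrays(val_beats)

    model = build_network(spec, seed=config.seed)
    optimizer = Adam(model.named_parameters(), lr=config.learning_rate)
    scheduler = PlateauScheduler(config.learning_rate, config.plateau_factor,
                                 config.plateau_patience)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_state, best_loss, best_epoch = None, np.inf, -1
    lr = config.learning_rate
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i: i + config.batch_size]
            optimizer.zero_grad()
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits = cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch + 1}", history)
            model.backward(dlogits)
            optimizer.step(lr)
            epoch_losses.append(loss)
        val_loss, val_acc = evaluate_loss(model, x_val, y_val)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(
                f"non-finite validation loss at epoch {epoch + 1}", history)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        if val_loss < best_loss:
            best_loss, best_epoch = val_loss, epoch
            best_state = copy.deepcopy(model.state_dict())
        lr = scheduler.step(val_loss)

    model.load_state_dict(best_state)
    meta = {"epoch": best_epoch, "val_loss": best_loss, "seed": config.seed,
            "val_accuracy": history.val_accuracy[best_epoch],
            "history": {"train_loss": history.train_loss,
                        "val_loss": history.val_loss,
                        "learning_rate": history.learning_rate}}
    checkpoint = Checkpoint(spec=spec, weights=model.state_dict(), meta=meta,
                            freeze_mask={k: False
                                         for k in model.named_parameters()})
    return checkpoint, history


def predict_classes(model: ResNet1D, x: np.ndarray, batch_size: int = 512
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(argmax classes, hyperkalemia probabilities) in evaluation mode."""
    classes, probs = [], []
    for i in range(0, len(x), batch_size):
        p = softmax(model.forward(x[i: i + batch_size], train=False))
        classes.append(p.argmax(axis=1))
        probs.append(p[:, CLASS_INDEX[Label.HYPER]])
    return np.concatenate(classes), np.concatenate(probs)
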