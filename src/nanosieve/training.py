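"""Dataset splitting and the Adam training loop.

The reference recipe is Adam at learning rate 1e-3 with batch size 1000
for 6 epochs of cross-entropy on preprocessed 3000-sample windows; those
are the defaults here, with batch size and epochs reducible for smaller
corpora.  Splits are label-stratified and deterministic given the seed,
and the checkpoint retained is the one with the best validation
accuracy.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nanosieve.errors import ValidationError
from nanosieve import nn
from nanosieve.model import Network
from nanosieve.signal_io import Manifest

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 1000
    epochs: int = 6
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    device: str = "cpu"

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        f = self.split_fractions
        if len(f) != 3 or min(f) <= 0 or abs(sum(f) - 1.0) > 1e-9:
            raise ValidationError(
                f"split fractions must be positive and sum to 1, got {f}")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_accuracy: float
    wall_seconds: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def make_splits(manifest: Manifest, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                seed: int = 0) -> tuple[Manifest, Manifest, Manifest]:
    """Label-stratified, disjoint, exhaustive train/val/test manifests.

    Deterministic given the seed.  Raises if any class would be absent
    from any split.
    """
    if len(fractions) != 3 or min(fractions) <= 0 or abs(sum(fractions) - 1) > 1e-9:
        raise ValidationError(f"fractions must be positive and sum to 1: {fractions}")
    rng = np.random.default_rng(seed)
    rows = manifest.rows
    parts: dict[str, list[pd.DataFrame]] = {"train": [], "val": [], "test": []}
    for label in sorted(rows["label"].unique()):
        cls = rows[rows["label"] == label].reset_index(drop=True)
        order = rng.permutation(len(cls))
        n = len(cls)
        n_tr = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_tr = min(n_tr, n)
        n_val = min(n_val, n - n_tr)
        idx = {"train": order[:n_tr], "val": order[n_tr:n_tr + n_val],
               "test": order[n_tr + n_val:]}
        for name, ix in idx.items():
            if ix.size == 0:
                raise ValidationError(
                    f"class {label} absent from {name} split; "
                    f"{n} reads cannot fill fractions {fractions}")
            parts[name].append(cls.iloc[ix])
    out = []
    for name in ("train", "val", "test"):
        df = pd.concat(parts[name], ignore_index=True)
        out.append(Manifest(df.sort_values("read_id").reset_index(drop=True)))
    return tuple(out)


def _eval_network(network: Network, X: np.ndarray, y: np.ndarray,
                  batch_size: int = 512) -> tuple[float, float]:
    losses, correct = [], 0
    for start in range(0, len(X), batch_size):
        xb, yb = X[start:start + batch_size], y[start:start + batch_size]
        logits = network.logits(xb, training=False)
        loss, _ = nn.cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(network: Network, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray],
          config: TrainConfig | None = None) -> tuple[Network, TrainHistory]:
    """Cross-entropy Adam training; keeps the best-validation-accuracy state.

    ``train_set`` / ``val_set`` are (windows, labels) with windows shaped
    (n, input_length).  Fully reproducible given ``config.seed`` on one
    device.  Raises on an empty training set; aborts with diagnostics if
    the loss becomes non-finite.
    """
    config = config or TrainConfig()
    config.validate()
    X_tr, y_tr = np.asarray(train_set[0], dtype=nn.DTYPE), np.asarray(train_set[1])
    X_val, y_val = np.asarray(val_set[0], dtype=nn.DTYPE), np.asarray(val_set[1])
    if len(X_tr) == 0:
        raise ValidationError("training set is empty")
    if len(X_val) == 0:
        raise ValidationError("validation set is empty")

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(network.trainable_layers(), lr=config.learning_rate)
    history = TrainHistory()
    best_state: dict[str, np.ndarray] | None = None

    for epoch in range(1, config.epochs + 1):
        t0 = time.perf_counter()
        order = rng.permutation(len(X_tr))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(X_tr), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = network.logits(X_tr[idx], training=True)
            loss, dlogits = nn.cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{start // config.batch_size}: loss={loss}")
            network.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        val_loss, val_acc = _eval_network(network, X_val, y_val)
        rec = EpochRecord(epoch=epoch, train_loss=epoch_loss / n_seen,
                          val_loss=val_loss, val_accuracy=val_acc,
                          wall_seconds=time.perf_counter() - t0)
        history.records.append(rec)
        logger.info("epoch %d: train_loss=%.4f val_loss=%.4f val_acc=%.4f (%.1fs)",
                    epoch, rec.train_loss, rec.val_loss, rec.val_accuracy,
                    rec.wall_seconds)
        if not (history.best_val_accuracy >= val_acc):  # NaN-safe first epoch
            history.best_val_accuracy = val_acc
            history.best_epoch = epoch
            best_state = copy.deepcopy(network.state_dict())

    if best_state is not None:
        network.load_state_dict(best_state)
    # refresh batch-norm running statistics on the training data so that
    # evaluation-mode inference does not rely on mid-training estimates
    for start in range(0, len(X_tr), 256):
        network.logits(X_tr[start:start + 256], training=True)
    return network, history
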