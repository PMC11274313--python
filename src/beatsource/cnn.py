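"""The supervised 1D-CNN classifier: build, train, predict, persist.

Architecture: four conv(k=9) -> ReLU -> maxpool(2) blocks with channel
widths 16/32/64/128, a flatten, and one fully connected layer to two logits
followed by softmax.  Training minimises cross-entropy with Adam at the
fixed learning rate 6.066e-4, batch size 64; the delivered model is the
epoch checkpoint with the best validation loss.  Class 0 is fetal, class 1
vessel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Union

import numpy as np

from .config import CnnConfig
from .nn import Adam, Conv1d, Flatten, Linear, MaxPool1d, ReLU, Sequential, cross_entropy, softmax
from .pipeline import SplitDataset
from .signals import Window, as_window_matrix

INPUT_SAMPLES = 2000
CLASS_NAMES = ("fetal", "vessel")


class TrainingDiverged(RuntimeError):
    pass


def build_model(cfg: CnnConfig) -> Sequential:
    """Construct the seeded, untrained network for 2000-sample windows."""
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 7])
    layers = []
    length, channels = INPUT_SAMPLES, 1
    for cout, k, p in zip(cfg.channels, cfg.kernel_sizes, cfg.pool_sizes):
        layers += [Conv1d(channels, cout, k, rng), ReLU(), MaxPool1d(p)]
        length = (length - k + 1) // p
        if length < 1:
            raise ValueError("configuration collapses the sequence to zero length")
        channels = cout
    layers += [Flatten(), Linear(length * channels, 2, rng)]
    return Sequential(layers)


@dataclass
class TrainedModel:
    """A trained network plus its config and per-epoch history."""

    model: Sequential
    config: CnnConfig
    history: Dict[str, List[float]] = field(default_factory=dict)

    def predict_proba(self, windows) -> np.ndarray:
        return predict_proba(self, windows)

    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "parameters.npz", **self.model.state_dict())
        meta = {
            "config": {
                "channels": list(self.config.channels),
                "kernel_sizes": list(self.config.kernel_sizes),
                "pool_sizes": list(self.config.pool_sizes),
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "learning_rate": self.config.learning_rate,
                "seed": self.config.seed,
                "device": self.config.device,
            },
            "history": self.history,
            "classes": list(CLASS_NAMES),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg = CnnConfig(**meta["config"])
        model = build_model(cfg)
        with np.load(directory / "parameters.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return cls(model=model, config=cfg, history=meta.get("history", {}))


def _as_batches(n: int, batch_size: int, perm: np.ndarray):
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def _eval_loss_acc(model: Sequential, x: np.ndarray, y: np.ndarray,
                   batch_size: int = 256):
    losses, correct = [], 0
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size, :, None]
        yb = y[start:start + batch_size]
        logits = model.forward(xb)
        loss, _, p = cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        correct += int((p.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model: Sequential, data: Union[SplitDataset, dict], cfg: CnnConfig) -> TrainedModel:
    """Train with Adam/cross-entropy; return the best-validation-loss epoch.

    ``data`` is a SplitDataset or a dict with keys ``x_train, y_train,
    x_val, y_val`` (windows as (n, 2000) float arrays, labels 0=fetal,
    1=vessel).  Shuffling is seeded; history records per-epoch training
    loss and validation loss/accuracy.
    """
    cfg.validate()
    if isinstance(data, SplitDataset):
        x_train, y_train = data.window_array("train")
        x_val, y_val = data.window_array("validation")
    else:
        x_train = np.asarray(data["x_train"], dtype=np.float32)
        y_train = np.asarray(data["y_train"], dtype=np.int64)
        x_val = np.asarray(data["x_val"], dtype=np.float32)
        y_val = np.asarray(data["y_val"], dtype=np.int64)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    if len(x_val) == 0:
        raise ValueError("validation set is empty")

    opt = Adam(model, cfg.learning_rate)
    shuffle_rng = np.random.default_rng([int(cfg.seed), 8])
    history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best_loss, best_state = np.inf, None
    for epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(len(x_train))
        epoch_losses = []
        for idx in _as_batches(len(x_train), cfg.batch_size, perm):
            xb = x_train[idx][:, :, None]
            logits = model.forward(xb)
            loss, dlogits, _ = cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch + 1}; "
                    "lower the learning rate or check the input scaling"
                )
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss * len(idx))
        val_loss, val_acc = _eval_loss_acc(model, x_val, y_val)
        history["train_loss"].append(float(np.sum(epoch_losses) / len(x_train)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainedModel(model=model, config=cfg, history=history)


def predict_proba(model: Union[TrainedModel, Sequential], windows,
                  batch_size: int = 256) -> np.ndarray:
    """Per-window class probabilities, columns (p_fetal, p_vessel)."""
    net = model.model if isinstance(model, TrainedModel) else model
    if isinstance(windows, np.ndarray) and windows.ndim == 2:
        x = windows.astype(np.float32)
    elif isinstance(windows, (Window, np.ndarray)) and np.asarray(windows).ndim == 1:
        x = as_window_matrix([windows])
    else:
        x = as_window_matrix(windows)
    if x.shape[1] != INPUT_SAMPLES:
        raise ValueError(f"windows must have {INPUT_SAMPLES} samples, got {x.shape[1]}")
    out = np.empty((len(x), 2), dtype=np.float64)
    for start in range(0, len(x), batch_size):
        logits = net.forward(x[start:start + batch_size, :, None])
        out[start:start + batch_size] = softmax(logits)
    return out


def predict_labels(model: Union[TrainedModel, Sequential], windows) -> np.ndarray:
    """Hard labels by argmax; exact ties go to the fetal majority class."""
    proba = predict_proba(model, windows)
    labels = np.where(proba[:, 1] > proba[:, 0], "vessel", "fetal")
    return labels.astype(object)
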