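"""Tissue-patch classifier with a two-layer replacement head.

Backbone-agnostic: any feature extractor satisfying the ``images in,
feature vectors out`` contract can sit under the head, which is always
FC -> ReLU -> dropout(0.5) -> FC -> softmax.  The bundled desk-scale
backbone is a four-block CNN; an adapter slot is left for a user-supplied
GoogleNet/InceptionV3-style network, whose pretrained weights are an
external concern.

Training is plain SGD with the recursive cosine learning-rate scheme

    lr_ep = lr_{ep-1} * [ (1 + cos(pi * ep / epochs)) / 2 * (1 - lr_f) + lr_f ]

applied once per epoch (ep = 1..epochs).  Note the recursion: each epoch's
rate multiplies the previous one, so the decay is faster than standard
(non-recursive) cosine annealing; at ep = epochs the factor is exactly
lr_f.  The same classifier object serves three roles in the pipeline:
baseline model, confidence scorer for synthetic-image selection, and the
final augmented model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .data import LabeledImageSet

__all__ = [
    "ClassifierConfig",
    "LRScheduleState",
    "lr_step",
    "lr_schedule",
    "SmallCnnClassifier",
    "build_classifier",
    "train_classifier",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1

BACKBONES = ("small_cnn",)


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    n_classes: int = 9
    backbone: str = "small_cnn"
    hidden_width: int = 256
    dropout_p: float = 0.5
    lr_initial: float = 0.001
    lr_f: float = 0.1
    momentum: float = 0.0
    epochs: int = 20
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")
        if not 0.0 < self.lr_f <= 1.0:
            raise ValueError("lr_f must be in (0, 1]")
        if self.backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; available: {BACKBONES}")


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LRScheduleState:
    lr_prev: float
    ep: int
    epochs: int
    lr_f: float

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 1 <= self.ep <= self.epochs:
            raise ValueError(f"ep must lie in [1, {self.epochs}], got {self.ep}")
        if self.lr_prev <= 0:
            raise ValueError("lr_prev must be positive")


def lr_step(state: LRScheduleState) -> float:
    """One epoch of the recursive cosine scheme; the factor lies in [lr_f, 1]."""
    bracket = (1.0 + np.cos(np.pi * state.ep / state.epochs)) / 2.0 \
        * (1.0 - state.lr_f) + state.lr_f
    return float(state.lr_prev * bracket)


def lr_schedule(lr_initial: float, epochs: int, lr_f: float) -> np.ndarray:
    """Learning rate used during each epoch 1..epochs.

    Epoch 1 runs at ``lr_initial``; the recursive factor is applied at the
    end of each epoch, so epoch e runs at lr_initial * prod_{ep<e} factor(ep).
    """
    rates = np.empty(epochs)
    lr = lr_initial
    for ep in range(1, epochs + 1):
        rates[ep - 1] = lr
        lr = lr_step(LRScheduleState(lr, ep, epochs, lr_f))
    return rates


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class _SmallCnnBackbone(nn.Module):
    """Four conv blocks (3x3 conv, leaky ReLU, 2x2 average pool) + flatten."""

    CHANNELS = (16, 32, 64, 64)

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        c_in = 3
        for i, c_out in enumerate(self.CHANNELS):
            setattr(self, f"conv{i}", nn.Conv2d(c_in, c_out, 3, rng))
            c_in = c_out
        self.act = nn.LeakyReLU(0.1)
        self.pool = nn.AvgPool2x()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        for i in range(len(self.CHANNELS)):
            x = self.pool(self.act(getattr(self, f"conv{i}")(x)))
        return x.reshape(x.shape[0], -1)

    def feature_dim(self, resolution: int) -> int:
        return self.CHANNELS[-1] * (resolution // 2 ** len(self.CHANNELS)) ** 2


class SmallCnnClassifier(nn.Module):
    """Backbone + the two-FC replacement head (ReLU, dropout, softmax)."""

    def __init__(self, config: ClassifierConfig, resolution: int):
        super().__init__()
        if resolution < 2 ** len(_SmallCnnBackbone.CHANNELS):
            raise ValueError(f"resolution {resolution} too small for the backbone")
        self.config = config
        self.resolution = int(resolution)
        ss = np.random.SeedSequence([config.seed, 0xC1F])
        init_seed, drop_seed = ss.spawn(2)
        rng = np.random.default_rng(init_seed)
        self.backbone = _SmallCnnBackbone(rng)
        feat = self.backbone.feature_dim(resolution)
        self.fc1 = nn.Linear(feat, config.hidden_width, rng)
        self.fc2 = nn.Linear(config.hidden_width, config.n_classes, rng)
        self.relu = nn.ReLU()
        self.dropout = nn.Dropout(config.dropout_p,
                                  seed=int(drop_seed.generate_state(1)[0] % 2**31))
        self.fitted = False

    def logits(self, x: nn.Tensor) -> nn.Tensor:
        h = self.backbone(x)
        h = self.dropout(self.relu(self.fc1(h)))
        return self.fc2(h)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.logits(x)


def build_classifier(config: ClassifierConfig,
                     resolution: int = 32) -> SmallCnnClassifier:
    """Untrained classifier; two builds from the same seed are identical."""
    return SmallCnnClassifier(config, resolution)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

def _to_nchw(images: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2))


def _forward_proba(model: SmallCnnClassifier, images_nchw: np.ndarray,
                   batch_size: int = 256) -> np.ndarray:
    outs = []
    for start in range(0, len(images_nchw), batch_size):
        x = nn.Tensor(images_nchw[start:start + batch_size])
        lsm = nn.log_softmax(model.logits(x))
        outs.append(np.exp(lsm.data.astype(np.float64)))
    return np.concatenate(outs)


def predict_proba(model: SmallCnnClassifier, images: LabeledImageSet | np.ndarray) -> np.ndarray:
    """(N, K) class-probability matrix; rows sum to 1."""
    arr = images.images if isinstance(images, LabeledImageSet) else np.asarray(images)
    if arr.shape[1] != model.resolution:
        raise ValueError(
            f"images are {arr.shape[1]}px, model expects {model.resolution}px")
    model.eval()
    probs = _forward_proba(model, _to_nchw(arr))
    return probs / probs.sum(axis=1, keepdims=True)


def _accuracy(model: SmallCnnClassifier, images_nchw, labels) -> float:
    probs = _forward_proba(model, images_nchw)
    return float((probs.argmax(axis=1) == labels).mean())


def train_classifier(train: LabeledImageSet, val: LabeledImageSet | None,
                     config: ClassifierConfig) -> tuple[SmallCnnClassifier, pd.DataFrame]:
    """SGD training with the cosine-recursive schedule; returns model + log.

    The log has one row per epoch: (epoch, lr, train_loss, train_acc,
    val_acc); ``val_acc`` is NaN when no validation set is supplied.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if val is not None and val.class_names != train.class_names:
        raise ValueError("train and validation class sets differ")
    if train.n_classes != config.n_classes:
        raise ValueError(
            f"config expects {config.n_classes} classes, data has {train.n_classes}")
    model = build_classifier(config, resolution=train.resolution)
    opt = nn.SGD(model.parameters(), config.lr_initial, momentum=config.momentum)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x70A]))
    x_all = _to_nchw(train.images)
    y_all = train.labels
    onehot = np.eye(config.n_classes, dtype=np.float32)[y_all]
    x_val = _to_nchw(val.images) if val is not None else None
    rows = []
    lr = config.lr_initial
    for ep in range(1, config.epochs + 1):
        model.train()
        opt.lr = lr
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(train), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = nn.Tensor(x_all[idx])
            lsm = nn.log_softmax(model.logits(x))
            loss = -(lsm * nn.Tensor(onehot[idx])).sum() * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            lval = float(loss.item())
            if not np.isfinite(lval):
                raise RuntimeError(f"non-finite training loss at epoch {ep}")
            losses.append(lval)
        model.eval()
        train_acc = _accuracy(model, x_all, y_all)
        val_acc = _accuracy(model, x_val, val.labels) if val is not None else np.nan
        rows.append((ep, lr, float(np.mean(losses)), train_acc, val_acc))
        lr = lr_step(LRScheduleState(lr, ep, config.epochs, config.lr_f))
    model.fitted = True
    model.eval()
    return model, pd.DataFrame(
        rows, columns=["epoch", "lr", "train_loss", "train_acc", "val_acc"])


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SmallCnnClassifier, path: str | Path,
                    class_names: list[str] | None = None) -> None:
    header = {
        "version": CHECKPOINT_VERSION,
        "kind": "classifier",
        "config": dataclasses.asdict(model.config),
        "resolution": model.resolution,
        "fitted": model.fitted,
        "class_names": class_names,
    }
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **model.state_arrays())


def load_checkpoint(path: str | Path) -> tuple[SmallCnnClassifier, list[str] | None]:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        if header.get("kind") != "classifier":
            raise ValueError(f"{path} is not a classifier checkpoint")
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        arrays = {k: npz[k] for k in npz.files if k != "__header__"}
    model = SmallCnnClassifier(ClassifierConfig(**header["config"]),
                               header["resolution"])
    model.load_state_arrays(arrays)
    model.fitted = header["fitted"]
    model.eval()
    return model, header["class_names"]
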