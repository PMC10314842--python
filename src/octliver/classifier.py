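"""Binary tile classifier: architecture, training loop and inference.

The model maps one grayscale 299x299 tile, replicated onto three input
channels, through a convolutional trunk to global average pooling, a single
fully connected output and a sigmoid, yielding the probability that the
tile shows tumor tissue.  Two trunks share this head:

* ``xception`` — the 36-layer depthwise-separable-convolution stack, for
  GPU-scale fine-tuning (optional, needs torch);
* ``small_cnn`` — a fixed NumPy trunk under 10k parameters, so the whole
  pipeline runs on one CPU.

Training minimizes per-tile binary cross-entropy
``L = -[y log p + (1 - y) log(1 - p)]`` with mini-batch Adam and seeded
shuffling, recording loss and F1 on the training and validation partitions
every epoch.  Defaults follow the fine-tuning protocol (batch 20, 10
epochs, learning rate 1e-5); :func:`small_cnn_config` supplies the
from-scratch settings for the small trunk, which needs a conventional Adam
step size because its weights start at random rather than pretrained
values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._smallcnn import Adam, SmallCNN, bce_loss_and_dlogits, bce_loss_from_proba
from .exceptions import ParameterError, TrainingDataError

BACKBONES = ("xception", "small_cnn")


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "small_cnn"
    input_size_px: int = 299
    batch_size: int = 20
    epochs: int = 10
    learning_rate: float = 1e-5
    decision_threshold: float = 0.5
    seed: int = 0
    pretrained: bool = False

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ParameterError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ParameterError("decision_threshold must be in (0, 1)")


def small_cnn_config(seed: int = 0, epochs: int = 5, learning_rate: float = 1e-3,
                     **overrides) -> TrainConfig:
    """From-scratch training settings for the small CPU trunk."""
    return TrainConfig(
        backbone="small_cnn", epochs=epochs, learning_rate=learning_rate,
        seed=seed, **overrides,
    )


@dataclass
class EpochTrace:
    """Per-epoch learning curves for one training run."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_f1: list = field(default_factory=list)
    val_f1: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def build_model(config: TrainConfig):
    """Instantiate the configured backbone with the shared binary head."""
    if config.backbone == "small_cnn":
        return SmallCNN(seed=config.seed)
    if config.backbone == "xception":
        from ._xception import build_xception

        return build_xception(seed=config.seed, pretrained=config.pretrained)
    raise ParameterError(f"unknown backbone {config.backbone!r}")  # pragma: no cover


def tiles_to_arrays(tiles) -> tuple[np.ndarray, np.ndarray]:
    """Stack tiles into (pixels uint8 (N, s, s), y uint8 with tumor = 1)."""
    if len(tiles) == 0:
        return np.empty((0, 0, 0), dtype=np.uint8), np.empty(0, dtype=np.uint8)
    pixels = np.stack([np.asarray(t.pixels, dtype=np.uint8) for t in tiles])
    y = np.array([1 if t.label == "tumor" else 0 for t in tiles], dtype=np.uint8)
    return pixels, y


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    den = 2 * tp + fp + fn
    return 2 * tp / den if den else 0.0


def _check_partition(y: np.ndarray, name: str) -> None:
    if y.size == 0:
        raise TrainingDataError(f"{name} partition is empty")
    if len(np.unique(y)) < 2:
        raise TrainingDataError(
            f"{name} partition contains a single class; loss and F1 are not meaningful"
        )


def train(model, train_tiles, val_tiles, config: TrainConfig):
    """Mini-batch gradient training of the small trunk.

    Returns ``(model, EpochTrace)``.  Training metrics are the running
    per-batch values of the epoch; validation metrics are recomputed on the
    full validation partition after each epoch.
    """
    if not isinstance(model, SmallCNN):
        raise ParameterError(
            "the NumPy training loop supports the small_cnn backbone; train the "
            "xception backbone with a torch loop"
        )
    x_train, y_train = tiles_to_arrays(train_tiles)
    x_val, y_val = tiles_to_arrays(val_tiles)
    _check_partition(y_train, "training")
    _check_partition(y_val, "validation")
    _check_tile_size(x_train, config)
    _check_tile_size(x_val, config)

    optim = Adam(model.params, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    trace = EpochTrace()
    thr = config.decision_threshold
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(x_train.shape[0])
        loss_sum = 0.0
        preds = np.empty_like(y_train)
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = model.prepare(x_train[idx])
            yb = y_train[idx]
            logits, cache = model.forward(xb, keep_cache=True)
            loss, dlogits = bce_loss_and_dlogits(logits, yb)
            grads = model.backward(cache, dlogits)
            optim.step(model.params, grads)
            loss_sum += loss * idx.size
            preds[idx] = (1.0 / (1.0 + np.exp(-logits)) >= thr).astype(np.uint8)
        trace.train_loss.append(loss_sum / order.size)
        trace.train_f1.append(_binary_f1(y_train, preds))
        p_val = model.predict_proba(x_val)
        trace.val_loss.append(bce_loss_from_proba(p_val, y_val))
        trace.val_f1.append(_binary_f1(y_val, (p_val >= thr).astype(np.uint8)))
    return model, trace


def _check_tile_size(pixels: np.ndarray, config: TrainConfig) -> None:
    expected = (config.input_size_px, config.input_size_px)
    if pixels.shape[1:] != expected:
        raise ParameterError(
            f"tile size {pixels.shape[1:]} does not match model input {expected}"
        )


def predict(model, tiles, config: TrainConfig) -> tuple[np.ndarray, list[str]]:
    """Per-tile tumor probabilities and thresholded labels, order preserved.

    A tile is called tumor when its probability reaches the decision
    threshold (``>=``).
    """
    pixels, _ = tiles_to_arrays(tiles)
    _check_tile_size(pixels, config)
    probs = model.predict_proba(pixels, batch_size=max(config.batch_size, 64))
    labels = ["tumor" if p >= config.decision_threshold else "healthy" for p in probs]
    return probs, labels


def save_model(model: SmallCNN, config: TrainConfig, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "weights.npz", **model.state_dict())
    (out_dir / "config.json").write_text(json.dumps(asdict(config), indent=1))
    return out_dir


def load_model(model_dir) -> tuple[SmallCNN, TrainConfig]:
    model_dir = Path(model_dir)
    config = TrainConfig(**json.loads((model_dir / "config.json").read_text()))
    model = SmallCNN(seed=config.seed)
    with np.load(model_dir / "weights.npz") as npz:
        model.load_state_dict(dict(npz))
    return model, config


__all__ = [
    "BACKBONES",
    "TrainConfig",
    "EpochTrace",
    "small_cnn_config",
    "build_model",
    "tiles_to_arrays",
    "train",
    "predict",
    "save_model",
    "load_model",
]
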