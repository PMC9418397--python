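"""Severity-grading CNN: configuration, training loop and prediction.

The default network takes single-channel rectangular 180x80 inputs through
three conv/pool blocks (16, 32, 64 filters, 3x3 kernels, 2x2 max pooling),
dropout, a 128-unit dense layer and a softmax head over 5 or 6 classes.
A square-input (227x227) variant is provided for resized/padded encodings;
pretrained-weight initialization is deliberately not implemented (it would
require an external download) and raises if requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .balancing import AugmentationPolicy, online_augment
from .network import Adam, Conv2D, Dense, Dropout, Flatten, MaxPool2, Network, ReLU, SGD, softmax, weighted_cross_entropy

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "Model",
    "build_network",
    "train_network",
    "predict",
    "square_input_config",
    "save_model",
    "load_model",
]


@dataclass
class NetworkConfig:
    input_shape: tuple[int, int] = (180, 80)
    channels: int = 1
    num_classes: int = 6
    conv_filters: tuple[int, ...] = (16, 32, 64)
    kernel: int = 3
    dense_width: int = 128
    dropout: float = 0.5
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.num_classes not in (5, 6):
            raise ValueError(f"num_classes must be 5 or 6, got {self.num_classes}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {self.dropout}")
        if len(self.conv_filters) == 0:
            raise ValueError("need at least one conv block")


def square_input_config(num_classes: int = 6, channels: int = 3) -> NetworkConfig:
    """227x227 variant for resized/padded encodings (from-scratch weights)."""
    return NetworkConfig(
        input_shape=(227, 227),
        channels=channels,
        num_classes=num_classes,
        conv_filters=(16, 32, 64),
    )


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    class_weights: np.ndarray | list[float] | None = None
    online_policy: AugmentationPolicy | None = None
    seed: int = 0
    early_stop_val_accuracy: float | None = None  # stop once val accuracy >= this

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class Model:
    """Model handle: the layer stack plus the config it was built from."""

    net: Network
    config: NetworkConfig
    seed: int

    def parameter_count(self) -> int:
        return self.net.parameter_count()


def build_network(cfg: NetworkConfig, seed: int = 0) -> Model:
    """Instantiate the CNN with seeded He-initialized weights."""
    if cfg.pretrained:
        raise NotImplementedError(
            "pretrained initialization requires an external weight download "
            "and is not available; build with pretrained=False"
        )
    rng = np.random.default_rng(seed)
    h, w = cfg.input_shape
    layers: list = []
    in_ch = cfg.channels
    for out_ch in cfg.conv_filters:
        layers += [Conv2D(in_ch, out_ch, cfg.kernel, rng), ReLU(), MaxPool2()]
        in_ch = out_ch
        h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError("too many conv blocks for the input size")
    layers.append(Flatten())
    if cfg.dropout > 0:
        layers.append(Dropout(cfg.dropout))
    layers += [
        Dense(h * w * in_ch, cfg.dense_width, rng),
        ReLU(),
        Dense(cfg.dense_width, cfg.num_classes, rng),
    ]
    return Model(net=Network(layers), config=cfg, seed=seed)


def _as_batch(x: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Coerce (N,H,W) or (N,C,H,W) float arrays to the model's input layout."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if x.ndim != 4:
        raise ValueError(f"expected (N,H,W) or (N,C,H,W) input, got shape {x.shape}")
    if x.shape[1] == 1 and cfg.channels > 1:
        x = np.repeat(x, cfg.channels, axis=1)
    if x.shape[1:] != (cfg.channels, *cfg.input_shape):
        raise ValueError(
            f"input shape {x.shape[1:]} does not match network "
            f"{(cfg.channels, *cfg.input_shape)}"
        )
    return x


def train_network(
    model: Model,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    tc: TrainConfig | None = None,
) -> list[dict]:
    """Minimize (optionally class-weighted) cross-entropy; keep best-val weights.

    Returns one history row per completed epoch with train/val loss and
    accuracy.  When validation data is supplied, the weights achieving the
    best validation accuracy are restored into the model at the end.
    """
    tc = tc or TrainConfig()
    y_train = np.asarray(y_train, dtype=int)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if len(x_train) != len(y_train):
        raise ValueError("x_train and y_train length mismatch")
    k = model.config.num_classes
    if y_train.min() < 0 or y_train.max() >= k:
        raise ValueError(f"labels must lie in [0,{k}), got range "
                         f"[{y_train.min()},{y_train.max()}]")
    weights = None
    if tc.class_weights is not None:
        weights = np.asarray(tc.class_weights, dtype=float)
        if weights.shape != (k,):
            raise ValueError(f"class_weights must have length {k}")

    xb_all = _as_batch(x_train, model.config)
    rng = np.random.default_rng(tc.seed)
    if tc.optimizer == "adam":
        opt = Adam(model.net.params, lr=tc.learning_rate)
    else:
        opt = SGD(model.net.params, lr=tc.learning_rate)

    history: list[dict] = []
    best_val_acc = -1.0
    best_weights = None
    n = len(xb_all)
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb = xb_all[idx]
            yb = y_train[idx]
            if tc.online_policy is not None:
                xb = np.stack(
                    [_augment_array(img, tc.online_policy, rng) for img in xb]
                )
            logits = model.net.forward(xb, train=True, rng=rng)
            probs = softmax(logits)
            loss, grad = weighted_cross_entropy(probs, yb, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // tc.batch_size}; "
                    "reduce the learning rate or check the inputs"
                )
            model.net.backward(grad)
            opt.step(model.net.grads)
            epoch_loss += loss * len(idx)
            correct += int((probs.argmax(axis=1) == yb).sum())
        row = {
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "train_accuracy": correct / n,
        }
        if x_val is not None and y_val is not None and len(x_val):
            val_labels, val_probs = predict(model, x_val)
            y_val_arr = np.asarray(y_val, dtype=int)
            eps = 1e-12
            row["val_loss"] = float(
                -np.log(val_probs[np.arange(len(y_val_arr)), y_val_arr] + eps).mean()
            )
            row["val_accuracy"] = float((val_labels == y_val_arr).mean())
            if row["val_accuracy"] > best_val_acc:
                best_val_acc = row["val_accuracy"]
                best_weights = model.net.get_weights()
        history.append(row)
        if (
            tc.early_stop_val_accuracy is not None
            and row.get("val_accuracy", -1.0) >= tc.early_stop_val_accuracy
        ):
            break
    if best_weights is not None:
        model.net.set_weights(best_weights)
    return history


def _augment_array(img: np.ndarray, policy: AugmentationPolicy,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply the online policy channel-wise to a (C,H,W) float array."""
    from .core import EncodedInput, EncodeMode

    out = np.empty_like(img)
    sample = EncodedInput(values=img[0].astype(float), mode=EncodeMode.RECTANGULAR)
    aug = online_augment(sample, policy, rng).values.astype(img.dtype)
    for c in range(img.shape[0]):
        out[c] = aug  # channels are replicated copies of one thermal channel
    return out


def predict(
    model: Model, x: np.ndarray, batch_size: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels and softmax probability vectors (dropout disabled).

    Evaluation runs in chunks of `batch_size` to bound the im2col memory.
    """
    xb = _as_batch(x, model.config)
    probs = np.concatenate(
        [
            model.net.predict_proba(xb[i : i + batch_size])
            for i in range(0, len(xb), batch_size)
        ]
    )
    return probs.argmax(axis=1), probs


def save_model(model: Model, path) -> None:
    """Checkpoint weights plus the embedded NetworkConfig as .npz."""
    import dataclasses
    import json

    cfg = dataclasses.asdict(model.config)
    arrays = {f"param_{i}": w for i, w in enumerate(model.net.get_weights())}
    np.savez(path, __config__=json.dumps(cfg), __seed__=model.seed, **arrays)


def load_model(path) -> Model:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
        model = build_network(NetworkConfig(**cfg_dict), seed=int(data["__seed__"]))
        weights = [data[f"param_{i}"] for i in range(len(model.net.params))]
    model.net.set_weights(weights)
    return model
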