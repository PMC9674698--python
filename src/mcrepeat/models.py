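"""Small trainable severity classifiers with spatial dropout (model zoo).

The default backbone is a three-block CNN for 32x32 grayscale inputs:

    [conv3x3 -> ReLU -> maxpool2 -> channel dropout] x 3
    flatten -> dense(hidden) -> ReLU -> head

Channel (spatial) dropout sits after each conv block only, mirroring the
placement used for residual-block backbones; the dense classifier stage
is deterministic.

The same dropout layers are re-sampled at test time for Monte Carlo
inference. Four head types are supported, each with its training loss:

    binary     1 logit,  sigmoid,  binary cross-entropy
    multiclass k logits, softmax,  cross-entropy
    ordinal    k-1 logits (shared weight vector + rank biases, CORAL),
               per-task sigmoid, summed binary cross-entropy
    regression 1 linear output, MSE against the class index

Conventional ("no-dropout") variants contain no dropout layers at all and
are fully deterministic; dropout variants use the same architecture plus
the dropout layers, toggled by one config field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from mcrepeat import nn
from mcrepeat.scoring import HeadKind, encode_ordinal_label

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "SmallCNN",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
    "bce_with_logits",
    "cross_entropy",
    "coral_loss",
    "mse_loss",
    "train",
    "TrainHistory",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for :func:`build_model`.

    ``dropout_rate=None`` builds a conventional model with no dropout
    layers; ``dropout_rate=0.0`` keeps the layers in place but makes them
    inert (useful for degenerate-dropout checks).
    """

    head: HeadKind
    dropout_rate: float | None = 0.1
    input_size: int = 32
    channels: tuple[int, int, int] = (8, 16, 32)
    hidden: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dropout_rate is not None and not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (three 2x2 pools)")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults: Adam, reduce-on-plateau scheduler (factor 0.1, patience 10
    epochs), training-only augmentation of rotations within +/-15 degrees
    and horizontal flips with 50% probability.
    """

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 75
    seed: int = 0
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10
    rotation_deg: float = 15.0
    hflip_prob: float = 0.5
    augment: bool = True
    snapshot: str = "final"  # or "best_val"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.snapshot not in ("final", "best_val"):
            raise ValueError("snapshot must be 'final' or 'best_val'")


class SmallCNN:
    """A predictor with deterministic and dropout-active forward modes."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        c1, c2, c3 = spec.channels
        layers: list[nn.Layer] = []
        for cin, cout in ((1, c1), (c1, c2), (c2, c3)):
            layers += [nn.Conv2d(cin, cout, rng=rng), nn.ReLU(), nn.MaxPool2d(2)]
            if spec.dropout_rate is not None:
                layers.append(nn.ChannelDropout(spec.dropout_rate))
        feat = c3 * (spec.input_size // 8) ** 2
        layers += [nn.Flatten(), nn.Dense(feat, spec.hidden, rng=rng), nn.ReLU()]
        head = spec.head
        if head.kind == "ordinal":
            layers.append(nn.CoralHead(spec.hidden, head.k, rng=rng))
        else:
            layers.append(nn.Dense(spec.hidden, head.output_width, rng=rng))
        self.net = nn.Sequential(layers)

    # -- inference ---------------------------------------------------------
    @property
    def head(self) -> HeadKind:
        return self.spec.head

    @property
    def has_dropout(self) -> bool:
        """True iff the network contains dropout layers (of any rate)."""
        return len(self.net.dropout_layers) > 0

    def forward_logits(self, x: np.ndarray, *, stochastic: bool = False, rng=None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return self.net.forward(x, stochastic=stochastic, rng=rng)

    def predict(self, x: np.ndarray, *, stochastic: bool = False, rng=None) -> np.ndarray:
        """Head output in probability/score space, one row per input image.

        binary -> sigmoid probability (B, 1); multiclass -> softmax
        (B, k); ordinal -> per-threshold sigmoids (B, k-1); regression ->
        raw scalar (B, 1).
        """
        z = self.forward_logits(x, stochastic=stochastic, rng=rng)
        kind = self.head.kind
        if kind == "multiclass":
            return _softmax(z)
        if kind in ("binary", "ordinal"):
            return _sigmoid(z)
        return z  # regression

    # -- persistence -------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return self.net.get_state()

    def set_state(self, state: list[np.ndarray]) -> None:
        self.net.set_state(state)


def build_model(spec: ModelSpec) -> SmallCNN:
    """Instantiate the small CNN for ``spec`` (seeded, reproducible)."""
    return SmallCNN(spec)


def save_checkpoint(model: SmallCNN, path, train_cfg: TrainConfig | None = None) -> None:
    """Serialize weights plus the embedded ModelSpec (and TrainConfig)."""
    import json
    from dataclasses import asdict

    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta = {"spec": asdict(model.spec)}
    if train_cfg is not None:
        meta["train"] = asdict(train_cfg)
    arrays = {f"p{i}": p for i, p in enumerate(model.get_state())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[SmallCNN, TrainConfig | None]:
    """Rebuild a model (and its TrainConfig, if stored) from a checkpoint."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        n = len([k for k in data.files if k.startswith("p")])
        state = [data[f"p{i}"] for i in range(n)]
    spec_d = meta["spec"]
    spec_d["head"] = HeadKind(**spec_d["head"])
    spec_d["channels"] = tuple(spec_d["channels"])
    spec = ModelSpec(**spec_d)
    model = build_model(spec)
    model.set_state(state)
    train_cfg = TrainConfig(**meta["train"]) if "train" in meta else None
    return model, train_cfg


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


# -- losses (value + gradient wrt logits, averaged over the batch) ---------

def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy; mean over batch, summed
    over output units (so the ordinal case sums its k-1 tasks)."""
    z, t = np.asarray(logits, float), np.asarray(targets, float)
    per = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    loss = per.sum(axis=-1).mean()
    grad = (_sigmoid(z) - t) / z.shape[0]
    return float(loss), grad


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy against integer class labels."""
    z = np.asarray(logits, float)
    y = np.asarray(labels, int)
    zs = z - z.max(axis=1, keepdims=True)
    logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(len(y)), y].mean()
    p = np.exp(logp)
    grad = p.copy()
    grad[np.arange(len(y)), y] -= 1.0
    return float(loss), grad / len(y)


def coral_loss(logits: np.ndarray, encoded: np.ndarray) -> tuple[float, np.ndarray]:
    """CORAL loss: summed binary cross-entropy over the k-1 cumulative
    threshold tasks (importance weights 1), against the prefix-of-ones
    encoding from :func:`mcrepeat.scoring.encode_ordinal_label`."""
    return bce_with_logits(logits, encoded)


def mse_loss(outputs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    y = np.asarray(outputs, float)
    t = np.asarray(targets, float).reshape(y.shape)
    diff = y - t
    return float((diff**2).mean()), 2.0 * diff / diff.size


def _targets_for_head(labels: np.ndarray, head: HeadKind) -> np.ndarray:
    if head.kind == "ordinal":
        return np.stack([encode_ordinal_label(c, head.k) for c in labels])
    if head.kind in ("binary", "regression"):
        return np.asarray(labels, float)[:, None]
    return np.asarray(labels, int)


def _loss_for_head(head: HeadKind, logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    if head.kind == "binary":
        return bce_with_logits(logits, targets)
    if head.kind == "multiclass":
        return cross_entropy(logits, targets)
    if head.kind == "ordinal":
        return coral_loss(logits, targets)
    return mse_loss(logits, targets)


def _augment_batch(x: np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(x)
    for i, img in enumerate(x):
        im = img[0]
        if rng.random() < cfg.hflip_prob:
            im = im[:, ::-1]
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        im = ndimage.rotate(im, angle, reshape=False, order=1, mode="nearest")
        out[i, 0] = im
    return out


def _decisions_from_logits(logits: np.ndarray, head: HeadKind) -> np.ndarray:
    if head.kind == "multiclass":
        return logits.argmax(axis=1)
    if head.kind == "binary":
        return (logits.ravel() >= 0.0).astype(int)
    if head.kind == "ordinal":
        return (logits >= 0.0).sum(axis=1)
    raise ValueError("no decision rule from logits for regression")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train(model: SmallCNN, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray, cfg: TrainConfig) -> TrainHistory:
    """Train ``model`` in place for ``cfg.epochs`` epochs.

    Labels are integer classes; targets are derived per head (cumulative
    encoding for ordinal, float class index for regression). Dropout is
    active during training whenever the model has dropout layers; the
    plateau scheduler monitors validation loss. By default the final-epoch
    weights are kept (each model is trained once for a fixed epoch
    budget); ``cfg.snapshot == "best_val"`` instead restores the epoch
    with the best validation accuracy (validation loss for regression),
    keeping the latest epoch among ties. Fully seeded: identical config
    and data give bitwise-identical histories.
    """
    if len(x_val) == 0:
        raise ValueError("validation split is empty")
    head = model.head
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.scheduler_factor, patience=cfg.scheduler_patience)
    hist = TrainHistory()
    t_val = _targets_for_head(y_val, head)
    best_score = -np.inf
    best_state = model.get_state()
    n = len(x_train)
    stochastic = model.has_dropout
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x_train[idx]
            if cfg.augment:
                xb = _augment_batch(xb, cfg, rng)
            tb = _targets_for_head(y_train[idx], head)
            logits = model.forward_logits(xb, stochastic=stochastic, rng=rng)
            loss, grad = _loss_for_head(head, logits, tb)
            model.net.backward(grad.astype(np.float32))
            opt.step(model.net.grads())
            epoch_loss += loss * len(idx)
        val_logits = model.forward_logits(x_val, stochastic=False)
        val_loss, _ = _loss_for_head(head, val_logits, t_val)
        sched.step(val_loss)
        if head.kind == "regression":
            val_acc = float("nan")
            snap_score = -val_loss
        else:
            val_acc = float((_decisions_from_logits(val_logits, head) == y_val).mean())
            snap_score = val_acc
        hist.train_loss.append(epoch_loss / n)
        hist.val_loss.append(val_loss)
        hist.val_accuracy.append(val_acc)
        hist.lr.append(opt.lr)
        if snap_score >= best_score:  # ties keep the latest epoch
            best_score = snap_score
            best_state = model.get_state()
            hist.best_epoch = epoch
    if cfg.snapshot == "best_val":
        model.set_state(best_state)
    else:
        hist.best_epoch = cfg.epochs - 1
    logger.debug("training done: kept epoch %d", hist.best_epoch)
    return hist
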