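"""The full encoder-decoder segmentation network.

Architecture: a five-level encoder of MA blocks with filter counts
(32, 64, 128, 256, 512) and 2x2 max pooling after levels 1-4, an FCN
block at the bottleneck, and a four-level decoder where each level
applies a 2x2/stride-2 transpose convolution, an additive attention gate
against the encoder skip, channel-wise concatenation and an MA block.
A 1x1 convolution plus per-pixel softmax produces class probabilities.

Training uses Adam (default learning rate 0.001) on categorical
cross-entropy; per-epoch history records the full monitoring roster
(accuracy, dice_coef, precision, sensitivity, specificity, Tversky,
focal and boundary loss). ``width_multiplier`` scales every filter count
so the architecture can be exercised at desk scale on a CPU.
"""

from __future__ import annotations

import csv
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import losses as L
from . import metrics as M
from .blocks import AttentionBlock, FCNBlock, MABlock
from .engine import Adam, Conv2D, ConvTranspose2x2, MaxPool2x2, softmax

__all__ = ["ModelConfig", "SegmentationModel", "build_model", "predict", "train",
           "count_parameters", "save_model", "load_model"]

DEFAULT_FILTERS = (32, 64, 128, 256, 512)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters."""

    input_height: int = 128
    input_width: int = 128
    in_channels: int = 1
    num_classes: int = 4
    encoder_filters: tuple = DEFAULT_FILTERS
    width_multiplier: float = 1.0
    seed: int = 0
    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 10
    loss_config: L.LossConfig = field(default_factory=L.LossConfig)

    def __post_init__(self):
        if self.input_height % 16 or self.input_width % 16:
            raise ValueError(
                f"input size {self.input_height}x{self.input_width} must be divisible "
                "by 16 (four pooling halvings)")
        if len(self.encoder_filters) != 5:
            raise ValueError("encoder_filters must list exactly 5 stages")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must lie in (0, 1]")

    @property
    def filters(self) -> tuple:
        """Effective per-level filter counts after width scaling (min 1)."""
        return tuple(max(1, round(f * self.width_multiplier)) for f in self.encoder_filters)


class SegmentationModel:
    """Assembled network with explicit forward and backward passes."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.filters
        self.encoders = []
        cin = config.in_channels
        for level, nf in enumerate(f, start=1):
            self.encoders.append(MABlock(cin, nf, rng=rng, name=f"enc{level}"))
            cin = nf
        self.pools = [MaxPool2x2() for _ in range(4)]
        self.bottleneck = FCNBlock(f[4], f[4], rng=rng, name="fcn")
        self.upconvs, self.attentions, self.decoders = [], [], []
        gating_ch = f[4]
        for level in (4, 3, 2, 1):
            nf = f[level - 1]
            self.upconvs.append(ConvTranspose2x2(gating_ch, nf, name=f"up{level}", rng=rng))
            self.attentions.append(
                AttentionBlock(nf, nf, nf, rng=rng, name=f"att{level}"))
            self.decoders.append(MABlock(2 * nf, nf, rng=rng, name=f"dec{level}"))
            gating_ch = nf
        self.head = Conv2D(f[0], config.num_classes, 1, name="head", rng=rng)
        # small head init: start near the uniform prediction (loss ~ ln K)
        self.head.weight.value *= 0.1

    # -- graph traversal ----------------------------------------------------

    def _layers(self):
        yield from self.encoders
        yield self.bottleneck
        yield from self.upconvs
        yield from self.attentions
        yield from self.decoders
        yield self.head

    def parameters(self):
        params = []
        for layer in self._layers():
            params.extend(layer.parameters())
        return params

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities of shape (batch, H, W, num_classes)."""
        x = np.asarray(x, dtype=np.float64)
        cfg = self.config
        if x.ndim != 4 or x.shape[1:] != (cfg.input_height, cfg.input_width, cfg.in_channels):
            raise ValueError(
                f"expected input (B, {cfg.input_height}, {cfg.input_width}, "
                f"{cfg.in_channels}), got {x.shape}")
        skips = []
        y = x
        for level in range(4):
            y = self.encoders[level](y, training)
            skips.append(y)
            y = self.pools[level](y, training)
        y = self.encoders[4](y, training)
        y = self.bottleneck(y, training)
        for i, level in enumerate((4, 3, 2, 1)):
            up = self.upconvs[i](y, training)
            att = self.attentions[i](skips[level - 1], up, training)
            y = self.decoders[i](np.concatenate([att, up], axis=-1), training)
        logits = self.head(y, training)
        self._logits = logits
        return softmax(logits, axis=-1)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the head logits into all parameters."""
        dy = self.head.backward(dlogits)
        dskips = {}  # encoder level -> gradient arriving via the attention gate
        for j in range(3, -1, -1):  # decoder stages shallow-to-deep
            level = (4, 3, 2, 1)[j]
            dcat = self.decoders[j].backward(dy)
            natt = self.attentions[j].out_channels
            datt, dup = dcat[..., :natt], dcat[..., natt:]
            dskip, dgate = self.attentions[j].backward(datt)
            dskips[level] = dskip
            dy = self.upconvs[j].backward(dup + dgate)
        dy = self.bottleneck.backward(dy)
        dy = self.encoders[4].backward(dy)
        for level in (4, 3, 2, 1):
            dy = self.pools[level - 1].backward(dy)
            dy = self.encoders[level - 1].backward(dy + dskips[level])
        return dy

    def __call__(self, x, training=False):
        return self.forward(x, training)


def build_model(config: ModelConfig) -> SegmentationModel:
    """Construct the network; raises on an illegal configuration."""
    return SegmentationModel(config)


def predict(model: SegmentationModel, batch: np.ndarray) -> np.ndarray:
    """Inference-mode class probabilities (deterministic; running BN stats)."""
    return model.forward(batch, training=False)


HISTORY_ROSTER = ("loss", "accuracy", "dice_coef", "precision", "sensitivity",
                  "specificity", "tversky_loss", "focal_loss", "boundary_loss")


def _epoch_metrics(model: SegmentationModel, dataset, cfg: ModelConfig) -> dict:
    """Monitoring roster evaluated in inference mode over the whole dataset."""
    import warnings

    probs, truths = [], []
    for xb, yb in dataset:
        probs.append(predict(model, xb))
        truths.append(np.asarray(yb, dtype=np.float64))
    pred = np.concatenate(probs, axis=0)
    truth = np.concatenate(truths, axis=0)
    pred_labels = pred.argmax(axis=-1)
    true_labels = truth.argmax(axis=-1)
    lc = cfg.loss_config
    fg = tuple(range(1, cfg.num_classes))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # conventions cover absent classes
        sets = M.RegionSets.from_labels(pred_labels, true_labels, fg)
        row = {
            "loss": L.categorical_crossentropy(pred, truth, lc.smooth),
            "accuracy": M.overall_accuracy(pred_labels, true_labels),
            "dice_coef": L.soft_dice(pred, truth, lc.smooth),
            "precision": M.precision(M.confusion(pred_labels, true_labels, fg)),
            "sensitivity": M.sensitivity(sets),
            "specificity": M.specificity(sets),
            "tversky_loss": L.tversky_loss(pred, truth, lc),
            "focal_loss": L.focal_loss(pred, truth, lc),
            "boundary_loss": L.boundary_loss(pred, truth),
            "dice_foreground": M.dice(pred_labels != 0, true_labels != 0),
        }
    return row


def train(model: SegmentationModel, dataset, config: ModelConfig | None = None,
          early_stop_dice: float | None = None, verbose: bool = False) -> list:
    """Train with Adam on categorical cross-entropy.

    ``dataset`` is a re-iterable of (image batch, one-hot mask batch)
    pairs. Returns the per-epoch history: a list of dicts carrying the
    training loss plus the monitoring roster (accuracy, dice_coef,
    precision, sensitivity, specificity, Tversky/focal/boundary loss and
    a hard foreground Dice). ``early_stop_dice`` stops once the
    foreground Dice reaches the given value. Raises on an empty dataset
    and on a non-finite loss (with the epoch index).
    """
    config = config or model.config
    batches = list(dataset) if not isinstance(dataset, list) else dataset
    if not batches:
        raise ValueError("empty dataset")
    optimizer = Adam(model.parameters(), learning_rate=config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        epoch_loss = 0.0
        n_pix = 0
        for xb, yb in batches:
            xb = np.asarray(xb, dtype=np.float64)
            yb = np.asarray(yb, dtype=np.float64)
            probs = model.forward(xb, training=True)
            batch_pix = int(np.prod(probs.shape[:-1]))
            loss = L.categorical_crossentropy(probs, yb, config.loss_config.smooth)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            # d(mean CE)/dlogits for softmax outputs
            optimizer.zero_grad()
            model.backward((probs - yb) / batch_pix)
            optimizer.step()
            epoch_loss += loss * batch_pix
            n_pix += batch_pix
        row = _epoch_metrics(model, batches, config)
        row["epoch"] = epoch
        row["train_loss"] = epoch_loss / n_pix
        history.append(row)
        if verbose:
            print(f"epoch {epoch:3d}  loss {row['loss']:.4f}  "
                  f"dice_fg {row['dice_foreground']:.4f}")
        if early_stop_dice is not None and row["dice_foreground"] >= early_stop_dice:
            break
    return history


def history_to_csv(history: list, path) -> None:
    """Write the per-epoch history as a CSV with one row per epoch."""
    if not history:
        raise ValueError("empty history")
    fields = list(history[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(history)


def save_model(model: SegmentationModel, path) -> None:
    """Checkpoint the configuration and all parameter values."""
    state = {
        "config": replace(model.config),
        "params": {p.name: p.value for p in model.parameters()},
    }
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_model(path) -> SegmentationModel:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    model = SegmentationModel(state["config"])
    for p in model.parameters():
        if p.name not in state["params"]:
            raise ValueError(f"checkpoint missing parameter {p.name}")
        p.value = np.asarray(state["params"][p.name], dtype=np.float64)
    return model


def count_parameters(model: SegmentationModel) -> dict:
    """Exact trainable / non-trainable parameter counts."""
    trainable = sum(p.size for p in model.parameters() if p.trainable)
    non_trainable = sum(p.size for p in model.parameters() if not p.trainable)
    return {"trainable": trainable, "non_trainable": non_trainable,
            "total": trainable + non_trainable}
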