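"""Classifier harness: a small VGG-style CNN, block-wise fine-tuning
degrees, the training schedule, gradient saliency and the random baseline.

The network is organized in blocks, each a run of 3x3 convolutions closed
by a 2x2 max-pool; the block is the unit of transfer-learning freezing.
Degree ``kconv`` unfreezes convolution blocks 1..k counting from the input
side, ``all`` unfreezes every block; the 2-class head is always trainable,
since a task-specific output layer cannot be inherited from pre-training.
The default demonstrator is a five-block network for 64x64 inputs (one
convolution per block, 8-16-32-32-32 channels); VGG-16 at 270x270 is
expressible through :class:`ClassifierConfig` but not required anywhere.

Training follows SGD with momentum 0.5 at learning rate 0.02, decayed by
a factor 0.9 every 5 epochs, batch size 32, cross-entropy loss, keeping
the weights of the best validation-accuracy epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from ._cnn import (
    SGD,
    BatchNorm,
    Conv3x3,
    Dense,
    Flatten,
    InputHighpass,
    MaxPool2,
    ReLU,
    Sequential,
    cross_entropy,
    softmax,
)
from .baseline_explainers import HeatMap, normalize_attribution
from .lesion_forge import IRREGULAR, REGULAR

logger = logging.getLogger(__name__)

#: class index convention: 0 = regular, 1 = irregular
CLASS_NAMES = (REGULAR, IRREGULAR)
FINE_TUNE_DEGREES = ("1conv", "2conv", "3conv", "4conv", "all")


@dataclass(frozen=True)
class ClassifierConfig:
    """Block structure of the classifier.

    ``blocks`` lists (number of convolutions, output channels) per block;
    each block ends in a 2x2 max-pool, so ``input_size`` must be divisible
    by ``2 ** len(blocks)``.  Convolutions are batch-normalized by default,
    which is what lets a fixed momentum-0.5 schedule train reliably from
    scratch within a 30-epoch budget.  ``highpass_sigma`` configures the
    fixed background-suppression front end (0 disables it).
    """

    blocks: tuple[tuple[int, int], ...] = ((1, 8), (1, 16), (1, 32), (1, 32), (1, 32))
    input_size: int = 64
    n_classes: int = 2
    seed: int = 0
    batch_norm: bool = True
    highpass_sigma: float = 3.0

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError("need at least 2 blocks")
        if self.input_size % (2 ** len(self.blocks)) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by "
                f"2**{len(self.blocks)} pooling stages"
            )

    def parameter_count(self) -> int:
        """Closed-form parameter count from the layer dimensions."""
        total, in_ch = 0, 1
        for n_convs, out_ch in self.blocks:
            for _ in range(n_convs):
                total += out_ch * in_ch * 9 + out_ch
                if self.batch_norm:
                    total += 2 * out_ch
                in_ch = out_ch
        side = self.input_size // (2 ** len(self.blocks))
        total += side * side * in_ch * self.n_classes + self.n_classes
        return total


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.02
    momentum: float = 0.5
    decay_factor: float = 0.9
    decay_every: int = 5
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.momentum, self.batch_size, self.epochs) <= 0:
            raise ValueError("training parameters must be positive")
        if not 0 < self.decay_factor < 1:
            raise ValueError("decay factor must be in (0, 1)")

    def lr_at(self, epoch: int) -> float:
        """Learning rate at a 0-indexed epoch: lr0 * decay^(epoch // every)."""
        return self.learning_rate * self.decay_factor ** (epoch // self.decay_every)


@dataclass
class Classifier:
    """A block-structured CNN plus its config and freezing state."""

    config: ClassifierConfig
    net: Sequential
    conv_blocks: list[list]          # per block: its Conv3x3 (+ BatchNorm) layers
    head: Dense
    degree: str = "all"

    def forward(self, x: NDArray) -> NDArray:
        return self.net.forward(x)

    def parameter_count(self, trainable_only: bool = False) -> int:
        return self.net.parameter_count(trainable_only)

    def parameters_hash(self) -> str:
        return self.net.parameters_hash()


def build_classifier(config: ClassifierConfig | None = None) -> Classifier:
    """Deterministically initialized classifier from a block config."""
    config = config or ClassifierConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1A55]))
    layers: list = []
    conv_blocks: list[list] = []
    in_ch = 1
    if config.highpass_sigma > 0:
        layers.append(InputHighpass(config.highpass_sigma))
    for n_convs, out_ch in config.blocks:
        block: list = []
        for _ in range(n_convs):
            conv = Conv3x3(in_ch, out_ch, rng)
            block.append(conv)
            layers.append(conv)
            if config.batch_norm:
                bn = BatchNorm(out_ch)
                block.append(bn)
                layers.append(bn)
            layers.append(ReLU())
            in_ch = out_ch
        layers.append(MaxPool2())
        conv_blocks.append(block)
    layers.append(Flatten())
    side = config.input_size // (2 ** len(config.blocks))
    head = Dense(side * side * in_ch, config.n_classes, rng)
    layers.append(head)
    model = Classifier(
        config=config, net=Sequential(layers), conv_blocks=conv_blocks, head=head
    )
    assert model.parameter_count() == config.parameter_count()
    return model


def freeze_to_degree(model: Classifier, degree: str) -> Classifier:
    """Set trainability per fine-tuning degree.

    ``kconv`` leaves convolution blocks 1..k (from the input) trainable and
    freezes the rest; ``all`` unfreezes everything.  The classification
    head is always trainable.
    """
    if degree == "all":
        k = len(model.conv_blocks)
    elif degree in FINE_TUNE_DEGREES:
        k = int(degree[0])
    else:
        raise ValueError(f"unknown fine-tuning degree {degree!r}")
    for i, block in enumerate(model.conv_blocks):
        for layer in block:
            layer.trainable = i < k
    model.head.trainable = True
    model.degree = degree
    return model


def _to_arrays(samples) -> tuple[NDArray, NDArray]:
    x = np.stack([s.image for s in samples])[:, None, :, :]
    y = np.array([CLASS_NAMES.index(s.label) for s in samples])
    return x, y


def _evaluate(model: Classifier, x: NDArray, y: NDArray, batch: int = 128) -> tuple[float, float]:
    losses, hits, n = 0.0, 0, x.shape[0]
    for i in range(0, n, batch):
        logits = model.forward(x[i : i + batch])
        loss, _ = cross_entropy(logits, y[i : i + batch])
        losses += loss * logits.shape[0]
        hits += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return losses / n, hits / n


def train(
    model: Classifier,
    dataset,
    tc: TrainConfig | None = None,
) -> tuple[Classifier, pd.DataFrame]:
    """Train on the dataset's train split, validating each epoch.

    Returns the model carrying the best-validation-accuracy weights and a
    history frame (epoch, lr, train/val loss and accuracy).  Aborts on
    non-finite loss.
    """
    tc = tc or TrainConfig()
    train_samples = dataset.subset("train")
    val_samples = dataset.subset("val")
    if not train_samples or not val_samples:
        raise ValueError("dataset needs non-empty train and val splits")
    x_train, y_train = _to_arrays(train_samples)
    x_val, y_val = _to_arrays(val_samples)
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 0x7EA1]))
    opt = SGD(model.net, tc.learning_rate, tc.momentum)
    history = []
    best_acc, best_state = -1.0, None
    for epoch in range(tc.epochs):
        opt.lr = tc.lr_at(epoch)
        order = rng.permutation(x_train.shape[0])
        epoch_loss, epoch_hits = 0.0, 0
        model.net.train_mode(True)
        for i in range(0, order.size, tc.batch_size):
            idx = order[i : i + tc.batch_size]
            logits = model.forward(x_train[idx])
            loss, dlogits = cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})"
                )
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * idx.size
            epoch_hits += int((logits.argmax(axis=1) == y_train[idx]).sum())
        model.net.train_mode(False)
        val_loss, val_acc = _evaluate(model, x_val, y_val)
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": epoch_loss / order.size,
                "train_acc": epoch_hits / order.size,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc, best_state = val_acc, model.net.state()
        logger.info(
            "epoch %d lr=%.4f train_acc=%.3f val_acc=%.3f",
            epoch, opt.lr, epoch_hits / order.size, val_acc,
        )
    if best_state is not None:
        model.net.load_state(best_state)
    return model, pd.DataFrame(history)


def predict(model: Classifier, samples) -> pd.DataFrame:
    """Per-sample predictions: sample_id, predicted, true, score columns."""
    x, y = _to_arrays(samples)
    rows = []
    for i in range(0, x.shape[0], 128):
        logits = model.forward(x[i : i + 128])
        probs = softmax(logits)
        for j, sample in enumerate(samples[i : i + 128]):
            pred = int(np.argmax(logits[j]))
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "predicted": CLASS_NAMES[pred],
                    "true": sample.label,
                    "p_regular": probs[j, 0],
                    "p_irregular": probs[j, 1],
                }
            )
    return pd.DataFrame(rows)


def accuracy(predictions: pd.DataFrame) -> float:
    return float((predictions["predicted"] == predictions["true"]).mean())


def saliency_map(model: Classifier, image: NDArray) -> HeatMap:
    """Gradient saliency: |d score(predicted class) / d input|, normalized."""
    x = np.asarray(image, dtype=float)[None, None, :, :]
    logits = model.forward(x)
    target = int(np.argmax(logits[0]))
    dlogits = np.zeros_like(logits)
    dlogits[0, target] = 1.0
    dx = model.net.backward(dlogits)
    return normalize_attribution(
        dx[0, 0], method="saliency", provenance={"target": CLASS_NAMES[target]}
    )


def random_baseline_model(
    config: ClassifierConfig | None = None, seed: int | None = None
) -> Classifier:
    """A randomly initialized, never-trained classifier.

    On a balanced test set its accuracy is 50% in expectation; its saliency
    maps are the untrained-model null baseline for explanation performance.
    """
    config = config or ClassifierConfig()
    if seed is not None:
        config = ClassifierConfig(
            blocks=config.blocks,
            input_size=config.input_size,
            n_classes=config.n_classes,
            seed=seed,
        )
    return build_classifier(config)


def attribution_adapter(name: str, fn):
    """Wrap an external attribution callable into an explainer.

    ``fn(model, image, target, baseline)`` must return a signed attribution
    map; the wrapper supplies the all-zeros baseline image, takes absolute
    values, peak-normalizes, and records provenance.  Exceptions are
    re-raised with the method name and sample context attached.
    """

    def explain(model: Classifier, image: NDArray, sample_id: str = "?") -> HeatMap:
        x = np.asarray(image, dtype=float)
        logits = model.forward(x[None, None, :, :])
        target = int(np.argmax(logits[0]))
        baseline = np.zeros_like(x)
        try:
            raw = fn(model, x, target, baseline)
        except Exception as exc:  # re-raise with context
            raise RuntimeError(f"adapter {name!r} failed on sample {sample_id}") from exc
        return normalize_attribution(
            raw, method=name, provenance={"adapter": name, "target": CLASS_NAMES[target]}
        )

    return explain
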