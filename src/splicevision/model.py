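"""The splice-site convolutional classifier.

One model is trained per site type (donor or acceptor).  The canonical
architecture is three unpadded convolution blocks (16, 32 and 64 filters of
widths 7, 6 and 6, stride 1), each followed by 20% dropout and 2-wide
max-pooling, then a 100-unit ReLU dense layer and a 2-class softmax head.
At the default input length of 200 nt this stack holds 144,222 trainable
parameters.  Inputs too short for the full stack (e.g. 20 nt) automatically
drop the trailing conv block(s), with a warning.

Training minimizes softmax cross-entropy with the Adamax optimizer
(learning rate 1e-5, batch size 32, 400 epochs by default), holding out a
stratified 15% validation slice of the training data to monitor learning.

Usage follows the model/results idiom::

    model = SpliceCNN(train_batch, site_type="donor", config=ModelConfig())
    res = model.fit(TrainConfig(epochs=30, learning_rate=1e-3, seed=0))
    probs = res.predict_proba(test_batch)
    print(res.summary())
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adamax, ConvNet, cross_entropy, softmax
from .encoding import EncodedBatch, encode_batch


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the classifier."""

    input_length: int = 200
    conv_filters: tuple[int, ...] = (16, 32, 64)
    conv_kernel_sizes: tuple[int, ...] = (7, 6, 6)
    conv_stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    dropout_rate: float = 0.20
    dense_units: int = 100
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.conv_stride != 1 or self.pool_size != 2 or self.pool_stride != 2:
            raise ValueError("only stride-1 convolutions with 2/2 pooling are supported")
        if len(self.conv_filters) != len(self.conv_kernel_sizes):
            raise ValueError("conv_filters and conv_kernel_sizes must align")

    def effective_stack(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """The conv blocks that actually fit the input length.

        Blocks are dropped from the tail while the running spatial length is
        shorter than the next kernel or would pool to nothing; at least one
        block must fit.
        """
        filters, kernels = [], []
        L = self.input_length
        for f, k in zip(self.conv_filters, self.conv_kernel_sizes):
            if L < k or (L - k + 1) // 2 < 1:
                break
            filters.append(f)
            kernels.append(k)
            L = (L - k + 1) // 2
        if not filters:
            raise ValueError(
                f"input length {self.input_length} is too short for the first "
                f"convolution (kernel {self.conv_kernel_sizes[0]})")
        return tuple(filters), tuple(kernels)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    epochs: int = 400
    batch_size: int = 32
    learning_rate: float = 1e-5
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class SpliceCNN:
    """Classifier model bound to a training batch and a site type."""

    def __init__(self, train_batch: EncodedBatch, site_type: str = "donor",
                 config: ModelConfig | None = None):
        if site_type not in ("donor", "acceptor"):
            raise ValueError(f"site_type must be donor or acceptor, got {site_type!r}")
        config = config or ModelConfig(input_length=train_batch.width)
        if train_batch.width != config.input_length:
            raise ValueError(
                f"batch width {train_batch.width} != configured input length "
                f"{config.input_length}; adapt windows first (see adapt_length)")
        if len(np.unique(train_batch.labels)) < 2:
            raise ValueError("training data contains a single class")
        self.batch = train_batch
        self.site_type = site_type
        self.config = config
        self.net = _build_net(config)

    @classmethod
    def from_windows(cls, windows: list[str], labels: list[int],
                     site_type: str = "donor",
                     config: ModelConfig | None = None) -> "SpliceCNN":
        return cls(encode_batch(windows, labels), site_type=site_type, config=config)

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def fit(self, train_config: TrainConfig | None = None,
            verbose: bool = False) -> "SpliceCNNResults":
        tc = train_config or TrainConfig()
        rng = np.random.Generator(np.random.PCG64(tc.seed))
        x = self.batch.data[:, 0]            # (N, W, 4)
        y = self.batch.labels

        # stratified validation split
        val_idx, train_idx = _stratified_holdout(y, tc.validation_fraction, rng)
        x_tr, y_tr = x[train_idx], y[train_idx]
        x_val, y_val = x[val_idx], y[val_idx]

        opt = Adamax(self.net.param_refs(), lr=tc.learning_rate)
        onehot = np.eye(self.config.n_classes, dtype=np.float32)
        history = []
        for epoch in range(1, tc.epochs + 1):
            order = rng.permutation(len(x_tr))
            losses = []
            for i in range(0, len(order), tc.batch_size):
                idx = order[i:i + tc.batch_size]
                xb, yb = x_tr[idx], y_tr[idx]
                caches: list = []
                logits = self.net.forward(xb, train_rng=rng, caches=caches)
                probs = softmax(logits)
                losses.append(cross_entropy(probs, yb))
                dlogits = (probs - onehot[yb]) / len(yb)
                grads = self.net.backward(dlogits, caches)
                opt.step(grads)
            tr_probs = self.net.predict_proba(x_tr)
            val_probs = self.net.predict_proba(x_val)
            row = {
                "epoch": epoch,
                "train_loss": cross_entropy(tr_probs, y_tr),
                "train_accuracy": float((tr_probs.argmax(1) == y_tr).mean()),
                "val_loss": cross_entropy(val_probs, y_val),
                "val_accuracy": float((val_probs.argmax(1) == y_val).mean()),
            }
            history.append(row)
            if verbose:
                print(f"epoch {epoch:4d}  loss {row['train_loss']:.4f}  "
                      f"val_loss {row['val_loss']:.4f}  "
                      f"val_acc {row['val_accuracy']:.4f}")
        return SpliceCNNResults(model=self, train_config=tc,
                                history=pd.DataFrame(history))


class SpliceCNNResults:
    """Fitted classifier: weights, training history, prediction and summary."""

    def __init__(self, model: SpliceCNN, train_config: TrainConfig,
                 history: pd.DataFrame):
        self.model = model
        self.train_config = train_config
        self.history = history

    # -- prediction ----------------------------------------------------------
    @property
    def site_type(self) -> str:
        return self.model.site_type

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    @property
    def net(self):
        return self.model.net

    def predict_proba(self, batch: EncodedBatch | np.ndarray) -> np.ndarray:
        """S x 2 rows of (P(non-SS), P(SS)); each row sums to 1."""
        x = batch.data[:, 0] if isinstance(batch, EncodedBatch) else np.asarray(batch)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.input_length:
            raise ValueError(
                f"window length {x.shape[1]} != model input length "
                f"{self.config.input_length}; use adapt_length first")
        return self.net.predict_proba(x)

    def predict(self, batch: EncodedBatch | np.ndarray,
                threshold: float = 0.5) -> np.ndarray:
        return classify(self.predict_proba(batch), threshold=threshold)

    def summary(self) -> str:
        cfg, tc = self.config, self.train_config
        last = self.history.iloc[-1]
        filters, kernels = cfg.effective_stack()
        lines = [
            "Splice-site CNN results",
            "=" * 47,
            f"site type:            {self.site_type}",
            f"input length:         {cfg.input_length} nt",
            f"conv stack:           {tuple(filters)} filters, {tuple(kernels)} kernels",
            f"trainable parameters: {self.model.n_params:,}",
            f"epochs / batch / lr:  {tc.epochs} / {tc.batch_size} / {tc.learning_rate:g}",
            f"final train loss:     {last['train_loss']:.4f}",
            f"final train accuracy: {100 * last['train_accuracy']:.2f}%",
            f"final val loss:       {last['val_loss']:.4f}",
            f"final val accuracy:   {100 * last['val_accuracy']:.2f}%",
        ]
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write config.json, weights.npz and training_history.tsv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "site_type": self.site_type,
            "model_config": dataclasses.asdict(self.config),
            "train_config": dataclasses.asdict(self.train_config),
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "weights.npz", **self.net.get_weights())
        self.history.to_csv(directory / "training_history.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "SpliceCNNResults":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        mc = meta["model_config"]
        for key in ("conv_filters", "conv_kernel_sizes"):
            mc[key] = tuple(mc[key])
        config = ModelConfig(**mc)
        tc = TrainConfig(**meta["train_config"])
        model = object.__new__(SpliceCNN)
        model.batch = None
        model.site_type = meta["site_type"]
        model.config = config
        model.net = _build_net(config)
        with np.load(directory / "weights.npz") as npz:
            model.net.set_weights({k: npz[k] for k in npz.files})
        history = pd.read_csv(directory / "training_history.tsv", sep="\t")
        return cls(model=model, train_config=tc, history=history)


# ---------------------------------------------------------------------------
# Functional surface

def _build_net(config: ModelConfig) -> ConvNet:
    filters, kernels = config.effective_stack()
    if len(filters) < len(config.conv_filters):
        warnings.warn(
            f"input length {config.input_length} only accommodates "
            f"{len(filters)} of {len(config.conv_filters)} conv blocks; "
            "using the reduced stack", stacklevel=3)
    return ConvNet(input_length=config.input_length, conv_filters=filters,
                   conv_kernels=kernels, dropout_rate=config.dropout_rate,
                   dense_units=config.dense_units, n_classes=config.n_classes,
                   seed=config.seed)


def build_model(config: ModelConfig, batch: EncodedBatch,
                site_type: str = "donor") -> SpliceCNN:
    """Construct an untrained model for a training batch."""
    return SpliceCNN(batch, site_type=site_type, config=config)


def train(model: SpliceCNN, train_config: TrainConfig | None = None,
          verbose: bool = False) -> SpliceCNNResults:
    return model.fit(train_config, verbose=verbose)


def predict_proba(results: SpliceCNNResults, batch: EncodedBatch) -> np.ndarray:
    return results.predict_proba(batch)


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff P(SS) strictly exceeds the threshold (ties -> non-SS)."""
    probs = np.asarray(probabilities)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("expected S×2 probability rows")
    return (probs[:, 1] > threshold).astype(np.int64)


def adapt_length(window: str, target_W: int) -> str:
    """Center-crop or N-pad a window to the target length.

    Both lengths must be even so the central dinucleotide stays at positions
    L/2, L/2+1.
    """
    L = len(window)
    if L % 2 or target_W % 2:
        raise ValueError("window lengths must be even")
    if L == target_W:
        return window
    if L > target_W:
        start = L // 2 - target_W // 2
        return window[start:start + target_W]
    pad = (target_W - L) // 2
    return "N" * pad + window + "N" * pad


def _stratified_holdout(y: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (holdout_idx, rest_idx), stratified by label."""
    holdout, rest = [], []
    for label in np.unique(y):
        idx = np.nonzero(y == label)[0]
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(fraction * len(idx))))
        holdout.append(idx[:k])
        rest.append(idx[k:])
    return np.concatenate(holdout), np.concatenate(rest)
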