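"""Four-channel multimodal fusion classifier.

The model predicts a binary 12-month developmental outcome from a
`FeatureBundle`. Each channel has its own encoder; encodings are
concatenated and passed through a dropout-regularized dense head:

* connectivity: Conv1D (128 filters over the ordered upper-triangle vector)
  -> ReLU -> MaxPool -> flatten -> Dense(64) -> ReLU
* graph metrics: Dense(32) -> ReLU -> Dense(16) -> ReLU
* motor scores:  Dense(32) -> ReLU
* cognitive scores: Dense(32) -> ReLU
* fusion head: Dense(128) -> Dense(64) -> Dense(32), ReLU + dropout after
  each, then a single-logit output.

Training is binary cross-entropy with Adam (lr 1e-3, batch 32), at most 100
epochs with early stopping on validation loss (patience 10) and restoration
of the best-validation weights. Ablation variants consume only their
channels: ``connectivity_only`` sees conn+graph, ``behavioral_only`` sees
motor+cog.

Usage follows the model/results convention: build `FusionClassifier` from
data, call :meth:`fit`, get a `FusionResults` carrying the trained weights,
training history, and prediction/summary methods.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import Adam, Conv1D, Dense, Dropout, Flatten, MaxPool1D, ReLU, Sequential, bce_with_logits
from .features import FeatureBundle

__all__ = ["ModelConfig", "FusionClassifier", "FusionResults", "VARIANT_CHANNELS"]

VARIANT_CHANNELS = {
    "multimodal": ("conn", "graph", "motor", "cog"),
    "connectivity_only": ("conn", "graph"),
    "behavioral_only": ("motor", "cog"),
}


@dataclass
class ModelConfig:
    """Architecture and training schedule of the fusion network."""

    variant: str = "multimodal"
    conv_filters: int = 128
    conv_kernel: int = 7
    conv_stride: int = 1
    pool_size: int = 4
    conv_to_dense: int = 64
    graph_channel_widths: tuple = (32, 16)
    behavior_dense: int = 32
    fusion_widths: tuple = (128, 64, 32)
    dropout_rate: float = 0.3
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANT_CHANNELS:
            raise ValueError(f"unknown variant {self.variant!r}")
        widths = (self.conv_filters, self.conv_to_dense, self.behavior_dense,
                  *self.graph_channel_widths, *self.fusion_widths)
        if any(w <= 0 for w in widths):
            raise ValueError("all layer widths must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    @property
    def channels(self) -> tuple:
        return VARIANT_CHANNELS[self.variant]


class _Network:
    """The assembled channel encoders + fusion head."""

    def __init__(self, cfg: ModelConfig, dims: dict, rng: np.random.Generator):
        self.cfg = cfg
        self.dims = dict(dims)
        self.encoders = {}
        concat_dim = 0
        for ch in cfg.channels:
            d = dims[ch]
            if ch == "conn":
                l_out = (d - cfg.conv_kernel) // cfg.conv_stride + 1
                pooled = l_out // cfg.pool_size
                if pooled < 1:
                    raise ValueError("connectivity vector too short for conv/pool settings")
                enc = Sequential([
                    Conv1D(cfg.conv_filters, cfg.conv_kernel, cfg.conv_stride, rng),
                    ReLU(),
                    MaxPool1D(cfg.pool_size),
                    Flatten(),
                    Dense(pooled * cfg.conv_filters, cfg.conv_to_dense, rng),
                    ReLU(),
                ])
                concat_dim += cfg.conv_to_dense
            elif ch == "graph":
                w1, w2 = cfg.graph_channel_widths
                enc = Sequential([Dense(d, w1, rng), ReLU(), Dense(w1, w2, rng), ReLU()])
                concat_dim += w2
            else:
                enc = Sequential([Dense(d, cfg.behavior_dense, rng), ReLU()])
                concat_dim += cfg.behavior_dense
            self.encoders[ch] = enc

        head_layers = []
        d_in = concat_dim
        for w in cfg.fusion_widths:
            head_layers += [Dense(d_in, w, rng), ReLU(), Dropout(cfg.dropout_rate)]
            d_in = w
        head_layers.append(Dense(d_in, 1, rng))
        self.head = Sequential(head_layers)

        self.params, self.grads = [], []
        for enc in self.encoders.values():
            self.params += enc.params
            self.grads += enc.grads
        self.params += self.head.params
        self.grads += self.head.grads

    def forward(self, arrays: dict, train=False, rng=None):
        outs = []
        self._splits = []
        for ch in self.cfg.channels:
            if arrays[ch].shape[1] != self.dims[ch]:
                raise ValueError(
                    f"feature-length mismatch on channel {ch!r}: expected "
                    f"{self.dims[ch]}, got {arrays[ch].shape[1]}"
                )
            o = self.encoders[ch].forward(arrays[ch], train=train, rng=rng)
            self._splits.append(o.shape[1])
            outs.append(o)
        return self.head.forward(np.concatenate(outs, axis=1), train=train, rng=rng)

    def backward(self, g):
        g = self.head.backward(g)
        offset = 0
        for ch, width in zip(self.cfg.channels, self._splits):
            self.encoders[ch].backward(g[:, offset:offset + width])
            offset += width

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w


def _arrays(bundle: FeatureBundle, channels) -> dict:
    return {ch: np.asarray(getattr(bundle, ch), dtype=float) for ch in channels}


class FusionClassifier:
    """Model object: training data + config; :meth:`fit` returns results.

    Parameters
    ----------
    train : FeatureBundle
        Fold-preprocessed training features.
    y_train : ndarray of {0, 1}
        Binary outcome labels (never imputed upstream).
    config : ModelConfig
    val, y_val : optional validation split for early stopping. Without one,
        early stopping monitors training loss.
    """

    def __init__(self, train: FeatureBundle, y_train, config: ModelConfig | None = None,
                 val: FeatureBundle | None = None, y_val=None):
        self.config = config or ModelConfig()
        self.train_bundle = train
        self.y_train = np.asarray(y_train, dtype=float).ravel()
        if self.y_train.size != train.n:
            raise ValueError("label count does not match bundle size")
        if len(np.unique(self.y_train)) < 2:
            raise ValueError("training labels are class-degenerate (single class)")
        if val is not None and set(val.ids) & set(train.ids):
            raise ValueError("train and validation sets share participants")
        self.val_bundle, self.y_val = val, (
            None if y_val is None else np.asarray(y_val, dtype=float).ravel()
        )

    def fit(self) -> "FusionResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        x_train = _arrays(self.train_bundle, cfg.channels)
        dims = {ch: a.shape[1] for ch, a in x_train.items()}
        net = _Network(cfg, dims, rng)
        opt = Adam(net.params, net.grads, lr=cfg.learning_rate)

        n = self.train_bundle.n
        monitor_val = self.val_bundle is not None
        if monitor_val:
            x_val = _arrays(self.val_bundle, cfg.channels)

        history = []
        best_loss, best_weights, best_epoch, wait = np.inf, net.get_weights(), 0, 0
        stopped_epoch = cfg.max_epochs
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = {ch: a[idx] for ch, a in x_train.items()}
                logits = net.forward(batch, train=True, rng=rng)
                loss, grad = bce_with_logits(logits, self.y_train[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf training loss at epoch {epoch} "
                        f"(lr={cfg.learning_rate}, batch={cfg.batch_size})"
                    )
                net.backward(grad)
                opt.step()
                epoch_loss += loss * idx.size
            train_loss = epoch_loss / n

            if monitor_val:
                logits = net.forward(x_val, train=False)
                monitored, _ = bce_with_logits(logits, self.y_val)
            else:
                monitored = train_loss
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": monitored if monitor_val else np.nan})
            if monitored < best_loss - 1e-12:
                best_loss, best_weights, best_epoch, wait = monitored, net.get_weights(), epoch, 0
            else:
                wait += 1
                if wait >= cfg.early_stop_patience:
                    stopped_epoch = epoch
                    break
        else:
            stopped_epoch = cfg.max_epochs

        net.set_weights(best_weights)
        return FusionResults(
            config=cfg, _net=net,
            history=pd.DataFrame(history),
            best_epoch=best_epoch, stopped_epoch=stopped_epoch,
        )


@dataclass
class FusionResults:
    """Trained fusion network: weights, history, prediction interface."""

    config: ModelConfig
    _net: _Network
    history: pd.DataFrame
    best_epoch: int
    stopped_epoch: int

    def predict_proba(self, bundle: FeatureBundle) -> np.ndarray:
        """Class-1 probabilities in (0, 1); deterministic given the weights."""
        x = _arrays(bundle, self.config.channels)
        logits = self._net.forward(x, train=False).ravel()
        p = 1.0 / (1.0 + np.exp(-logits))
        return np.clip(p, 1e-12, 1 - 1e-12)

    def predict(self, bundle: FeatureBundle, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(bundle) >= threshold).astype(int)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Fusion classifier results",
            "=" * 40,
            f"variant:          {cfg.variant}",
            f"channels:         {', '.join(cfg.channels)}",
            f"parameters:       {sum(p.size for p in self._net.params):,}",
            f"epochs run:       {self.stopped_epoch} (best: {self.best_epoch})",
            f"final train loss: {self.history['train_loss'].iloc[-1]:.4f}",
        ]
        if self.history["val_loss"].notna().any():
            lines.append(f"best val loss:    {self.history['val_loss'].min():.4f}")
        return "\n".join(lines)

    def get_weights(self):
        return self._net.get_weights()

    def plot_history(self, ax=None):
        """Training (and validation) loss curves; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train")
        if self.history["val_loss"].notna().any():
            ax.plot(self.history["epoch"], self.history["val_loss"], label="validation")
            ax.axvline(self.best_epoch, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("binary cross-entropy")
        ax.legend(frameon=False)
        return ax
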