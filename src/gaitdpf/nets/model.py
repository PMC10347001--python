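"""The LSTM-CNN gait-phase classifier: build, train, predict, persist.

The stack, for a 20-sample window of C normalized channels:

    LSTM(128, full sequence) -> LSTM(128, full sequence)
    -> Conv1D(64, width 3, stride 1, 'same', ReLU) -> MaxPool(2, stride 2)
    -> Conv1D(128, width 3, stride 1, 'same', ReLU) -> MaxPool(2, stride 1)
    -> Flatten -> Dense -> softmax over the 4 phases

Both LSTM layers return their full 20-step hidden sequence so the 1x3
kernels convolve along time over 128-channel feature maps.  Pooling is
'valid', leaving time lengths 20 -> 10 -> 9 into the dense head.  Training
minimizes cross-entropy with Adam and stops early when the validation loss
stops improving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ..phases import N_PHASES, SITES
from ..preprocess import NormalizerParams, SensorGroup, apply_normalizer, select_channels
from . import layers as _L
from .layers import (
    Adam,
    Conv1D,
    Dense,
    Flatten,
    Layer,
    LSTMLayer,
    MaxPool1D,
    cross_entropy,
    softmax,
)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters (defaults are the reference stack)."""

    lstm_layers: int = 2
    lstm_units: int = 128
    conv_filters: tuple[int, int] = (64, 128)
    conv_kernel_width: int = 3
    conv_stride: int = 1
    pool_width: int = 2
    pool_strides: tuple[int, int] = (2, 1)
    output_classes: int = N_PHASES
    window_len: int = 20

    def __post_init__(self) -> None:
        if self.output_classes != N_PHASES:
            raise ValueError("this classifier is fixed to the 4-phase alphabet")
        counts = (
            self.lstm_layers,
            self.lstm_units,
            *self.conv_filters,
            self.conv_kernel_width,
            self.conv_stride,
            self.pool_width,
            *self.pool_strides,
            self.window_len,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all architecture counts must be positive")
        if self.conv_stride != 1:
            raise ValueError("only stride-1 convolutions are supported")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-4
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


class LSTMCNN:
    """The assembled network; weights live in the layer objects."""

    def __init__(self, spec: ModelSpec, n_channels: int, seed: int = 0) -> None:
        if n_channels < 1:
            raise ValueError(f"need at least one input channel, got {n_channels}")
        self.spec = spec
        self.n_channels = n_channels
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed]))

        layers: list[Layer] = []
        in_dim = n_channels
        for _ in range(spec.lstm_layers):
            layers.append(LSTMLayer(in_dim, spec.lstm_units, rng))
            in_dim = spec.lstm_units
        t = spec.window_len
        for filters, pool_stride in zip(spec.conv_filters, spec.pool_strides):
            layers.append(Conv1D(in_dim, filters, spec.conv_kernel_width, rng))
            layers.append(MaxPool1D(spec.pool_width, pool_stride))
            t = (t - spec.pool_width) // pool_stride + 1
            in_dim = filters
        if t < 1:
            raise ValueError(f"window_len {spec.window_len} too short for the pooling stack")
        layers.append(Flatten())
        layers.append(Dense(t * in_dim, spec.output_classes, rng))
        self.layers = layers
        self.feature_len = t

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_L.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != (self.spec.window_len, self.n_channels):
            raise ValueError(
                f"expected windows of shape (N, {self.spec.window_len}, "
                f"{self.n_channels}), got {x.shape}"
            )
        return x

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        out = self._check_input(x)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax phase probabilities, row sums exactly normalized."""
        x = self._check_input(x)
        outs = [
            softmax(self.forward_logits(x[i : i + batch_size]).astype(np.float64))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)


def build_model(spec: ModelSpec, n_channels: int, seed: int = 0) -> LSTMCNN:
    """Construct an untrained classifier for ``n_channels`` input channels."""
    return LSTMCNN(spec, n_channels, seed)


@dataclass
class TrainedModel:
    """A fitted classifier bound to its sensor group and normalizer.

    ``predict_proba`` expects windows already restricted to the bound
    group's channels and normalized with the bound parameters;
    ``predict_on_raw`` does both steps from full six-channel raw windows.
    """

    network: LSTMCNN
    sensor_group: SensorGroup
    normalizer: NormalizerParams
    train_config: TrainConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    name: str = ""

    @property
    def n_channels(self) -> int:
        return self.sensor_group.n_channels

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        try:
            return self.network.predict_proba(windows)
        except ValueError as err:
            raise ValueError(
                f"{err} (model {self.name or 'LSTM-CNN'} is bound to sensor "
                f"group {self.sensor_group.group_id}: {self.sensor_group.sites})"
            ) from None

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.predict_proba(windows).argmax(axis=1).astype(np.int8)

    def prepare_raw(self, windows6: np.ndarray, source_sites=SITES) -> np.ndarray:
        """Select the bound group's channels and apply the bound normalizer."""
        sel = select_channels(np.asarray(windows6), self.sensor_group, source_sites)
        return apply_normalizer(self.normalizer, sel).astype(_L.DTYPE)

    def predict_on_raw(self, windows6: np.ndarray, source_sites=SITES) -> np.ndarray:
        return self.predict_proba(self.prepare_raw(windows6, source_sites))

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Weights to ``<path>.npz``, spec/group/normalizer to ``<path>.json``."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            **{f"w{i}": w for i, w in enumerate(self.network.get_weights())},
        )
        meta = {
            "name": self.name,
            "spec": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in self.network.spec.__dict__.items()
                }
            },
            "seed": self.network.seed,
            "group_id": self.sensor_group.group_id,
            "normalizer": {
                "channels": list(self.normalizer.channels),
                "x_min": self.normalizer.x_min.tolist(),
                "x_max": self.normalizer.x_max.tolist(),
                "y_min": self.normalizer.y_min,
                "y_max": self.normalizer.y_max,
            },
            "train_config": self.train_config.__dict__,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        if not self.history.empty:
            self.history.to_csv(path.with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        spec_d = dict(meta["spec"])
        for k in ("conv_filters", "pool_strides"):
            spec_d[k] = tuple(spec_d[k])
        spec = ModelSpec(**spec_d)
        group = SensorGroup(meta["group_id"])
        net = LSTMCNN(spec, group.n_channels, seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as npz:
            net.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
        norm = NormalizerParams(
            channels=tuple(meta["normalizer"]["channels"]),
            x_min=np.array(meta["normalizer"]["x_min"]),
            x_max=np.array(meta["normalizer"]["x_max"]),
            y_min=meta["normalizer"]["y_min"],
            y_max=meta["normalizer"]["y_max"],
        )
        hist_path = path.with_suffix(".history.csv")
        hist = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
        return cls(
            network=net,
            sensor_group=group,
            normalizer=norm,
            train_config=TrainConfig(**meta["train_config"]),
            history=hist,
            name=meta.get("name", ""),
        )


def _epoch_eval(net: LSTMCNN, x: np.ndarray, y: np.ndarray, batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = net.forward_logits(x[i : i + batch])
        loss, _ = cross_entropy(logits, y[i : i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(
    network: LSTMCNN,
    windows: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    sensor_group: SensorGroup | None = None,
    normalizer: NormalizerParams | None = None,
    name: str = "",
) -> TrainedModel:
    """Fit the network on labeled, already-normalized windows.

    Deterministic given ``config.seed`` (validation split, shuffling and
    weight initialization all derive from it).  A seeded fraction of the
    windows is held out to monitor the loss; training stops at
    ``max_epochs`` or when the validation loss has not improved by
    ``early_stop_min_delta`` for ``early_stop_patience`` epochs, and the
    best-validation-loss weights are restored.
    """
    x = np.asarray(windows, dtype=_L.DTYPE)
    y = np.asarray(labels, dtype=np.int64).ravel()
    if len(x) != len(y):
        raise ValueError("windows and labels differ in length")
    present = np.unique(y)
    missing = sorted(set(range(N_PHASES)) - set(present.tolist()))
    if missing:
        raise ValueError(f"training data lacks phase class(es) {missing}")

    ss = np.random.SeedSequence([config.seed, 17])
    rng = np.random.default_rng(ss)
    order = rng.permutation(len(x))
    n_val = max(1, int(round(config.validation_fraction * len(x))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("no training windows left after the validation split")
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    opt = Adam(network.params, network.grads, learning_rate=config.learning_rate)
    rows = []
    best_loss, best_weights, since_best = np.inf, network.get_weights(), 0
    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(x_tr))
        ep_losses, ep_correct = [], 0
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            logits = network.forward_logits(x_tr[idx])
            loss, dlogits = cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            network.backward(dlogits)
            opt.step()
            ep_losses.append(loss * len(idx))
            ep_correct += int((logits.argmax(axis=1) == y_tr[idx]).sum())
        val_loss, val_acc = _epoch_eval(network, x_val, y_val, config.batch_size)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.sum(ep_losses) / len(x_tr)),
                "train_accuracy": ep_correct / len(x_tr),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_loss - config.early_stop_min_delta:
            best_loss, best_weights, since_best = val_loss, network.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    network.set_weights(best_weights)

    group = sensor_group if sensor_group is not None else SensorGroup(7)
    if normalizer is None:
        normalizer = NormalizerParams(
            channels=tuple(f"ch{i}" for i in range(network.n_channels)),
            x_min=np.full(network.n_channels, -1.0),
            x_max=np.full(network.n_channels, 1.0),
        )
    return TrainedModel(
        network=network,
        sensor_group=group,
        normalizer=normalizer,
        train_config=config,
        history=pd.DataFrame(rows),
        name=name,
    )


#: specialist name -> sensor group id: the full six-site model, the
#: shanks+feet model (best for SW-L) and the thighs+shanks model (best for
#: SU-LHS).
SPECIALIST_GROUPS: dict[str, int] = {
    "LSTM-CNN-1": 7,
    "LSTM-CNN-2": 6,
    "LSTM-CNN-3": 4,
}


def train_specialists(
    raw_windows6: np.ndarray,
    labels: np.ndarray,
    normalizer6: NormalizerParams,
    config: TrainConfig,
    spec: ModelSpec | None = None,
    groups: dict[str, int] | None = None,
) -> dict[str, TrainedModel]:
    """Train the per-phase specialist models from six-channel raw windows.

    ``normalizer6`` must be fitted on the full six training channels; each
    specialist binds the subset for its sensor group.  Seeds for the three
    fits are derived from ``config.seed``.
    """
    if raw_windows6.shape[-1] != len(SITES):
        raise ValueError("specialist training needs all six channels")
    spec = spec or ModelSpec()
    groups = groups or SPECIALIST_GROUPS
    models: dict[str, TrainedModel] = {}
    for k, (mname, gid) in enumerate(groups.items()):
        group = SensorGroup(gid)
        sub_norm = normalizer6.subset(group.sites)
        xg = apply_normalizer(sub_norm, select_channels(raw_windows6, group))
        seed = int(np.random.SeedSequence([config.seed, 100 + k]).generate_state(1)[0] % (2**31))
        net = build_model(spec, group.n_channels, seed=seed)
        models[mname] = train(
            net,
            xg,
            labels,
            replace(config, seed=seed),
            sensor_group=group,
            normalizer=sub_norm,
            name=mname,
        )
    return models
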