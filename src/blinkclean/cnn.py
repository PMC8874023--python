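"""Two-channel 1D convolutional denoiser, implemented in NumPy.

The network maps a (512, 2) window — reference blink channel plus the
contaminated channel — to the 512-sample clean window:

====================  =====================================================
Layer                 Parameters
====================  =====================================================
Input                 shape (512, 2)
Conv1D + ReLU         20 filters, kernel 40, stride 2, "same" padding
Conv1D + ReLU         10 filters, kernel 20, stride 1, "same" padding
Flatten               2560 features
Dense                 512 outputs (the clean window)
====================  =====================================================

Training minimizes mean squared error with Adam (lr 1e-3, β1 0.9, β2 0.999,
ε 1e-7), batches of 128.  Convolutions use an im2col strategy: patches are
gathered with one strided copy per kernel tap and reduced to a single matrix
product, which keeps both the forward and backward passes inside BLAS.  All
stochastic steps (weight initialization, epoch shuffling) come from one
seeded generator, so a fixed seed reproduces the loss history exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from blinkclean.config import TrainConfig, REFERENCE_CHANNEL
from blinkclean.recording import PairedWindowDataset, Recording

_DTYPE = np.float32


@dataclass(frozen=True)
class ConvLayerSpec:
    filters: int
    kernel: int
    stride: int


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description of the denoiser."""

    window_samples: int = 512
    in_channels: int = 2
    conv1: ConvLayerSpec = field(default_factory=lambda: ConvLayerSpec(20, 40, 2))
    conv2: ConvLayerSpec = field(default_factory=lambda: ConvLayerSpec(10, 20, 1))

    def __post_init__(self) -> None:
        if self.window_samples <= 0 or self.in_channels <= 0:
            raise ValueError("window_samples and in_channels must be positive")
        for c in (self.conv1, self.conv2):
            if min(c.filters, c.kernel, c.stride) <= 0:
                raise ValueError("conv layer parameters must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        for key in ("conv1", "conv2"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = ConvLayerSpec(**d[key])
        return cls(**d)


def _same_padding(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_length, pad_left, pad_right) for "same" padding."""
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    return out, total // 2, total - total // 2


class _Conv1D:
    """1D convolution with ReLU-ready im2col forward/backward."""

    def __init__(self, in_ch: int, spec: ConvLayerSpec, in_len: int,
                 rng: np.random.Generator):
        self.spec = spec
        self.in_ch = in_ch
        self.in_len = in_len
        self.out_len, self.pad_l, self.pad_r = _same_padding(
            in_len, spec.kernel, spec.stride)
        fan_in = spec.kernel * in_ch
        fan_out = spec.kernel * spec.filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit,
                             size=(spec.kernel * in_ch, spec.filters)).astype(_DTYPE)
        self.b = np.zeros(spec.filters, dtype=_DTYPE)
        self._cache: tuple | None = None

    def _patches(self, x: np.ndarray) -> np.ndarray:
        k, s = self.spec.kernel, self.spec.stride
        b = x.shape[0]
        xp = np.zeros((b, self.in_len + self.pad_l + self.pad_r, self.in_ch),
                      dtype=_DTYPE)
        xp[:, self.pad_l:self.pad_l + self.in_len] = x
        patches = np.empty((b, self.out_len, k, self.in_ch), dtype=_DTYPE)
        for tap in range(k):
            patches[:, :, tap, :] = xp[:, tap:tap + s * self.out_len:s, :]
        return patches

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        patches = self._patches(x)
        flat = patches.reshape(x.shape[0], self.out_len, -1)
        out = flat @ self.W + self.b
        if training:
            self._cache = (flat,)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (flat,) = self._cache
        b = dout.shape[0]
        k, s = self.spec.kernel, self.spec.stride
        self.dW = (flat.reshape(-1, self.W.shape[0]).T
                   @ dout.reshape(-1, self.spec.filters))
        self.db = dout.sum(axis=(0, 1))
        dflat = dout @ self.W.T
        dpatches = dflat.reshape(b, self.out_len, k, self.in_ch)
        dxp = np.zeros((b, self.in_len + self.pad_l + self.pad_r, self.in_ch),
                       dtype=_DTYPE)
        for tap in range(k):
            dxp[:, tap:tap + s * self.out_len:s, :] += dpatches[:, :, tap, :]
        return dxp[:, self.pad_l:self.pad_l + self.in_len]


class _ReLU:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class CNNDenoiser:
    """Untrained denoiser network built from a :class:`ModelSpec`.

    ``fit`` (or the module-level :func:`train`) returns a
    :class:`TrainedDenoiser` results object carrying the weights and the
    per-epoch loss history.
    """

    def __init__(self, spec: ModelSpec | None = None, seed: int | None = None):
        self.spec = spec or ModelSpec()
        self.seed = seed
        rng = np.random.default_rng(seed)
        s = self.spec
        self.conv1 = _Conv1D(s.in_channels, s.conv1, s.window_samples, rng)
        self.relu1 = _ReLU()
        self.conv2 = _Conv1D(s.conv1.filters, s.conv2, self.conv1.out_len, rng)
        self.relu2 = _ReLU()
        flat_features = self.conv2.out_len * s.conv2.filters
        self.dense = _Dense(flat_features, s.window_samples, rng)
        self._layers = [self.conv1, self.relu1, self.conv2, self.relu2]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.spec.window_samples, self.spec.in_channels):
            raise ValueError(
                f"expected input of shape (batch, {self.spec.window_samples}, "
                f"{self.spec.in_channels}); got {x.shape}")
        h = x
        for layer in self._layers:
            h = layer.forward(h, training)
        h = h.reshape(h.shape[0], -1)
        return self.dense.forward(h, training)

    predict = forward

    def backward(self, dout: np.ndarray) -> None:
        dh = self.dense.backward(dout)
        dh = dh.reshape(dh.shape[0], self.conv2.out_len, self.spec.conv2.filters)
        for layer in reversed(self._layers):
            dh = layer.backward(dh)

    # -- parameter access ---------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {"conv1_W": self.conv1.W, "conv1_b": self.conv1.b,
                "conv2_W": self.conv2.W, "conv2_b": self.conv2.b,
                "dense_W": self.dense.W, "dense_b": self.dense.b}

    def set_weights(self, weights: Mapping[str, np.ndarray]) -> None:
        expected = self.get_weights()
        for name, target in expected.items():
            w = np.asarray(weights[name], dtype=_DTYPE)
            if w.shape != target.shape:
                raise ValueError(
                    f"weight {name} has shape {w.shape}, expected {target.shape}")
        self.conv1.W = np.array(weights["conv1_W"], dtype=_DTYPE)
        self.conv1.b = np.array(weights["conv1_b"], dtype=_DTYPE)
        self.conv2.W = np.array(weights["conv2_W"], dtype=_DTYPE)
        self.conv2.b = np.array(weights["conv2_b"], dtype=_DTYPE)
        self.dense.W = np.array(weights["dense_W"], dtype=_DTYPE)
        self.dense.b = np.array(weights["dense_b"], dtype=_DTYPE)

    def fit(self, dataset: PairedWindowDataset,
            config: TrainConfig | None = None) -> "TrainedDenoiser":
        return train(self, dataset, config)


def build_model(spec: ModelSpec | None = None, seed: int | None = None) -> CNNDenoiser:
    """Construct the untrained denoiser network."""
    return CNNDenoiser(spec, seed)


class _Adam:
    def __init__(self, config: TrainConfig, shapes: dict[str, tuple]):
        self.lr = config.learning_rate
        self.b1, self.b2, self.eps = config.beta1, config.beta2, config.epsilon
        self.m = {k: np.zeros(s, dtype=_DTYPE) for k, s in shapes.items()}
        self.v = {k: np.zeros(s, dtype=_DTYPE) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        correction = (np.sqrt(1.0 - self.b2 ** self.t)
                      / (1.0 - self.b1 ** self.t))
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            params[k] -= self.lr * correction * m / (np.sqrt(v) + self.eps)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=1, keepdims=True)
    std = x.std(axis=1, keepdims=True)
    std = np.where(std < 1e-12, 1.0, std)
    return (x - mean) / std, mean, std


def train(model: CNNDenoiser, dataset: PairedWindowDataset,
          config: TrainConfig | None = None) -> "TrainedDenoiser":
    """Train the denoiser with minibatch Adam on MSE loss.

    Uses the dataset's recorded train/validation split; reports per-epoch
    mean training loss and end-of-epoch validation loss (μV²).
    """
    config = config or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(config.seed)

    x = np.asarray(dataset.inputs, dtype=_DTYPE)
    y = np.asarray(dataset.targets, dtype=_DTYPE)
    tr, va = dataset.train_indices, dataset.val_indices
    if len(tr) == 0:
        raise ValueError("dataset has an empty training split")

    weights = {"conv1_W": model.conv1.W, "conv1_b": model.conv1.b,
               "conv2_W": model.conv2.W, "conv2_b": model.conv2.b,
               "dense_W": model.dense.W, "dense_b": model.dense.b}
    opt = _Adam(config, {k: w.shape for k, w in weights.items()})

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    bs = config.batch_size
    for _ in range(config.epochs):
        order = rng.permutation(tr)
        epoch_sse = 0.0
        epoch_count = 0
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            xb, yb = x[idx], y[idx]
            if config.standardize:
                xb, mean, std = _standardize(xb)
                yb = (yb - mean[:, 0, 1:2].reshape(-1, 1)) / std[:, 0, 1:2].reshape(-1, 1)
            pred = model.forward(xb, training=True)
            err = pred - yb
            epoch_sse += float(np.sum(err * err))
            epoch_count += err.size
            model.backward(2.0 * err / err.size)
            grads = {"conv1_W": model.conv1.dW, "conv1_b": model.conv1.db,
                     "conv2_W": model.conv2.dW, "conv2_b": model.conv2.db,
                     "dense_W": model.dense.dW, "dense_b": model.dense.db}
            opt.step(weights, grads)
        history["train_loss"].append(epoch_sse / max(epoch_count, 1))
        history["val_loss"].append(_eval_loss(model, x, y, va, config))

    return TrainedDenoiser(model=model, spec=model.spec, config=config,
                           history=history, seed=config.seed)


def _eval_loss(model: CNNDenoiser, x: np.ndarray, y: np.ndarray,
               indices: np.ndarray, config: TrainConfig,
               chunk: int = 1024) -> float:
    if len(indices) == 0:
        return float("nan")
    sse = 0.0
    count = 0
    for start in range(0, len(indices), chunk):
        idx = indices[start:start + chunk]
        xb, yb = x[idx], y[idx]
        if config.standardize:
            xb, mean, std = _standardize(xb)
            yb = (yb - mean[:, 0, 1:2].reshape(-1, 1)) / std[:, 0, 1:2].reshape(-1, 1)
        err = model.forward(xb) - yb
        sse += float(np.sum(err * err))
        count += err.size
    return sse / count


@dataclass
class TrainedDenoiser:
    """Fit results: trained network, configuration echo and loss history."""

    model: CNNDenoiser
    spec: ModelSpec
    config: TrainConfig
    history: dict[str, list[float]]
    seed: int | None

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        x = np.asarray(inputs, dtype=_DTYPE)
        if self.config.standardize:
            raise NotImplementedError(
                "per-window standardization must be handled by the caller "
                "holding the window statistics; use clean_recording")
        return self.model.forward(x)

    def clean(self, recording: Recording,
              reference_channel: str = REFERENCE_CHANNEL) -> Recording:
        return clean_recording(self, recording, reference_channel)

    def summary(self) -> str:
        s = self.spec
        lines = [
            "Trained 1D convolutional denoiser",
            "=" * 46,
            f"Input shape          ({s.window_samples}, {s.in_channels})",
            f"Conv1D + ReLU        {s.conv1.filters} filters, kernel "
            f"{s.conv1.kernel}, stride {s.conv1.stride}, same padding",
            f"Conv1D + ReLU        {s.conv2.filters} filters, kernel "
            f"{s.conv2.kernel}, stride {s.conv2.stride}, same padding",
            f"Dense output         {s.window_samples}",
            f"Parameters           {self.n_parameters}",
            "-" * 46,
            f"Optimizer            Adam(lr={self.config.learning_rate}, "
            f"b1={self.config.beta1}, b2={self.config.beta2}, "
            f"eps={self.config.epsilon})",
            f"Batch size           {self.config.batch_size}",
            f"Epochs               {self.config.epochs}",
            f"Seed                 {self.seed}",
        ]
        for i, (t, v) in enumerate(zip(self.history["train_loss"],
                                       self.history["val_loss"]), 1):
            lines.append(f"epoch {i:>3}  train MSE {t:10.4f} μV²   "
                         f"val MSE {v:10.4f} μV²")
        return "\n".join(lines)

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.model.get_weights().values())

    def save(self, path: str | Path) -> None:
        save_model(self, path)


def clean_recording(trained: TrainedDenoiser, recording: Recording,
                    reference_channel: str = REFERENCE_CHANNEL) -> Recording:
    """Apply the denoiser to every non-reference channel of a recording.

    Each channel is split into consecutive 1-s windows, paired with the
    synchronous reference window, and replaced by the network output; the
    reference channel passes through unchanged.  A trailing partial window is
    zero-padded to the window length and the output truncated back.
    """
    n = trained.spec.window_samples
    if round(recording.sampling_rate) != n:
        raise ValueError(
            f"recording sampling rate {recording.sampling_rate} does not "
            f"match the training window of {n} samples per second")
    ref = recording.channel(reference_channel)  # KeyError if absent
    n_samples = recording.n_samples
    n_full = n_samples // n
    n_windows = n_full + (1 if n_samples % n else 0)

    out = recording.data.copy()
    targets = [c for c in recording.channel_names if c != reference_channel]
    # One batched forward pass: (n_windows * n_targets, n, 2)
    batch = np.zeros((n_windows * len(targets), n, 2), dtype=_DTYPE)
    for w in range(n_windows):
        lo, hi = w * n, min((w + 1) * n, n_samples)
        for t_i, ch in enumerate(targets):
            row = w * len(targets) + t_i
            batch[row, :hi - lo, 0] = ref[lo:hi]
            batch[row, :hi - lo, 1] = recording.channel(ch)[lo:hi]
    if trained.config.standardize:
        batch, mean, std = _standardize(batch)
        pred = _predict_chunks(trained.model, batch)
        pred = pred * std[:, 0, 1:2] + mean[:, 0, 1:2]
    else:
        pred = _predict_chunks(trained.model, batch)
    for w in range(n_windows):
        lo, hi = w * n, min((w + 1) * n, n_samples)
        for t_i, ch in enumerate(targets):
            out[recording.channel_index(ch), lo:hi] = \
                pred[w * len(targets) + t_i, :hi - lo]
    meta = dict(recording.meta)
    meta["cleaned_by"] = {"method": "cnn", "reference": reference_channel,
                          "train_seed": trained.seed}
    return Recording(out, recording.sampling_rate,
                     list(recording.channel_names), meta)


def _predict_chunks(model: CNNDenoiser, x: np.ndarray, chunk: int = 512) -> np.ndarray:
    outs = [model.forward(x[i:i + chunk]) for i in range(0, len(x), chunk)]
    return np.concatenate(outs, axis=0)


def save_model(trained: TrainedDenoiser, path: str | Path) -> None:
    """Serialize weights (.npz) plus a JSON sidecar with spec and history."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **trained.model.get_weights())
    sidecar = {
        "spec": trained.spec.to_dict(),
        "train_config": trained.config.to_dict(),
        "history": trained.history,
        "seed": trained.seed,
        "format_version": 1,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedDenoiser:
    """Load a saved denoiser; round-trips predictions bit-exactly."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    weights_path = path.with_suffix(".npz")
    if not sidecar_path.exists() or not weights_path.exists():
        raise FileNotFoundError(f"model files not found at {path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        spec = ModelSpec.from_dict(sidecar["spec"])
        config = TrainConfig.from_dict(sidecar["train_config"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"corrupt model sidecar at {sidecar_path}: {exc}") from exc
    model = CNNDenoiser(spec, seed=sidecar.get("seed"))
    with np.load(weights_path) as archive:
        weights = {k: archive[k] for k in archive.files}
    try:
        model.set_weights(weights)
    except (KeyError, ValueError) as exc:
        raise ValueError(
            f"model weights at {weights_path} do not match the stored "
            f"architecture: {exc}") from exc
    return TrainedDenoiser(model=model, spec=spec, config=config,
                           history=sidecar["history"], seed=sidecar.get("seed"))
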