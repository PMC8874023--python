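"""Core data containers: recordings, blink trains, spectra, paired datasets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class Recording:
    """A multichannel signal matrix in μV.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values in μV, one row per channel.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_names : list of str
        Ordered electrode labels, one per row.
    meta : dict
        Free-form provenance (seed, config echo, realized gains, ...).
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"row count {self.data.shape[0]} != number of channel names "
                f"{len(self.channel_names)}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return the signal row for electrode ``name``."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None
        return self.data[idx]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.sampling_rate,
                         list(self.channel_names), dict(self.meta))


@dataclass
class ReferenceSpectrum:
    """Discrete Fourier coefficients of one reference window.

    Coefficients are the plain (unnormalized) DFT of a real-valued 1-s
    window in μV, hence Hermitian-symmetric.
    """

    coefficients: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.coefficients.ndim != 1:
            raise ValueError("coefficients must be 1-D")

    @property
    def window_samples(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class BlinkTrain:
    """Sequence of blink events: (onset s, peak amplitude μV, width s)."""

    events: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        onsets = [e[0] for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("blink onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e[0] for e in self.events], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([e[1] for e in self.events], dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return np.array([e[2] for e in self.events], dtype=float)


@dataclass
class PairedWindowDataset:
    """Aligned training examples for the convolutional denoiser.

    Attributes
    ----------
    inputs : ndarray, shape (n, window_samples, 2)
        Channel 0 is the contaminated reference (Fp1 with blinks), channel 1
        the contaminated target channel, both in μV.
    targets : ndarray, shape (n, window_samples)
        Clean target-channel windows, μV.
    channel_labels : list of str, length n
        Target-channel electrode label per example.
    train_indices, val_indices : ndarray of int
        Disjoint 80/20 split of ``range(n)``.
    meta : dict
        Config echo, seed, per-example bookkeeping.
    """

    inputs: np.ndarray
    targets: np.ndarray
    channel_labels: list[str]
    train_indices: np.ndarray
    val_indices: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 3 or self.inputs.shape[2] != 2:
            raise ValueError("inputs must have shape (n, window_samples, 2)")
        if self.targets.shape != self.inputs.shape[:2]:
            raise ValueError("targets must align with inputs 1:1")
        if len(self.channel_labels) != self.inputs.shape[0]:
            raise ValueError("one channel label per example required")
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.val_indices = np.asarray(self.val_indices, dtype=int)

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def window_samples(self) -> int:
        return self.inputs.shape[1]
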