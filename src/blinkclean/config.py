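"""Configuration objects for generation, training and ICA.

Default values encode the study conditions: 512 Hz sampling, 1-s windows,
clean-EEG standard deviation 5–15 μV and peak-to-peak 45–100 μV, spectrum
jitter bounded by ±2 μV, stitch boundary jumps bounded by 7 μV, blink
amplitudes 0–650 μV and inter-blink intervals 0.5–4 s, on the 16-channel
10–20 montage with Fp1 as the blink reference electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

# 10-20 montage used throughout, ordered occipital -> frontal as recorded.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Oz", "O2", "O1", "Pz", "P4", "P3", "C4", "C3", "Cz",
    "F8", "F7", "Fz", "F4", "F3", "Fp1", "F9",
)

# Blink propagation gains: monotone frontal -> occipital decay. The reference
# electrode Fp1 (closest to the eye) carries the full-amplitude blink.
DEFAULT_GAINS: Mapping[str, float] = {
    "Fp1": 1.00,
    "F9": 0.85,
    "F3": 0.65, "F4": 0.65, "F7": 0.65, "F8": 0.65, "Fz": 0.65,
    "C3": 0.40, "C4": 0.40, "Cz": 0.40,
    "P3": 0.25, "P4": 0.25, "Pz": 0.25,
    "O1": 0.10, "O2": 0.10, "Oz": 0.10,
}

REFERENCE_CHANNEL = "Fp1"


@dataclass(frozen=True)
class GeneratorConfig:
    """All stochastic-generation parameters for the surrogate EEG/EOG generator.

    Parameters
    ----------
    sampling_rate : float
        Sampling frequency in Hz.
    window_samples : int
        Samples per generated window; must equal one second of signal.
    std_range : (float, float)
        Admissible per-window standard deviation of clean EEG, μV.
    p2p_range : (float, float)
        Admissible per-window peak-to-peak amplitude of clean EEG, μV.
    spectrum_jitter : float
        Bound (μV) on the uniform perturbation added independently to the
        real and imaginary part of each positive-frequency DFT coefficient
        of the reference window.
    stitch_limit : float
        Maximum allowed amplitude jump (μV) at the junction of two stitched
        windows.
    blink_amp_range : (float, float)
        Blink peak amplitude range at the reference electrode, μV.
    blink_interval_range : (float, float)
        Range of gaps between successive blink onsets, s.
    blink_width_range : (float, float)
        Range of the blink duration parameter (s). The Gaussian pulse has
        σ = width / 2 and support truncated at ±3σ, giving the ~1-s visible
        envelope of a natural blink for widths around 0.3 s.
    channel_names : sequence of str
        Ordered electrode labels; must contain the reference channel.
    propagation_gains : mapping str -> float
        Per-channel dimensionless blink gain in [-1, 1]; the reference
        channel must have gain 1.0.
    gain_jitter : float
        Relative jitter applied to non-reference gains once per recording
        (0.2 means ±20%); jittered gains are clipped to [0, 0.98] so the
        reference row always carries the largest artifact.
    seed : int
        Default seed for top-level convenience calls.
    """

    sampling_rate: float = 512.0
    window_samples: int = 512
    std_range: tuple[float, float] = (5.0, 15.0)
    p2p_range: tuple[float, float] = (45.0, 100.0)
    spectrum_jitter: float = 2.0
    stitch_limit: float = 7.0
    blink_amp_range: tuple[float, float] = (0.0, 650.0)
    blink_interval_range: tuple[float, float] = (0.5, 4.0)
    blink_width_range: tuple[float, float] = (0.2, 0.4)
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    propagation_gains: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAINS))
    gain_jitter: float = 0.2
    reference_channel: str = REFERENCE_CHANNEL
    seed: int = 20220211

    def __post_init__(self) -> None:
        for name in ("std_range", "p2p_range", "blink_amp_range",
                     "blink_interval_range", "blink_width_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if self.spectrum_jitter < 0:
            raise ValueError("spectrum_jitter must be non-negative")
        if self.stitch_limit < 0:
            raise ValueError("stitch_limit must be non-negative")
        if self.window_samples != round(self.sampling_rate):
            raise ValueError(
                "window_samples must cover exactly 1 s: expected "
                f"{round(self.sampling_rate)}, got {self.window_samples}")
        if self.reference_channel not in self.channel_names:
            raise ValueError(f"reference channel {self.reference_channel!r} missing from channel_names")
        gains = self.propagation_gains
        missing = [c for c in self.channel_names if c not in gains]
        if missing:
            raise ValueError(f"propagation_gains missing channels: {missing}")
        if gains[self.reference_channel] != 1.0:
            raise ValueError("reference channel gain must be 1.0")
        for c, g in gains.items():
            if not -1.0 <= g <= 1.0:
                raise ValueError(f"gain for {c} outside [-1, 1]: {g}")

    @property
    def gain_vector(self) -> "list[float]":
        return [self.propagation_gains[c] for c in self.channel_names]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["propagation_gains"] = dict(self.propagation_gains)
        d["channel_names"] = list(self.channel_names)
        for name in ("std_range", "p2p_range", "blink_amp_range",
                     "blink_interval_range", "blink_width_range"):
            d[name] = list(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for name in ("std_range", "p2p_range", "blink_amp_range",
                     "blink_interval_range", "blink_width_range"):
            if name in d:
                d[name] = tuple(d[name])
        if "channel_names" in d:
            d["channel_names"] = tuple(d["channel_names"])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings for the convolutional denoiser.

    Defaults are Adam with learning rate 1e-3, β1 0.9, β2 0.999, ε 1e-7,
    mean-squared-error loss, minibatches of 128, 10 epochs and an 80/20
    train/validation split.
    """

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 128
    epochs: int = 10
    train_fraction: float = 0.8
    standardize: bool = False
    seed: int = 20220211

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.beta1, self.beta2, self.epsilon) <= 0:
            raise ValueError("optimizer hyperparameters must be positive")
        if self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("batch_size and epochs must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrainConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class ICAConfig:
    """Settings for the ICA component-rejection baseline.

    The recording is high-pass filtered (zero-phase Butterworth, order 6,
    1 Hz cutoff), decomposed into ``n_components`` independent components
    (15 by default, on 16 channels), and the ``n_remove`` components most
    correlated with the reference signal (2 by default) are zeroed before
    remixing.
    """

    n_components: int = 15
    highpass_cutoff: float = 1.0
    filter_order: int = 6
    n_remove: int = 2
    max_iterations: int = 1000
    tolerance: float = 1e-4
    seed: int = 20220211

    def __post_init__(self) -> None:
        if self.n_components <= 0:
            raise ValueError("n_components must be positive")
        if not 0 <= self.n_remove <= self.n_components:
            raise ValueError("n_remove must lie in [0, n_components]")
        if self.highpass_cutoff <= 0 or self.filter_order <= 0:
            raise ValueError("highpass_cutoff and filter_order must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ICAConfig":
        return cls(**dict(d))
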