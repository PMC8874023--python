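"""Classical artifact-removal baselines: reference regression and ICA.

Linear regression removes from every non-reference channel the least-squares
projection onto the mean-centered reference (Fp1) signal:

    cov = EOGref · EOGrefᵀ
    B   = cov⁻¹ · EOGref · EEGnoisedᵀ
    EEGclear = EEGnoised − B · EOGref

ICA high-pass filters the recording (zero-phase Butterworth), estimates
independent components with FastICA, zeroes the components most correlated
with the reference signal, and remixes the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from blinkclean.config import ICAConfig, REFERENCE_CHANNEL
from blinkclean.recording import Recording


@dataclass
class RegressionResult:
    """Results of reference-channel regression cleaning.

    Attributes
    ----------
    B : dict str -> float
        Dimensionless propagation factor per non-reference channel.
    cov : float
        Auto-covariance scalar of the centered reference, μV²·samples.
    reference_mean : float
        Mean of the raw reference signal, μV.
    channel_means : dict str -> float
        Mean of each raw channel, μV.
    cleaned : Recording
        Cleaned recording; the reference channel is passed through unchanged.
    """

    B: dict[str, float]
    cov: float
    reference_mean: float
    channel_means: dict[str, float]
    cleaned: Recording
    reference_channel: str = REFERENCE_CHANNEL

    def summary(self) -> str:
        lines = ["Reference-channel regression",
                 "=" * 40,
                 f"reference        {self.reference_channel}",
                 f"cov              {self.cov:.6g} μV²·samples",
                 "-" * 40,
                 "channel   propagation factor B"]
        for ch, b in self.B.items():
            lines.append(f"{ch:<9} {b:+.6f}")
        return "\n".join(lines)


def regression_clean(recording: Recording,
                     reference_channel: str = REFERENCE_CHANNEL) -> RegressionResult:
    """Remove the reference channel's contribution from every other channel.

    Mean-centers the reference and each target channel, solves
    ``cov * B = EOGref · EEGnoisedᵀ`` per channel, and subtracts
    ``B * EOGref``.  Cleaned channels are returned mean-centered: restoring
    the raw channel mean would re-inject the artifact's DC, because blinks
    are one-sided deflections whose time average is not zero.  The reference
    channel is returned untouched.  Raises on a constant (zero-variance)
    reference.
    """
    if recording.n_samples < 2:
        raise ValueError("need at least 2 samples for regression")
    ref_raw = recording.channel(reference_channel)
    ref_mean = float(ref_raw.mean())
    ref = ref_raw - ref_mean
    cov = float(ref @ ref)
    if cov <= 0.0:
        raise ValueError("reference channel is constant; regression is degenerate")

    out = recording.data.copy()
    b_factors: dict[str, float] = {}
    channel_means: dict[str, float] = {}
    for idx, ch in enumerate(recording.channel_names):
        channel_means[ch] = float(recording.data[idx].mean())
        if ch == reference_channel:
            continue
        centered = recording.data[idx] - channel_means[ch]
        b = float(ref @ centered) / cov
        b_factors[ch] = b
        out[idx] = centered - b * ref

    meta = dict(recording.meta)
    meta["cleaned_by"] = {"method": "reg", "reference": reference_channel}
    cleaned = Recording(out, recording.sampling_rate,
                        list(recording.channel_names), meta)
    return RegressionResult(B=b_factors, cov=cov, reference_mean=ref_mean,
                            channel_means=channel_means, cleaned=cleaned,
                            reference_channel=reference_channel)


def highpass_filter(recording: Recording, cutoff: float = 1.0,
                    order: int = 6) -> Recording:
    """Zero-phase (forward-backward) Butterworth high-pass, per channel.

    The effective magnitude response is the squared analog response
    |H(f)|² = (1 + (cutoff/f)^(2·order))⁻¹ applied without phase distortion.
    """
    nyquist = recording.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz; got {cutoff}")
    sos = sps.butter(order, cutoff, btype="highpass",
                     fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.data, axis=1)
    meta = dict(recording.meta)
    meta["highpass"] = {"cutoff_hz": cutoff, "order": order, "zero_phase": True}
    return Recording(filtered, recording.sampling_rate,
                     list(recording.channel_names), meta)


@dataclass
class ICAModel:
    """Fitted ICA decomposition of a recording.

    ``sources`` has one zero-mean row per component; ``mixing`` (channels ×
    components) and ``unmixing`` (components × channels) satisfy
    ``unmixing @ mixing ≈ I`` on the retained subspace.  ``converged`` is
    False when the fixed-point iteration hit ``max_iterations`` (carried as a
    flag, not an exception).
    """

    mixing: np.ndarray
    unmixing: np.ndarray
    sources: np.ndarray
    channel_means: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    config: ICAConfig
    converged: bool = True
    removed: list[int] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def summary(self) -> str:
        lines = ["ICA decomposition",
                 "=" * 40,
                 f"channels         {len(self.channel_names)}",
                 f"components       {self.n_components}",
                 f"converged        {self.converged}",
                 f"removed          {self.removed or 'none'}"]
        return "\n".join(lines)


def ica_decompose(recording: Recording, config: ICAConfig | None = None,
                  highpass: bool = False) -> ICAModel:
    """Estimate an independent-component decomposition of the recording.

    Mean-removal, whitening onto ``n_components`` principal directions and a
    FastICA fixed-point iteration with log-cosh contrast.  Set
    ``highpass=True`` to apply the configured zero-phase Butterworth
    high-pass first (otherwise the caller is expected to have filtered).
    """
    config = config or ICAConfig()
    if recording.n_channels < config.n_components:
        raise ValueError(
            f"n_components ({config.n_components}) exceeds channel count "
            f"({recording.n_channels})")
    if highpass:
        recording = highpass_filter(recording, config.highpass_cutoff,
                                    config.filter_order)
    x = recording.data.T  # samples x channels
    means = recording.data.mean(axis=1)
    ica = FastICA(n_components=config.n_components, fun="logcosh",
                  whiten="unit-variance", tol=config.tolerance,
                  max_iter=config.max_iterations,
                  random_state=config.seed % (2**32))
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(x).T  # components x samples
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
    return ICAModel(mixing=ica.mixing_.copy(),
                    unmixing=ica.components_.copy(),
                    sources=sources,
                    channel_means=means,
                    channel_names=list(recording.channel_names),
                    sampling_rate=recording.sampling_rate,
                    config=config,
                    converged=converged,
                    meta=dict(recording.meta))


def select_blink_components(model: ICAModel, reference_signal: np.ndarray,
                            n_remove: int | None = None) -> list[int]:
    """Indices of the components most correlated with the reference signal.

    Components are ranked by |Pearson correlation| of each source row with
    the (time-aligned) reference; the top ``n_remove`` are returned.  This is
    the automatic stand-in for visual component assessment.
    """
    if n_remove is None:
        n_remove = model.config.n_remove
    if n_remove > model.n_components:
        raise ValueError(
            f"n_remove ({n_remove}) exceeds component count "
            f"({model.n_components})")
    if n_remove == 0:
        return []
    reference_signal = np.asarray(reference_signal, dtype=float)
    if reference_signal.shape[0] != model.sources.shape[1]:
        raise ValueError("reference signal is not time-aligned with sources")
    ref = reference_signal - reference_signal.mean()
    ref_norm = np.linalg.norm(ref)
    scores = np.zeros(model.n_components)
    if ref_norm > 0:
        for i, src in enumerate(model.sources):
            s = src - src.mean()
            denom = np.linalg.norm(s) * ref_norm
            scores[i] = abs(float(s @ ref) / denom) if denom > 0 else 0.0
    order = np.argsort(-scores, kind="stable")
    return [int(i) for i in order[:n_remove]]


def ica_reconstruct(model: ICAModel, removed: list[int] | None = None) -> Recording:
    """Remix the sources with the removed components' contributions zeroed.

    Zeroing columns of the mixing matrix forms the modified mixing transform;
    the remaining components are mixed back and channel means restored.
    """
    removed = list(model.removed if removed is None else removed)
    for i in removed:
        if not 0 <= i < model.n_components:
            raise ValueError(f"component index {i} out of range "
                             f"[0, {model.n_components})")
    mixing_mod = model.mixing.copy()
    if removed:
        mixing_mod[:, removed] = 0.0
    data = mixing_mod @ model.sources + model.channel_means[:, None]
    meta = dict(model.meta)
    meta["cleaned_by"] = {"method": "ica", "removed_components": removed,
                          "n_components": model.n_components}
    return Recording(data, model.sampling_rate, list(model.channel_names), meta)


def ica_clean(recording: Recording, config: ICAConfig | None = None,
              reference_channel: str = REFERENCE_CHANNEL,
              components: list[int] | None = None,
              ) -> tuple[Recording, ICAModel]:
    """Full ICA pipeline: high-pass, decompose, select, reject, remix.

    Components are chosen automatically by correlation with the (filtered)
    reference channel unless explicit ``components`` are given.  Returns the
    cleaned recording and the fitted model (with ``removed`` populated).
    """
    config = config or ICAConfig()
    filtered = highpass_filter(recording, config.highpass_cutoff,
                               config.filter_order)
    model = ica_decompose(filtered, config)
    if components is None:
        components = select_blink_components(
            model, filtered.channel(reference_channel), config.n_remove)
    model.removed = list(components)
    return ica_reconstruct(model, components), model
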