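"""Surrogate EEG/EOG generation.

Clean EEG is built one 1-s window at a time: take a reference window (a real
EEG fragment, or the built-in 1/f-noise surrogate), compute its unitary DFT,
add small bounded random perturbations to the coefficients, and invert.  The
perturbed windows keep the reference's spectral character while differing in
detail.  Windows are stitched into continuous signal under a bound on the
amplitude jump at each junction.  Eye blinks are Gaussian-shaped pulses with
random amplitude and spacing, propagated to each electrode with a gain that
decays from frontal to occipital sites, and added to the clean signal.

All generation is driven by an explicit :class:`numpy.random.Generator`; the
same seed reproduces the same signals bit for bit.
"""

from __future__ import annotations

import numpy as np

from blinkclean.config import GeneratorConfig
from blinkclean.recording import (
    BlinkTrain,
    PairedWindowDataset,
    Recording,
    ReferenceSpectrum,
)

_MAX_ATTEMPTS = 100
_IMAG_TOL = 1e-9


def _rng_of(rng: np.random.Generator | int | None, config: GeneratorConfig) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(config.seed if rng is None else rng)


def derive_reference_spectrum(window: np.ndarray, sampling_rate: float) -> ReferenceSpectrum:
    """Discrete Fourier coefficients of a single reference window.

    Raises a size error if the window does not cover exactly one second at
    ``sampling_rate`` and a value error on non-finite samples.
    """
    window = np.asarray(window, dtype=float)
    expected = round(sampling_rate)
    if window.ndim != 1 or window.shape[0] != expected:
        raise ValueError(
            f"window must be 1-D with exactly {expected} samples "
            f"(1 s at {sampling_rate} Hz); got shape {window.shape}")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    coeff = np.fft.fft(window)
    return ReferenceSpectrum(coefficients=coeff, sampling_rate=sampling_rate)


def _scale_into_ranges(window: np.ndarray, config: GeneratorConfig,
                       rng: np.random.Generator | None) -> np.ndarray | None:
    """Linear rescale of a zero-jitter-free window into the std/p2p ranges.

    Returns the rescaled window, or None when no single scale factor can
    satisfy both ranges (peak-to-peak/std ratio outside the feasible band).
    When an rng is given the scale is drawn uniformly from the feasible
    interval, otherwise its midpoint is used.
    """
    std = float(np.std(window))
    p2p = float(np.ptp(window))
    if std == 0.0 or p2p == 0.0:
        return None
    s_lo = max(config.std_range[0] / std, config.p2p_range[0] / p2p)
    s_hi = min(config.std_range[1] / std, config.p2p_range[1] / p2p)
    if s_lo > s_hi:
        return None
    s = rng.uniform(s_lo, s_hi) if rng is not None else 0.5 * (s_lo + s_hi)
    return window * s


def _in_ranges(window: np.ndarray, config: GeneratorConfig) -> bool:
    std = float(np.std(window))
    p2p = float(np.ptp(window))
    return (config.std_range[0] <= std <= config.std_range[1]
            and config.p2p_range[0] <= p2p <= config.p2p_range[1])


def pink_reference(config: GeneratorConfig, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """A 1-s window of 1/f ("pink") noise scaled into the configured ranges.

    Used as the reference signal when no real EEG fragment is supplied.  The
    spectrum is built in rfft space with complex-Gaussian coefficients whose
    power falls off as 1/f, inverted with the unitary transform, and linearly
    scaled so the window's standard deviation and peak-to-peak amplitude fall
    inside ``std_range`` and ``p2p_range``.
    """
    rng = _rng_of(rng, config)
    n = config.window_samples
    n_bins = n // 2 + 1
    for _ in range(_MAX_ATTEMPTS):
        coeff = np.zeros(n_bins, dtype=complex)
        k = np.arange(1, n_bins, dtype=float)
        mags = 1.0 / np.sqrt(k)
        coeff[1:] = (rng.standard_normal(n_bins - 1)
                     + 1j * rng.standard_normal(n_bins - 1)) * mags
        coeff[-1] = coeff[-1].real  # Nyquist bin of a real signal
        window = np.fft.irfft(coeff, n=n, norm="ortho")
        scaled = _scale_into_ranges(window, config, rng)
        if scaled is not None:
            return scaled
    raise RuntimeError("could not draw a 1/f window compatible with the "
                       "configured std/p2p ranges")


def perturb_spectrum(spectrum: ReferenceSpectrum, config: GeneratorConfig,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a bounded random perturbation of the reference coefficients.

    Each positive-frequency coefficient receives an i.i.d. uniform draw in
    [-spectrum_jitter, +spectrum_jitter] (μV) on its real and imaginary part;
    negative frequencies are mirrored so the perturbed spectrum stays
    Hermitian, and the DC and Nyquist bins are perturbed in their real part
    only.  Returns ``(perturbed_coefficients, drawn_perturbations)`` where the
    second array holds every independently drawn value (for bound auditing).
    """
    rng = _rng_of(rng, config)
    n = spectrum.window_samples
    if n != config.window_samples:
        raise ValueError(
            f"spectrum length {n} does not match config window_samples "
            f"{config.window_samples}")
    j = config.spectrum_jitter
    coeff = spectrum.coefficients.copy()
    n_pos = (n - 1) // 2              # strictly positive, non-Nyquist bins
    has_nyquist = n % 2 == 0
    # Draws: DC(real), [re+im for each positive bin], Nyquist(real).
    n_draws = 1 + 2 * n_pos + (1 if has_nyquist else 0)
    draws = rng.uniform(-j, j, size=n_draws)
    coeff[0] += draws[0]
    pos = draws[1:1 + 2 * n_pos].reshape(n_pos, 2)
    delta = pos[:, 0] + 1j * pos[:, 1]
    coeff[1:1 + n_pos] += delta
    coeff[-n_pos:] = np.conj(coeff[1:1 + n_pos][::-1])  # Hermitian mirror
    if has_nyquist:
        coeff[n // 2] = coeff[n // 2].real + draws[-1]
    return coeff, draws


def generate_clean_window(spectrum: ReferenceSpectrum, config: GeneratorConfig,
                          rng: np.random.Generator | int | None = None,
                          info: dict | None = None) -> np.ndarray:
    """One clean 1-s window: jittered spectrum, inverse transform, range check.

    The jitter is redrawn up to 100 times until the window's std and
    peak-to-peak fall inside the configured ranges; if no draw succeeds the
    window is linearly rescaled into them.  With ``spectrum_jitter = 0`` the
    output is exactly the inverse transform of the reference spectrum
    (when that window already satisfies the ranges).

    ``info`` (optional dict) receives bookkeeping: the drawn perturbations
    of the accepted window ("perturbations"), the enforcement path taken
    ("path": "accepted" or "rescaled") and the attempt count.
    """
    rng = _rng_of(rng, config)
    window = None
    for attempt in range(1, _MAX_ATTEMPTS + 1):
        coeff, draws = perturb_spectrum(spectrum, config, rng)
        window_c = np.fft.ifft(coeff)
        imag_residue = float(np.max(np.abs(window_c.imag)))
        if imag_residue > _IMAG_TOL:
            raise RuntimeError(
                f"Hermitian symmetry violated: imaginary residue {imag_residue}")
        window = window_c.real
        if _in_ranges(window, config):
            if info is not None:
                info.update(perturbations=draws, path="accepted", attempts=attempt)
            return window
    rescaled = _scale_into_ranges(window, config, None)
    if rescaled is None:
        raise RuntimeError("window shape incompatible with std/p2p ranges "
                           "even after rescaling")
    if info is not None:
        info.update(perturbations=draws, path="rescaled", attempts=_MAX_ATTEMPTS)
    return rescaled


def stitch_windows(windows: list[np.ndarray], config: GeneratorConfig) -> np.ndarray:
    """Concatenate 1-s windows, bounding the amplitude jump at each junction.

    A window whose first sample would jump more than ``stitch_limit`` μV from
    the last sample already emitted is vertically offset so the jump lands
    exactly on the limit (the redraw mechanism lives in
    :func:`generate_recording`, which can redraw the jitter before falling
    back to this offset).
    """
    if len(windows) == 0:
        raise ValueError("need at least one window to stitch")
    n = config.window_samples
    for w in windows:
        if np.asarray(w).shape != (n,):
            raise ValueError(f"every window must have shape ({n},)")
    out = [np.asarray(windows[0], dtype=float)]
    limit = config.stitch_limit
    for w in windows[1:]:
        w = np.asarray(w, dtype=float)
        jump = w[0] - out[-1][-1]
        if abs(jump) > limit:
            w = w - (jump - np.clip(jump, -limit, limit))
        out.append(w)
    return np.concatenate(out)


def blink_waveform(amplitude: float, width: float, sampling_rate: float) -> np.ndarray:
    """Gaussian-window blink pulse with peak value ``amplitude`` μV.

    ``width`` (s) sets the pulse duration: the Gaussian has σ = width / 2 and
    finite support truncated at ±3σ, so a 0.3-s width yields the ~1-s visible
    envelope of a natural blink.
    """
    if width <= 0:
        raise ValueError("blink width must be positive")
    if amplitude < 0:
        raise ValueError("blink amplitude must be non-negative")
    sigma = width / 2.0
    half = int(round(3.0 * sigma * sampling_rate))
    t = np.arange(-half, half + 1, dtype=float) / sampling_rate
    return amplitude * np.exp(-0.5 * (t / sigma) ** 2)


def sample_blink_train(duration: float, config: GeneratorConfig,
                       rng: np.random.Generator | int | None = None) -> BlinkTrain:
    """Draw a blink train covering ``duration`` seconds.

    Onsets accumulate i.i.d. uniform gaps from ``blink_interval_range``;
    amplitudes are uniform in ``blink_amp_range`` and widths uniform in
    ``blink_width_range``.  Events falling beyond ``duration`` are discarded.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = _rng_of(rng, config)
    events: list[tuple[float, float, float]] = []
    t = 0.0
    while True:
        t += rng.uniform(*config.blink_interval_range)
        if t >= duration:
            break
        amp = rng.uniform(*config.blink_amp_range)
        width = rng.uniform(*config.blink_width_range)
        events.append((t, amp, width))
    return BlinkTrain(events=events)


def render_blink_signal(train: BlinkTrain, n_samples: int,
                        sampling_rate: float) -> np.ndarray:
    """Superpose the train's Gaussian pulses on a zero baseline."""
    signal = np.zeros(n_samples)
    for onset, amp, width in train.events:
        pulse = blink_waveform(amp, width, sampling_rate)
        center = int(round(onset * sampling_rate))
        half = (len(pulse) - 1) // 2
        lo, hi = center - half, center + half + 1
        p_lo, p_hi = max(0, -lo), len(pulse) - max(0, hi - n_samples)
        lo, hi = max(lo, 0), min(hi, n_samples)
        if lo < hi:
            signal[lo:hi] += pulse[p_lo:p_hi]
    return signal


def propagate_blinks(blink_signal: np.ndarray, gains: np.ndarray) -> np.ndarray:
    """Multichannel artifact matrix: row c = gains[c] x blink_signal."""
    blink_signal = np.asarray(blink_signal, dtype=float)
    gains = np.asarray(gains, dtype=float)
    if blink_signal.ndim != 1 or gains.ndim != 1:
        raise ValueError("blink_signal and gains must both be 1-D")
    return np.outer(gains, blink_signal)


def _channel_clean_signal(n_windows: int, config: GeneratorConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Stitched clean signal for one channel: fresh jittered 1/f windows.

    For each incoming window the jitter is redrawn (up to 100 times) until
    the junction jump obeys ``stitch_limit``.  When no jitter draw can close
    the gap, the incoming window receives a linearly tapered offset: the
    full correction at its first sample, decaying to zero at its last.  The
    junction bound then holds exactly, the window endpoints stay untouched,
    and — unlike a constant vertical offset, whose corrections chain from
    window to window — the per-window DC stays near zero, keeping the clean
    signal stationary.
    """
    n = config.window_samples
    out = np.empty(n_windows * n)
    prev_last: float | None = None
    limit = config.stitch_limit
    # The per-sample RMS effect of the spectrum jitter is
    # jitter * sqrt(2 / (3 N)); beyond a few times that no redraw can close
    # the junction gap, so skip straight to the offset path.
    slack = 5.0 * config.spectrum_jitter * np.sqrt(2.0 / (3.0 * config.window_samples))
    taper = (n - 1 - np.arange(n)) / (n - 1)  # 1 at first sample, 0 at last
    for i in range(n_windows):
        reference = pink_reference(config, rng)
        spectrum = derive_reference_spectrum(reference, config.sampling_rate)
        window = generate_clean_window(spectrum, config, rng)
        if prev_last is not None and abs(window[0] - prev_last) > limit:
            if abs(reference[0] - prev_last) <= limit + slack:
                for _ in range(_MAX_ATTEMPTS - 1):
                    window = generate_clean_window(spectrum, config, rng)
                    if abs(window[0] - prev_last) <= limit:
                        break
            jump = window[0] - prev_last
            if abs(jump) > limit:
                window = window - taper * (jump - np.clip(jump, -limit, limit))
        out[i * n:(i + 1) * n] = window
        prev_last = window[-1]
    return out


def realized_gains(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-recording propagation gains: base topography jittered ±gain_jitter.

    The reference channel keeps gain exactly 1.0; jittered non-reference
    gains are clipped to [0, 0.98] so the reference row always carries the
    largest-magnitude artifact.
    """
    base = np.array(config.gain_vector, dtype=float)
    jitter = 1.0 + config.gain_jitter * rng.uniform(-1.0, 1.0, size=base.shape)
    gains = np.clip(base * jitter, 0.0, 0.98)
    gains[list(config.channel_names).index(config.reference_channel)] = 1.0
    return gains


def generate_recording(duration: float, config: GeneratorConfig,
                       rng: np.random.Generator | int | None = None,
                       ) -> tuple[Recording, Recording, BlinkTrain]:
    """Paired clean/contaminated multichannel recordings plus the blink train.

    ``duration`` must be a whole number of seconds.  Contamination is strictly
    additive: ``contaminated.data - clean.data`` equals the propagated
    artifact matrix, and the realized per-channel gains are recorded in both
    recordings' metadata.
    """
    if duration <= 0 or abs(duration - round(duration)) > 1e-9:
        raise ValueError("duration must be a positive whole number of seconds")
    n_sec = int(round(duration))
    rng = _rng_of(rng, config)
    fs = config.sampling_rate
    n_samples = n_sec * config.window_samples

    gains = realized_gains(config, rng)
    clean_data = np.empty((len(config.channel_names), n_samples))
    for c in range(len(config.channel_names)):
        clean_data[c] = _channel_clean_signal(n_sec, config, rng)
    train = sample_blink_train(float(n_sec), config, rng)
    blink = render_blink_signal(train, n_samples, fs)
    artifact = propagate_blinks(blink, gains)
    contaminated_data = clean_data + artifact

    meta = {
        "generator_config": config.to_dict(),
        "realized_gains": {name: float(g) for name, g in
                           zip(config.channel_names, gains)},
        "blink_events": [list(e) for e in train.events],
        "synthetic": True,
    }
    names = list(config.channel_names)
    clean = Recording(clean_data, fs, names, dict(meta, kind="clean"))
    contaminated = Recording(contaminated_data, fs, names,
                             dict(meta, kind="contaminated"))
    return clean, contaminated, train


def train_val_split(n: int, train_fraction: float = 0.8,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled train/validation split of ``range(n)`` (80/20 by default)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    perm = rng.permutation(n) if rng is not None else np.arange(n)
    n_train = int(round(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def generate_dataset(n_windows: int = 70_000,
                     config: GeneratorConfig | None = None,
                     rng: np.random.Generator | int | None = None,
                     recording_duration: float = 60.0,
                     train_fraction: float = 0.8) -> PairedWindowDataset:
    """Paired (reference, contaminated) -> clean training examples.

    Recordings of ``recording_duration`` seconds are generated one after
    another and sliced into aligned 1-s windows; each window of every
    non-reference channel becomes one example, so the examples cycle over all
    15 non-reference electrodes.  A seeded shuffle assigns an 80/20
    train/validation split.
    """
    if n_windows < 0:
        raise ValueError("n_windows must be non-negative")
    config = config or GeneratorConfig()
    rng = _rng_of(rng, config)
    n = config.window_samples
    ref = config.reference_channel
    non_ref = [c for c in config.channel_names if c != ref]

    inputs = np.empty((n_windows, n, 2))
    targets = np.empty((n_windows, n))
    labels: list[str] = []
    gains_per_example = np.empty(n_windows)
    recording_seeds: list[int] = []
    filled = 0
    while filled < n_windows:
        rec_seed = int(rng.integers(2**31))
        recording_seeds.append(rec_seed)
        clean, cont, _ = generate_recording(recording_duration, config,
                                            np.random.default_rng(rec_seed))
        gmap = cont.meta["realized_gains"]
        ref_sig = cont.channel(ref)
        windows_in_rec = cont.n_samples // n
        for w in range(windows_in_rec):
            sl = slice(w * n, (w + 1) * n)
            for ch in non_ref:
                if filled >= n_windows:
                    break
                inputs[filled, :, 0] = ref_sig[sl]
                inputs[filled, :, 1] = cont.channel(ch)[sl]
                targets[filled] = clean.channel(ch)[sl]
                labels.append(ch)
                gains_per_example[filled] = gmap[ch]
                filled += 1
            if filled >= n_windows:
                break

    train_idx, val_idx = train_val_split(n_windows, train_fraction, rng)
    meta = {
        "generator_config": config.to_dict(),
        "recording_seeds": recording_seeds,
        "recording_duration": recording_duration,
        "example_gains": gains_per_example,
        "train_fraction": train_fraction,
    }
    return PairedWindowDataset(inputs=inputs, targets=targets,
                               channel_labels=labels,
                               train_indices=train_idx, val_indices=val_idx,
                               meta=meta)
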