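"""The five denoising-quality statistics and method comparison tables.

For every channel and method the suite reports:

* ``C_kk``   — Pearson correlation between the cleaned and the true clean
  signal on electrode k (higher is better);
* ``C_Fp1``  — Pearson correlation between the cleaned signal and the blink
  reference (closer to zero is better);
* ``MAPE``   — mean absolute percentage error (1/n)·Σ|yᵢ−ŷᵢ|/|yᵢ|, reported
  as a raw ratio;
* ``RMSE``   — root mean squared error in μV;
* ``Skewness`` — third standardized moment of the cleaned signal (a blink's
  one-sided deflection pushes it away from zero).

Statistics are computed per 1-s window and averaged across windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sstats

from blinkclean.recording import Recording

#: samples with |y| below this bound (μV) are excluded from the MAPE mean
MAPE_GUARD = 1e-3

METRIC_COLUMNS = ["C_kk", "C_Fp1", "MAPE", "RMSE", "Skewness"]


def _as_1d(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    return x


def pearson_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two equal-length signals."""
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant signal")
    return float(sstats.pearsonr(a, b).statistic)


def mape(y: np.ndarray, yhat: np.ndarray, guard: float = MAPE_GUARD) -> float:
    """Mean absolute percentage error (raw ratio, not ×100).

    Samples whose reference magnitude |yᵢ| falls below ``guard`` μV are
    excluded from the mean to keep the ratio finite; if every sample is
    excluded the input is degenerate and an error is raised.
    """
    y, yhat = _as_1d(y, "y"), _as_1d(yhat, "yhat")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    keep = np.abs(y) >= guard
    if not np.any(keep):
        raise ValueError("all samples below the MAPE denominator guard; "
                         "reference signal is (near-)zero")
    return float(np.mean(np.abs(y[keep] - yhat[keep]) / np.abs(y[keep])))


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error in μV."""
    y, yhat = _as_1d(y, "y"), _as_1d(yhat, "yhat")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def skewness(x: np.ndarray) -> float:
    """Moment-based skewness g1 = m3 / m2^1.5 (bias-uncorrected)."""
    x = _as_1d(x, "x")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for skewness")
    if np.ptp(x) == 0:
        raise ValueError("skewness undefined for a constant signal")
    return float(sstats.skew(x, bias=True))


def amplitude_spectrum(signal: np.ndarray, sampling_rate: float,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum (μV per bin) of a real signal."""
    signal = _as_1d(signal, "signal")
    n = signal.shape[0]
    if n == 0:
        raise ValueError("signal is empty")
    coeff = np.fft.rfft(signal)
    amplitudes = np.abs(coeff) / n
    amplitudes[1:] *= 2.0
    if n % 2 == 0:
        amplitudes[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return freqs, amplitudes


@dataclass
class MetricReport:
    """Per-channel-per-method statistics plus cross-channel means.

    ``table`` has one row per (channel, method) with the five statistics;
    ``method_means`` holds the arithmetic mean of each statistic across
    channels, per method.  ``descriptive`` (optional) reports standard
    deviation and peak-to-peak per channel for the raw and cleaned signals.
    """

    table: pd.DataFrame
    method_means: pd.DataFrame
    descriptive: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        parts = ["Denoising quality report",
                 "=" * 60,
                 self.table.to_string(index=False, float_format="%.4f"),
                 "-" * 60,
                 "cross-channel means:",
                 self.method_means.to_string(index=False, float_format="%.4f")]
        if self.descriptive is not None:
            parts += ["-" * 60, "descriptive statistics (μV):",
                      self.descriptive.to_string(index=False,
                                                 float_format="%.2f")]
        return "\n".join(parts)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _windowed(fn, *signals: np.ndarray, window: int) -> float:
    """Average a statistic over consecutive equal-length windows.

    Windows on which the statistic is undefined (constant input, fully
    guarded MAPE denominator) are skipped.
    """
    n = signals[0].shape[0]
    n_win = max(n // window, 1)
    values = []
    for w in range(n_win):
        sl = slice(w * window, min((w + 1) * window, n))
        try:
            values.append(fn(*(s[sl] for s in signals)))
        except ValueError:
            continue
    if not values:
        raise ValueError("statistic undefined on every window")
    return float(np.mean(values))


def evaluate_method(clean: Recording, cleaned: Recording,
                    reference_signal: np.ndarray,
                    method: str = "method") -> pd.DataFrame:
    """Five statistics per channel for one cleaning method.

    ``C_kk`` and errors compare the cleaned recording against the known
    clean one; ``C_Fp1`` correlates each cleaned channel with the supplied
    reference signal.  Statistics are computed per 1-s window and averaged.
    """
    if clean.data.shape != cleaned.data.shape:
        raise ValueError(f"recordings misaligned: {clean.data.shape} vs "
                         f"{cleaned.data.shape}")
    if list(clean.channel_names) != list(cleaned.channel_names):
        raise ValueError("channel names differ between recordings")
    reference_signal = _as_1d(reference_signal, "reference_signal")
    if reference_signal.shape[0] != clean.n_samples:
        raise ValueError("reference signal is not aligned with the recordings")
    window = round(clean.sampling_rate)
    rows = []
    for idx, ch in enumerate(clean.channel_names):
        y, yhat = clean.data[idx], cleaned.data[idx]
        rows.append({
            "channel": ch,
            "method": method,
            "C_kk": _windowed(pearson_corr, yhat, y, window=window),
            "C_Fp1": _windowed(pearson_corr, yhat, reference_signal,
                               window=window),
            "MAPE": _windowed(mape, y, yhat, window=window),
            "RMSE": _windowed(rmse, y, yhat, window=window),
            "Skewness": _windowed(lambda s: skewness(s), yhat, window=window),
        })
    return pd.DataFrame(rows, columns=["channel", "method"] + METRIC_COLUMNS)


def compare_methods(clean: Recording, contaminated: Recording,
                    cleaned: Mapping[str, Recording],
                    reference_channel: str = "Fp1") -> MetricReport:
    """Full comparison report across methods.

    ``cleaned`` maps method name -> cleaned recording.  The report contains
    the per-channel statistics for every method, cross-channel means, and a
    descriptive table (standard deviation, peak-to-peak) for the raw
    contaminated signal and each cleaned signal.
    """
    if not cleaned:
        raise ValueError("no methods to compare")
    reference = contaminated.channel(reference_channel)
    tables = [evaluate_method(clean, rec, reference, method=name)
              for name, rec in cleaned.items()]
    table = pd.concat(tables, ignore_index=True)
    method_means = (table.groupby("method", sort=False)[METRIC_COLUMNS]
                    .mean().reset_index())

    desc_rows = []
    signals = {"raw": contaminated, **cleaned}
    for name, rec in signals.items():
        for idx, ch in enumerate(rec.channel_names):
            x = rec.data[idx]
            desc_rows.append({"method": name, "channel": ch,
                              "std": float(np.std(x)),
                              "peak_to_peak": float(np.ptp(x))})
    descriptive = pd.DataFrame(desc_rows,
                               columns=["method", "channel", "std",
                                        "peak_to_peak"])
    provenance = {
        "n_samples": int(clean.n_samples),
        "n_windows": int(clean.n_samples // round(clean.sampling_rate)),
        "reference_channel": reference_channel,
        "methods": list(cleaned.keys()),
        "clean_meta": dict(clean.meta),
    }
    return MetricReport(table=table, method_means=method_means,
                        descriptive=descriptive, provenance=provenance)
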