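"""Minimal European Data Format (EDF) reader and writer.

EDF stores multichannel signals as 16-bit integers in fixed-duration data
records, preceded by an ASCII header.  The writer uses 1-s records with the
physical range taken from the data, so the quantization error per sample is
bounded by (physical range) / 2¹⁶.  Recordings whose length is not a whole
number of records are zero-padded to the record boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from blinkclean.recording import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with 1-s data records."""
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))  # samples per record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    ns = recording.n_channels
    n_records = -(-recording.n_samples // spr)  # ceil
    padded = np.zeros((ns, n_records * spr))
    padded[:, :recording.n_samples] = recording.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + ns)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(ns), 4),
    ])
    labels = b"".join(_field(c, 16) for c in recording.channel_names)
    transducer = _field("", 80) * ns
    dimension = b"".join(_field("uV", 8) for _ in range(ns))
    phys_min = b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmin)
    phys_max = b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmax)
    dig_min = _field(str(_DIG_MIN), 8) * ns
    dig_max = _field(str(_DIG_MAX), 8) * ns
    prefilter = _field("", 80) * ns
    spr_field = _field(str(spr), 8) * ns
    reserved = _field("", 32) * ns

    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dimension + phys_min
                 + phys_max + dig_min + dig_max + prefilter + spr_field
                 + reserved)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read a 16-bit EDF file written by :func:`write_edf` (or compatible)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: too short to be an EDF file")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        record_duration = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed EDF header: {exc}") from exc
    off = 256

    def sig_fields(width: int) -> list[str]:
        nonlocal off
        out = [raw[off + i * width: off + (i + 1) * width].decode("ascii").strip()
               for i in range(ns)]
        off += ns * width
        return out

    labels = sig_fields(16)
    sig_fields(80)   # transducer
    sig_fields(8)    # physical dimension
    pmin = np.array([float(v) for v in sig_fields(8)])
    pmax = np.array([float(v) for v in sig_fields(8)])
    dmin = np.array([float(v) for v in sig_fields(8)])
    dmax = np.array([float(v) for v in sig_fields(8)])
    sig_fields(80)   # prefiltering
    spr = [int(v) for v in sig_fields(8)]
    sig_fields(32)   # reserved

    if len(set(spr)) != 1:
        raise ValueError(f"{path}: per-channel sampling rates are unsupported")
    spr0 = spr[0]
    fs = spr0 / record_duration
    data = np.empty((ns, n_records * spr0))
    body = np.frombuffer(raw[off:], dtype="<i2")
    expected = n_records * ns * spr0
    if body.shape[0] < expected:
        raise ValueError(f"{path}: truncated EDF data section")
    body = body[:expected].reshape(n_records, ns, spr0)
    digital = np.concatenate([body[r] for r in range(n_records)], axis=1)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return Recording(data, fs, labels, {"source": str(path), "format": "edf"})
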