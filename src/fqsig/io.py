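"""Reading and writing signals as CSV and WAV files."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .signal import Signal

__all__ = ["read_signal", "write_signal_csv", "write_signal_wav"]


def _read_csv(path: Path, fs: float | None) -> Signal:
    df = pd.read_csv(path)
    if df.shape[1] == 1:
        if fs is None:
            raise ValueError("value-only CSV needs an explicit sampling rate (fs)")
        values = df.iloc[:, 0].to_numpy(dtype=float)
    elif df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        values = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time column must be strictly increasing")
        med = float(np.median(dt))
        if np.max(np.abs(dt - med)) > 0.01 * med:
            warnings.warn("sampling jitter above 1% of the median interval")
        inferred = 1.0 / med
        if fs is None:
            fs = inferred
    else:
        raise ValueError("empty CSV")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite values in {path}")
    return Signal(values, fs)


def read_signal(path, fmt: str | None = None, fs: float | None = None) -> Signal:
    """Load a Signal from CSV ([time,]value columns) or WAV.

    The sampling rate comes from the WAV header, the CSV time column
    (median interval; jitter above 1% warns) or the ``fs`` argument, in
    that order of preference; value-only CSVs require ``fs``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _read_csv(path, fs)
    if fmt == "wav":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]  # first channel
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return Signal(np.asarray(data, dtype=float), float(fs or rate))
    raise ValueError(f"unsupported format {fmt!r} (expected csv or wav)")


def write_signal_csv(x: Signal, path, header: tuple = ("t_s", "value")) -> None:
    """Two-column CSV with a header naming the units."""
    pd.DataFrame({header[0]: x.times, header[1]: x.samples}).to_csv(path, index=False)


def write_signal_wav(x: Signal, path) -> None:
    """Float32 PCM WAV."""
    wavfile.write(path, int(round(x.fs)), x.samples.astype(np.float32))
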