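"""Core signal container shared by every module.

A :class:`Signal` is nothing more than a finite real sample vector together
with its sampling rate.  All transforms, analytic-signal constructions and
filter banks in this package operate on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array_like of float, shape (N,)
        The sample values, N >= 2, all finite.
    fs : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    fs: float = 1.0

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {x.shape}")
        if x.size < 2:
            raise ValueError(f"need at least 2 samples, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples contain non-finite values")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"fs must be a positive finite number, got {self.fs}")
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times n/fs in seconds."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Signal":
        """New Signal with the same sampling rate."""
        return Signal(np.asarray(samples, dtype=float), self.fs)


def as_samples(x) -> np.ndarray:
    """Accept a Signal or a bare array and return the sample vector."""
    if isinstance(x, Signal):
        return x.samples
    return np.asarray(x, dtype=float)
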