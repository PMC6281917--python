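"""Gabor analytic signal and instantaneous amplitude/phase/frequency.

The Gabor analytic signal (GAS) of a real signal x[n] is the complex signal
whose discrete Fourier spectrum keeps only the non-negative-frequency bins:
DC and (for even N) Nyquist unscaled, interior positive bins doubled.  Its
real part is x, its imaginary part the (periodic) Hilbert transform of x,
and the two parts are orthogonal.

Instantaneous descriptors follow the standard polar route: amplitude is the
modulus, phase the two-argument arctangent in (-pi, pi], and frequency a
finite difference of the phase.  Because atan2 phase is only known modulo
2*pi - and, through the multivalued arctangent, increments are physically
meaningful modulo pi - the differencing is done as follows:

1. one-sample increments d[n] = ip[n+1] - ip[n] are wrapped into [-pi, pi],
   preserving the sign of an increment of exactly +-pi (a genuine
   half-turn per sample can legitimately be approached from either side,
   and collapsing the two onto one endpoint biases quantized phases);
2. each wrapped increment is corrected for positivity: d if d >= 0 else
   d + pi, so every increment lies in [0, pi];
3. FFD takes the corrected increment ahead of n, BFD the one behind, CFD
   the average of the two; endpoints fall back to the one-sided value.

The resulting omega[n] is in [0, pi] rad/sample, i.e. [0, fs/2] Hz, for
monocomponent and multicomponent signals alike.  This recipe yields the
exactly flat omega = pi/2 (fs/4 Hz) instantaneous frequency of a unit
sample sequence analysed with the type-2 FSAS, where the phase is
quantized to +-pi/2 and plain forward/backward differences chatter
between 0 and pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quadrature import AnalyticSignal
from .signal import Signal, as_samples

__all__ = [
    "IF_METHODS",
    "InstantaneousDescriptors",
    "gas",
    "polar",
    "instantaneous_frequency",
    "descriptors",
]

IF_METHODS = ("ffd", "bfd", "cfd")


@dataclass(frozen=True)
class InstantaneousDescriptors:
    """Per-sample instantaneous amplitude, phase and frequency."""

    ia: np.ndarray        # amplitude, >= 0
    ip: np.ndarray        # phase in (-pi, pi]
    omega: np.ndarray     # corrected IF in [0, pi] rad/sample
    f_hz: np.ndarray      # omega * fs / (2 pi), in [0, fs/2]
    fs: float


def gas(x) -> AnalyticSignal:
    """Gabor analytic signal via the one-sided DFT spectrum.

    Works for even and odd N; the strictly-negative-frequency bins of the
    result are zero and the real part equals the input to ~1e-15.
    """
    fs = x.fs if isinstance(x, Signal) else 1.0
    xv = as_samples(x)
    N = xv.size
    X = np.fft.fft(xv)
    Z = np.zeros(N, dtype=complex)
    Z[0] = X[0]
    if N % 2 == 0:
        Z[1 : N // 2] = 2.0 * X[1 : N // 2]
        Z[N // 2] = X[N // 2]
    else:
        Z[1 : (N + 1) // 2] = 2.0 * X[1 : (N + 1) // 2]
    values = np.fft.ifft(Z)
    return AnalyticSignal(values, fs, "GAS", "real")


def polar(z: AnalyticSignal) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and phase of an analytic signal.

    ia = |z|; ip = atan2(imag, real) in (-pi, pi], with atan2(0, 0) = 0 at
    samples where the amplitude vanishes exactly.
    """
    v = z.values if isinstance(z, AnalyticSignal) else np.asarray(z, dtype=complex)
    ia = np.abs(v)
    ip = np.arctan2(v.imag, v.real)
    return ia, ip


def _wrap_increments(d: np.ndarray) -> np.ndarray:
    """Wrap raw phase increments into [-pi, pi], keeping the sign of +-pi."""
    return np.where(d > np.pi, d - 2 * np.pi, np.where(d < -np.pi, d + 2 * np.pi, d))


def instantaneous_frequency(
    ip: np.ndarray,
    method: str = "cfd",
    fs: float = 1.0,
    zero_amplitude_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous frequency from a wrapped phase vector.

    Parameters
    ----------
    ip : array of phase values in (-pi, pi]
    method : 'ffd', 'bfd' or 'cfd' (default)
    fs : sampling rate in Hz
    zero_amplitude_mask : optional bool array
        Samples where the amplitude is exactly zero carry no phase
        information; their omega is linearly interpolated from neighbours.

    Returns
    -------
    (omega, f_hz) : omega in [0, pi] rad/sample, f_hz = omega * fs / (2 pi)
    """
    ip = np.asarray(ip, dtype=float)
    N = ip.size
    if method not in IF_METHODS:
        raise ValueError(f"method must be one of {IF_METHODS}, got {method!r}")
    if method == "cfd" and N < 3:
        raise ValueError("CFD needs at least 3 samples")
    if N < 2:
        raise ValueError("need at least 2 phase samples")

    d = _wrap_increments(np.diff(ip))
    d = np.where(d >= 0, d, d + np.pi)  # positivity correction, per increment

    omega = np.empty(N)
    if method == "ffd":
        omega[:-1] = d
        omega[-1] = d[-1]
    elif method == "bfd":
        omega[1:] = d
        omega[0] = d[0]
    else:  # cfd
        omega[1:-1] = 0.5 * (d[:-1] + d[1:])
        omega[0] = d[0]
        omega[-1] = d[-1]

    if zero_amplitude_mask is not None:
        zero = np.asarray(zero_amplitude_mask, dtype=bool)
        if zero.any() and not zero.all():
            idx = np.arange(N)
            omega[zero] = np.interp(idx[zero], idx[~zero], omega[~zero])
        elif zero.all():
            omega[:] = 0.0

    f_hz = omega * fs / (2 * np.pi)
    return omega, f_hz


def descriptors(z: AnalyticSignal, method: str = "cfd") -> InstantaneousDescriptors:
    """IA/IP/IF of an analytic signal in one call."""
    ia, ip = polar(z)
    omega, f_hz = instantaneous_frequency(
        ip, method=method, fs=z.fs, zero_amplitude_mask=(ia == 0)
    )
    return InstantaneousDescriptors(ia=ia, ip=ip, omega=omega, f_hz=f_hz, fs=z.fs)
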