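"""Fourier decomposition method (FDM): zero-phase filter banks over DCT or
DFT coefficients.

A signal is analysed once (type-2 DCT by default, optionally the one-sided
DFT), its frequency bins k = 1..K_max are partitioned into M contiguous
bands, and each band is synthesized back to the time domain.  Because the
masks are real and non-negative, filtering introduces no group delay
("zero-phase"): maxima and minima of each component stay where they are in
the original waveform.  The band components - Fourier intrinsic band
functions (FIBFs) - are exactly orthogonal and sum, together with the mean
term a0, back to the input:

    x[n] = a0 + sum_i x_i[n].

Each FIBF carries an analytic companion: either its Fourier-Singh analytic
signal (band-limited type-2 FSAS synthesis, one-sided by construction) or
its Gabor analytic signal.  The analytic components feed the
time-frequency-energy machinery in :mod:`fqsig.tfe`.

Frequency/bin conventions
-------------------------
For the DCT basis, bin k covers frequency f_k = k * fs / (2N) Hz and
K_max = N - 1; for the DFT basis, f_k = k * fs / N and K_max = floor(N/2).
Hz -> bin conversion rounds to the nearest bin with ties toward the lower
bin.  Bin k = 0 is never part of a band; it is carried separately as the
mean term a0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as _sfft

from .analytic import gas
from .quadrature import AnalyticSignal
from .signal import Signal

__all__ = [
    "BandPlan",
    "FIBFSet",
    "select_bands",
    "zero_phase_mask",
    "decompose",
    "reconstruct",
    "remove_bands",
    "extract_trend",
    "window_reconstruct",
]


def _k_max(N: int, basis: str) -> int:
    return N - 1 if basis == "dct2" else N // 2


def bin_frequency(k, N: int, fs: float, basis: str = "dct2"):
    """Centre frequency of bin k in Hz."""
    k = np.asarray(k, dtype=float)
    return k * fs / (2 * N) if basis == "dct2" else k * fs / N


def hz_to_bin(f: float, N: int, fs: float, basis: str = "dct2") -> int:
    """Nearest bin to a frequency in Hz; ties round toward the lower bin."""
    x = f * 2 * N / fs if basis == "dct2" else f * N / fs
    return int(np.ceil(x - 0.5))


@dataclass(frozen=True)
class BandPlan:
    """Contiguous, non-overlapping bin bands covering k = 1..K_max.

    ``bands`` are inclusive (k_lo, k_hi) pairs ordered low to high;
    ``edges_hz``, when present, records the nominal band edges in Hz
    (length M + 1, starting at 0) that generated the plan.
    """

    bands: tuple
    strategy: str
    N: int
    fs: float
    basis: str = "dct2"
    edges_hz: tuple | None = None

    def __post_init__(self) -> None:
        if self.basis not in ("dct2", "dft"):
            raise ValueError(f"basis must be 'dct2' or 'dft', got {self.basis!r}")
        kmax = _k_max(self.N, self.basis)
        bands = tuple((int(lo), int(hi)) for lo, hi in self.bands)
        if not bands:
            raise ValueError("band plan must contain at least one band")
        if bands[0][0] != 1 or bands[-1][1] != kmax:
            raise ValueError(
                f"bands must cover k = 1..{kmax}, got {bands[0][0]}..{bands[-1][1]}"
            )
        prev_hi = 0
        for lo, hi in bands:
            if lo != prev_hi + 1:
                raise ValueError("bands must be contiguous and non-overlapping")
            if lo > hi:
                raise ValueError(f"empty band ({lo}, {hi})")
            prev_hi = hi
        object.__setattr__(self, "bands", bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_edges_hz(self) -> list:
        """Nominal Hz edges if recorded, else the bin-derived edges."""
        if self.edges_hz is not None:
            return list(self.edges_hz)
        edges = [0.0]
        for _, hi in self.bands:
            edges.append(float(bin_frequency(hi, self.N, self.fs, self.basis)))
        return edges


@dataclass(frozen=True)
class FIBFSet:
    """Mean term plus per-band analytic components of one decomposition."""

    a0: float
    components: tuple  # of AnalyticSignal
    band_plan: BandPlan
    analytic_kind: str  # 'FSAS' or 'GAS'

    @property
    def fibfs(self) -> list:
        """The real band components x_i[n]."""
        return [c.signal for c in self.components]


# ---------------------------------------------------------------------------
# band selection
# ---------------------------------------------------------------------------

def _equal_bands(kmax: int, M: int):
    base, extra = divmod(kmax, M)
    bands, lo = [], 1
    for i in range(M):
        width = base + (1 if i < extra else 0)
        bands.append((lo, lo + width - 1))
        lo += width
    return bands


def _dyadic_edges_hz(fs: float, M: int):
    """[0, fs/2^M, ..., fs/4, fs/2]: top band is [fs/4, fs/2), each band
    below halves, and the lowest band spans (0, fs/2^M]."""
    return [0.0] + [fs / 2**j for j in range(M, 0, -1)]


def select_bands(
    N: int,
    fs: float,
    M: int,
    strategy: str = "equal",
    basis: str = "dct2",
    x=None,
) -> BandPlan:
    """Partition bins k = 1..K_max into M bands.

    strategy 'equal'       : (near-)equal index widths;
             'dyadic'      : octave bands halving downward from [fs/4, fs/2);
             'equal_energy': boundaries at cumulative-energy quantiles of
                             the signal's own spectrum (requires ``x``).
    """
    kmax = _k_max(N, basis)
    if not 1 <= M <= kmax:
        raise ValueError(f"M must be in 1..{kmax} for N={N} ({basis}), got {M}")

    if strategy == "equal":
        return BandPlan(tuple(_equal_bands(kmax, M)), "equal", N, fs, basis)

    if strategy == "dyadic":
        edges_hz = _dyadic_edges_hz(fs, M)
        edges_k = [hz_to_bin(f, N, fs, basis) for f in edges_hz]
        edges_k[0], edges_k[-1] = 0, kmax
        bands, lo = [], 1
        for i in range(1, M + 1):
            hi = edges_k[i]
            if hi < lo:
                raise ValueError(
                    f"dyadic band {i - 1} is empty at N={N}, fs={fs}: "
                    "increase the record length or reduce M"
                )
            bands.append((lo, hi))
            lo = hi + 1
        return BandPlan(tuple(bands), "dyadic", N, fs, basis, tuple(edges_hz))

    if strategy == "equal_energy":
        if x is None:
            raise ValueError("equal_energy band selection requires the signal x")
        xv = x.samples if isinstance(x, Signal) else np.asarray(x, dtype=float)
        if xv.size != N:
            raise ValueError(f"signal length {xv.size} != N={N}")
        if basis == "dct2":
            X = _sfft.dct(xv, type=2, norm="ortho")
            energy = X[1 : kmax + 1] ** 2
        else:
            X = np.fft.fft(xv) / N
            energy = np.abs(X[1 : kmax + 1]) ** 2
        total = energy.sum()
        if total == 0:
            return BandPlan(tuple(_equal_bands(kmax, M)), "equal_energy", N, fs, basis)
        csum = np.cumsum(energy)
        bands, lo = [], 1
        for i in range(1, M):
            target = i * total / M
            # first bin index (1-based) at which the running sum reaches the
            # quantile belongs to the earlier band
            hi = int(np.searchsorted(csum, target - 1e-12 * total) + 1)
            hi = min(max(hi, lo), kmax - (M - i))  # keep room for later bands
            bands.append((lo, hi))
            lo = hi + 1
        bands.append((lo, kmax))
        return BandPlan(tuple(bands), "equal_energy", N, fs, basis)

    raise ValueError(f"unknown strategy {strategy!r}")


def zero_phase_mask(band, N: int, shape: str = "binary", sigma_bins: float | None = None) -> np.ndarray:
    """Real non-negative frequency mask for one band of an N-bin spectrum.

    'binary' is 1 on k_lo..k_hi inclusive and 0 elsewhere; 'gaussian' is a
    Gaussian bump centred on the band (default sigma: a quarter of the band
    width) - any real non-negative mask keeps the filtering zero-phase.
    """
    k_lo, k_hi = int(band[0]), int(band[1])
    if not (0 <= k_lo <= k_hi <= N - 1):
        raise ValueError(f"band ({k_lo}, {k_hi}) outside 0..{N - 1}")
    k = np.arange(N)
    if shape == "binary":
        return ((k >= k_lo) & (k <= k_hi)).astype(float)
    if shape == "gaussian":
        centre = 0.5 * (k_lo + k_hi)
        if sigma_bins is None:
            sigma_bins = max((k_hi - k_lo + 1) / 4.0, 0.5)
        return np.exp(-0.5 * ((k - centre) / sigma_bins) ** 2)
    raise ValueError(f"shape must be 'binary' or 'gaussian', got {shape!r}")


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _band_analytic_dct(X: np.ndarray, lo: int, hi: int, N: int) -> np.ndarray:
    """z_i[n] = sqrt(2/N) sum_{k=lo}^{hi} X[k] exp(j pi k (2n+1) / 2N),
    via a zero-padded inverse FFT (k >= 1, so no sigma factor)."""
    u = np.zeros(2 * N, dtype=complex)
    ks = np.arange(lo, hi + 1)
    u[lo : hi + 1] = np.sqrt(2.0 / N) * X[lo : hi + 1] * np.exp(1j * np.pi * ks / (2 * N))
    return 2 * N * np.fft.ifft(u)[:N]


def decompose(x: Signal, plan: BandPlan, analytic_kind: str = "FSAS") -> FIBFSet:
    """Split a signal into FIBFs with analytic companions.

    analytic_kind 'FSAS': the companion of each band is its band-limited
    type-2 FSAS synthesis (imaginary part = masked sine synthesis);
    'GAS': the Gabor analytic signal of the real band component.
    For basis 'dft' both kinds coincide with the one-sided per-band DFT
    synthesis and 'GAS' semantics apply.
    """
    if analytic_kind not in ("FSAS", "GAS"):
        raise ValueError(f"analytic_kind must be 'FSAS' or 'GAS', got {analytic_kind!r}")
    xv = x.samples
    N = xv.size
    if plan.N != N:
        raise ValueError(f"plan is for N={plan.N}, signal has N={N}")

    components = []
    if plan.basis == "dct2":
        X = _sfft.dct(xv, type=2, norm="ortho")
        a0 = float(X[0] / np.sqrt(N))  # = mean(x)
        for lo, hi in plan.bands:
            if analytic_kind == "FSAS":
                z = _band_analytic_dct(X, lo, hi, N)
                comp = AnalyticSignal(z, x.fs, "FSAS_cosine_2", "real")
            else:
                Xm = np.zeros_like(X)
                Xm[lo : hi + 1] = X[lo : hi + 1]
                xi = _sfft.idct(Xm, type=2, norm="ortho")
                comp = gas(Signal(xi, x.fs))
            components.append(comp)
    else:
        X = np.fft.fft(xv) / N
        a0 = float(X[0].real)
        for lo, hi in plan.bands:
            z = np.fft.ifft(_one_sided_weights(X, lo, hi, N)) * N
            components.append(AnalyticSignal(z, x.fs, "GAS", "real"))

    return FIBFSet(a0=a0, components=tuple(components), band_plan=plan, analytic_kind=analytic_kind)


def _one_sided_weights(X: np.ndarray, lo: int, hi: int, N: int) -> np.ndarray:
    w = np.zeros(N, dtype=complex)
    w[lo : hi + 1] = 2.0 * X[lo : hi + 1]
    if N % 2 == 0 and hi >= N // 2:
        w[N // 2] = X[N // 2]
    return w


def reconstruct(f: FIBFSet, include=None, with_mean: bool = True) -> Signal:
    """Sum the real parts of selected components (plus a0 when requested).

    ``include`` is an iterable of band indices (0-based); None means all.
    """
    N = f.band_plan.N
    out = np.full(N, f.a0 if with_mean else 0.0, dtype=float)
    idx = range(len(f.components)) if include is None else include
    for i in idx:
        out += f.components[i].signal
    return Signal(out, f.band_plan.fs)


# ---------------------------------------------------------------------------
# application operators
# ---------------------------------------------------------------------------

def _merge_stop_specs(stop_specs, fs):
    """Sort stop bands, merge overlaps (with a warning), validate ranges."""
    specs = sorted((float(lo), float(hi)) for lo, hi in stop_specs)
    for lo, hi in specs:
        if not (0 <= lo < hi <= fs / 2):
            raise ValueError(f"stop band ({lo}, {hi}) outside 0..fs/2 = {fs / 2}")
    merged = []
    for lo, hi in specs:
        if merged and lo <= merged[-1][1]:
            warnings.warn(f"overlapping stop bands merged: {merged[-1]} and ({lo}, {hi})")
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def remove_bands(x: Signal, stop_specs, basis: str = "dct2"):
    """Zero-phase removal of frequency bands given in Hz.

    Each (f_lo, f_hi) stop band is aligned to the nearest bins, those
    coefficients are synthesized separately as the removed components, and
    the cleaned signal is the input minus their sum (so clean plus removed
    reproduce the input exactly).  A stop band reaching down to 0 Hz also
    removes the mean term.

    Returns ``(clean, removed)`` with one removed Signal per stop band.
    """
    xv = x.samples
    N = xv.size
    merged = _merge_stop_specs(stop_specs, x.fs)
    kmax = _k_max(N, basis)

    if basis == "dct2":
        X = _sfft.dct(xv, type=2, norm="ortho")
    else:
        X = np.fft.fft(xv) / N

    removed = []
    for f_lo, f_hi in merged:
        k_lo = max(hz_to_bin(f_lo, N, x.fs, basis), 0)
        k_hi = min(hz_to_bin(f_hi, N, x.fs, basis), kmax)
        if f_lo > 0:
            k_lo = max(k_lo, 1)
        if basis == "dct2":
            Xm = np.zeros_like(X)
            Xm[k_lo : k_hi + 1] = X[k_lo : k_hi + 1]
            w = _sfft.idct(Xm, type=2, norm="ortho")
        else:
            wgt = _one_sided_weights(X, max(k_lo, 1), k_hi, N)
            if k_lo == 0:
                wgt[0] = X[0]
            w = (np.fft.ifft(wgt) * N).real
        removed.append(Signal(w, x.fs))

    clean = xv - sum((r.samples for r in removed), np.zeros(N))
    return Signal(clean, x.fs), removed


def extract_trend(x: Signal, timescale: float, basis: str = "dct2"):
    """Split a signal into its trend at a timescale and the rest.

    The trend keeps the mean plus every bin with frequency <= 1/timescale
    (variations of period ``timescale`` or longer); the variability is the
    exact remainder x - trend.  A timescale longer than the record leaves
    only the mean in the trend.
    """
    if timescale <= 2.0 / x.fs:
        raise ValueError(
            f"timescale must exceed two sampling intervals ({2.0 / x.fs}), got {timescale}"
        )
    xv = x.samples
    N = xv.size
    f_cut = 1.0 / timescale
    kmax = _k_max(N, basis)
    k_cut = min(hz_to_bin(f_cut, N, x.fs, basis), kmax)

    if basis == "dct2":
        X = _sfft.dct(xv, type=2, norm="ortho")
        Xm = np.zeros_like(X)
        Xm[: k_cut + 1] = X[: k_cut + 1]
        trend = _sfft.idct(Xm, type=2, norm="ortho")
    else:
        X = np.fft.fft(xv)
        Xm = np.zeros_like(X)
        Xm[: k_cut + 1] = X[: k_cut + 1]
        if k_cut >= 1:
            Xm[N - k_cut :] = X[N - k_cut :]  # conjugate bins keep it real
        trend = np.fft.ifft(Xm).real

    return Signal(trend, x.fs), Signal(xv - trend, x.fs)


def window_reconstruct(f: FIBFSet, windows: dict | list, include=None) -> Signal:
    """Reconstruct sum_i w_i[n] * x_i[n] with per-band time-domain weights.

    ``windows`` maps band index -> weight vector (or is a list aligned with
    ``include``); all-ones weights reduce to :func:`reconstruct` without the
    mean term.  Useful for Gaussian-windowed band reconstruction.
    """
    N = f.band_plan.N
    if include is None:
        include = list(range(len(f.components)))
    if not isinstance(windows, dict):
        if len(windows) != len(include):
            raise ValueError("need one window per included band")
        windows = dict(zip(include, windows))
    out = np.zeros(N)
    for i in include:
        w = np.asarray(windows[i], dtype=float)
        if w.shape != (N,):
            raise ValueError(f"window for band {i} has shape {w.shape}, expected ({N},)")
        out += w * f.components[i].signal
    return Signal(out, f.band_plan.fs)
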