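"""Synthetic test signals and SNR metrics.

Everything the rest of the package needs for worked examples and testing is
generated here: unit sample sequences, linear chirps, exact single-bin DCT
tones, multicomponent AM-FM mixtures with stored ground truth, and a
template-based synthetic ECG with baseline-wander / power-line corruption.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import Signal

__all__ = [
    "unit_sample",
    "linear_chirp",
    "dct_tone",
    "AMFMComponent",
    "multicomponent_amfm",
    "synthetic_ecg",
    "CorruptionRecipe",
    "add_blw_pli",
    "snr_input",
    "snr_output",
]


def unit_sample(N: int, n0: int, fs: float = 1.0) -> Signal:
    """Unit sample (delta) sequence: 1 at n0, 0 elsewhere."""
    if not 0 <= n0 < N:
        raise ValueError(f"n0 must be in 0..{N - 1}, got {n0}")
    x = np.zeros(N)
    x[n0] = 1.0
    return Signal(x, fs)


def linear_chirp(fs: float, duration: float, f0: float, f1: float):
    """Linear chirp cos(2 pi (f0 t + (f1-f0)/(2 T) t^2)) over [0, duration).

    Returns ``(signal, f_true)`` where f_true[n] = f0 + (f1-f0) * t/T is the
    ground-truth instantaneous frequency law.
    """
    if not 0 <= f0 < f1 <= fs / 2:
        raise ValueError(f"need 0 <= f0 < f1 <= fs/2, got f0={f0}, f1={f1}, fs={fs}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(int(round(fs * duration))) / fs
    phase = 2 * np.pi * (f0 * t + (f1 - f0) / (2 * duration) * t**2)
    f_true = f0 + (f1 - f0) * t / duration
    return Signal(np.cos(phase), fs), f_true


def dct_tone(N: int, k0: int, amplitude: float = 1.0, fs: float = 1.0) -> Signal:
    """Single-bin DCT-2 tone: amplitude * cos(pi k0 (2n+1) / 2N)."""
    if not 0 <= k0 <= N - 1:
        raise ValueError(f"k0 must be in 0..{N - 1}, got {k0}")
    n = np.arange(N)
    return Signal(amplitude * np.cos(np.pi * k0 * (2 * n + 1) / (2 * N)), fs)


@dataclass(frozen=True)
class AMFMComponent:
    """One AM-FM component: a(t) cos(phi(t)).

    amplitude   : carrier amplitude a0
    f_lo, f_hi  : linear IF sweep from f_lo to f_hi over the record
                  (equal values give a pure tone)
    am_depth    : amplitude modulation depth m in a0 (1 + m cos(2 pi f_am t))
    am_freq     : AM frequency in Hz
    """

    amplitude: float = 1.0
    f_lo: float = 0.0
    f_hi: float = 0.0
    am_depth: float = 0.0
    am_freq: float = 0.0

    def band(self):
        """Spectral support estimate [min, max] Hz incl. AM sidebands."""
        lo = min(self.f_lo, self.f_hi) - self.am_freq
        hi = max(self.f_lo, self.f_hi) + self.am_freq
        return lo, hi


def multicomponent_amfm(components, fs: float, N: int, seed: int | None = None):
    """Sum of AM-FM components with per-component ground truth.

    Returns ``(signal, truths)``; each truth is a dict with keys 'x'
    (component samples), 'ia' and 'f_hz' (instantaneous amplitude and
    frequency laws).  Components whose estimated spectral supports overlap
    raise a ValueError, since band-separated recovery is then ill-posed.
    """
    t = np.arange(N) / fs
    bands = sorted(c.band() for c in components)
    for (alo, ahi), (blo, bhi) in zip(bands, bands[1:]):
        if blo < ahi:
            raise ValueError(
                f"component bands overlap: ({alo}, {ahi}) and ({blo}, {bhi})"
            )
    total = np.zeros(N)
    truths = []
    duration = N / fs
    for c in components:
        ia = c.amplitude * (1.0 + c.am_depth * np.cos(2 * np.pi * c.am_freq * t))
        f_hz = c.f_lo + (c.f_hi - c.f_lo) * t / duration
        phase = 2 * np.pi * np.concatenate(([0.0], np.cumsum(f_hz[:-1] + np.diff(f_hz) / 2))) / fs
        xc = ia * np.cos(phase)
        truths.append({"x": xc, "ia": ia, "f_hz": f_hz})
        total += xc
    return Signal(total, fs), truths


# ---------------------------------------------------------------------------
# synthetic ECG
# ---------------------------------------------------------------------------

#: PQRST template: (offset from R peak in s, amplitude in mV, width in s).
#: Rough textbook morphology; fixed so the generator is reproducible.
ECG_WAVES = (
    ("P", -0.200, 0.15, 0.025),
    ("Q", -0.030, -0.10, 0.010),
    ("R", 0.000, 1.00, 0.012),
    ("S", 0.030, -0.15, 0.010),
    ("T", 0.250, 0.30, 0.045),
)

#: relative standard deviation of the seeded RR-interval jitter
ECG_RR_JITTER = 0.02


def synthetic_ecg(fs: float, duration: float, heart_rate_bpm: float = 72.0, seed: int = 0) -> Signal:
    """Template ECG: Gaussian P-QRS-T bumps repeated with jittered RR intervals.

    Deterministic given ``seed``.  The mean is removed so the clean signal
    carries no DC; its spectral energy sits well above the sub-0.5 Hz
    baseline-wander band (heart rate and QRS harmonics) and away from the
    50/60 Hz power-line band for realistic beat widths.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz for a resolvable QRS, got {fs}")
    rng = np.random.default_rng(seed)
    rr = 60.0 / heart_rate_bpm
    n_beats = int(np.ceil(duration / rr)) + 2
    jitter = rng.normal(0.0, ECG_RR_JITTER * rr, size=n_beats)
    r_times = np.cumsum(np.full(n_beats, rr) + jitter) - rr / 2
    t = np.arange(int(round(fs * duration))) / fs
    x = np.zeros_like(t)
    for r in r_times:
        if r < -0.5 or r > duration + 0.5:
            continue
        for _, off, amp, width in ECG_WAVES:
            x += amp * np.exp(-0.5 * ((t - r - off) / width) ** 2)
    x -= x.mean()
    return Signal(x, fs)


@dataclass(frozen=True)
class CorruptionRecipe:
    """Baseline wander + power-line interference mixture.

    blw_hz below 0.5 Hz; pli_hz normally 50 or 60 Hz; the two components
    carry equal energy and are jointly scaled to hit ``target_snr_db``
    (input SNR of signal vs. noise).  ``blw_walk`` adds a seeded slow
    random-walk drift to the baseline wander.
    """

    blw_hz: float = 0.3
    pli_hz: float = 50.0
    target_snr_db: float = -18.4
    blw_walk: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.blw_hz < 0.5:
            raise ValueError(f"blw_hz must be in (0, 0.5), got {self.blw_hz}")


def add_blw_pli(x: Signal, recipe: CorruptionRecipe):
    """Corrupt a signal with baseline wander and power-line interference.

    Returns ``(noisy, w)`` with noisy = x + w; the noise w is scaled so
    that snr_input(x, w) equals the recipe target to well within 0.01 dB.
    """
    t = x.times
    rng = np.random.default_rng(recipe.seed)
    phi_b, phi_p = rng.uniform(0, 2 * np.pi, size=2)
    blw = np.sin(2 * np.pi * recipe.blw_hz * t + phi_b)
    if recipe.blw_walk:
        walk = np.cumsum(rng.normal(0, 1, t.size))
        walk -= walk.mean()
        # keep the drift slow and comparable in scale to the sinusoid
        blw = blw + walk / max(np.abs(walk).max(), 1e-12)
    pli = np.sin(2 * np.pi * recipe.pli_hz * t + phi_p)

    e_x = float(np.sum(x.samples**2))
    if e_x == 0:
        raise ValueError("cannot set an SNR target for a zero-energy signal")
    e_b, e_p = float(np.sum(blw**2)), float(np.sum(pli**2))
    # equal-energy mixture, then global scale to the SNR target
    w = blw / np.sqrt(e_b) + pli / np.sqrt(e_p)
    e_w = float(np.sum(w**2))
    scale = np.sqrt(e_x / (e_w * 10 ** (recipe.target_snr_db / 10)))
    w = scale * w
    return Signal(x.samples + w, x.fs), Signal(w, x.fs)


def snr_input(x, w) -> float:
    """10 log10( sum x^2 / sum w^2 ) in dB; inf for zero noise."""
    xs = x.samples if isinstance(x, Signal) else np.asarray(x, float)
    ws = w.samples if isinstance(w, Signal) else np.asarray(w, float)
    e_w = np.sum(ws**2)
    if e_w == 0:
        return np.inf
    return float(10 * np.log10(np.sum(xs**2) / e_w))


def snr_output(x, x_est) -> float:
    """10 log10( sum x^2 / sum (x - x_est)^2 ) in dB; inf for exact recovery."""
    xs = x.samples if isinstance(x, Signal) else np.asarray(x, float)
    es = x_est.samples if isinstance(x_est, Signal) else np.asarray(x_est, float)
    e_r = np.sum((xs - es) ** 2)
    if e_r == 0:
        return np.inf
    return float(10 * np.log10(np.sum(xs**2) / e_r))
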