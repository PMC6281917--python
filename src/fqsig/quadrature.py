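"""Fourier quadrature transforms (FQTs) and Fourier-Singh analytic signals.

The Hilbert transform maps each cosine to the sine of the same frequency.
The Fourier quadrature transforms do the same thing with finite cosine/sine
bases: a Fourier *cosine* quadrature transform (FCQT) analyses the signal on
a DCT basis and re-synthesizes the coefficients on the companion sine basis,

    x~_ci = S~_i^T  C_i  x      (here realized as  S~_i @ (C_i^T @ x)
                                 with all matrices indexed [n][k]),

and a Fourier *sine* quadrature transform (FSQT) mirrors this with a DST
analysis and a cosine-companion synthesis.  Each companion matrix uses the
same kernel arguments and normalization factors as its partner transform
with cos and sin exchanged.

Pairing each signal with its quadrature gives the 16 Fourier-Singh analytic
signal (FSAS) representations

    z~_ci = x + j x~_ci         (cosine family: real part IS the signal)
    z~_si = x~_si + j x         (sine family: imaginary part IS the signal).

Their spectra are one-sided like the Gabor analytic signal, but unlike it
the real and imaginary parts are in general *not* orthogonal; the closed
form of the cosine-sine cross inner product is provided as
:func:`basis_cross_inner_product`.

The type-2 cosine case is the workhorse (it anchors the DCT-based
decomposition in :mod:`fqsig.fdm`) and has an O(N log N) path via a
zero-padded inverse FFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as _sfft

from .signal import Signal, as_samples
from .transforms import (
    TransformSpec,
    _cosine_entries,
    _sine_entries,
    build_transform_matrix,
    forward,
)

__all__ = [
    "QuadratureMatrix",
    "AnalyticSignal",
    "build_quadrature_matrix",
    "fcqt",
    "fsqt",
    "fsas",
    "invert_fcqt",
    "basis_cross_inner_product",
]

#: quadrature companions that lose one order of rank (zero row/column or
#: reduced index grid), mirroring their reduced partner transforms
_REDUCED_COMPANIONS = {
    ("sine_companion", 1),
    ("sine_companion", 2),
    ("sine_companion", 3),
    ("sine_companion", 5),
    ("sine_companion", 7),
    ("cosine_companion", 1),
    ("cosine_companion", 5),
}


@dataclass(frozen=True)
class QuadratureMatrix:
    """Companion basis matrix, entries indexed [sample n][frequency k].

    family 'sine_companion' is the sine version of cosine transform
    ``type_index`` (the S~_i of the construction); 'cosine_companion' is the
    cosine version of sine transform ``type_index`` (the C~_i).
    """

    entries: np.ndarray
    family: str
    type_index: int
    order: int

    @property
    def reduced_order(self) -> bool:
        return (self.family, self.type_index) in _REDUCED_COMPANIONS


@dataclass(frozen=True)
class AnalyticSignal:
    """Complex signal with a one-sided spectrum.

    ``kind`` records the construction ('GAS', 'FSAS_cosine_t', 'FSAS_sine_t')
    and ``original_part`` says which part of ``values`` is the input signal.
    """

    values: np.ndarray
    fs: float
    kind: str
    original_part: str  # 'real' or 'imaginary'

    def __len__(self) -> int:
        return self.values.size

    @property
    def signal(self) -> np.ndarray:
        """The original real signal embedded in this representation."""
        return self.values.real if self.original_part == "real" else self.values.imag

    @property
    def quadrature(self) -> np.ndarray:
        """The quadrature companion of the original signal."""
        return self.values.imag if self.original_part == "real" else self.values.real


def build_quadrature_matrix(family: str, type_index: int, N: int) -> QuadratureMatrix:
    """Build the companion matrix S~_i (family='sine_companion') or
    C~_i (family='cosine_companion') of order N.

    The matrix lives on the same index grid as its partner transform, so
    the cosine companions of the (N-1)-order DST-1/DST-5 are (N-1) x (N-1);
    the other reduced companions keep the full grid and simply contain an
    identically zero row or column.
    """
    if not 1 <= type_index <= 8:
        raise ValueError(f"type_index must be in 1..8, got {type_index}")
    if family == "sine_companion":
        spec = TransformSpec("cosine", type_index, N)
        entries = _cosine_entries(spec, trig=np.sin)
    elif family == "cosine_companion":
        spec = TransformSpec("sine", type_index, N)
        entries = _sine_entries(spec, trig=np.cos)
    else:
        raise ValueError(
            "family must be 'sine_companion' or 'cosine_companion', "
            f"got {family!r}"
        )
    return QuadratureMatrix(entries=entries, family=family, type_index=type_index, order=N)


# ---------------------------------------------------------------------------
# fast type-2 cosine path
# ---------------------------------------------------------------------------

def _fsas2_values(xv: np.ndarray) -> np.ndarray:
    """Type-2 cosine FSAS via one DCT and one zero-padded length-2N IFFT.

    z[n] = sqrt(2/N) * sum_k sigma_k X_c2[k] exp(j pi k (2n+1) / 2N)
    """
    N = xv.size
    X = _sfft.dct(xv, type=2, norm="ortho")
    u = np.zeros(2 * N, dtype=complex)
    u[:N] = np.sqrt(2.0 / N) * X * np.exp(1j * np.pi * np.arange(N) / (2 * N))
    u[0] /= np.sqrt(2.0)  # sigma_0
    z = 2 * N * np.fft.ifft(u)[:N]
    # the real part is the signal by construction; pin it bit-exactly
    return xv + 1j * z.imag


def fcqt(x, type_index: int = 2) -> np.ndarray:
    """Fourier cosine quadrature transform: DCT analysis, sine synthesis.

    Maps cos(pi k (2n+1)/2N) -> sin(pi k (2n+1)/2N) for type 2; a constant
    signal (all its energy in the k=0 bin, annihilated by the sine basis)
    maps to zero.  Returns a bare sample vector.
    """
    xv = as_samples(x)
    if type_index == 2:
        return _fsas2_values(xv).imag
    spec = TransformSpec("cosine", type_index, xv.size)
    if xv.size != spec.effective_order:
        raise ValueError("length mismatch")
    C = build_transform_matrix(spec).entries
    St = build_quadrature_matrix("sine_companion", type_index, xv.size).entries
    return St @ (C.T @ xv)


def fsqt(x, type_index: int = 2) -> np.ndarray:
    """Fourier sine quadrature transform: DST analysis, cosine synthesis.

    For the reduced-order DST-1/DST-5 the input length is N-1 for a spec of
    order N; pass a vector of the length you have and it is taken as the
    effective order.
    """
    xv = as_samples(x)
    N = xv.size if type_index not in (1, 5) else xv.size + 1
    spec = TransformSpec("sine", type_index, N)
    S = build_transform_matrix(spec).entries
    Ct = build_quadrature_matrix("cosine_companion", type_index, N).entries
    return Ct @ (S.T @ xv)


def fsas(x, family: str = "cosine", type_index: int = 2) -> AnalyticSignal:
    """Fourier-Singh analytic signal of the requested family and type.

    cosine family: values = x + j * fcqt(x)   (original part: real)
    sine family:   values = fsqt(x) + j * x   (original part: imaginary)
    """
    fs = x.fs if isinstance(x, Signal) else 1.0
    xv = as_samples(x)
    if family == "cosine":
        if type_index == 2:
            values = _fsas2_values(xv)
        else:
            values = xv + 1j * fcqt(xv, type_index)
        return AnalyticSignal(values, fs, f"FSAS_cosine_{type_index}", "real")
    if family == "sine":
        values = fsqt(xv, type_index) + 1j * xv
        return AnalyticSignal(values, fs, f"FSAS_sine_{type_index}", "imaginary")
    raise ValueError(f"family must be 'cosine' or 'sine', got {family!r}")


def invert_fcqt(x_tilde, type_index: int = 2) -> np.ndarray:
    """Recover the zero-mean part of a signal from its type-2 FCQT.

    The FCQT annihilates the mean (the k=0 cosine coefficient lands on the
    identically zero sine column), so only the zero-mean part is
    recoverable: sine analysis of the quadrature gives back the DCT
    coefficients for k >= 1, the k=0 coefficient is set to zero, and an
    inverse DCT synthesizes x - mean(x).
    """
    if type_index != 2:
        raise NotImplementedError("inversion is implemented for the type-2 FCQT")
    xt = as_samples(x_tilde)
    N = xt.size
    St = build_quadrature_matrix("sine_companion", 2, N).entries
    X = St.T @ xt  # sine-basis coefficients; row k=0 is zero by construction
    X[0] = 0.0
    return _sfft.idct(X, type=2, norm="ortho")


def basis_cross_inner_product(k: int, m: int, N: int) -> float:
    """Closed form of sum_n cos(pi k (2n+1)/2N) * sin(pi m (2n+1)/2N).

    Zero when k == m or when m +- k is even; otherwise
    Sigma_{m+k} + Sigma_{m-k} with Sigma_d = 1 / (2 sin(pi d / 2N)) for odd
    d (and 0 at d = 0).  The nonzero values are why the FSAS real and
    imaginary parts are not orthogonal.
    """
    if not (0 <= k <= N - 1 and 0 <= m <= N - 1):
        raise ValueError(f"indices must be in 0..{N - 1}, got k={k}, m={m}")
    if k == m or (m + k) % 2 == 0:
        return 0.0

    def _sigma_term(d: int) -> float:
        if d == 0:
            return 0.0
        return 0.5 / np.sin(np.pi * d / (2 * N))

    return _sigma_term(m + k) + _sigma_term(m - k)
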