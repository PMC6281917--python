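"""The eight discrete cosine and eight discrete sine orthogonal transforms.

All sixteen transforms are defined through explicit orthonormal basis
matrices with entries indexed ``[sample n][frequency k]``.  The forward
transform contracts over the sample index,

    X[k] = sum_n  A[n, k] x[n],

so that for the type-2 cosine transform

    X_c2[k] = sqrt(2/N) * sigma_k * sum_n x[n] cos(pi k (2n+1) / 2N),

with sigma_0 = 1/sqrt(2) and sigma_k = 1 otherwise, which is the common
orthonormal DCT-2 convention.  Because every matrix is orthonormal, the
inverse is synthesis with the same matrix: ``x = A @ X``.

Types 1-4 of either family admit fast O(N log N) routines
(:func:`scipy.fft.dct` / :func:`scipy.fft.dst`); the forward/inverse
operations use them transparently and the explicit matrices remain the
reference definition.  The odd types 5-8 are applied as dense matrix
products, which is entirely adequate at the record lengths this package
targets (N up to a few thousand).

Index-range conventions
-----------------------
All matrices are of order N except DST-1 and DST-5, whose natural index
range is 1 <= n, k <= N-1: for those two, a spec of ``order=N`` yields an
(N-1) x (N-1) matrix (``effective_order = N-1``) and the forward transform
accepts vectors of length N-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as _sfft

from .signal import Signal, as_samples

__all__ = [
    "TransformSpec",
    "TransformMatrix",
    "SpectrumCoefficients",
    "build_transform_matrix",
    "forward",
    "inverse",
]


@dataclass(frozen=True)
class TransformSpec:
    """Which of the 16 transforms: family 'cosine' or 'sine', type 1..8, order N."""

    family: str
    type_index: int
    order: int

    def __post_init__(self) -> None:
        if self.family not in ("cosine", "sine"):
            raise ValueError(f"family must be 'cosine' or 'sine', got {self.family!r}")
        if not 1 <= self.type_index <= 8:
            raise ValueError(f"type_index must be in 1..8, got {self.type_index}")
        if self.order < 2:
            raise ValueError(f"order must be >= 2, got {self.order}")

    @property
    def effective_order(self) -> int:
        """Number of samples/coefficients the transform actually acts on."""
        if self.family == "sine" and self.type_index in (1, 5):
            return self.order - 1
        return self.order


@dataclass(frozen=True)
class TransformMatrix:
    """Orthonormal analysis/synthesis matrix, entries indexed [n][k]."""

    entries: np.ndarray
    spec: TransformSpec

    @property
    def effective_order(self) -> int:
        return self.spec.effective_order


@dataclass(frozen=True)
class SpectrumCoefficients:
    """Real transform coefficients indexed by frequency bin k."""

    coeffs: np.ndarray
    spec: TransformSpec
    fs: float = 1.0


# ---------------------------------------------------------------------------
# normalization helpers
# ---------------------------------------------------------------------------

_ISQ2 = 1.0 / np.sqrt(2.0)


def _gamma(idx: np.ndarray, N: int) -> np.ndarray:
    """1/sqrt(2) at indices 0 and N-1, else 1 (type-1 cosine)."""
    return np.where((idx == 0) | (idx == N - 1), _ISQ2, 1.0)


def _sigma(idx: np.ndarray) -> np.ndarray:
    """1/sqrt(2) at index 0, else 1."""
    return np.where(idx == 0, _ISQ2, 1.0)


def _eps(idx: np.ndarray, N: int) -> np.ndarray:
    """1/sqrt(2) at index N-1, else 1."""
    return np.where(idx == N - 1, _ISQ2, 1.0)


def _kernel_args(spec: TransformSpec):
    """Index grids (n, k) and the scale factors a, b, c, d for order N."""
    N = spec.order
    if spec.family == "sine" and spec.type_index in (1, 5):
        n, k = np.meshgrid(np.arange(1, N), np.arange(1, N), indexing="ij")
    else:
        n, k = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    a = np.sqrt(2.0 / (N - 1))
    b = np.sqrt(2.0 / N)
    # Odd-type scales: 2/sqrt(2N -+ 1) makes types 5-8 orthonormal.
    c = 2.0 / np.sqrt(2 * N - 1)
    d = 2.0 / np.sqrt(2 * N + 1)
    return N, n, k, a, b, c, d


def _cosine_entries(spec: TransformSpec, trig=np.cos) -> np.ndarray:
    """Cosine-family kernel of Eq-type ``spec.type_index``.

    ``trig`` swaps the kernel function: the quadrature module builds the
    sine companion of each cosine transform by passing ``np.sin`` (same
    index shifts, same normalization factors).
    """
    N, n, k, a, b, c, d = _kernel_args(spec)
    t = spec.type_index
    if t == 1:
        return a * _gamma(n, N) * _gamma(k, N) * trig(n * k * np.pi / (N - 1))
    if t == 2:
        return b * _sigma(k) * trig((n + 0.5) * k * np.pi / N)
    if t == 3:
        return b * _sigma(n) * trig((k + 0.5) * n * np.pi / N)
    if t == 4:
        return b * trig((n + 0.5) * (k + 0.5) * np.pi / N)
    if t == 5:
        return c * _sigma(n) * _sigma(k) * trig(n * k * 2 * np.pi / (2 * N - 1))
    if t == 6:
        return c * _eps(n, N) * _sigma(k) * trig((n + 0.5) * k * 2 * np.pi / (2 * N - 1))
    if t == 7:
        return c * _eps(k, N) * _sigma(n) * trig((k + 0.5) * n * 2 * np.pi / (2 * N - 1))
    return d * trig((n + 0.5) * (k + 0.5) * 2 * np.pi / (2 * N + 1))


def _sine_entries(spec: TransformSpec, trig=np.sin) -> np.ndarray:
    """Sine-family kernel; ``trig=np.cos`` gives the cosine companion."""
    N, n, k, a, b, c, d = _kernel_args(spec)
    t = spec.type_index
    if t == 1:
        return b * trig(n * k * np.pi / N)
    if t == 2:
        return b * _eps(k, N) * trig((n + 0.5) * (k + 1) * np.pi / N)
    if t == 3:
        return b * _eps(n, N) * trig((k + 0.5) * (n + 1) * np.pi / N)
    if t == 4:
        return b * trig((n + 0.5) * (k + 0.5) * np.pi / N)
    if t == 5:
        return c * trig(n * k * 2 * np.pi / (2 * N - 1))
    if t == 6:
        return d * trig((n + 0.5) * (k + 1) * 2 * np.pi / (2 * N + 1))
    if t == 7:
        return d * trig((n + 1) * (k + 0.5) * 2 * np.pi / (2 * N + 1))
    return c * _eps(n, N) * _eps(k, N) * trig((n + 0.5) * (k + 0.5) * 2 * np.pi / (2 * N - 1))


def build_transform_matrix(spec: TransformSpec) -> TransformMatrix:
    """Construct the orthonormal basis matrix for the requested transform.

    The returned entries are indexed ``[sample n][frequency k]`` and satisfy
    ``entries.T @ entries == I`` on the effective order.
    """
    if spec.family == "cosine":
        entries = _cosine_entries(spec)
    else:
        entries = _sine_entries(spec)
    return TransformMatrix(entries=entries, spec=spec)


# ---------------------------------------------------------------------------
# forward / inverse
# ---------------------------------------------------------------------------

def _fast_forward(x: np.ndarray, spec: TransformSpec) -> np.ndarray | None:
    """O(N log N) path for types 1-4; None when no fast routine applies."""
    if spec.type_index > 4:
        return None
    fn = _sfft.dct if spec.family == "cosine" else _sfft.dst
    return fn(x, type=spec.type_index, norm="ortho")


def _fast_inverse(X: np.ndarray, spec: TransformSpec) -> np.ndarray | None:
    if spec.type_index > 4:
        return None
    fn = _sfft.idct if spec.family == "cosine" else _sfft.idst
    return fn(X, type=spec.type_index, norm="ortho")


def forward(x, spec: TransformSpec, *, use_fast: bool = True) -> SpectrumCoefficients:
    """Analyse a signal: ``X[k] = sum_n A[n, k] x[n]``.

    Parameters
    ----------
    x : Signal or array_like
        Input of length ``spec.effective_order``.
    spec : TransformSpec
    use_fast : bool
        Use the scipy fast routine for types 1-4 (identical to the matrix
        path to ~1e-14); set False to force the explicit matrix product.
    """
    fs = x.fs if isinstance(x, Signal) else 1.0
    xv = as_samples(x)
    if xv.size != spec.effective_order:
        raise ValueError(
            f"signal length {xv.size} does not match transform order "
            f"{spec.effective_order} (spec order {spec.order})"
        )
    coeffs = _fast_forward(xv, spec) if use_fast else None
    if coeffs is None:
        A = build_transform_matrix(spec).entries
        coeffs = A.T @ xv
    return SpectrumCoefficients(coeffs=coeffs, spec=spec, fs=fs)


def inverse(X: SpectrumCoefficients, *, use_fast: bool = True) -> Signal:
    """Synthesize the signal back: ``x = A @ X`` (orthonormal inverse)."""
    spec = X.spec
    Xv = np.asarray(X.coeffs, dtype=float)
    if Xv.size != spec.effective_order:
        raise ValueError(
            f"coefficient length {Xv.size} does not match transform order "
            f"{spec.effective_order}"
        )
    xv = _fast_inverse(Xv, spec) if use_fast else None
    if xv is None:
        A = build_transform_matrix(spec).entries
        xv = A @ Xv
    return Signal(xv, X.fs)
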