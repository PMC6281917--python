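# Methods

This note records the models implemented in `fqsig`, the conventions and
numerical choices behind them, and what the synthetic test signals do and
do not establish about real data.

## Transform families

`fqsig.transforms` implements the eight discrete cosine transforms and
eight discrete sine transforms as explicit orthonormal matrices with
entries indexed `[sample n][frequency k]`. The forward transform contracts
over n (`X = Aᵀx`), the inverse is synthesis with the same matrix
(`x = AX`). For the even types (1–4) of both families the scale factor is
√(2/N) (√(2/(N−1)) for DCT-1), with the usual half-weights: γ = 1/√2 at
both ends of the DCT-1 index range, σ = 1/√2 at k = 0, ε = 1/√2 at
k = N−1. The odd types (5–8) use the scale 2/√(2N∓1) appropriate to their
odd denominators; all 16 matrices verify AᵀA = I to 1e−15 at every order
tested, and the test suite pins this at N ∈ {4, 7, 16}.

DST-1 and DST-5 are naturally (N−1)-order transforms (their kernels vanish
on the n = 0 and k = 0 lines), so a spec of order N produces an
(N−1)×(N−1) matrix and the forward transform takes vectors of length N−1.
This keeps every stored matrix full-rank instead of carrying a zero
row/column through the algebra.

Types 1–4 run through `scipy.fft.dct/dst` (`norm="ortho"`), which match
the explicit matrices to ~1e−14; the matrices remain the definition and
the agreement is asserted in tests. Types 5–8 have no widely available
fast routine and are applied as dense products — at the record lengths
this package targets (N up to a few thousand) this is never the
bottleneck.

## Quadrature companions and the FSAS

Each transform has a quadrature companion built from the same kernel
arguments and normalization factors with cosine and sine exchanged. The
Fourier cosine quadrature transform of type i is then
x̃ = S̃ᵢ(Cᵢᵀ x): analysis on the cosine basis, synthesis on the companion
sine basis. Composition order is anchored to the fully written-out type-2
pair (analysis carries σ_k, the sine synthesis does not need it because
the k = 0 sine vector vanishes); the same orientation is applied uniformly
to all 16 variants.

Two structural null spaces fall out of the construction rather than being
defects:

* the FCQT annihilates constants (DC lands on the zero sine column), so
  inversion recovers only the zero-mean part of a signal — `invert_fcqt`
  documents and tests exactly this;
* the type-2 FSQT annihilates the Nyquist alternation (−1)ⁿ: the cosine
  companion of the top DST-2 basis vector is identically zero, mirroring
  the DC case in the sine family.

The type-2 FSAS z̃ = x + j·x̃ is computed in O(N log N) by one DCT and one
zero-padded length-2N inverse FFT of σ_k X_c2[k]·e^{jπk/2N}; the real part
is pinned to the input bit-exactly. On a cosine basis vector the FSAS is
exactly exp(jπk₀(2n+1)/2N): unit modulus and linear phase, the harmonic
correspondence that justifies reading IA/IF off the polar form. Unlike the
Gabor construction, the real and imaginary parts are *not* orthogonal in
general; the closed form of the cosine–sine cross inner product (zero iff
k = m or m±k even, else ½[1/sin(π(m+k)/2N) + 1/sin(π(m−k)/2N)]) is
implemented and checked against the brute-force sum.

## Instantaneous frequency

Phase is always the two-argument arctangent, in (−π, π], with
atan2(0, 0) = 0 at exactly-zero-amplitude samples. Frequency comes from
finite differences of that wrapped phase, and the differencing convention
matters more than it looks:

1. one-sample increments are wrapped into [−π, π] **preserving the sign of
   an increment of exactly ±π** — a half-turn per sample is legitimately
   approached from either side, and collapsing both onto one endpoint
   biases quantized phases;
2. the positivity correction (add π to negative increments) is applied
   **per one-sample increment**, putting each into [0, π] — the IF of a
   real signal is meaningful modulo π through the multivalued arctangent;
3. FFD/BFD take the corrected increment ahead of/behind the sample, CFD
   averages the two; endpoints use the one-sided value. CFD is the
   default.

The unit sample sequence is the stress test: its type-2 FSAS phase is
quantized to ±π/2 with increments of exactly ±π alternating in sign.
Steps 1–2 turn the alternation into 0, π, 0, π … and the CFD average is
exactly π/2 at every interior sample — a flat fs/4 = 25 Hz IF, which is
the analytically correct value. FFD/BFD alone chatter between 0 and π on
this signal (and are kept selectable for smooth signals, where all three
agree). Samples with exactly zero amplitude carry no phase information;
their ω is linearly interpolated from neighbours.

The Gabor analytic signal is built from the one-sided DFT spectrum (DC
and, for even N, Nyquist kept unscaled; interior positive bins doubled) —
numerically identical to `scipy.signal.hilbert`, which the tests use as an
independent oracle. Its periodicity produces the well-known boundary
artifacts: on a 5–100 Hz, 1 s, fs = 1 kHz linear chirp the FSAS IF stays
within 1 Hz RMSE over the central 80% of samples while the GAS IF error in
the end 10% windows is an order of magnitude larger; the suite asserts the
ordering, not a fragile exact number.

## The decomposition

`decompose` takes one forward transform and M per-band syntheses
(asserted structurally in a test by counting calls — the advertised
(M+1)-FFT cost shape). Bin k of the DCT basis covers f_k = k·fs/2N Hz with
K_max = N−1; the DFT basis uses f_k = k·fs/N with K_max = ⌊N/2⌋. Hz→bin
conversion rounds to the nearest bin with ties toward the lower bin. DC is
never inside a band: it is carried as the mean term a₀.

Band strategies:

* **equal** — near-equal index widths, earlier bands take the remainder;
* **dyadic** — octave edges fs/2ʲ for j = 1..M: top band [fs/4, fs/2),
  each next band halves, the lowest spans (0, fs/2^M]. At fs = 50 Hz,
  M = 8 this gives edges 0.1953125, 0.390625, 0.78125, 1.5625, 3.125,
  6.25, 12.5, 25 Hz;
* **equal-energy** — a greedy cumulative walk over |X[k]|²: a bin belongs
  to the earlier band when the running sum first reaches i·(total/M).
  Deterministic; on a flat spectrum it reduces to equal widths.

Masks are binary by default; any real non-negative mask (a Gaussian bump
is provided) keeps the filtering zero-phase. With binary masks on the
orthonormal DCT, FIBFs of distinct bands are exactly orthogonal and
complete, and a midpoint-symmetric input yields midpoint-symmetric FIBFs
(no group delay) — both property-tested.

Analytic companions: `FSAS` synthesizes each band's coefficients on the
complex kernel e^{jπk(2n+1)/2N} (real part = the FIBF, imaginary part =
the band-limited FCQT); `GAS` applies the one-sided DFT construction to
the real FIBF. The DFT basis uses the one-sided per-band synthesis
directly.

Applications are thin layers over the same machinery: `remove_bands`
zeroes stop bands given in Hz and returns the cleaned signal plus each
removed component (clean + removed = input exactly); `extract_trend`
keeps every bin at or below 1/timescale plus the mean (trend +
variability = input exactly); `window_reconstruct` multiplies chosen
FIBFs by time-domain weights before summation.

## Synthetic signals: what they show and what they don't

The generators fix the study conditions used throughout the tests:

* **unit sample** δ[n−499], N = 1000, fs = 100 Hz — the flat-IF worked
  example;
* **linear chirp** fs = 1000 Hz, t ∈ [0, 1) s, 5→100 Hz — IF tracking and
  end-artifact comparison;
* **DCT tones** — exact single-bin signals; two of them split exactly
  (< 1e−10) across a band boundary;
* **AM–FM mixtures** — sum of aᵢ(t)cos(φᵢ(t)) with stored IA/IF laws;
  components whose spectral supports overlap are rejected;
* **template ECG** — Gaussian P, Q, R, S, T bumps (offsets −0.20, −0.03,
  0, 0.03, 0.25 s; amplitudes 0.15, −0.10, 1.00, −0.15, 0.30 mV; widths
  25, 10, 12, 10, 45 ms) repeated at the requested heart rate with 2%
  seeded RR jitter, mean-removed. Its spectrum keeps < 2% of its energy
  below 0.5 Hz or within 49–51 Hz, so stop-band denoising is
  near-lossless on the clean part;
* **corruption recipe** — a 0.3 Hz baseline-wander sinusoid (optionally
  plus a seeded slow random walk) and a 50 Hz power-line sinusoid in an
  equal-energy mixture, jointly scaled to an exact input SNR (default
  −18.4 dB). SNRs are 10·log₁₀ of energy ratios; exact recovery and zero
  noise report +inf rather than raising.

All generators are byte-deterministic given their seed.

Two honest limits of the synthetic setting. First, finite-length off-grid
components carry rectangular-window spectral tails, so band-separated
recovery of generic AM–FM mixtures is accurate to a few percent at
N = 1000 (improving as the record grows), not machine precision; exact
separation holds only for on-grid content, and the tests assert each
regime at its own scale. Second, the template ECG establishes that the
operators behave correctly on a signal with ECG-like morphology and
spectrum; it does not certify clinical performance on recorded ECGs, whose
noise is richer than two sinusoids. Real recordings (CSV/WAV) are first-
class inputs through the CLI, but no downloaded data is used in the tests.

## Numerical conventions

* Orthogonality/round-trip tolerances: 1e−10 for double precision at
  N ≤ 4096; worked four-decimal values are asserted at 5e−5.
* Hz→bin ties round toward the lower bin everywhere.
* Overlapping stop bands are merged with a warning rather than rejected.
* Problem sizes in tests and the acceptance script (N between 256 and
  3600, a 10 s ECG at 360 Hz) are desk-scale choices that exercise every
  code path; all matrices at these sizes build in milliseconds.

## Known limitations

* Odd-type transforms (5–8) are O(N²); fine at desk scale, not for long
  records.
* The FSAS one-sided-spectrum property is asserted via the exact on-grid
  harmonic correspondence; off-grid signals show the usual leakage and no
  claim is made in the DTFT sense.
* 2-D transforms, modified DCT and continuous-time formulations are out
  of scope.
* The equal-energy boundary walk is one deterministic tie-break among
  several defensible ones; plans from other implementations may differ by
  one bin at boundaries.
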