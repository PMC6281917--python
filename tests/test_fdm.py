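"""Band planning, zero-phase filter bank, decomposition and its applications."""

import numpy as np
import pytest

from fqsig.fdm import (
    BandPlan,
    decompose,
    extract_trend,
    hz_to_bin,
    reconstruct,
    remove_bands,
    select_bands,
    window_reconstruct,
    zero_phase_mask,
)
from fqsig.signal import Signal
from fqsig.synthetic import (
    CorruptionRecipe,
    add_blw_pli,
    dct_tone,
    snr_input,
    snr_output,
    synthetic_ecg,
)

DYADIC_EDGES_50HZ = [0.0, 0.1953125, 0.390625, 0.78125, 1.5625, 3.125, 6.25, 12.5, 25.0]


# ---------------------------------------------------------------------------
# band selection
# ---------------------------------------------------------------------------

def test_dyadic_edges_at_50_hz_8_bands():
    plan = select_bands(1000, 50.0, 8, "dyadic")
    assert plan.band_edges_hz() == pytest.approx(DYADIC_EDGES_50HZ, abs=1e-12)


def test_equal_split_of_nine_point_plan():
    plan = select_bands(9, 1.0, 2, "equal")
    assert plan.bands == ((1, 4), (5, 8))


def test_equal_energy_on_flat_spectrum_gives_equal_widths(rng):
    """A spectrally flat input splits at equal widths."""
    N, M = 33, 4
    # synthesize a signal whose DCT spectrum is exactly flat on k=1..N-1
    import scipy.fft

    X = np.ones(N)
    x = scipy.fft.idct(X, type=2, norm="ortho")
    plan = select_bands(N, 1.0, M, "equal_energy", x=Signal(x))
    widths = [hi - lo + 1 for lo, hi in plan.bands]
    assert max(widths) - min(widths) <= 1


def test_equal_energy_requires_signal():
    with pytest.raises(ValueError):
        select_bands(64, 1.0, 4, "equal_energy")


def test_band_plan_validation():
    with pytest.raises(ValueError):
        select_bands(16, 1.0, 20, "equal")
    with pytest.raises(ValueError):
        BandPlan(((1, 4), (6, 15)), "custom", 16, 1.0)  # gap
    with pytest.raises(ValueError):
        BandPlan(((2, 15),), "custom", 16, 1.0)  # misses bin 1
    # custom contiguous cover is fine
    BandPlan(((1, 7), (8, 15)), "custom", 16, 1.0)


def test_hz_to_bin_ties_round_down():
    # f*2N/fs = 62.5 exactly -> bin 62
    assert hz_to_bin(1.5625, 1000, 50.0) == 62
    assert hz_to_bin(0.0, 1000, 50.0) == 0


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def test_binary_mask_worked_example():
    m = zero_phase_mask((3, 5), 8)
    assert np.array_equal(m, [0, 0, 0, 1, 1, 1, 0, 0])


def test_masks_of_plan_partition_spectrum():
    plan = select_bands(64, 1.0, 5, "equal")
    total = sum(zero_phase_mask(b, 64) for b in plan.bands)
    assert total[0] == 0
    assert np.array_equal(total[1:], np.ones(63))


def test_gaussian_mask_nonnegative():
    m = zero_phase_mask((10, 20), 64, shape="gaussian")
    assert np.all(m >= 0)
    assert m[15] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        zero_phase_mask((3, 70), 64)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("analytic_kind", ["FSAS", "GAS"])
@pytest.mark.parametrize("basis", ["dct2", "dft"])
def test_completeness_and_orthogonality(analytic_kind, basis, rng):
    """a0 + sum of FIBFs reproduces the input; distinct bands are orthogonal."""
    N = 200
    x = Signal(rng.standard_normal(N) + 0.7, 25.0)
    plan = select_bands(N, 25.0, 6, "equal", basis)
    f = decompose(x, plan, analytic_kind)
    rec = reconstruct(f)
    scale = np.max(np.abs(x.samples))
    assert np.max(np.abs(rec.samples - x.samples)) < 1e-9 * scale
    fib = f.fibfs
    for i in range(len(fib)):
        for j in range(i + 1, len(fib)):
            bound = 1e-9 * np.linalg.norm(fib[i]) * np.linalg.norm(fib[j])
            assert abs(np.dot(fib[i], fib[j])) <= max(bound, 1e-12)


def test_two_tone_exact_band_separation():
    """On-grid tones split exactly into their bands."""
    N = 64
    x1, x2 = dct_tone(N, 3), dct_tone(N, 11)
    x = Signal(x1.samples + x2.samples, 1.0)
    plan = BandPlan(((1, 7), (8, N - 1)), "custom", N, 1.0)
    f = decompose(x, plan, "FSAS")
    assert np.max(np.abs(f.fibfs[0] - x1.samples)) < 1e-10
    assert np.max(np.abs(f.fibfs[1] - x2.samples)) < 1e-10


def test_single_band_fibf_is_demeaned_signal(rng):
    N = 50
    x = Signal(rng.standard_normal(N) + 2.0, 1.0)
    f = decompose(x, select_bands(N, 1.0, 1, "equal"), "FSAS")
    assert f.a0 == pytest.approx(x.samples.mean(), abs=1e-12)
    assert np.max(np.abs(f.fibfs[0] - (x.samples - x.samples.mean()))) < 1e-9


def test_decomposition_idempotent_per_band(rng):
    """Re-decomposing one FIBF returns itself in its own band, ~0 elsewhere."""
    N = 128
    x = Signal(rng.standard_normal(N), 1.0)
    plan = select_bands(N, 1.0, 4, "equal")
    f = decompose(x, plan, "FSAS")
    f2 = decompose(Signal(f.fibfs[1], 1.0), plan, "FSAS")
    assert np.max(np.abs(f2.fibfs[1] - f.fibfs[1])) < 1e-9
    for j in (0, 2, 3):
        assert np.max(np.abs(f2.fibfs[j])) < 1e-9


def test_zero_phase_symmetry(rng):
    """A midpoint-symmetric input yields midpoint-symmetric FIBFs: binary
    frequency masks add no group delay."""
    N = 100
    half = rng.standard_normal(N // 2)
    x = Signal(np.concatenate([half, half[::-1]]), 1.0)
    f = decompose(x, select_bands(N, 1.0, 5, "equal"), "FSAS")
    for xi in f.fibfs:
        assert np.max(np.abs(xi - xi[::-1])) < 1e-9


def test_transform_call_budget(monkeypatch, rng):
    """Decomposition costs one forward transform plus M band syntheses."""
    import fqsig.fdm as fdm_mod

    calls = {"dct": 0, "ifft": 0}
    real_dct = fdm_mod._sfft.dct
    real_ifft = np.fft.ifft
    monkeypatch.setattr(fdm_mod._sfft, "dct", lambda *a, **k: calls.__setitem__("dct", calls["dct"] + 1) or real_dct(*a, **k))
    monkeypatch.setattr(np.fft, "ifft", lambda *a, **k: calls.__setitem__("ifft", calls["ifft"] + 1) or real_ifft(*a, **k))
    M = 5
    x = Signal(rng.standard_normal(64), 1.0)
    decompose(x, select_bands(64, 1.0, M, "equal"), "FSAS")
    assert calls["dct"] == 1
    assert calls["ifft"] == M


def test_reconstruct_subsets(rng):
    N = 80
    x = Signal(rng.standard_normal(N), 1.0)
    plan = select_bands(N, 1.0, 4, "equal")
    f = decompose(x, plan, "FSAS")
    none = reconstruct(f, include=[])
    assert np.allclose(none.samples, f.a0)
    partial = reconstruct(f, include=[0, 2], with_mean=False)
    expected = f.fibfs[0] + f.fibfs[2]
    assert np.max(np.abs(partial.samples - expected)) < 1e-12
    complement = reconstruct(f, include=[1, 3], with_mean=True)
    assert np.max(np.abs(partial.samples + complement.samples - x.samples)) < 1e-9


# ---------------------------------------------------------------------------
# remove_bands / denoising
# ---------------------------------------------------------------------------

def test_remove_bands_identity_on_empty_stop_list(rng):
    x = Signal(rng.standard_normal(64), 100.0)
    clean, removed = remove_bands(x, [])
    assert removed == []
    assert np.array_equal(clean.samples, x.samples)


def test_remove_bands_partition(rng):
    x = Signal(rng.standard_normal(256), 100.0)
    clean, removed = remove_bands(x, [(1, 5), (20, 30)])
    total = clean.samples + sum(r.samples for r in removed)
    assert np.max(np.abs(total - x.samples)) < 1e-9


def test_remove_bands_merges_overlaps_with_warning(rng):
    x = Signal(rng.standard_normal(64), 100.0)
    with pytest.warns(UserWarning):
        clean, removed = remove_bands(x, [(1, 5), (4, 10)])
    assert len(removed) == 1


def test_ecg_denoising_improves_snr():
    """Baseline wander + mains interference removal raises the SNR."""
    ecg = synthetic_ecg(360.0, 10.0, 72.0, seed=3)
    noisy, w = add_blw_pli(ecg, CorruptionRecipe(target_snr_db=-18.4, seed=3))
    snr_i = snr_input(ecg, w)
    clean, removed = remove_bands(noisy, [(0.0, 0.5), (49.0, 51.0)])
    snr_o = snr_output(ecg, clean)
    assert snr_o > snr_i
    assert len(removed) == 2
    # the removed pieces carry almost all the injected noise energy
    resid = noisy.samples - sum(r.samples for r in removed) - ecg.samples
    assert np.sum(resid**2) < 0.05 * np.sum(w.samples**2)


# ---------------------------------------------------------------------------
# trend extraction
# ---------------------------------------------------------------------------

def test_trend_keeps_slow_tone():
    """A 100-sample-period tone survives a 64-sample trend threshold.

    The tone sits exactly on DCT bin k=8 (period 2N/k = 100 at N=400), so
    the split is pure bin arithmetic."""
    fs, N = 1.0, 400
    x = Signal(1.5 + dct_tone(N, 8).samples, fs)
    trend, var = extract_trend(x, 64.0)
    assert np.max(np.abs(var.samples)) < 1e-9
    assert np.max(np.abs(trend.samples + var.samples - x.samples)) == 0.0


def test_trend_drops_fast_tone():
    """A 4-sample-period tone (bin k=200) is variability, not trend,
    at a 64-sample timescale."""
    fs, N = 1.0, 400
    x = Signal(2.0 + dct_tone(N, 200).samples, fs)
    trend, var = extract_trend(x, 64.0)
    assert np.max(np.abs(trend.samples - 2.0)) < 1e-9


def test_trend_timescale_validation():
    x = Signal(np.ones(10), 1.0)
    with pytest.raises(ValueError):
        extract_trend(x, 1.0)


# ---------------------------------------------------------------------------
# windowed reconstruction
# ---------------------------------------------------------------------------

def test_window_reconstruct_all_ones_equals_reconstruct(rng):
    N = 60
    x = Signal(rng.standard_normal(N), 1.0)
    f = decompose(x, select_bands(N, 1.0, 3, "equal"), "FSAS")
    wr = window_reconstruct(f, [np.ones(N)] * 3, include=[0, 1, 2])
    plain = reconstruct(f, with_mean=False)
    assert np.max(np.abs(wr.samples - plain.samples)) < 1e-12


def test_window_reconstruct_zero_windows(rng):
    N = 40
    f = decompose(Signal(rng.standard_normal(N), 1.0), select_bands(N, 1.0, 2, "equal"))
    wr = window_reconstruct(f, [np.zeros(N), np.zeros(N)], include=[0, 1])
    assert np.max(np.abs(wr.samples)) == 0.0


def test_gaussian_window_localizes_energy(rng):
    """A Gaussian window centred mid-record suppresses energy outside it."""
    N = 200
    x = Signal(rng.standard_normal(N), 1.0)
    f = decompose(x, select_bands(N, 1.0, 2, "equal"))
    n = np.arange(N)
    g = np.exp(-0.5 * ((n - 100) / 20.0) ** 2)
    wr = window_reconstruct(f, {0: g, 1: g})
    inside = slice(80, 121)
    xi = sum(f.fibfs)
    out_energy_w = np.sum(wr.samples[:60] ** 2) + np.sum(wr.samples[140:] ** 2)
    out_energy_x = np.sum(xi[:60] ** 2) + np.sum(xi[140:] ** 2)
    assert out_energy_w < 0.5 * out_energy_x
    with pytest.raises(ValueError):
        window_reconstruct(f, [np.ones(N - 1)], include=[0])
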