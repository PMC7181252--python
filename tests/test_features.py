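"""Spectral feature representations and contextual stacking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fogkit import features as ft
from fogkit.errors import ContractError
from fogkit.io_preprocess import Window, WindowSet

from conftest import sine_window


def direct_dft_magnitudes(x, n_bins=64):
    """O(n^2) DFT summation — independent of any FFT routine."""
    n = len(x)
    k = np.arange(n_bins)[:, None]
    t = np.arange(n)[None, :]
    basis = np.exp(-2j * np.pi * k * t / n)
    return np.abs(basis @ x)


class TestFFTSpectrum:
    def test_shape_and_zero_window(self):
        spec = ft.fft_spectrum(np.zeros((128, 3)))
        assert spec.shape == (64, 3)
        assert spec.size == 192
        assert np.all(spec == 0)

    def test_matches_direct_dft_summation(self, rng):
        w = rng.normal(size=(128, 3))
        spec = ft.fft_spectrum(w)
        for axis in range(3):
            np.testing.assert_allclose(
                spec[:, axis], direct_dft_magnitudes(w[:, axis]), atol=1e-8
            )

    def test_5hz_sine_peaks_at_bin_16(self):
        spec = ft.fft_spectrum(sine_window(5.0))
        assert spec[:, 0].argmax() == 16  # 5 * 128 / 40

    def test_wrong_length_rejected(self):
        with pytest.raises(ContractError):
            ft.fft_spectrum(np.zeros((64, 3)))

    def test_parseval(self, rng):
        w = rng.normal(size=(128, 3))
        full = np.abs(np.fft.fft(w, axis=0))
        time_energy = (w ** 2).sum(axis=0)
        freq_energy = (full ** 2).sum(axis=0) / 128.0
        np.testing.assert_allclose(freq_energy, time_energy, rtol=1e-6)


class TestBandPower:
    def test_zero_spectrum(self):
        assert ft.band_power(np.zeros(64), ft.FREEZE_BAND) == 0

    def test_disjoint_bands_are_additive(self, rng):
        spec = rng.random(64)
        lo = ft.band_power(spec, (0.5, 3.0))
        hi = ft.band_power(spec, (3.0, 8.0))
        assert lo + hi == pytest.approx(ft.band_power(spec, (0.5, 8.0)), abs=1e-12)

    def test_6hz_sine_power_concentrates_in_freeze_band(self):
        spec = ft.fft_spectrum(sine_window(6.0))[:, 0]
        # one-sided total power equals half the Parseval sum; the ratio of
        # freeze-band power to it must be dominated by the 6 Hz line
        total = (spec ** 2).sum()
        assert ft.band_power(spec, ft.FREEZE_BAND) / total > 0.9

    def test_inverted_band_rejected(self):
        with pytest.raises(ContractError):
            ft.band_power(np.zeros(64), (8.0, 3.0))

    def test_boundary_bin_3hz_belongs_to_freeze_band(self):
        spec = np.zeros(64)
        freqs = ft.bin_frequencies()
        k3 = int(np.searchsorted(freqs, 3.0))  # first bin at/above 3 Hz
        spec[k3] = 1.0
        assert ft.band_power(spec, ft.FREEZE_BAND) > 0
        assert ft.band_power(spec, ft.LOCOMOTION_BAND) == 0


class TestMazilu:
    def test_dimensionality(self, rng):
        vec = ft.mazilu_features(rng.normal(size=(128, 3)))
        assert vec.shape == (21,)

    def test_zero_window_conventions(self):
        vec = ft.mazilu_features(np.zeros((128, 3)))
        np.testing.assert_array_equal(vec, np.zeros(21))

    def test_freeze_index_discriminates_tremble_from_gait(self):
        spec6 = ft.fft_spectrum(sine_window(6.0))[:, 0]
        spec1 = ft.fft_spectrum(sine_window(1.0))[:, 0]
        assert ft.freeze_index(spec6) > 10
        assert ft.freeze_index(spec1) < 0.1

    @given(amp=st.floats(0.01, 100.0))
    def test_freeze_index_scale_invariant(self, amp):
        base = ft.fft_spectrum(sine_window(6.0, amp=1.0))[:, 0]
        scaled = ft.fft_spectrum(sine_window(6.0, amp=amp))[:, 0]
        assert ft.freeze_index(scaled) == pytest.approx(ft.freeze_index(base),
                                                        rel=1e-6)


def bruteforce_mfcc(x, fs=40.0, n_filters=20, n_coeff=12):
    """Explicit triangle-filter loop + DCT summation (independent oracle)."""
    power = direct_dft_magnitudes(x) ** 2
    freqs = np.arange(64) * fs / 128.0
    mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)
    imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    pts = imel(np.linspace(mel(0.0), mel(fs / 2), n_filters + 2))
    energies = np.zeros(n_filters)
    for i in range(n_filters):
        lo, mid, hi = pts[i], pts[i + 1], pts[i + 2]
        for k, f in enumerate(freqs):
            if lo <= f < mid and mid > lo:
                energies[i] += power[k] * (f - lo) / (mid - lo)
            elif mid <= f < hi and hi > mid:
                energies[i] += power[k] * (hi - f) / (hi - mid)
    log_e = np.log(np.maximum(energies, 1e-10))
    # orthonormal DCT-II by direct summation
    coeffs = np.zeros(n_coeff)
    n = n_filters
    for c in range(n_coeff):
        s = sum(log_e[j] * np.cos(np.pi * c * (2 * j + 1) / (2 * n))
                for j in range(n))
        scale = np.sqrt(1.0 / (4 * n)) if c == 0 else np.sqrt(1.0 / (2 * n))
        coeffs[c] = 2 * s * scale
    return coeffs


class TestInertialMFCC:
    def test_dimensionality(self, rng):
        vec = ft.inertial_mfcc(rng.normal(size=(128, 3)))
        assert vec.shape == (36,)

    def test_matches_bruteforce_filterbank(self, rng):
        w = rng.normal(size=(128, 3))
        vec = ft.inertial_mfcc(w)
        for axis in range(3):
            np.testing.assert_allclose(
                vec[axis * 12 : (axis + 1) * 12],
                bruteforce_mfcc(w[:, axis]), atol=1e-8,
            )

    def test_zero_window_only_c0_nonzero(self):
        vec = ft.inertial_mfcc(np.zeros((128, 3)))
        per_axis = vec.reshape(3, 12)
        np.testing.assert_allclose(per_axis[:, 1:], 0, atol=1e-12)
        assert np.all(per_axis[:, 0] != 0)

    def test_too_many_coefficients_rejected(self, rng):
        with pytest.raises(ContractError):
            ft.inertial_mfcc(rng.normal(size=(128, 3)), n_coeff=21)


class TestContextualStacking:
    def test_k3_dimensionality(self, rng):
        spectra = rng.random((10, 64, 3))
        out = ft.stack_contextual(spectra, 3)
        assert out.shape == (7, 4, 64, 3)
        assert out[0].size == 768

    def test_k0_identity(self, rng):
        spectra = rng.random((5, 64, 3))
        out = ft.stack_contextual(spectra, 0)
        np.testing.assert_array_equal(out[:, 0], spectra)

    @given(n=st.integers(1, 20), k=st.integers(0, 3))
    def test_count_matches_enumeration(self, n, k):
        spectra = np.zeros((n, 64, 3))
        out = ft.stack_contextual(spectra, k)
        expected = n if k == 0 else max(n - k, 0)
        assert out.shape[0] == expected

    def test_timestep_order_oldest_to_current(self, rng):
        spectra = rng.random((6, 64, 3))
        out = ft.stack_contextual(spectra, 2)
        np.testing.assert_array_equal(out[0, 0], spectra[0])
        np.testing.assert_array_equal(out[0, 2], spectra[2])

    def test_negative_k_rejected(self):
        with pytest.raises(ContractError):
            ft.stack_contextual(np.zeros((5, 64, 3)), -1)

    def test_no_mixing_across_recordings(self, rng):
        def make_ws(subject, fill):
            wins = [Window(np.full((128, 3), fill * (i + 1), dtype=float), 0,
                           subject, i * 32) for i in range(5)]
            return WindowSet(wins, 40.0, 32, subject)

        fm = ft.extract_features([make_ws("A", 1.0), make_ws("B", 100.0)],
                                 "fft", 3)
        # each recording contributes 5 - 3 = 2 stacked rows
        assert fm.n == 4
        assert list(fm.subject_ids) == ["A", "A", "B", "B"]
        # rows tagged B must contain no spectra from A's windows: B's DC bin
        # magnitudes are ~100x A's, in every time step
        b_rows = fm.values[fm.subject_ids == "B"]
        assert b_rows[:, :, 0, :].min() > ft.fft_spectrum(
            np.full((128, 3), 5.0)).max()


class TestRepresentationDims:
    @pytest.mark.parametrize("rep,k,dim", [
        ("mazilu", 0, 21), ("mfcc", 0, 36), ("fft", 0, 192),
        ("fft", 1, 384), ("fft", 2, 576), ("fft", 3, 768),
    ])
    def test_pipeline_dimensionalities(self, rep, k, dim, windowsets_75):
        fm = ft.extract_features(windowsets_75[:1], rep, k)
        assert fm.flat.shape[1] == dim
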