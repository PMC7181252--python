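"""Feature representations for 128-sample accelerometer windows.

Three per-window representations are supported:

``mazilu``
    Seven statistical/spectral features per axis (21 total): mean, standard
    deviation, variance, spectral entropy, energy, freeze index, and total
    band power 0.5-8 Hz. The freeze index is the ratio of power in the
    freeze band (3-8 Hz) to power in the locomotion band (0.5-3 Hz) and is
    the classic single-number FOG marker.
``mfcc``
    Twelve mel-frequency cepstral coefficients per axis (36 total), with the
    mel filterbank remapped onto 0-20 Hz to suit low-frequency inertial
    signals.
``fft``
    The 64 one-sided magnitude bins of a 128-point FFT per axis (192 total),
    optionally stacked with up to three preceding windows of the same
    recording ("contextual windows", 384/576/768 values).

Band membership uses half-open intervals [f_lo, f_hi) at bin centres, so
3 Hz belongs to the freeze band. Windows are used as-is (rectangular taper):
the signal is already band-limited upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.fft import dct

from .errors import ContractError
from .io_preprocess import ANALYSIS_FS, WINDOW_SAMPLES, WindowSet

LOCOMOTION_BAND = (0.5, 3.0)
FREEZE_BAND = (3.0, 8.0)
TOTAL_BAND = (0.5, 8.0)

N_FFT = 128
N_BINS = 64
N_MEL_FILTERS = 20
N_MFCC = 12
LOG_FLOOR = 1e-10
FI_EPS = 1e-12  # locomotion power below this => freeze index 0 (standing)

REPRESENTATION_DIMS = {"mazilu": 21, "mfcc": 36, "fft": 192}


@dataclass
class BandSpec:
    """The canonical analysis bands, all within [0, fs/2]."""

    locomotion: tuple = LOCOMOTION_BAND
    freeze: tuple = FREEZE_BAND
    total: tuple = TOTAL_BAND


@dataclass
class FeatureMatrix:
    """Per-window feature vectors with their provenance.

    ``values`` is (N, D) for flat representations and (N, k+1, 64, 3) for
    contextual FFT stacks before flattening.
    """

    values: np.ndarray
    representation: str
    context_depth: int
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.subject_ids = np.asarray(self.subject_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """(N, D) view with any contextual structure flattened."""
        return self.values.reshape(self.n, -1)


def _check_window(window: np.ndarray) -> np.ndarray:
    window = np.asarray(window, dtype=float)
    if window.shape != (WINDOW_SAMPLES, 3):
        raise ContractError(
            f"expected a {WINDOW_SAMPLES}x3 window, got {window.shape}"
        )
    return window


def bin_frequencies(fs: float = ANALYSIS_FS, n_fft: int = N_FFT) -> np.ndarray:
    """Centre frequency of each of the 64 retained FFT bins (k * fs / n_fft)."""
    return np.arange(N_BINS) * fs / n_fft


def fft_spectrum(window: np.ndarray) -> np.ndarray:
    """One-sided magnitude spectrum of a window, shape (64, 3).

    Bin k corresponds to k * 40 / 128 Hz; only the first 64 of the 128 DFT
    bins are retained (the symmetric half is redundant for real signals).
    """
    window = _check_window(window)
    return np.abs(np.fft.fft(window, n=N_FFT, axis=0)[:N_BINS])


def band_power(spectrum: np.ndarray, band: Sequence[float],
               fs: float = ANALYSIS_FS) -> np.ndarray:
    """Sum of squared magnitudes over bins with centre frequency in [f_lo, f_hi).

    ``spectrum`` is (64,) or (64, n_axes); returns a scalar or per-axis array.
    """
    f_lo, f_hi = band
    if not 0 <= f_lo < f_hi <= fs / 2:
        raise ContractError(f"invalid band {band} for fs={fs}")
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[0] != N_BINS:
        raise ContractError(f"spectrum must have {N_BINS} bins, got {spectrum.shape}")
    freqs = bin_frequencies(fs)
    mask = (freqs >= f_lo) & (freqs < f_hi)
    return (spectrum[mask] ** 2).sum(axis=0)


def freeze_index(spectrum: np.ndarray, fs: float = ANALYSIS_FS) -> np.ndarray:
    """Freeze-band power over locomotion-band power, per axis.

    Standing windows have essentially no locomotion power and would blow up
    the ratio; below ``FI_EPS`` the index is defined as 0.
    """
    p_freeze = np.atleast_1d(band_power(spectrum, FREEZE_BAND, fs))
    p_loco = np.atleast_1d(band_power(spectrum, LOCOMOTION_BAND, fs))
    out = np.where(p_loco < FI_EPS, 0.0, p_freeze / np.maximum(p_loco, FI_EPS))
    return out if out.size > 1 else float(out[0])


def spectral_entropy(spectrum: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of the normalised 64-bin power spectrum.

    All-zero spectra have entropy 0 by convention.
    """
    power = np.asarray(spectrum, dtype=float) ** 2
    power = np.atleast_2d(power.T).T  # (64, n_axes)
    total = power.sum(axis=0)
    out = np.zeros(power.shape[1])
    for j in range(power.shape[1]):
        if total[j] <= 0:
            continue
        p = power[:, j] / total[j]
        nz = p > 0
        out[j] = float(-(p[nz] * np.log2(p[nz])).sum())
    return out if out.size > 1 else float(out[0])


def mazilu_features(window: np.ndarray, fs: float = ANALYSIS_FS) -> np.ndarray:
    """The 7-per-axis statistical/spectral feature set, concatenated to 21.

    Per axis: mean, standard deviation, variance, spectral entropy, energy
    (sum of squared samples), freeze index, total band power 0.5-8 Hz.
    """
    window = _check_window(window)
    spec = fft_spectrum(window)
    mean = window.mean(axis=0)
    std = window.std(axis=0)
    var = window.var(axis=0)
    entropy = np.atleast_1d(spectral_entropy(spec))
    energy = (window ** 2).sum(axis=0)
    fi = np.atleast_1d(freeze_index(spec, fs))
    p_total = np.atleast_1d(band_power(spec, TOTAL_BAND, fs))
    per_axis = np.stack([mean, std, var, entropy, energy, fi, p_total])  # (7, 3)
    return per_axis.T.reshape(-1)  # axis-major concatenation, 21 values


def mel_filterbank(n_filters: int = N_MEL_FILTERS, fs: float = ANALYSIS_FS,
                   n_fft: int = N_FFT) -> np.ndarray:
    """Triangular mel-spaced filterbank over 0 .. fs/2, shape (n_filters, 64).

    The usual speech filterbank is remapped onto the accelerometer's 0-20 Hz
    range; the mel warp is kept (mel(f) = 2595 log10(1 + f/700)) so low
    frequencies get finer resolution, which suits gait spectra.
    """

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(fs / 2), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = bin_frequencies(fs, n_fft)
    fb = np.zeros((n_filters, N_BINS))
    for i in range(n_filters):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        rising = (freqs >= lo) & (freqs < mid)
        falling = (freqs >= mid) & (freqs < hi)
        if mid > lo:
            fb[i, rising] = (freqs[rising] - lo) / (mid - lo)
        if hi > mid:
            fb[i, falling] = (hi - freqs[falling]) / (hi - mid)
    return fb


def inertial_mfcc(window: np.ndarray, fs: float = ANALYSIS_FS,
                  n_coeff: int = N_MFCC) -> np.ndarray:
    """Inertial-adapted MFCCs: 12 coefficients per axis, concatenated to 36.

    Pipeline per axis: 64-bin power spectrum -> 20 triangular mel filters on
    0-20 Hz -> log (floored at 1e-10) -> orthonormal DCT-II -> first
    ``n_coeff`` coefficients.
    """
    window = _check_window(window)
    if n_coeff > N_MEL_FILTERS:
        raise ContractError(
            f"n_coeff={n_coeff} exceeds the {N_MEL_FILTERS}-filter bank"
        )
    power = fft_spectrum(window) ** 2  # (64, 3)
    fb = mel_filterbank(fs=fs)
    energies = fb @ power  # (20, 3)
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    coeffs = dct(log_e, type=2, norm="ortho", axis=0)[:n_coeff]  # (12, 3)
    return coeffs.T.reshape(-1)  # 36 values


def stack_contextual(spectra: np.ndarray, k: int) -> np.ndarray:
    """Stack each spectrum with its k predecessors from the same recording.

    Parameters
    ----------
    spectra : (N, 64, 3) array
        Per-window spectra of ONE recording, ordered by start index.
    k : int
        Number of previous windows, 0-3 in practice.

    Returns
    -------
    (N - k, k + 1, 64, 3) array, time-step order oldest -> current. The
    first k windows of the recording have no full context and are dropped.
    """
    if k < 0:
        raise ContractError(f"context depth must be >= 0, got {k}")
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 3 or spectra.shape[1:] != (N_BINS, 3):
        raise ContractError(f"expected (N, {N_BINS}, 3) spectra, got {spectra.shape}")
    n = spectra.shape[0]
    if k == 0:
        return spectra[:, None, :, :].copy()
    if n <= k:
        return np.empty((0, k + 1, N_BINS, 3))
    return np.stack([spectra[i - k : i + 1] for i in range(k, n)])


def _windowset_spectra(ws: WindowSet) -> np.ndarray:
    if len(ws) == 0:
        return np.empty((0, N_BINS, 3))
    return np.stack([fft_spectrum(w.samples) for w in ws.windows])


def extract_features(
    windowsets: Sequence[WindowSet], representation: str, context_depth: int = 0
) -> FeatureMatrix:
    """Compute a representation for a cohort of per-recording window sets.

    Contextual stacking is performed strictly within each recording, so
    feature rows never mix windows across subjects or recordings.
    """
    if representation not in REPRESENTATION_DIMS:
        raise ContractError(f"unknown representation {representation!r}")
    if representation != "fft" and context_depth != 0:
        raise ContractError("contextual stacking only applies to the fft representation")
    chunks, labels, subjects = [], [], []
    for ws in windowsets:
        if len(ws) == 0:
            continue
        if representation == "mazilu":
            vals = np.stack([mazilu_features(w.samples, ws.fs) for w in ws.windows])
            lab = ws.labels
        elif representation == "mfcc":
            vals = np.stack([inertial_mfcc(w.samples, ws.fs) for w in ws.windows])
            lab = ws.labels
        else:
            spectra = _windowset_spectra(ws)
            vals = stack_contextual(spectra, context_depth)
            lab = ws.labels[context_depth:]
        if vals.shape[0] == 0:
            continue
        chunks.append(vals)
        labels.append(lab)
        subjects.append(np.full(vals.shape[0], ws.subject_id, dtype=object))
    if not chunks:
        dim = REPRESENTATION_DIMS[representation]
        shape = (0, context_depth + 1, N_BINS, 3) if representation == "fft" else (0, dim)
        return FeatureMatrix(np.empty(shape), representation, context_depth,
                             np.empty(0, dtype=np.int8), np.empty(0, dtype=object))
    return FeatureMatrix(
        np.concatenate(chunks), representation, context_depth,
        np.concatenate(labels), np.concatenate(subjects),
    )
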