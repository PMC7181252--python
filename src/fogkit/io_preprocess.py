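"""Recording I/O and signal preprocessing.

Waist-worn triaxial accelerometer recordings are read from plain CSV,
resampled to the 40 Hz analysis rate, band-limited to the 0.2-15 Hz range
that contains gait and freeze-of-gait (FOG) energy, and cut into 128-sample
(3.2 s) analysis windows with a majority labelling rule:

* a window is labelled FOG only if more than 50% of its samples carry the
  FOG flag;
* a window is labelled non-FOG only if *no* sample carries the flag;
* every other (mixed) window is discarded and tallied.

All sample indices are 0-based; windows are half-open ``[start, start+128)``.
Filters are applied causally (single forward pass) so the pipeline remains
usable for low-latency cueing; filter state is reset per recording, and edge
transients are kept rather than trimmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ContractError, FormatError, ValidationError

ANALYSIS_FS = 40.0
WINDOW_SAMPLES = 128
#: low-pass: order 2, 15 Hz cut-off; high-pass: order 3, 0.2 Hz cut-off
LOWPASS_ORDER, LOWPASS_CUTOFF_HZ = 2, 15.0
HIGHPASS_ORDER, HIGHPASS_CUTOFF_HZ = 3, 0.2

FOG, NONFOG = 1, 0

CSV_COLUMNS = ("subject", "t", "ax", "ay", "az", "label")


@dataclass
class Recording:
    """A single per-subject triaxial acceleration time series.

    Attributes
    ----------
    subject_id : str
    fs : float
        Sampling rate in Hz, > 0.
    accel : (T, 3) float array
        Acceleration in g, axis order x, y, z.
    labels : (T,) int array
        Per-sample binary FOG flags (1 = FOG).
    meta : dict
        Free-form provenance.
    """

    subject_id: str
    fs: float
    accel: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.accel.shape[0] != self.labels.shape[0]:
            raise ValidationError(
                f"accel has {self.accel.shape[0]} rows but labels has "
                f"{self.labels.shape[0]}"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            bad = np.setdiff1d(np.unique(self.labels), [0, 1])
            raise ValidationError(f"labels must be binary; found {bad.tolist()}")
        self.labels = self.labels.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Window:
    """One 128-sample analysis window with a resolved binary label."""

    samples: np.ndarray  # (128, 3)
    label: int  # FOG or NONFOG
    subject_id: str
    start_index: int  # 0-based offset in the source recording

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (WINDOW_SAMPLES, 3):
            raise ContractError(
                f"window must be {WINDOW_SAMPLES}x3, got {self.samples.shape}"
            )
        if self.label not in (FOG, NONFOG):
            raise ContractError(f"window label must be 0/1, got {self.label}")


@dataclass
class WindowSet:
    """Ordered windows from one recording plus windowing provenance."""

    windows: list[Window]
    fs: float
    hop: int
    subject_id: str
    n_discarded: int = 0

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=np.int8)

    @property
    def samples(self) -> np.ndarray:
        """Stack of all windows, shape (N, 128, 3)."""
        if not self.windows:
            return np.empty((0, WINDOW_SAMPLES, 3))
        return np.stack([w.samples for w in self.windows])

    @property
    def start_indices(self) -> np.ndarray:
        return np.array([w.start_index for w in self.windows], dtype=int)


def read_recording(path, fs: float = 200.0) -> Recording:
    """Read a recording from CSV with header ``subject,t,ax,ay,az,label``.

    Parameters
    ----------
    path : file path
    fs : float
        Declared sampling rate of the file (the original study devices
        sampled at 200 Hz).
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    labels = df["label"].to_numpy()
    if labels.size and not np.isin(labels, (0, 1)).all():
        bad = np.setdiff1d(np.unique(labels), [0, 1])
        raise ValidationError(f"{path}: non-binary label values {bad.tolist()}")
    subjects = df["subject"].astype(str).unique()
    if len(subjects) > 1:
        raise FormatError(f"{path}: multiple subject ids in one file: {subjects}")
    subject = subjects[0] if len(subjects) else "unknown"
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    return Recording(
        subject_id=subject, fs=fs, accel=accel, labels=labels,
        meta={"source": str(path)},
    )


def write_recording(rec: Recording, path) -> None:
    """Write a recording in the CSV dialect read by :func:`read_recording`."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(
        {
            "subject": rec.subject_id,
            "t": t,
            "ax": rec.accel[:, 0],
            "ay": rec.accel[:, 1],
            "az": rec.accel[:, 2],
            "label": rec.labels,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def resample_to(rec: Recording, fs_out: float) -> Recording:
    """Resample to ``fs_out`` Hz with a polyphase anti-aliasing filter.

    200 -> 40 Hz is a clean 1:5 decimation; the anti-aliasing filter keeps
    out-of-band energy from folding into the 3-8 Hz freeze band. Labels are
    resampled by nearest-neighbour on the output time grid.
    """
    if fs_out <= 0:
        raise ContractError(f"fs_out must be positive, got {fs_out}")
    if fs_out == rec.fs:
        return replace(rec, accel=rec.accel.copy(), labels=rec.labels.copy())
    if rec.n_samples == 0:
        return replace(rec, fs=fs_out, accel=rec.accel.copy(),
                       labels=rec.labels.copy())
    ratio = Fraction(fs_out / rec.fs).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    accel = signal.resample_poly(rec.accel, up, down, axis=0)
    n_out = accel.shape[0]
    # nearest source sample for each output instant
    idx = np.clip(np.round(np.arange(n_out) * rec.fs / fs_out).astype(int),
                  0, rec.n_samples - 1)
    labels = rec.labels[idx]
    meta = dict(rec.meta, resampled_from_hz=rec.fs)
    return Recording(rec.subject_id, fs_out, accel, labels, meta)


def butterworth_cascade(fs: float = ANALYSIS_FS):
    """(b, a) pairs of the low-pass then high-pass Butterworth stages."""
    lp = signal.butter(LOWPASS_ORDER, LOWPASS_CUTOFF_HZ, "lowpass", fs=fs)
    hp = signal.butter(HIGHPASS_ORDER, HIGHPASS_CUTOFF_HZ, "highpass", fs=fs)
    return lp, hp


def bandlimit(rec: Recording) -> Recording:
    """Causal band-limiting to 0.2-15 Hz at the 40 Hz analysis rate.

    Applies a second-order 15 Hz low-pass (sensor noise) followed by a
    third-order 0.2 Hz high-pass (gravity/orientation drift), each as a
    single causal pass per axis. Labels are untouched.
    """
    if not np.isclose(rec.fs, ANALYSIS_FS):
        raise ContractError(
            f"bandlimit is defined at fs={ANALYSIS_FS} Hz, got {rec.fs}"
        )
    (b_lp, a_lp), (b_hp, a_hp) = butterworth_cascade(rec.fs)
    accel = signal.lfilter(b_lp, a_lp, rec.accel, axis=0)
    accel = signal.lfilter(b_hp, a_hp, accel, axis=0)
    meta = dict(rec.meta, bandlimited=True, edge_transient_kept=True)
    return Recording(rec.subject_id, rec.fs, accel, rec.labels.copy(), meta)


def preprocess(rec: Recording, fs_out: float = ANALYSIS_FS) -> Recording:
    """Convenience composition: resample to the analysis rate then band-limit."""
    return bandlimit(resample_to(rec, fs_out))


def enumerate_starts(n_samples: int, win: int, hop: int) -> np.ndarray:
    """All valid 0-based window start indices for a length-``n_samples`` record."""
    if n_samples < win:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - win + 1, hop)


def window_and_label(
    rec: Recording, win: int = WINDOW_SAMPLES, overlap: float = 0.75
) -> WindowSet:
    """Cut a 40 Hz recording into labelled analysis windows.

    ``hop = win * (1 - overlap)``. Labelling follows the majority rule
    described in the module docstring; mixed windows are discarded and
    counted in ``WindowSet.n_discarded``.
    """
    if not np.isclose(rec.fs, ANALYSIS_FS):
        raise ContractError(f"windowing expects fs={ANALYSIS_FS}, got {rec.fs}")
    if overlap not in (0, 0.5, 0.75):
        raise ContractError(f"overlap must be one of 0, 0.5, 0.75; got {overlap}")
    hop = int(round(win * (1 - overlap)))
    if rec.n_samples < win:
        warnings.warn(
            f"recording {rec.subject_id} has {rec.n_samples} < {win} samples; "
            "empty window set", stacklevel=2,
        )
        return WindowSet([], rec.fs, hop, rec.subject_id, 0)
    windows: list[Window] = []
    n_discarded = 0
    for start in enumerate_starts(rec.n_samples, win, hop):
        seg_labels = rec.labels[start : start + win]
        n_fog = int(seg_labels.sum())
        if n_fog > win // 2:
            label = FOG
        elif n_fog == 0:
            label = NONFOG
        else:
            n_discarded += 1
            continue
        windows.append(
            Window(rec.accel[start : start + win], label, rec.subject_id, int(start))
        )
    return WindowSet(windows, rec.fs, hop, rec.subject_id, n_discarded)


def windowsets_from_recordings(
    recordings: Iterable[Recording], overlap: float = 0.75,
    fs_out: float = ANALYSIS_FS,
) -> list[WindowSet]:
    """Full preprocessing of a cohort: resample, band-limit, window each recording."""
    return [window_and_label(preprocess(r, fs_out), overlap=overlap)
            for r in recordings]
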