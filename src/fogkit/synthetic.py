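"""Synthetic waist-accelerometer cohort with labelled FOG episodes.

The generator emulates the structure the detection pipeline relies on,
without claiming biomechanical realism:

* normal gait is a quasi-periodic oscillation with its fundamental in the
  locomotion band (0.5-3 Hz) plus two decaying harmonics;
* FOG episodes replace gait with leg-trembling at a subject-specific
  dominant frequency in 6-8 Hz (inside the 3-8 Hz freeze band) over a
  reduced residue of locomotion movement;
* standing segments contain sensor noise only;
* a constant 1 g gravity offset sits on the vertical axis so the 0.2 Hz
  high-pass stage has real work to do;
* the three axes share one motion component with axis-specific gains plus
  independent noise (a waist-worn device sees one underlying trunk motion).

Recordings are sampled at 200 Hz, like the original acquisition devices,
and are meant to be pushed through ``fogkit.io_preprocess`` before any
feature extraction.

A semi-Markov walk/stand schedule is generated first; FOG episodes are then
placed inside walking segments (freezing manifests when gait is attempted)
with total episode time budgeted to the target class imbalance, 10.5% FOG
samples by default. Subject-to-subject heterogeneity (fundamental, tremble
frequency, amplitudes, noise) is what makes leave-one-subject-out evaluation
genuinely harder than within-subject cross-validation on this data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ContractError, ValidationError
from .io_preprocess import Recording, write_recording

DEFAULT_FS = 200.0

#: schedule defaults (seconds); gamma-distributed segment durations
WALK_MEAN_S, WALK_SHAPE = 25.0, 4.0
STAND_MEAN_S, STAND_SHAPE = 6.0, 4.0
EPISODE_SHAPE = 3.0
MIN_EPISODE_S = 1.5
EDGE_RAMP_S = 0.3  # raised-cosine on/off ramp of the trembling envelope


@dataclass
class SubjectProfile:
    """Per-subject signal parameters; frequencies in Hz, amplitudes in g."""

    subject_id: str
    gait_fundamental: float = 1.2  # locomotion band 0.5-3 Hz
    gait_amplitude: float = 0.3
    fog_tremble_freq: float = 7.0  # dominant FOG frequency, 6-8 Hz
    fog_amplitude: float = 0.3
    noise_sd: float = 0.03
    episode_rate: float = 1.0  # FOG episodes per minute (provenance)
    episode_duration: float = 7.0  # mean episode length, seconds
    axis_gains: tuple = (1.0, 0.6, 0.35)

    def __post_init__(self) -> None:
        if not 0.5 <= self.gait_fundamental <= 3.0:
            raise ValidationError(
                f"gait fundamental must lie in the 0.5-3 Hz locomotion band, "
                f"got {self.gait_fundamental}"
            )
        if not 6.0 <= self.fog_tremble_freq <= 8.0:
            raise ValidationError(
                f"tremble frequency must lie in 6-8 Hz, got {self.fog_tremble_freq}"
            )
        if min(self.gait_amplitude, self.fog_amplitude, self.noise_sd) < 0:
            raise ValidationError("amplitudes must be non-negative")


@dataclass
class CohortSpec:
    """Cohort-level generation parameters (defaults mirror the study design:
    21 subjects, two ~20-minute free-living recordings each, 10.5% FOG)."""

    n_subjects: int = 21
    recording_minutes: float = 20.0
    n_recordings: int = 2
    target_fog_fraction: float = 0.105
    amplitude_contrast: float = 1.0  # FOG/gait amplitude ratio scale (difficulty knob)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_fog_fraction < 1:
            raise ValidationError("target_fog_fraction must be in (0, 1)")
        if self.n_subjects < 1:
            raise ContractError("need at least one subject")


def draw_profile(subject_id: str, rng: np.random.Generator,
                 amplitude_contrast: float = 1.0) -> SubjectProfile:
    """Draw one subject's parameters from the documented cohort distributions."""
    gait_amp = rng.uniform(0.2, 0.4)
    return SubjectProfile(
        subject_id=subject_id,
        gait_fundamental=rng.uniform(0.9, 1.4),
        gait_amplitude=gait_amp,
        fog_tremble_freq=rng.uniform(6.0, 8.0),
        fog_amplitude=gait_amp * amplitude_contrast * rng.uniform(0.8, 1.2),
        noise_sd=rng.uniform(0.02, 0.05),
        episode_rate=rng.uniform(0.6, 1.4),
        episode_duration=rng.uniform(5.0, 9.0),
        axis_gains=(1.0, rng.uniform(0.4, 0.8), rng.uniform(0.2, 0.5)),
    )


# ---------------------------------------------------------------------------
# schedule


def _walk_stand_schedule(duration: float, rng: np.random.Generator):
    """Alternating (state, start, end) walk/stand segments covering [0, duration)."""
    segments = []
    t = 0.0
    state = "walk"
    while t < duration:
        if state == "walk":
            seg = rng.gamma(WALK_SHAPE, WALK_MEAN_S / WALK_SHAPE)
        else:
            seg = rng.gamma(STAND_SHAPE, STAND_MEAN_S / STAND_SHAPE)
        end = min(t + max(seg, 1.0), duration)
        segments.append((state, t, end))
        t = end
        state = "stand" if state == "walk" else "walk"
    return segments


def _place_episodes(segments, duration: float, profile: SubjectProfile,
                    rng: np.random.Generator,
                    target_fog_fraction: float | None) -> list[tuple[float, float]]:
    """Non-overlapping FOG intervals inside walking segments.

    With a target fraction, episode durations are drawn until the total FOG
    time budget ``target * duration`` is met (last episode truncated), so
    the realised class ratio tracks the schedule; otherwise the count comes
    from the profile's episode rate.
    """
    walk_segs = [(s, e) for st, s, e in segments if st == "walk"]
    if not walk_segs or duration <= 0:
        return []
    if target_fog_fraction is not None:
        budget = target_fog_fraction * duration
        durations = []
        total = 0.0
        while total < budget:
            d = max(rng.gamma(EPISODE_SHAPE, profile.episode_duration / EPISODE_SHAPE),
                    MIN_EPISODE_S)
            d = min(d, budget - total) if budget - total > MIN_EPISODE_S else budget - total
            if d <= 0:
                break
            durations.append(max(d, 0.5))
            total += durations[-1]
    else:
        n = rng.poisson(profile.episode_rate * duration / 60.0)
        durations = [
            max(rng.gamma(EPISODE_SHAPE, profile.episode_duration / EPISODE_SHAPE),
                MIN_EPISODE_S)
            for _ in range(n)
        ]
    # place longest first into remaining walking gaps; a 0.25 s margin on
    # both sides keeps episodes separated, so label runs map 1:1 to episodes
    margin = 0.25
    gaps = sorted(walk_segs, key=lambda g: g[0])
    episodes: list[tuple[float, float]] = []
    for d in sorted(durations, reverse=True):
        candidates = [i for i, (s, e) in enumerate(gaps)
                      if e - s >= d + 2 * margin]
        if not candidates:
            raise ContractError(
                "cannot place FOG episodes: walking time exhausted; the target "
                "FOG fraction is infeasible with these schedule parameters"
            )
        i = candidates[int(rng.integers(len(candidates)))]
        s, e = gaps.pop(i)
        start = rng.uniform(s + margin, e - d - margin)
        episodes.append((start, start + d))
        if start - s > 2 * margin:
            gaps.append((s, start))
        if e - (start + d) > 2 * margin:
            gaps.append((start + d, e))
    return sorted(episodes)


# ---------------------------------------------------------------------------
# signal synthesis


def simulate_subject(
    profile: SubjectProfile,
    duration: float,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    target_fog_fraction: float | None = 0.105,
) -> Recording:
    """Synthesize one labelled recording for a subject.

    Returns a :class:`Recording` at ``fs`` Hz (200 by default) whose labels
    mark FOG samples. ``target_fog_fraction=None`` falls back to the
    profile's episode rate instead of budgeting episode time.
    """
    if duration < 0:
        raise ContractError(f"duration must be >= 0, got {duration}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    if n == 0:
        return Recording(profile.subject_id, fs, np.empty((0, 3)),
                         np.empty(0, dtype=np.int8), {"profile": asdict(profile)})
    t = np.arange(n) / fs
    segments = _walk_stand_schedule(duration, rng)
    episodes = _place_episodes(segments, duration, profile, rng,
                               target_fog_fraction)

    labels = np.zeros(n, dtype=np.int8)
    fog_env = np.zeros(n)
    for start, end in episodes:
        i0, i1 = int(np.floor(start * fs)), min(int(np.floor(end * fs)), n)
        labels[i0:i1] = 1
        ramp = min(int(EDGE_RAMP_S * fs), max((i1 - i0) // 4, 1))
        env = np.ones(i1 - i0)
        up = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp) / ramp)
        env[:ramp] = up
        env[-ramp:] = up[::-1]
        fog_env[i0:i1] = env

    walk_mask = np.zeros(n, dtype=bool)
    for state, s, e in segments:
        if state == "walk":
            walk_mask[int(np.floor(s * fs)) : min(int(np.floor(e * fs)), n)] = True
    fog_mask = labels == 1
    walk_only = walk_mask & ~fog_mask

    f0 = profile.gait_fundamental
    phases = rng.uniform(0, 2 * np.pi, size=4)
    gait = profile.gait_amplitude * (
        np.sin(2 * np.pi * f0 * t + phases[0])
        + 0.4 * np.sin(2 * np.pi * 2 * f0 * t + phases[1])
        + 0.15 * np.sin(2 * np.pi * 3 * f0 * t + phases[2])
    )
    gait *= 1.0 + 0.2 * np.sin(2 * np.pi * 0.08 * t)  # slow stride modulation
    tremble = profile.fog_amplitude * np.sin(
        2 * np.pi * profile.fog_tremble_freq * t + phases[3]
    )

    motion = np.zeros(n)
    motion[walk_only] = gait[walk_only]
    # trembling over a reduced locomotion residue during FOG
    motion[fog_mask] = (fog_env[fog_mask] * tremble[fog_mask]
                        + 0.25 * gait[fog_mask])

    gains = np.asarray(profile.axis_gains)
    accel = motion[:, None] * gains[None, :]
    accel += rng.normal(0.0, profile.noise_sd, size=(n, 3))
    accel[:, 2] += 1.0  # gravity on the vertical axis

    meta = {
        "profile": asdict(profile),
        "seed": seed,
        "n_fog_episodes": len(episodes),
        "fog_fraction": float(fog_mask.mean()),
        "target_fog_fraction": target_fog_fraction,
    }
    return Recording(profile.subject_id, fs, accel, labels, meta)


def simulate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate the full cohort: ``n_recordings`` per subject.

    Raises a diagnostic error if the realised cohort FOG sample fraction
    lands more than 2 percentage points from the target.
    """
    root = np.random.SeedSequence(spec.seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    recordings: list[Recording] = []
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        profile = draw_profile(sid, profile_rng, spec.amplitude_contrast)
        for j in range(spec.n_recordings):
            rec_seed = int(np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed,
                                       spawn_key=(i, j))).integers(2**31 - 1))
            recordings.append(
                simulate_subject(profile, spec.recording_minutes * 60.0,
                                 seed=rec_seed,
                                 target_fog_fraction=spec.target_fog_fraction)
            )
    realized = cohort_fog_fraction(recordings)
    if abs(realized - spec.target_fog_fraction) > 0.02:
        raise ContractError(
            f"realised FOG fraction {realized:.4f} is more than 2 points from "
            f"target {spec.target_fog_fraction:.4f}; schedule parameters are "
            "infeasible for this target"
        )
    return recordings


def cohort_fog_fraction(recordings) -> float:
    """Fraction of FOG-labelled samples over all recordings."""
    n_fog = sum(int(r.labels.sum()) for r in recordings)
    n_all = sum(r.n_samples for r in recordings)
    return n_fog / n_all if n_all else 0.0


def export_cohort(recordings: list[Recording], out_dir) -> Path:
    """Write per-recording CSVs plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    counts: dict[str, int] = {}
    for rec in recordings:
        k = counts.get(rec.subject_id, 0)
        counts[rec.subject_id] = k + 1
        name = f"{rec.subject_id}_rec{k}.csv"
        write_recording(rec, out_dir / name)
        manifest.append({
            "file": name, "subject": rec.subject_id, "fs": rec.fs,
            "n_samples": rec.n_samples,
            "fog_fraction": float(rec.labels.mean()) if rec.n_samples else 0.0,
            "meta": {k2: v for k2, v in rec.meta.items() if k2 != "profile"},
            "profile": rec.meta.get("profile"),
        })
    path = out_dir / "cohort_manifest.json"
    path.write_text(json.dumps(
        {"cohort_fog_fraction": cohort_fog_fraction(recordings),
         "recordings": manifest}, indent=2))
    return path
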