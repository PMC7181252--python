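"""Subject-wise evaluation of FOG detectors.

Two cross-validation schemes are provided:

LOSO (leave-one-subject-out, "generic model")
    One fold per held-out subject; the detector never sees any window of
    the test subject, and contextual spectral stacks are built strictly
    within recordings, so no information can leak across the subject
    boundary. The whole pass is repeated (six times by default, differing
    only in training seed and shuffling) and fold metrics are averaged.

R10fold (random 10-fold within one subject, "personalised model")
    Windows of a single subject are randomly split into ten folds. With
    overlapped windows, train and test folds inevitably share raw samples;
    the harness quantifies that leakage (count of test windows whose sample
    interval intersects a training window) instead of hiding it. Folds are
    random by design to reproduce the optimistic-personal-model phenomenon;
    pass ``grouped=True`` for contiguous (lower-leakage) blocks.

Metrics per fold: ROC AUC (trapezoidal), the equal-error operating point
(threshold where sensitivity and specificity are closest, ties resolved
toward the lower threshold), sensitivity, specificity, their geometric
mean, and the EER itself. Aggregates are arithmetic means over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .errors import ContractError, UndefinedMetricError
from .features import extract_features
from .io_preprocess import WINDOW_SAMPLES, WindowSet
from .models import ALL_KINDS, TrainConfig, fit_detector

METRIC_NAMES = ("sensitivity", "specificity", "gm", "auc", "eer")


@dataclass
class ModelSpec:
    """What to train in each fold."""

    kind: str
    context_depth: int = 0
    cfg: Optional[TrainConfig] = None

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ContractError(f"unknown detector kind {self.kind!r}")
        if self.kind != "cnn_lstm" and self.context_depth != 0:
            # contextual stacks are only consumed by the sequence model
            raise ContractError(
                f"context_depth={self.context_depth} is only valid for cnn_lstm"
            )


@dataclass
class EvalReport:
    """Per-fold metrics plus their mean, with full provenance."""

    scheme: str
    per_fold: list[dict]
    repeats: int
    aggregate: dict
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([
            {k: v for k, v in fold.items() if k not in ("scores", "labels")}
            for fold in self.per_fold
        ])
        return df


def _aggregate(per_fold: Sequence[dict]) -> dict:
    return {m: float(np.mean([f[m] for f in per_fold])) for m in METRIC_NAMES}


# ---------------------------------------------------------------------------
# ROC metrics


def roc_metrics(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC summary at the equal-error operating point.

    AUC is the trapezoidal area under the ROC. The operating threshold is
    the one minimising |sensitivity - specificity|; among ties the lower
    threshold wins. EER is the mean of the two error rates there, so at an
    exact crossing EER = 1 - sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ContractError("scores and labels must have matching length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise UndefinedMetricError(
            f"ROC metrics need both classes; labels contain only {classes.tolist()}"
        )
    fpr, tpr, thresholds = skmetrics.roc_curve(labels, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    diff = np.abs(tpr - (1.0 - fpr))
    # thresholds are descending: the last minimiser is the lowest threshold
    idx = len(diff) - 1 - int(np.argmin(diff[::-1]))
    sens = float(tpr[idx])
    spec = float(1.0 - fpr[idx])
    eer = float(((1.0 - sens) + (1.0 - spec)) / 2.0)
    return {
        "auc": auc,
        "eer": eer,
        "threshold_at_eer": float(thresholds[idx]),
        "sensitivity": sens,
        "specificity": spec,
        "gm": float(np.sqrt(max(sens, 0.0) * max(spec, 0.0))),
    }


# ---------------------------------------------------------------------------
# feature plumbing


def _features_for(spec: ModelSpec, windowsets: Sequence[WindowSet]):
    """(X, y, subjects) in the layout the detector kind expects."""
    if spec.kind == "cnn_lstm":
        fm = extract_features(windowsets, "fft", spec.context_depth)
        return fm.values, fm.labels, fm.subject_ids
    fm = extract_features(windowsets, "fft", 0)
    if spec.kind == "cnn":
        return fm.values[:, 0], fm.labels, fm.subject_ids
    return fm.flat, fm.labels, fm.subject_ids


def _fold_seed(seed: int, repeat: int, fold: int) -> int:
    return int((seed * 100003 + repeat * 211 + fold * 7) % (2**31 - 1))


# ---------------------------------------------------------------------------
# LOSO


def loso_evaluate(
    windowsets: Sequence[WindowSet],
    spec: ModelSpec,
    repeats: int = 6,
    seed: int = 0,
    keep_scores: bool = True,
) -> EvalReport:
    """Leave-one-subject-out evaluation over per-recording window sets.

    ``windowsets`` may contain several recordings per subject; folds are
    formed at the subject level. Features are computed per recording (so
    contextual stacks never span recordings) and detector normalisation is
    fitted on the training fold only, inside :func:`fogkit.models.fit_detector`.
    """
    by_subject: dict[str, list[WindowSet]] = {}
    for ws in windowsets:
        by_subject.setdefault(ws.subject_id, []).append(ws)
    subjects = sorted(by_subject)
    if len(subjects) < 2:
        raise ContractError(f"LOSO needs >= 2 subjects, got {len(subjects)}")
    per_fold: list[dict] = []
    for r in range(repeats):
        for i, held_out in enumerate(subjects):
            train_sets = [ws for s in subjects if s != held_out
                          for ws in by_subject[s]]
            test_sets = by_subject[held_out]
            x_tr, y_tr, subj_tr = _features_for(spec, train_sets)
            x_te, y_te, subj_te = _features_for(spec, test_sets)
            if held_out in set(subj_tr.tolist()):  # leakage audit, hard assert
                raise ContractError(
                    f"leakage: held-out subject {held_out} present in training fold"
                )
            fold_seed = _fold_seed(seed, r, i)
            cfg = replace(spec.cfg, seed=fold_seed) if spec.cfg else None
            det = fit_detector(spec.kind, x_tr, y_tr, cfg=cfg,
                               context_depth=spec.context_depth, seed=fold_seed)
            scores = det.score(x_te)
            fold = {"repeat": r, "held_out_subject": held_out,
                    "n_test": int(len(y_te)), "seed": fold_seed}
            fold.update(roc_metrics(scores, y_te))
            if keep_scores:
                fold["scores"] = scores
                fold["labels"] = np.asarray(y_te)
            per_fold.append(fold)
    return EvalReport(
        scheme="loso",
        per_fold=per_fold,
        repeats=repeats,
        aggregate=_aggregate(per_fold),
        provenance={
            "seed": seed,
            "model": spec.kind,
            "context_depth": spec.context_depth,
            "n_subjects": len(subjects),
            "leakage_audit": "train/test subject sets disjoint in every fold",
        },
    )


# ---------------------------------------------------------------------------
# R10fold


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Random folds dealt round-robin per class, so each fold sees both."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, w in enumerate(idx):
            folds[j % n_folds].append(int(w))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def count_sample_sharing(starts_test: np.ndarray, starts_train: np.ndarray,
                         win: int = WINDOW_SAMPLES) -> int:
    """Number of test windows whose [start, start+win) interval overlaps any
    training window of the same recording."""
    starts_train = np.sort(np.asarray(starts_train))
    n = 0
    for s in np.asarray(starts_test):
        lo = np.searchsorted(starts_train, s - win + 1)
        if lo < len(starts_train) and starts_train[lo] < s + win:
            n += 1
    return n


def r10fold_evaluate(
    subject_windows: WindowSet,
    spec: ModelSpec,
    seed: int = 0,
    n_folds: int = 10,
    grouped: bool = False,
    keep_scores: bool = True,
) -> EvalReport:
    """Random 10-fold cross-validation inside one subject's window set.

    Reports per-fold metrics plus a leakage figure: how many test windows
    share raw samples with at least one training window (always positive
    with 75% overlap, which is exactly why personalised R10fold results are
    optimistic). ``grouped=True`` uses contiguous blocks instead of random
    assignment, which removes sharing except at block boundaries.
    """
    n = len(subject_windows)
    if n < n_folds:
        raise ContractError(f"need >= {n_folds} windows, got {n}")
    labels = subject_windows.labels
    if len(np.unique(labels)) < 2:
        raise ContractError("subject has a single class; R10fold metrics undefined")
    x_all, y_all, _ = _features_for(spec, [subject_windows])
    offset = len(subject_windows) - len(y_all)  # windows dropped by stacking
    starts = subject_windows.start_indices[offset:]
    rng = np.random.default_rng(seed)
    if grouped:
        bounds = np.linspace(0, len(y_all), n_folds + 1).astype(int)
        folds = [np.arange(bounds[i], bounds[i + 1]) for i in range(n_folds)]
    else:
        folds = _stratified_folds(y_all, n_folds, rng)
    per_fold: list[dict] = []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(len(y_all), dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        fold_seed = _fold_seed(seed, 0, i)
        cfg = replace(spec.cfg, seed=fold_seed) if spec.cfg else None
        det = fit_detector(spec.kind, x_all[train_idx], y_all[train_idx],
                           cfg=cfg, context_depth=spec.context_depth,
                           seed=fold_seed)
        scores = det.score(x_all[test_idx])
        shared = count_sample_sharing(starts[test_idx], starts[train_idx])
        fold = {"fold": i, "n_test": int(len(test_idx)), "seed": fold_seed,
                "n_test_windows_sharing_samples": shared}
        fold.update(roc_metrics(scores, y_all[test_idx]))
        if keep_scores:
            fold["scores"] = scores
            fold["labels"] = y_all[test_idx]
        per_fold.append(fold)
    aggregate = _aggregate(per_fold)
    aggregate["n_test_windows_sharing_samples"] = int(
        sum(f["n_test_windows_sharing_samples"] for f in per_fold)
    )
    return EvalReport(
        scheme="r10fold",
        per_fold=per_fold,
        repeats=1,
        aggregate=aggregate,
        provenance={"seed": seed, "model": spec.kind,
                    "subject": subject_windows.subject_id,
                    "grouped": grouped, "n_windows": n},
    )


# ---------------------------------------------------------------------------
# reporting


def report(results: dict[str, EvalReport], out_dir, make_plots: bool = True) -> dict:
    """Write one metrics table plus a mean ROC curve per report.

    ``results`` maps a row name (e.g. a model or context depth) to its
    report. Emits ``metrics.csv`` (one row per report, mean metrics),
    ``folds_<name>.csv`` and, when scores were kept and ``make_plots`` is
    set, ``roc_<name>.png``. File names are deterministic. Returns the
    paths written.
    """
    if not results:
        raise ContractError("report needs at least one EvalReport")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    rows = []
    for name, rep in sorted(results.items()):
        row = {"name": name, "scheme": rep.scheme, "repeats": rep.repeats}
        row.update({m: rep.aggregate[m] for m in METRIC_NAMES})
        rows.append(row)
        fold_path = out_dir / f"folds_{name}.csv"
        rep.to_frame().to_csv(fold_path, index=False, float_format="%.6f")
        written[f"folds_{name}"] = fold_path
        if make_plots and rep.per_fold and "scores" in rep.per_fold[0]:
            written[f"roc_{name}"] = _roc_plot(rep, out_dir / f"roc_{name}.png", name)
    table_path = out_dir / "metrics.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False, float_format="%.6f")
    written["metrics"] = table_path
    return written


def _roc_plot(rep: EvalReport, path: Path, name: str) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    grid = np.linspace(0, 1, 101)
    tprs = []
    for fold in rep.per_fold:
        fpr, tpr, _ = skmetrics.roc_curve(fold["labels"], fold["scores"])
        tprs.append(np.interp(grid, fpr, tpr))
        ax.plot(fpr, tpr, color="grey", alpha=0.25, lw=0.8)
    ax.plot(grid, np.mean(tprs, axis=0), color="C0", lw=2,
            label=f"mean ROC (AUC={rep.aggregate['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{name} ({rep.scheme})")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
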