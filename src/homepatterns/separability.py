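"""Time-of-day separability via a multiclass linear SVM.

Each (logical day, ToD phase) pair becomes one 6-feature sample — busyness
and TE for the three rooms — labelled by its phase.  A one-vs-rest linear
SVM trained on a randomized 70% of days then measures, through per-phase
F-scores on the held-out days, how distinguishable each time of day's
activity signature is.  Sweeping the dataset size (78, 57, 36 and 22 days,
i.e. learning sets of 55, 40, 25 and 15 days) probes how many days are
needed for a stable behavioural baseline.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .events import N_PHASES
from .features import ROOMS, FAMILIES, DaySplit, feature_name, split_days

#: Per-sample feature order: busyness and TE for each room.
SAMPLE_FEATURES = tuple(f"{room}_{family}" for room in ROOMS for family in FAMILIES)


def _unstack_days(day_frames: Mapping[str, pd.DataFrame],
                  days: Sequence[dt.date]) -> tuple[pd.DataFrame, np.ndarray]:
    """One row per (user, day, phase) with 6 features; labels = phase id."""
    blocks, labels = [], []
    for user_id, frame in day_frames.items():
        sel = frame.loc[frame.index.isin(set(days))]
        for p in range(1, N_PHASES + 1):
            cols = [feature_name(room, family, p)
                    for room in ROOMS for family in FAMILIES]
            block = sel[cols].copy()
            block.columns = list(SAMPLE_FEATURES)
            block.index = pd.MultiIndex.from_arrays(
                [[user_id] * len(block), block.index, [p] * len(block)],
                names=["user_id", "logical_day", "phase"])
            blocks.append(block)
            labels.append(np.full(len(block), p))
    X = pd.concat(blocks)
    return X, np.concatenate(labels)


def build_tod_samples(day_frames: Mapping[str, pd.DataFrame], split: DaySplit,
                      ) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray]:
    """Unstack day-level 42-feature rows into labelled per-phase samples."""
    X_train, y_train = _unstack_days(day_frames, split.train_days)
    X_test, y_test = _unstack_days(day_frames, split.test_days)
    return X_train, y_train, X_test, y_test


def fit_predict_svm(X_train: pd.DataFrame | np.ndarray, y_train: np.ndarray,
                    X_test: pd.DataFrame | np.ndarray,
                    C: float = 1.0) -> np.ndarray:
    """One-vs-rest linear SVM; features z-scored on train statistics."""
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.asarray(X_test, dtype=float)
    if Xtr.shape[0] == 0:
        raise ValueError("empty training set")
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LinearSVC(C=C, dual="auto", max_iter=20000, random_state=0)
    clf.fit((Xtr - mu) / sd, y_train)
    return clf.predict((Xte - mu) / sd)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = N_PHASES) -> np.ndarray:
    """n x n count matrix, rows = true phase, cols = predicted phase."""
    conf = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)):
        conf[t - 1, p - 1] += 1
    return conf


def f_measure(confusion: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class and macro F-score from a square count matrix.

    F = 2PR/(P+R) with precision over predicted counts and recall over true
    counts; any zero denominator yields F = 0 for that class.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1] or (conf < 0).any():
        raise ValueError("confusion must be a square nonnegative count matrix")
    tp = np.diag(conf)
    pred = conf.sum(axis=0)
    true = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, tp / pred, 0.0)
        recall = np.where(true > 0, tp / true, 0.0)
        denom = precision + recall
        f = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return f, float(f.mean())


@dataclass(frozen=True)
class SeparabilityResult:
    """Per-phase ToD separability at one dataset size."""

    dataset_size_days: int
    learning_days: int
    per_phase_f: tuple[float, ...]
    macro_f: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "dataset_size_days": self.dataset_size_days,
            "learning_days": self.learning_days,
            "per_phase_f": list(self.per_phase_f),
            "macro_f": self.macro_f,
            "confusion": self.confusion.tolist(),
        }


def evaluate_size(day_frames: Mapping[str, pd.DataFrame],
                  days: Sequence[dt.date], seed: int,
                  C: float = 1.0) -> SeparabilityResult:
    """Split the given days 70/30, fit the SVM and score the test phases."""
    split = split_days(days, 0.7, seed)
    X_train, y_train, X_test, y_test = build_tod_samples(day_frames, split)
    y_pred = fit_predict_svm(X_train, y_train, X_test, C=C)
    conf = confusion_counts(y_test, y_pred)
    per_phase, macro = f_measure(conf)
    return SeparabilityResult(len(days), len(split.train_days),
                              tuple(per_phase), macro, conf)


def size_sweep(day_frames: Mapping[str, pd.DataFrame],
               sizes: Sequence[int] = (78, 57, 36, 22),
               seed: int = 0) -> dict[int, SeparabilityResult]:
    """Separability across dataset sizes (first ``size`` shared logical days).

    All users' frames must cover at least ``max(sizes)`` common days; a
    single shared day split is used so every user contributes the same
    train/test days, and each size truncates to the earliest days.
    """
    all_days = sorted(set.intersection(
        *(set(frame.index) for frame in day_frames.values())))
    results: dict[int, SeparabilityResult] = {}
    for size in sizes:
        if len(all_days) < size:
            raise ValueError(
                f"need {size} shared days, have {len(all_days)}"
                f" (short by {size - len(all_days)})")
        results[size] = evaluate_size(day_frames, all_days[:size], seed)
    return results
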