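"""LOF-threshold calibration and ROC/AUC machinery.

The detector's one real hyperparameter is the LOF decision threshold.  Given
recordings with annotated bad channels, the optimal threshold is found by
exhaustive grid search (default 1.0-5.0 in steps of 0.1) maximizing the F1
score, wrapped in repeated-split cross-validation (default 10 folds, 50%
test size).  Recordings from the same subject can be kept on one side of
every split (group shuffling) to avoid subject-specific leakage.

Confusion counts are pooled across the recordings of a split before F1 is
computed; this stays well defined when individual recordings contain no bad
channels.  Ties in the grid search resolve toward the smallest (most
sensitive) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from sklearn.model_selection import GroupShuffleSplit, ShuffleSplit

from .containers import ChannelMatrix
from .detect import detect_flatlines
from .errors import CalibrationDegenerateError, ParameterError, SplitInfeasibleError
from .lof import DistanceSpec, lof_scores

__all__ = [
    "ConfusionCounts",
    "LabeledDataset",
    "CalibrationResult",
    "f1_score",
    "confusion_counts",
    "threshold_grid_search",
    "kfold_calibrate",
    "roc_auc",
    "DEFAULT_GRID",
]

DEFAULT_GRID = (1.0, 5.0, 0.1)


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.FN + other.FN, self.TN + other.TN
        )

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_counts(predicted, truth) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ParameterError("predicted and truth must have the same shape")
    return ConfusionCounts(
        TP=int(np.sum(predicted & truth)),
        FP=int(np.sum(predicted & ~truth)),
        FN=int(np.sum(~predicted & truth)),
        TN=int(np.sum(~predicted & ~truth)),
    )


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); 0 by convention when that denominator is 0."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        return 0.0
    return 2.0 * c.TP / denom


@dataclass
class LabeledDataset:
    """Recordings with per-channel bad-channel ground truth.

    ``group_ids`` (optional) identify the subject each recording came from,
    enabling group-shuffled splitting.
    """

    recordings: list[ChannelMatrix]
    truth: list[np.ndarray]
    group_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(self.recordings) != len(self.truth):
            raise ParameterError("one truth vector per recording required")
        self.truth = [np.asarray(t, dtype=bool) for t in self.truth]
        for rec, t in zip(self.recordings, self.truth):
            if t.shape[0] != rec.n_channels:
                raise ParameterError("truth length must match channel count")
        if self.group_ids is not None and len(self.group_ids) != len(self.recordings):
            raise ParameterError("one group id per recording required")

    def __len__(self) -> int:
        return len(self.recordings)


@dataclass
class CalibrationResult:
    per_fold_threshold: list[float]
    per_fold_train_f1: list[float]
    per_fold_test_f1: list[float]
    mean_threshold: float
    threshold_spread: float  # standard deviation across folds
    mean_test_f1: float
    grid: tuple[float, float, float]
    fold_assignments: list[dict] = field(default_factory=list)


def _grid_points(grid) -> np.ndarray:
    lo, hi, step = grid
    if not (lo > 0 and hi > lo and step > 0):
        raise ParameterError(f"invalid grid {grid}")
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


def _score_recordings(ds: LabeledDataset, spec: DistanceSpec, k, flatline: bool):
    """Per recording: (lof scores with NaN at flat channels, flat flags)."""
    scored = []
    for rec in ds.recordings:
        if flatline:
            flat = detect_flatlines(rec)
        else:
            flat = np.zeros(rec.n_channels, dtype=bool)
        keep = np.flatnonzero(~flat)
        lof = np.full(rec.n_channels, np.nan)
        if keep.size >= 3:
            lof[keep] = lof_scores(rec.subset(keep), spec, k).lof
        scored.append((lof, flat))
    return scored


def _pooled_confusion(scored, truths, thr: float) -> ConfusionCounts:
    total = ConfusionCounts()
    for (lof, flat), truth in zip(scored, truths):
        with np.errstate(invalid="ignore"):
            pred = flat | np.greater(lof, thr, where=~np.isnan(lof), out=np.zeros(lof.shape, bool))
        total = total + confusion_counts(pred, truth)
    return total


def _grid_search_scored(scored, truths, grid):
    points = _grid_points(grid)
    f1s = np.array([f1_score(_pooled_confusion(scored, truths, t)) for t in points])
    best = int(np.argmax(f1s))  # argmax takes the first maximum -> smallest threshold
    return float(points[best]), float(f1s[best])


def threshold_grid_search(
    train: LabeledDataset,
    spec: Optional[DistanceSpec] = None,
    grid=DEFAULT_GRID,
    k: Union[int, str] = "auto",
    flatline: bool = True,
) -> tuple[float, float]:
    """Exhaustively search the threshold grid for maximal pooled F1.

    Returns ``(best_threshold, best_f1)``.
    """
    if spec is None:
        spec = DistanceSpec()
    if len(train) == 0:
        raise CalibrationDegenerateError("empty training set")
    if not any(t.any() for t in train.truth):
        raise CalibrationDegenerateError("no bad channels in the training set")
    scored = _score_recordings(train, spec, k, flatline)
    return _grid_search_scored(scored, train.truth, grid)


def kfold_calibrate(
    ds: LabeledDataset,
    n_folds: int = 10,
    test_fraction: float = 0.5,
    grouped: bool = False,
    seed: int = 0,
    spec: Optional[DistanceSpec] = None,
    grid=DEFAULT_GRID,
    k: Union[int, str] = "auto",
    flatline: bool = True,
) -> CalibrationResult:
    """Repeated-split cross-validated threshold calibration.

    Each fold draws a random train/test split of the *recordings* (whole
    groups move together when ``grouped``); the threshold grid is searched
    on the training recordings and the resulting F1 is reported on the test
    recordings.
    """
    if spec is None:
        spec = DistanceSpec()
    if n_folds < 1:
        raise ParameterError("n_folds must be >= 1")
    if not 0 < test_fraction < 1:
        raise ParameterError("test_fraction must be in (0, 1)")
    if grouped:
        if ds.group_ids is None:
            raise SplitInfeasibleError("grouped splitting requires group_ids")
        if len(set(ds.group_ids)) < 2:
            raise SplitInfeasibleError("grouped splitting requires >= 2 distinct groups")
        splitter = GroupShuffleSplit(n_splits=n_folds, test_size=test_fraction, random_state=seed)
        splits = splitter.split(np.zeros(len(ds)), groups=ds.group_ids)
    else:
        if len(ds) < 2:
            raise SplitInfeasibleError("need >= 2 recordings to split")
        splitter = ShuffleSplit(n_splits=n_folds, test_size=test_fraction, random_state=seed)
        splits = splitter.split(np.zeros(len(ds)))

    scored = _score_recordings(ds, spec, k, flatline)
    thresholds, train_f1s, test_f1s, assignments = [], [], [], []
    for fold, (train_idx, test_idx) in enumerate(splits):
        train_scored = [scored[i] for i in train_idx]
        train_truth = [ds.truth[i] for i in train_idx]
        if not any(t.any() for t in train_truth):
            raise CalibrationDegenerateError(
                f"fold {fold}: no bad channels in the training recordings"
            )
        thr, f1_train = _grid_search_scored(train_scored, train_truth, grid)
        test_scored = [scored[i] for i in test_idx]
        test_truth = [ds.truth[i] for i in test_idx]
        f1_test = f1_score(_pooled_confusion(test_scored, test_truth, thr))
        thresholds.append(thr)
        train_f1s.append(f1_train)
        test_f1s.append(f1_test)
        assignments.append({"train": [int(i) for i in train_idx],
                            "test": [int(i) for i in test_idx]})
    return CalibrationResult(
        per_fold_threshold=thresholds,
        per_fold_train_f1=train_f1s,
        per_fold_test_f1=test_f1s,
        mean_threshold=float(np.mean(thresholds)),
        threshold_spread=float(np.std(thresholds)),
        mean_test_f1=float(np.mean(test_f1s)),
        grid=tuple(grid),
        fold_assignments=assignments,
    )


def roc_auc(measure, truth, step: float = 0.005):
    """ROC curve and AUC from a [0, 1]-normalized per-channel measure.

    The decision threshold sweeps 0 -> 1 in steps of ``step``; a channel is
    predicted bad when its measure strictly exceeds the threshold.  AUC is
    the trapezoidal integral of TPR over FPR (with (0,0)/(1,1) anchors).

    Returns ``(fpr, tpr, auc)`` where fpr/tpr are the sweep values in
    threshold order.
    """
    measure = np.asarray(measure, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if measure.shape != truth.shape:
        raise ParameterError("measure and truth must have the same shape")
    if np.any(measure < -1e-12) or np.any(measure > 1 + 1e-12):
        raise ParameterError("measure must be min-max normalized to [0, 1]")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC undefined: truth contains a single class")
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    pred = measure[None, :] > thresholds[:, None]
    tpr = (pred & truth[None, :]).sum(axis=1) / n_pos
    fpr = (pred & ~truth[None, :]).sum(axis=1) / n_neg
    # integrate over the monotone curve, anchored at the corners
    fx = np.concatenate(([1.0], fpr, [0.0]))[::-1]
    fy = np.concatenate(([1.0], tpr, [0.0]))[::-1]
    auc = float(np.trapezoid(fy, fx))
    return fpr, tpr, auc
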