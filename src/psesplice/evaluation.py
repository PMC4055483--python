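"""Evaluation protocols and the intuitive (miscall-count) metric set.

Metrics are written in terms of the two miscall counts: FN, the number
of true-site sequences predicted false, and FP, the number of
false-site sequences predicted true, out of N+ positives and N-
negatives:

    Sn  = 1 - FN/N+
    Sp  = 1 - FP/N-
    Acc = 1 - (FN + FP)/(N+ + N-)
    MCC = (1 - (FN/N+ + FP/N-)) /
          sqrt((1 + (FP - FN)/N+) * (1 + (FN - FP)/N-))

This MCC is algebraically identical to the familiar confusion-matrix
form (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); it is
undefined (reported as NaN with a flag) when a factor under the square
root is non-positive, which happens only when every prediction falls in
one class.

Protocols: the jackknife (leave-one-out) test, the faster stratified
k-fold test used while searching hyperparameters, and the outer
optimization of the encoder parameters (w, lambda) with (C, gamma)
re-tuned inside every cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut

from . import classifier
from .classifier import TrainingConfig, cv_splits, grid_search
from .encoder import EncoderParams, encode_dataset
from .sequence_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    """Totals and miscall counts for one evaluation run."""

    n_pos: int
    n_neg: int
    fn: int  # true sites predicted false
    fp: int  # false sites predicted true

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one positive and one negative")
        if not 0 <= self.fn <= self.n_pos:
            raise ValueError(f"fn={self.fn} outside [0, {self.n_pos}]")
        if not 0 <= self.fp <= self.n_neg:
            raise ValueError(f"fp={self.fp} outside [0, {self.n_neg}]")

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    acc: float
    mcc: float  # NaN when undefined
    mcc_defined: bool
    note: str = ""


def miscall_metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy and MCC from miscall counts."""
    n_pos, n_neg, fn, fp = counts.n_pos, counts.n_neg, counts.fn, counts.fp
    sn = 1.0 - fn / n_pos
    sp = 1.0 - fp / n_neg
    acc = 1.0 - (fn + fp) / (n_pos + n_neg)
    f1 = 1.0 + (fp - fn) / n_pos  # = (TP + FP)/N+
    f2 = 1.0 + (fn - fp) / n_neg  # = (TN + FN)/N-
    if f1 <= 0 or f2 <= 0:
        side = "false" if f1 <= 0 else "true"
        return MetricSet(
            sn, sp, acc, float("nan"), False,
            note=f"MCC undefined: every prediction fell in the {side}-site class",
        )
    mcc = (1.0 - (fn / n_pos + fp / n_neg)) / math.sqrt(f1 * f2)
    return MetricSet(sn, sp, acc, mcc, True)


@dataclass
class EvalReport:
    """Counts, metrics and provenance for one evaluation run."""

    counts: ConfusionCounts
    metrics: MetricSet
    protocol: str
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "protocol": self.protocol,
            "counts": {
                "n_pos": self.counts.n_pos,
                "n_neg": self.counts.n_neg,
                "fn": self.counts.fn,
                "fp": self.counts.fp,
            },
            "metrics": {
                "sn": self.metrics.sn,
                "sp": self.metrics.sp,
                "acc": self.metrics.acc,
                "mcc": None if not self.metrics.mcc_defined else self.metrics.mcc,
                "mcc_defined": self.metrics.mcc_defined,
                "note": self.metrics.note,
            },
            "params": self.params,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _counts_from_predictions(
    y: np.ndarray, pred: np.ndarray
) -> ConfusionCounts:
    y = np.asarray(y)
    pred = np.asarray(pred)
    return ConfusionCounts(
        n_pos=int((y == 1).sum()),
        n_neg=int((y == -1).sum()),
        fn=int(((y == 1) & (pred == -1)).sum()),
        fp=int(((y == -1) & (pred == 1)).sum()),
    )


def _encode(ds: LabeledDataset, params: EncoderParams | None, kind: str):
    fm = encode_dataset(ds, params, kind)
    return fm.X, fm.y


def jackknife(
    ds: LabeledDataset,
    params: EncoderParams | None = None,
    c: float = 8.0,
    gamma: float = 8.0,
    kind: str = "psednc",
) -> EvalReport:
    """Leave-one-out test: each sequence is singled out in turn and the
    model is retrained on the rest at fixed (lambda, w, C, gamma).

    Deterministic; trains exactly len(ds) models. Encoding is
    per-sequence and therefore identical whichever split holds the
    sequence out, so it is computed once.
    """
    if len(ds) < 3:
        raise ValueError("jackknife needs at least 3 sequences")
    X, y = _encode(ds, params, kind)
    if np.unique(y).size < 2:
        raise ValueError("jackknife needs both classes present")
    pred = np.empty_like(y)
    for train_idx, test_idx in LeaveOneOut().split(X):
        model = classifier.fit_svc(X[train_idx], y[train_idx], c, gamma)
        pred[test_idx] = model.predict(X[test_idx])
    counts = _counts_from_predictions(y, pred)
    return EvalReport(
        counts,
        miscall_metrics(counts),
        "jackknife",
        params={
            "lam": params.lam if params else None,
            "w": params.weight if params else None,
            "C": c,
            "gamma": gamma,
            "kind": kind,
        },
    )


def kfold(
    ds: LabeledDataset,
    params: EncoderParams | None = None,
    config: TrainingConfig | None = None,
    c: float | None = None,
    gamma: float | None = None,
    kind: str = "psednc",
) -> EvalReport:
    """Stratified k-fold test; miscalls aggregated over held-out folds.

    If (C, gamma) are not supplied they are first tuned once on the full
    data by grid search under the same fold configuration. With
    cv_folds equal to the dataset size the split degenerates to
    leave-one-out and reproduces the jackknife exactly.
    """
    if config is None:
        config = TrainingConfig()
    X, y = _encode(ds, params, kind)
    if np.unique(y).size < 2:
        raise ValueError("k-fold evaluation needs both classes present")
    tuned = False
    if c is None or gamma is None:
        gs = grid_search(X, y, config)
        c, gamma = gs.c, gs.gamma
        tuned = True
    if config.cv_folds == len(y):
        splits = list(LeaveOneOut().split(X))
    else:
        class_sizes = np.unique(y, return_counts=True)[1]
        if config.cv_folds > class_sizes.min():
            raise ValueError(
                f"cv_folds={config.cv_folds} exceeds smallest class size "
                f"{class_sizes.min()}"
            )
        splits = cv_splits(y, config.cv_folds, config.seed)
    pred = np.empty_like(y)
    for train_idx, test_idx in splits:
        model = classifier.fit_svc(X[train_idx], y[train_idx], c, gamma)
        pred[test_idx] = model.predict(X[test_idx])
    counts = _counts_from_predictions(y, pred)
    return EvalReport(
        counts,
        miscall_metrics(counts),
        "kfold",
        params={
            "lam": params.lam if params else None,
            "w": params.weight if params else None,
            "C": float(c),
            "gamma": float(gamma),
            "folds": config.cv_folds,
            "seed": config.seed,
            "tuned": tuned,
            "kind": kind,
        },
    )


@dataclass(frozen=True)
class OptimizationResult:
    best_w: float
    best_lam: int
    best_c: float
    best_gamma: float
    best_accuracy: float
    surface: pd.DataFrame  # columns: w, lam, C, gamma, cv_accuracy
    search_order: str = "outer (w, lambda) grid; inner (C, gamma) grid search"


def optimize_params(
    ds: LabeledDataset,
    w_grid: Sequence[float] | None = None,
    lam_grid: Sequence[int] | None = None,
    config: TrainingConfig | None = None,
    kind: str = "psednc",
    enforce_bounds: bool = True,
) -> OptimizationResult:
    """Search the (w, lambda) box, re-tuning (C, gamma) in every cell.

    Each cell's score is its best mean k-fold CV accuracy; the returned
    surface has one row per cell so selection effects stay visible.
    Ties resolve to smaller lambda, then smaller w (prefer the smaller
    feature space).
    """
    if w_grid is None:
        w_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    if lam_grid is None:
        lam_grid = range(1, 11)
    if config is None:
        config = TrainingConfig()
    L = ds.length
    rows = []
    best = None  # (acc, lam, w, c, gamma)
    for lam in lam_grid:
        if lam >= L - 1:
            raise ValueError(f"lambda={lam} infeasible for sequence length {L}")
        for w in w_grid:
            params = EncoderParams(lam=int(lam), weight=float(w), enforce_bounds=enforce_bounds)
            X, y = _encode(ds, params, kind)
            gs = grid_search(X, y, config)
            rows.append((float(w), int(lam), gs.c, gs.gamma, gs.cv_accuracy))
            if best is None or gs.cv_accuracy > best[0] + 1e-12:
                best = (gs.cv_accuracy, int(lam), float(w), gs.c, gs.gamma)
    surface = pd.DataFrame(rows, columns=["w", "lam", "C", "gamma", "cv_accuracy"])
    return OptimizationResult(
        best_w=best[2],
        best_lam=best[1],
        best_c=best[3],
        best_gamma=best[4],
        best_accuracy=best[0],
        surface=surface,
    )
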