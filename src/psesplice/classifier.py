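"""RBF-kernel SVM training, C/gamma grid search and prediction.

The classifier is a support vector machine with a radial basis
function kernel. Its two hyperparameters — the regularization constant
C and the kernel width gamma — are tuned by exhaustive grid search
under stratified k-fold cross-validation; the default lattices are the
conventional powers-of-two grids C in 2^-5..2^15, gamma in 2^-15..2^3.
Among cells whose mean CV accuracy ties (within 1e-12), the smallest C
and then the smallest gamma wins, preferring smoother models.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import sequence_io
from .encoder import EncoderParams, encode_sequence
from .sequence_io import LabeledDataset, Label


def _default_c_grid() -> np.ndarray:
    return 2.0 ** np.arange(-5, 16, 2)


def _default_gamma_grid() -> np.ndarray:
    return 2.0 ** np.arange(-15, 4, 2)


@dataclass(frozen=True)
class TrainingConfig:
    """Grid-search configuration: C/gamma lattices, folds and seed."""

    c_grid: Sequence[float] = field(default_factory=_default_c_grid)
    gamma_grid: Sequence[float] = field(default_factory=_default_gamma_grid)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name, grid in (("c_grid", self.c_grid), ("gamma_grid", self.gamma_grid)):
            arr = np.asarray(grid, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} is empty")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, arr)
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")


@dataclass(frozen=True)
class GridSearchResult:
    c: float
    gamma: float
    cv_accuracy: float
    table: pd.DataFrame  # columns: C, gamma, cv_accuracy


def fit_svc(X: np.ndarray, y: np.ndarray, c: float, gamma: float) -> SVC:
    """Fit one RBF-SVM; factored out so protocols can count/replace fits."""
    model = SVC(C=c, gamma=gamma, kernel="rbf")
    model.fit(X, y)
    return model


def _check_features(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"feature matrix {X.shape} does not match {y.shape[0]} labels")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("training data contain a single class")
    return X, y


def cv_splits(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold assignment, reused across grid cells."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def grid_search(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig | None = None
) -> GridSearchResult:
    """Pick (C, gamma) maximizing mean stratified k-fold CV accuracy.

    Deterministic given the seed: the same folds are reused for every
    grid cell, and ties resolve to the smallest C, then smallest gamma.
    """
    if config is None:
        config = TrainingConfig()
    X, y = _check_features(X, y)
    if config.cv_folds > len(y):
        raise ValueError(f"cv_folds={config.cv_folds} exceeds dataset size {len(y)}")
    splits = cv_splits(y, config.cv_folds, config.seed)
    rows = []
    best = None  # (accuracy, c, gamma)
    for c in config.c_grid:
        for gamma in config.gamma_grid:
            correct = 0
            for train_idx, test_idx in splits:
                model = fit_svc(X[train_idx], y[train_idx], c, gamma)
                correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
            acc = correct / len(y)
            rows.append((c, gamma, acc))
            if best is None or acc > best[0] + 1e-12:
                best = (acc, c, gamma)
    table = pd.DataFrame(rows, columns=["C", "gamma", "cv_accuracy"])
    return GridSearchResult(c=best[1], gamma=best[2], cv_accuracy=best[0], table=table)


@dataclass
class ModelBundle:
    """A trained SVM together with the encoding needed to apply it.

    Storing the encoder parameters (kind, lambda, w) with the model
    guarantees that prediction re-encodes inputs exactly as training did.
    """

    model: SVC
    kind: str
    params: EncoderParams | None
    c: float
    gamma: float
    metadata: dict

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model, directory / "model.joblib")
        meta = dict(self.metadata)
        meta.update(
            kind=self.kind,
            c=self.c,
            gamma=self.gamma,
            lam=self.params.lam if self.params else None,
            weight=self.params.weight if self.params else None,
        )
        with open(directory / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        model = joblib.load(directory / "model.joblib")
        with open(directory / "metadata.json") as fh:
            meta = json.load(fh)
        kind = meta.pop("kind")
        c = meta.pop("c")
        gamma = meta.pop("gamma")
        lam = meta.pop("lam")
        weight = meta.pop("weight")
        params = EncoderParams(lam=lam, weight=weight) if lam is not None else None
        return cls(model=model, kind=kind, params=params, c=c, gamma=gamma, metadata=meta)


def train(
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    gamma: float,
    params: EncoderParams | None = None,
    kind: str = "psednc",
    seed: int | None = None,
) -> ModelBundle:
    """Train the final RBF-SVM at fixed (C, gamma)."""
    X, y = _check_features(X, y)
    model = fit_svc(X, y, c, gamma)
    digest = hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()[:16]
    metadata = {
        "n_samples": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "data_sha256": digest,
        "seed": seed,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return ModelBundle(model=model, kind=kind, params=params, c=c, gamma=gamma, metadata=metadata)


def predict(
    bundle: ModelBundle,
    data: LabeledDataset | str | Path,
    permissive: bool = True,
) -> pd.DataFrame:
    """Classify sequences; returns id, predicted_label, decision_value.

    Sequences that cannot be encoded (e.g. shorter than lambda + 2) get
    predicted_label "invalid" with a NaN decision value when permissive,
    otherwise abort the run.
    """
    if not isinstance(data, LabeledDataset):
        ds = sequence_io.read_fasta(data)
    else:
        ds = data
    rows = []
    for s in ds:
        try:
            fv = encode_sequence(s, bundle.params, bundle.kind)
        except Exception as exc:
            if not permissive:
                raise
            import warnings

            warnings.warn(f"record {s.id!r} not encodable: {exc}")
            rows.append((s.id, "invalid", float("nan")))
            continue
        vec = fv.values.reshape(1, -1)
        if vec.shape[1] != bundle.metadata.get("n_features", vec.shape[1]):
            raise ValueError(
                f"record {s.id!r}: feature width {vec.shape[1]} does not match "
                f"model width {bundle.metadata['n_features']}"
            )
        decision = float(bundle.model.decision_function(vec)[0])
        label = (
            Label.TRUE_SITE.value if bundle.model.predict(vec)[0] > 0 else Label.FALSE_SITE.value
        )
        rows.append((s.id, label, decision))
    return pd.DataFrame(rows, columns=["id", "predicted_label", "decision_value"])
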