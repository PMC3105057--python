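"""Per-scheme RBF-kernel classifiers with grid-searched hyperparameters.

Model selection maximizes internally cross-validated MCC (ties broken by
smaller C, then smaller gamma); the winning configuration is refit on all
rows.  Class imbalance is handled by a positive-class weight defaulting
to n_neg / n_pos.  Feature values are compositions already in [0, 1], so
no further scaling is applied.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import SchemeSpec
from .metrics import ConfusionCounts, mcc
from .seqio import AFP, NONAFP


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM hyperparameters.

    ``gamma`` is a positive real or the literal ``"scale"`` (1 / (d * var));
    ``class_weight_positive`` of None means the automatic n_neg / n_pos.
    """

    C: float = 1.0
    gamma: float | str = "scale"
    class_weight_positive: float | None = None

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, str):
            if self.gamma != "scale":
                raise ValueError(f"gamma must be positive or 'scale', got {self.gamma!r}")
        elif self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.class_weight_positive is not None and self.class_weight_positive <= 0:
            raise ValueError("class_weight_positive must be positive")


def default_grid() -> list[ClassifierConfig]:
    """The conventional exponential grid: C in 2^-5..2^15, gamma in 2^-15..2^3."""
    return [
        ClassifierConfig(C=2.0**lc, gamma=2.0**lg)
        for lc in range(-5, 17, 2)
        for lg in range(-15, 5, 2)
    ]


def small_grid() -> list[ClassifierConfig]:
    """A cheap grid for wrapper feature selection loops."""
    return [ClassifierConfig(C=8.0, gamma="scale")]


def _labels_to_signs(labels: Sequence[str]) -> np.ndarray:
    return np.array([1 if y == AFP else -1 for y in labels], dtype=int)


def _make_svc(config: ClassifierConfig, y: np.ndarray) -> SVC:
    if config.class_weight_positive is None:
        n_pos = int((y == 1).sum())
        n_neg = int((y == -1).sum())
        weight = n_neg / n_pos if n_pos else 1.0
    else:
        weight = config.class_weight_positive
    return SVC(kernel="rbf", C=config.C, gamma=config.gamma, class_weight={1: weight, -1: 1.0})


@dataclass
class TrainedSchemeClassifier:
    scheme: SchemeSpec
    attribute_order: list[str]
    mask: np.ndarray  # boolean, one per attribute
    config: ClassifierConfig
    model: SVC
    training_fingerprint: str

    def __post_init__(self):
        if self.mask.shape != (len(self.attribute_order),):
            raise ValueError("mask length must equal attribute count")
        if not self.mask.any():
            raise ValueError("mask must select at least one attribute")

    @property
    def selected_attributes(self) -> list[str]:
        return [a for a, keep in zip(self.attribute_order, self.mask) if keep]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.attribute_order):
            raise ValueError(
                f"expected {len(self.attribute_order)} attributes, got {X.shape[1]}"
            )
        return self.model.decision_function(X[:, self.mask])

    def predict(self, X: np.ndarray) -> tuple[list[str], np.ndarray]:
        """Labels plus decision scores; positive score means AFP."""
        scores = self.decision_scores(X)
        return [AFP if s > 0 else NONAFP for s in scores], scores


def _fingerprint(X: np.ndarray, y: np.ndarray, mask: np.ndarray, config, seed) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(np.ascontiguousarray(mask).tobytes())
    h.update(repr((config, seed)).encode())
    return h.hexdigest()[:16]


def cv_confusion(
    X: np.ndarray,
    y_signs: np.ndarray,
    config: ClassifierConfig,
    internal_folds: int,
    seed: int,
) -> ConfusionCounts:
    """Pooled confusion counts from seeded stratified internal CV."""
    n_min = int(min((y_signs == 1).sum(), (y_signs == -1).sum()))
    folds = min(internal_folds, n_min)
    if folds < 2:
        raise TrainingError("need >= 2 items of each class for internal CV")
    if folds < internal_folds:
        warnings.warn(
            f"internal folds reduced {internal_folds} -> {folds} (minority class size)",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for train_idx, test_idx in skf.split(X, y_signs):
        model = _make_svc(config, y_signs[train_idx])
        model.fit(X[train_idx], y_signs[train_idx])
        pred = model.predict(X[test_idx])
        truth = y_signs[test_idx]
        tp += int(((pred == 1) & (truth == 1)).sum())
        tn += int(((pred == -1) & (truth == -1)).sum())
        fp += int(((pred == 1) & (truth == -1)).sum())
        fn += int(((pred == -1) & (truth == 1)).sum())
    return ConfusionCounts(tp, tn, fp, fn)


def grid_search_train(
    matrix: np.ndarray,
    labels: Sequence[str],
    scheme: SchemeSpec,
    attribute_order: Sequence[str],
    internal_folds: int = 5,
    grid: Sequence[ClassifierConfig] | None = None,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> tuple[TrainedSchemeClassifier, list[tuple[ClassifierConfig, float]]]:
    """Pick the grid point with the best internal CV MCC and refit on all rows.

    Ties are broken by smaller C, then smaller gamma (with "scale" ordered
    last).  Returns the classifier and the per-config scores.
    """
    X = np.asarray(matrix, dtype=float)
    y = _labels_to_signs(labels)
    if len({*labels}) < 2:
        raise TrainingError("both classes must be present for training")
    if X.shape[0] != len(labels):
        raise TrainingError("matrix rows must match label count")
    if mask is None:
        mask = np.ones(X.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise TrainingError("mask must select at least one attribute")
    grid = list(grid) if grid is not None else default_grid()
    Xm = X[:, mask]

    def gamma_key(c: ClassifierConfig) -> float:
        return float("inf") if isinstance(c.gamma, str) else c.gamma

    scores: list[tuple[ClassifierConfig, float]] = []
    for config in grid:
        scores.append((config, mcc(cv_confusion(Xm, y, config, internal_folds, seed))))
    best_config, _ = min(scores, key=lambda cs: (-cs[1], cs[0].C, gamma_key(cs[0])))
    model = _make_svc(best_config, y)
    model.fit(Xm, y)
    clf = TrainedSchemeClassifier(
        scheme=scheme,
        attribute_order=list(attribute_order),
        mask=mask,
        config=best_config,
        model=model,
        training_fingerprint=_fingerprint(X, y, mask, best_config, seed),
    )
    return clf, scores
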