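"""Linear maximum-margin diagnosis prediction under repeated nested CV.

The only hyper-parameter tuned is the correlation-feature window length Tw,
selected by inner cross-validation on each outer training fold; the margin
penalty is fixed at C = 1.  Features are z-scored with statistics fit on the
training fold only.  Fold-level weight vectors are retained so that feature
importance can be summarized across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .coordination_features import DEFAULT_TW_GRID

__all__ = [
    "POSITIVE_CLASS",
    "NEGATIVE_CLASS",
    "CohortFeatures",
    "CVConfig",
    "FoldRecord",
    "CVResult",
    "ClassificationMetrics",
    "nested_cv_predict",
    "loocv_predict",
    "participant_accuracy",
    "compute_metrics",
    "average_feature_weights",
]

POSITIVE_CLASS = "ASD"
NEGATIVE_CLASS = "NT"


@dataclass(frozen=True)
class CohortFeatures:
    """Per-window-length feature tables for one cohort.

    ``tables`` maps each candidate Tw (seconds) to an
    ``(n_participants, M)`` array; rows are aligned across tables.
    """

    tables: dict[float, np.ndarray]
    participant_ids: tuple[str, ...]
    labels: tuple[str, ...]
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "participant_ids", tuple(self.participant_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        n = len(self.participant_ids)
        if len(self.labels) != n:
            raise ValueError("one label per participant required")
        tables = {tw: np.asarray(x, dtype=float) for tw, x in self.tables.items()}
        object.__setattr__(self, "tables", tables)
        for tw, x in tables.items():
            if x.shape[0] != n:
                raise ValueError(f"table for Tw={tw} has {x.shape[0]} rows, not {n}")
            if not np.isfinite(x).all():
                raise ValueError(f"table for Tw={tw} contains non-finite values")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def tw_grid(self) -> tuple[float, ...]:
        return tuple(sorted(self.tables))

    def y(self) -> np.ndarray:
        return np.asarray(self.labels)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation scheme parameters."""

    outer_folds: int = 10
    repeats: int = 100
    inner_folds: int = 5
    tw_grid: tuple[float, ...] = DEFAULT_TW_GRID
    C: float = 1.0
    seed: int = 0
    standardize: bool = True
    stratified: bool = False
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass(frozen=True)
class FoldRecord:
    """One trained outer fold: selection, weights, held-out predictions."""

    repeat: int
    fold: int
    selected_tw: float
    test_indices: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    weights: np.ndarray  # (M,) in standardized feature space


@dataclass
class CVResult:
    """Predictions per repeat x participant plus fold-level bookkeeping."""

    predictions: np.ndarray  # (repeats, n) label strings
    scores: np.ndarray  # (repeats, n) signed decision values
    folds: list[FoldRecord]
    labels: tuple[str, ...]
    participant_ids: tuple[str, ...]
    config: CVConfig = field(repr=False)

    @property
    def n_repeats(self) -> int:
        return self.predictions.shape[0]

    def correct(self) -> np.ndarray:
        """Boolean (repeats, n) correctness matrix."""
        return self.predictions == np.asarray(self.labels)[None, :]

    def mean_accuracy(self) -> float:
        return float(self.correct().mean())

    def per_participant_accuracy(self) -> np.ndarray:
        return self.correct().mean(axis=0)

    def selected_tw_counts(self) -> dict[float, int]:
        counts: dict[float, int] = {}
        for rec in self.folds:
            counts[rec.selected_tw] = counts.get(rec.selected_tw, 0) + 1
        return dict(sorted(counts.items()))

    def fold_weights(self) -> np.ndarray:
        """(n_folds, M) stack of fold weight vectors."""
        return np.vstack([rec.weights for rec in self.folds])


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion-matrix summary; undefined ratios are NaN and flagged."""

    accuracy: float
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _make_classifier(cfg: CVConfig):
    svm = SVC(kernel="linear", C=cfg.C)
    if cfg.standardize:
        return make_pipeline(StandardScaler(), svm)
    return make_pipeline(svm)


def _extract_weights(model) -> np.ndarray:
    return np.asarray(model[-1].coef_).ravel()


def _select_tw(
    features: CohortFeatures, train_idx: np.ndarray, y: np.ndarray, cfg: CVConfig
) -> float:
    """Inner-CV window-length selection; ties go to the smallest Tw."""
    n_train = train_idx.shape[0]
    n_splits = min(cfg.inner_folds, n_train)
    inner = KFold(n_splits=n_splits, shuffle=False)
    best_tw, best_acc = None, -1.0
    for tw in sorted(cfg.tw_grid):
        X = features.tables[tw][train_idx]
        y_tr = y[train_idx]
        correct = 0
        for tr, te in inner.split(X):
            if len(np.unique(y_tr[tr])) < 2:
                # degenerate inner split: count the fold as uninformative
                continue
            model = _make_classifier(cfg)
            model.fit(X[tr], y_tr[tr])
            correct += int((model.predict(X[te]) == y_tr[te]).sum())
        acc = correct / n_train
        if acc > best_acc:  # strict: earlier (smaller) Tw wins ties
            best_tw, best_acc = tw, acc
    return best_tw


def _outer_fold_indices(order: np.ndarray, y: np.ndarray, cfg: CVConfig):
    """Test-index arrays for each outer fold, in shuffled participant order."""
    if cfg.stratified:
        splitter = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=False)
        return [order[te] for _, te in splitter.split(order[:, None], y[order])]
    splitter = KFold(n_splits=cfg.outer_folds, shuffle=False)
    return [order[te] for _, te in splitter.split(order[:, None])]


def nested_cv_predict(features: CohortFeatures, cfg: CVConfig) -> CVResult:
    """Repeated nested cross-validation over the cohort.

    Per repeat, participants are shuffled (seeded) and split into
    ``outer_folds`` folds.  On each outer training set, inner CV picks the
    Tw with highest accuracy; a fresh classifier is then fit on the full
    training set at that Tw and applied to the held-out fold.  Deterministic
    given ``cfg.seed``.
    """
    y = features.y()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 participants per class")
    n = features.n_participants
    if cfg.outer_folds > n:
        raise ValueError(f"outer_folds={cfg.outer_folds} exceeds n={n}")
    missing = set(cfg.tw_grid) - set(features.tables)
    if missing:
        raise ValueError(f"no feature table for Tw in {sorted(missing)}")

    rng = np.random.default_rng(cfg.seed)
    predictions = np.empty((cfg.repeats, n), dtype=object)
    scores = np.zeros((cfg.repeats, n))
    folds: list[FoldRecord] = []
    for rep in range(cfg.repeats):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        for k, test_idx in enumerate(_outer_fold_indices(order, y, cfg)):
            train_idx = np.setdiff1d(order, test_idx, assume_unique=True)
            # keep the shuffled order inside the training set (inner folds
            # depend on it)
            train_idx = order[np.isin(order, train_idx)]
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError(
                    f"training set of outer fold {k} (repeat {rep}) "
                    f"contains a single class"
                )
            tw = _select_tw(features, train_idx, y, cfg)
            X = features.tables[tw]
            model = _make_classifier(cfg)
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            raw = model.decision_function(X[test_idx])
            # sklearn orients decision_function by sorted class order; flip
            # so positive score always means the positive (ASD) class
            sign = 1.0 if model[-1].classes_[1] == POSITIVE_CLASS else -1.0
            predictions[rep, test_idx] = pred
            scores[rep, test_idx] = sign * raw
            folds.append(
                FoldRecord(
                    repeat=rep,
                    fold=k,
                    selected_tw=tw,
                    test_indices=test_idx.copy(),
                    predictions=pred,
                    scores=sign * raw,
                    weights=_extract_weights(model),
                )
            )
    return CVResult(
        predictions=predictions.astype(str),
        scores=scores,
        folds=folds,
        labels=features.labels,
        participant_ids=features.participant_ids,
        config=cfg,
    )


def loocv_predict(features: CohortFeatures, cfg: CVConfig | None = None) -> CVResult:
    """Leave-one-out prediction: n outer folds, one repeat, no shuffling."""
    cfg = cfg or CVConfig()
    cfg = replace(
        cfg, outer_folds=features.n_participants, repeats=1, shuffle=False,
        stratified=False,
    )
    return nested_cv_predict(features, cfg)


def participant_accuracy(
    features: CohortFeatures,
    k_folds: int = 5,
    repeats: int = 1000,
    cfg: CVConfig | None = None,
) -> np.ndarray:
    """Fraction of repeated k-fold rounds that predict each participant right."""
    cfg = cfg or CVConfig()
    cfg = replace(cfg, outer_folds=k_folds, repeats=repeats, shuffle=True)
    return nested_cv_predict(features, cfg).per_participant_accuracy()


def compute_metrics(
    predicted, truth, positive_class: str = POSITIVE_CLASS
) -> ClassificationMetrics:
    """Confusion-matrix metrics; degenerate ratios come back NaN + flagged."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty prediction vector")
    pos_pred = predicted == positive_class
    pos_true = truth == positive_class
    tp = int(np.sum(pos_pred & pos_true))
    fp = int(np.sum(pos_pred & ~pos_true))
    fn = int(np.sum(~pos_pred & pos_true))
    tn = int(np.sum(~pos_pred & ~pos_true))

    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ClassificationMetrics(
        accuracy=(tp + tn) / predicted.size,
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        undefined=tuple(undefined),
    )


def average_feature_weights(result: CVResult) -> tuple[np.ndarray, np.ndarray]:
    """Mean |weight| per feature across folds, with its standard error.

    The standard error uses the sample standard deviation (ddof 1) over
    folds; with a single fold it is zero by convention.
    """
    absw = np.abs(result.fold_weights())
    mean = absw.mean(axis=0)
    n_folds = absw.shape[0]
    if n_folds < 2:
        return mean, np.zeros_like(mean)
    stderr = absw.std(axis=0, ddof=1) / np.sqrt(n_folds)
    return mean, stderr
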