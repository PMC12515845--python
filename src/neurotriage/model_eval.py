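"""Gradient-boosted classification with a leakage-aware evaluation protocol.

Adjacent 1-s windows of the same subject are highly correlated, so a
conventional shuffled train/test split would leak near-duplicates across
the boundary and inflate accuracy.  The protocol here therefore splits
strictly by acquisition order: the first half of the windows trains (with
the last 30% of that pool held out for validation / hyperparameter
search), the second half tests; cross-validation folds are likewise
contiguous in time by default.

The classifier itself is LightGBM's gradient-boosted decision trees; its
objective is the usual boosting loss plus the per-tree regularizer
gamma*T + (lambda/2)*sum_j w_j^2 over the T leaves, which enters through
the ``reg_gamma`` (minimum split gain) and ``reg_lambda`` (L2 leaf
penalty) knobs.  Reported metrics treat MDD as the positive class, so
recall measures patient detection.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

from .features import META_COLUMNS, feature_columns
from .recording import LABEL_HC, LABEL_MDD

#: Hyperparameter grids of the enumeration search.
DEFAULT_LEAVES_GRID = (10, 20, 30, 40, 50, 100)
DEFAULT_LR_GRID = (0.01, 0.005, 0.001, 0.0005, 0.0001)


@dataclass(frozen=True)
class ClassifierConfig:
    """Boosting hyperparameters.

    The defaults (50 leaves, learning rate 0.01) are the argmax of the
    enumeration grid; ``n_estimators`` is the boosting-round count, sized
    for the small default learning rate (0.01 x 4000 rounds),
    ``reg_gamma``/``reg_lambda`` the per-leaf and L2 leaf-score penalties
    (0 unless configured).  ``min_child_samples`` is kept small so the
    trees can still split on modest training sets.
    """

    num_leaves: int = 50
    learning_rate: float = 0.01
    n_estimators: int = 4000
    reg_gamma: float = 0.0
    reg_lambda: float = 0.0
    seed: int = 0
    min_child_samples: int = 5

    def __post_init__(self) -> None:
        if self.num_leaves < 2:
            raise ValueError("num_leaves must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class EvaluationReport:
    """Confusion matrix and derived metrics, MDD positive.

    Metrics are percentages:
    accuracy  = (TP+TN)/(TP+TN+FP+FN)
    precision = TP/(TP+FP)
    recall    = TP/(TP+FN)
    F1        = 2*precision*recall/(precision+recall)
    ``mean_inference_time_ms`` is the wall-clock per-row prediction time,
    reported for real-time-feasibility context only (hardware-dependent,
    never asserted).
    """

    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)
    mean_inference_time_ms: float = 0.0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        m = self.recompute_metrics()
        self.accuracy = m["accuracy"]
        self.precision = m["precision"]
        self.recall = m["recall"]
        self.f1 = m["f1"]

    def recompute_metrics(self) -> dict[str, float]:
        """Metrics recomputed from the stored confusion counts (in %)."""
        tp, fn, fp, tn = self.tp, self.fn, self.fp, self.tn
        total = tp + fn + fp + tn
        acc = (tp + tn) / total if total else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return {"accuracy": 100 * acc, "precision": 100 * prec,
                "recall": 100 * rec, "f1": 100 * f1}

    @property
    def n_rows(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def confusion_matrix(self) -> np.ndarray:
        """2x2 matrix [[TP, FN], [FP, TN]] (rows: true MDD, true HC)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fn": self.fn,
                          "fp": self.fp, "tn": self.tn},
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "mean_inference_time_ms": self.mean_inference_time_ms,
            "positive_class": LABEL_MDD,
        }


@dataclass
class CVReport:
    """Per-fold reports plus mean and sd of each metric (in %)."""

    folds: list[EvaluationReport]
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.folds) < 2:
            raise ValueError("cross-validation needs at least 2 folds")
        names = ("accuracy", "precision", "recall", "f1")
        vals = {n: np.array([getattr(f, n) for f in self.folds]) for n in names}
        self.mean = {n: float(v.mean()) for n, v in vals.items()}
        self.sd = {n: float(v.std(ddof=1)) for n, v in vals.items()}

    def to_dict(self) -> dict:
        return {"folds": [f.to_dict() for f in self.folds],
                "mean": self.mean, "sd": self.sd}


def chronological_order(table: pd.DataFrame) -> pd.DataFrame:
    """Reorder a subject-major feature table along recording time.

    Subjects are recorded in separate, effectively parallel sessions, so
    the dataset-wide chronological axis is time *within* the recording:
    all subjects' first windows, then all second windows, and so on.
    Sorting by (within-subject window rank, subject) and reassigning
    ``order_index`` makes the plain first-half/second-half split of
    :func:`time_ordered_split` an early-minutes-train / late-minutes-test
    protocol in which every subject appears on both sides while adjacent
    (near-duplicate) windows stay on one side of the boundary.
    """
    t = table.copy()
    rank = t.groupby("subject_id", sort=False).cumcount()
    first_pos = {s: i for i, s in enumerate(t["subject_id"].drop_duplicates())}
    t = (
        t.assign(_rank=rank, _subj=t["subject_id"].map(first_pos))
        .sort_values(["_rank", "_subj"], kind="stable")
        .drop(columns=["_rank", "_subj"])
        .reset_index(drop=True)
    )
    t["order_index"] = np.arange(len(t), dtype=np.int64)
    return t


def time_ordered_split(
    table: pd.DataFrame,
    test_frac: float = 0.5,
    val_frac: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a time-ordered feature table into (train, validation, test).

    No shuffling: the last ``test_frac`` of rows (floor convention,
    remainders to the earlier part) form the test set; the last
    ``val_frac`` of the remaining training pool form the validation set.
    The three parts partition the table, and every test row lies after
    every training row in acquisition order.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    if not 0 <= val_frac < 1:
        raise ValueError("val_frac must be in [0, 1)")
    if not table["order_index"].is_monotonic_increasing:
        raise ValueError("table must be ordered by order_index")
    n = len(table)
    n_test = int(np.floor(n * test_frac))
    n_pool = n - n_test
    n_val = int(np.floor(n_pool * val_frac))
    n_train = n_pool - n_val
    if n_test < 1 or n_train < 1 or (val_frac > 0 and n_val < 1):
        raise ValueError(f"split of {n} rows leaves an empty part")
    train = table.iloc[:n_train].reset_index(drop=True)
    val = table.iloc[n_train:n_pool].reset_index(drop=True)
    test = table.iloc[n_pool:].reset_index(drop=True)
    return train, val, test


class TrainedModel:
    """A fitted classifier bound to its feature columns."""

    def __init__(self, booster: LGBMClassifier, columns: list[str],
                 cfg: ClassifierConfig):
        self.booster = booster
        self.columns = columns
        self.cfg = cfg

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted labels ("HC"/"MDD") for the rows of ``table``."""
        cols = feature_columns(table)
        if cols != self.columns:
            raise ValueError(
                "feature columns do not match training "
                f"(got {cols}, expected {self.columns})"
            )
        pred = self.booster.predict(table[self.columns])
        return np.where(pred == 1, LABEL_MDD, LABEL_HC)


def _labels_to_int(labels: pd.Series) -> np.ndarray:
    return (labels.to_numpy() == LABEL_MDD).astype(int)


def fit_classifier(train: pd.DataFrame, cfg: ClassifierConfig | None = None
                   ) -> TrainedModel:
    """Fit the gradient-boosted classifier (deterministic for a fixed
    seed: single-threaded, deterministic tree construction)."""
    if cfg is None:
        cfg = ClassifierConfig()
    y = _labels_to_int(train["label"])
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    cols = feature_columns(train)
    booster = LGBMClassifier(
        num_leaves=cfg.num_leaves,
        learning_rate=cfg.learning_rate,
        n_estimators=cfg.n_estimators,
        min_split_gain=cfg.reg_gamma,
        reg_lambda=cfg.reg_lambda,
        min_child_samples=cfg.min_child_samples,
        random_state=cfg.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    booster.fit(train[cols], y)
    return TrainedModel(booster, cols, cfg)


def evaluate(model: TrainedModel, test: pd.DataFrame) -> EvaluationReport:
    """Confusion matrix and metrics on a held-out table, MDD positive."""
    if len(test) == 0:
        raise ValueError("test table is empty")
    t0 = time.perf_counter()
    pred = model.predict(test)
    elapsed_ms = (time.perf_counter() - t0) * 1000.0
    true = test["label"].to_numpy()
    tp = int(np.sum((true == LABEL_MDD) & (pred == LABEL_MDD)))
    fn = int(np.sum((true == LABEL_MDD) & (pred == LABEL_HC)))
    fp = int(np.sum((true == LABEL_HC) & (pred == LABEL_MDD)))
    tn = int(np.sum((true == LABEL_HC) & (pred == LABEL_HC)))
    return EvaluationReport(tp=tp, fn=fn, fp=fp, tn=tn,
                            mean_inference_time_ms=elapsed_ms / len(test))


def grid_search(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    leaves_grid: tuple[int, ...] = DEFAULT_LEAVES_GRID,
    lr_grid: tuple[float, ...] = DEFAULT_LR_GRID,
    base_cfg: ClassifierConfig | None = None,
) -> tuple[ClassifierConfig, pd.DataFrame]:
    """Exhaustive enumeration over (num_leaves, learning_rate).

    Returns the config maximizing validation accuracy — ties broken in
    favor of fewer leaves, then a larger learning rate (the simpler,
    faster-converging model) — together with the full accuracy grid
    (rows: learning rate, columns: leaf counts, in %).  The result is
    independent of enumeration order.
    """
    if not leaves_grid or not lr_grid:
        raise ValueError("grids must be non-empty")
    if base_cfg is None:
        base_cfg = ClassifierConfig()
    grid = pd.DataFrame(index=list(lr_grid), columns=list(leaves_grid),
                        dtype=float)
    grid.index.name = "learning_rate"
    grid.columns.name = "num_leaves"
    best: tuple | None = None
    for lr in lr_grid:
        for leaves in leaves_grid:
            cfg = replace(base_cfg, num_leaves=leaves, learning_rate=lr)
            model = fit_classifier(train, cfg)
            acc = evaluate(model, validation).accuracy
            grid.loc[lr, leaves] = acc
            key = (-acc, leaves, -lr)  # max accuracy, then fewer leaves, larger lr
            if best is None or key < best[0]:
                best = (key, cfg)
    return best[1], grid


def cross_validate(
    train_pool: pd.DataFrame,
    cfg: ClassifierConfig | None = None,
    k: int = 5,
    seed: int = 0,
    shuffle: bool = False,
) -> CVReport:
    """k-fold cross-validation over the training pool.

    Folds are contiguous blocks in acquisition order by default (the
    stricter, leakage-respecting variant); ``shuffle=True`` permutes rows
    with ``seed`` first for the conventional protocol.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(train_pool) < k:
        raise ValueError(f"{len(train_pool)} rows cannot form {k} folds")
    if cfg is None:
        cfg = ClassifierConfig()
    if shuffle:
        rng = np.random.default_rng(seed)
        pool = train_pool.iloc[rng.permutation(len(train_pool))].reset_index(drop=True)
    else:
        pool = train_pool.reset_index(drop=True)
    fold_indices = np.array_split(np.arange(len(pool)), k)
    reports = []
    for held in fold_indices:
        mask = np.zeros(len(pool), dtype=bool)
        mask[held] = True
        model = fit_classifier(pool.loc[~mask].reset_index(drop=True), cfg)
        reports.append(evaluate(model, pool.loc[mask].reset_index(drop=True)))
    return CVReport(folds=reports)
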