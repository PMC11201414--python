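"""Confusion-matrix accounting, output MSE, and ten-fold cross-validation.

The six performance measures derived from (TP, TN, FP, FN):

    accuracy   = (TP + TN) / total * 100
    F1 score   = 2 TP / (2 TP + FP + FN) * 100
    MCC        = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))   (fraction)
    F-measure  = sqrt(precision * recall)                               (fraction)
    error rate = (FP + FN) / total * 100  (= 100 - accuracy)
    Jaccard    = TP / (TP + FP + FN) * 100

MCC and F-measure are reported as fractions and error rate as the accuracy
complement: this is the only reading consistent with the published benchmark
values these formulas are checked against.  Reported values are rounded
half-away-from-zero to 2 decimals; full precision is retained internally.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifiers import TargetScheme, as_int_labels, encode_targets, make_classifier
from .clustering import FeatureNormalizer

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "metrics_from_confusion",
    "output_mse",
    "CVPlan",
    "cross_validate",
    "CVResult",
    "reproduce_tables",
    "load_reference_confusions",
    "round2",
]


def load_reference_confusions() -> pd.DataFrame:
    """Published benchmark confusion matrices (eight classifiers x four
    feature methods on a 1859-image liver-ultrasound dataset) with the
    metric values printed alongside them, shipped as package data."""
    with resources.files("sonoliver").joinpath(
        "data/reference_confusions.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero."""
    if math.isnan(x):
        return x
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5) / 100.0, x)


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @staticmethod
    def from_labels(y_true, y_pred, positive: int = 1) -> "ConfusionMatrix":
        yt = as_int_labels(y_true)
        yp = as_int_labels(y_pred)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have equal length")
        pos_t, pos_p = yt == positive, yp == positive
        return ConfusionMatrix(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Full-precision metric values; ``rounded()`` gives the report form."""

    accuracy: float
    f1: float
    mcc: float
    f_measure: float
    error_rate: float
    jaccard: float

    def rounded(self) -> "MetricsReport":
        return MetricsReport(*(round2(v) for v in dataclasses.astuple(self)))

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """The six performance measures from one confusion matrix.

    MCC is 0 when any denominator factor vanishes; F-measure and Jaccard are
    0 when no positive predictions or positives exist.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    total = cm.total
    accuracy = (tp + tn) / total * 100.0
    denom_f1 = 2 * tp + fp + fn
    f1 = (2 * tp / denom_f1 * 100.0) if denom_f1 > 0 else 0.0
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / math.sqrt(mcc_den)) if mcc_den > 0 else 0.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f_measure = math.sqrt(precision * recall)
    error_rate = (fp + fn) / total * 100.0
    denom_jm = tp + fp + fn
    jaccard = (tp / denom_jm * 100.0) if denom_jm > 0 else 0.0
    return MetricsReport(accuracy, f1, mcc, f_measure, error_rate, jaccard)


def output_mse(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared deviation of continuous classifier outputs from targets."""
    outputs = np.asarray(outputs, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    if outputs.size != targets.size:
        raise ValueError("outputs and targets must have equal length")
    if outputs.size == 0:
        raise ValueError("need at least one output")
    return float(np.mean((outputs - targets) ** 2))


@dataclasses.dataclass(frozen=True)
class CVPlan:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def split(self, labels: np.ndarray):
        y = as_int_labels(labels)
        if self.stratified:
            if np.bincount(y, minlength=2).min() < self.n_folds:
                raise ValueError(
                    f"stratified {self.n_folds}-fold CV needs >= {self.n_folds} "
                    "samples per class"
                )
            skf = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.seed
            )
            yield from skf.split(np.zeros_like(y), y)
        else:
            rng = np.random.default_rng(self.seed)
            idx = rng.permutation(y.size)
            for fold in np.array_split(idx, self.n_folds):
                test = np.sort(fold)
                train = np.setdiff1d(idx, test)
                yield train, test


@dataclasses.dataclass
class CVResult:
    pooled: ConfusionMatrix
    per_fold_metrics: list[MetricsReport]
    mean_mse: float
    fold_assignments: np.ndarray

    @property
    def pooled_metrics(self) -> MetricsReport:
        return metrics_from_confusion(self.pooled)


def cross_validate(
    features: np.ndarray,
    labels,
    classifier: str,
    plan: CVPlan = CVPlan(),
    scheme: TargetScheme = TargetScheme(),
    classifier_kwargs: dict | None = None,
) -> CVResult:
    """Stratified k-fold evaluation of one classifier on raw feature vectors.

    Normalisation bounds and the model are fitted inside each training fold
    only; per-fold confusions are pooled by summation (micro-averaging) and
    the output MSE per fold is averaged.  Deterministic for a fixed plan seed.
    """
    X = np.asarray(features, dtype=float)
    y = as_int_labels(labels)
    targets = encode_targets(y, scheme)
    pooled: ConfusionMatrix | None = None
    per_fold: list[MetricsReport] = []
    mses: list[float] = []
    assignments = np.full(y.size, -1, dtype=int)
    for fold_id, (tr, te) in enumerate(plan.split(y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold_id}: a class is absent from training")
        assignments[te] = fold_id
        norm = FeatureNormalizer().fit(X[tr])
        Xtr, Xte = norm.transform(X[tr]), norm.transform(X[te])
        model = make_classifier(
            classifier, seed=plan.seed + fold_id, scheme=scheme,
            **(classifier_kwargs or {}),
        )
        model.fit(Xtr, y[tr])
        pred = model.predict(Xte)
        outputs = model.predict_outputs(Xte)
        cm = ConfusionMatrix.from_labels(y[te], pred)
        pooled = cm if pooled is None else pooled + cm
        per_fold.append(metrics_from_confusion(cm))
        mses.append(output_mse(outputs, targets[te]))
    assert pooled is not None
    return CVResult(pooled, per_fold, float(np.mean(mses)), assignments)


def reproduce_tables(
    confusions: pd.DataFrame, tolerance: float = 0.01
) -> pd.DataFrame:
    """Recompute the six metrics for labelled confusion matrices.

    ``confusions`` carries columns feature, classifier, tp, tn, fp, fn and
    optionally expected metric columns (exp_accuracy, exp_f1, exp_mcc,
    exp_f_measure, exp_error_rate, exp_jaccard).  The output has one row per
    input with the recomputed (rounded) metrics; where expected values are
    supplied, boolean ``flag_*`` columns mark recomputed values differing by
    more than ``tolerance``.
    """
    required = {"feature", "classifier", "tp", "tn", "fp", "fn"}
    missing = required - set(confusions.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for _, rec in confusions.iterrows():
        cm = ConfusionMatrix(int(rec.tp), int(rec.tn), int(rec.fp), int(rec.fn))
        rep = metrics_from_confusion(cm).rounded()
        row: dict = {
            "feature": rec.feature, "classifier": rec.classifier,
            "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
            **rep.as_dict(),
        }
        for name, value in rep.as_dict().items():
            exp_col = f"exp_{name}"
            if exp_col in confusions.columns and not pd.isna(rec[exp_col]):
                row[exp_col] = float(rec[exp_col])
                row[f"flag_{name}"] = (
                    abs(value - float(rec[exp_col])) > tolerance + 1e-12
                )
        rows.append(row)
    return pd.DataFrame(rows)
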